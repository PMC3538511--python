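import numpy as np
import pytest

import gxesim as gx


@pytest.fixture
def std_env():
    """Standard-normal causal exposure with a 1.2 odds ratio per unit."""
    return gx.EnvironmentSpec(mean=0.0, sd=1.0, or_per_unit=1.2)


@pytest.fixture
def std_loci():
    """Two co-dominant DPLs, allele frequency 0.3, genotypic RR 1.6."""
    return (
        gx.LocusSpec("d1", "A", 0.3, 1.6, 0.5),
        gx.LocusSpec("d2", "C", 0.3, 1.6, 0.5),
    )


@pytest.fixture
def std_freqs():
    return gx.hwe_genotype_freqs(0.3), gx.hwe_genotype_freqs(0.3)


@pytest.fixture
def std_tri(std_loci, std_freqs):
    """Independent penetrance matrix at prevalence 0.1 for the standard loci."""
    fa, fb = std_freqs
    marg = gx.marginal_risks_from_rr(*std_loci, fa, fb, 0.1)
    return gx.independent_tr(marg)


def base_config(**overrides):
    """A small, fully valid run configuration dict for pipeline/CLI tests."""
    raw = {
        "seed": 7,
        "prevalence": 0.1,
        "gxe_model": "ADD",
        "loci": [
            {"marker_id": "d1", "high_risk_allele": "A", "allele_freq": 0.3,
             "rr": 1.6, "dominance_w": 0.5},
            {"marker_id": "d2", "high_risk_allele": "C", "allele_freq": 0.3,
             "rr": 1.6, "dominance_w": 0.5},
        ],
        "environment": {"mean": 0.0, "sd": 1.0, "or_per_unit": 1.2},
        "n_individuals": 5000,
    }
    raw.update(overrides)
    return raw


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
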