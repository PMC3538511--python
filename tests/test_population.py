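"""Genotype/exposure generation: HWE expansion, LD panel, sampling, moments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gxesim as gx
from gxesim.errors import ValidationError


@pytest.mark.parametrize(
    "q, expected",
    [
        (0.5, (0.25, 0.50, 0.25)),
        (0.0, (1.0, 0.0, 0.0)),
        (0.3, (0.49, 0.42, 0.09)),
    ],
)
def test_hwe_expansion(q, expected):
    got = gx.hwe_genotype_freqs(q).p
    assert got == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.floats(min_value=0.0, max_value=1.0))
def test_hwe_sums_to_one(q):
    assert sum(gx.hwe_genotype_freqs(q).p) == pytest.approx(1.0, abs=1e-12)


def test_hwe_rejects_out_of_range():
    with pytest.raises(ValidationError):
        gx.hwe_genotype_freqs(1.2)


def _pairwise_r2(hap, i, j):
    c = np.corrcoef(hap[:, i].astype(float), hap[:, j].astype(float))[0, 1]
    return c * c


class TestHaplotypePanel:
    def test_independence_limit(self):
        panel = gx.generate_haplotype_panel(4, [4], 0.0, [0.4] * 4, seed=1, pool_size=10_000)
        for i in range(3):
            assert _pairwise_r2(panel.haplotypes, i, i + 1) < 0.01

    def test_duplication_limit(self):
        panel = gx.generate_haplotype_panel(3, [3], 1.0, [0.3] * 3, seed=2, pool_size=2_000)
        assert np.array_equal(panel.haplotypes[:, 0], panel.haplotypes[:, 1])
        assert _pairwise_r2(panel.haplotypes, 0, 2) == pytest.approx(1.0)

    def test_adjacent_r2_matches_request(self):
        panel = gx.generate_haplotype_panel(
            10, [5, 5], 0.8, [0.3] * 10, seed=3, pool_size=20_000
        )
        adj = [
            _pairwise_r2(panel.haplotypes, i, i + 1)
            for i in list(range(4)) + list(range(5, 9))
        ]
        assert np.mean(adj) == pytest.approx(0.8, abs=0.05)

    def test_r2_decays_with_distance_and_vanishes_across_blocks(self):
        panel = gx.generate_haplotype_panel(
            10, [5, 5], 0.8, [0.3] * 10, seed=3, pool_size=20_000
        )
        within = [_pairwise_r2(panel.haplotypes, 0, k) for k in (1, 2, 3, 4)]
        assert all(a > b for a, b in zip(within, within[1:]))
        assert _pairwise_r2(panel.haplotypes, 2, 7) < 0.01

    def test_allele_freqs_match_requests(self):
        freqs = [0.1, 0.3, 0.5, 0.7]
        panel = gx.generate_haplotype_panel(
            4, [1, 1, 1, 1], 0.5, freqs, seed=4, pool_size=50_000
        )
        assert panel.allele_freqs() == pytest.approx(freqs, abs=0.01)

    def test_deterministic_given_seed(self):
        a = gx.generate_haplotype_panel(6, [3, 3], 0.5, [0.3] * 6, seed=9, pool_size=500)
        b = gx.generate_haplotype_panel(6, [3, 3], 0.5, [0.3] * 6, seed=9, pool_size=500)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.alleles == b.alleles

    def test_positions_strictly_increasing(self):
        panel = gx.generate_haplotype_panel(6, [3, 3], 0.5, [0.3] * 6, seed=9, pool_size=100)
        assert np.all(np.diff(panel.positions) > 0)
        assert panel.positions.min() >= 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_loci=4, block_lengths=[3], within_block_r2=0.5, allele_freqs=[0.3] * 4),
            dict(n_loci=2, block_lengths=[2], within_block_r2=1.5, allele_freqs=[0.3] * 2),
            dict(n_loci=2, block_lengths=[2], within_block_r2=0.5, allele_freqs=[0.0, 0.3]),
            # r^2=1 is unattainable for unequal adjacent frequencies
            dict(n_loci=2, block_lengths=[2], within_block_r2=1.0, allele_freqs=[0.1, 0.6]),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            gx.generate_haplotype_panel(seed=1, pool_size=100, **kwargs)


class TestSampling:
    def test_zero_individuals_rejected(self):
        panel = gx.generate_haplotype_panel(2, [1, 1], 0.0, [0.5] * 2, seed=1, pool_size=100)
        with pytest.raises(ValidationError):
            gx.sample_individuals(panel, 0, seed=1)

    def test_degenerate_pool_all_high_risk(self):
        panel = gx.generate_haplotype_panel(2, [1, 1], 0.0, [0.999] * 2, seed=1, pool_size=4000)
        panel.haplotypes[:] = 1  # force a monomorphic carrier pool
        spec = gx.LocusSpec("snp0001", panel.alleles[0][1], 0.999, 2.0, 0.5)
        pop = gx.sample_individuals(panel, 20, seed=1, dpl_a=spec)
        assert np.all(pop.genotype_a == 3)

    def test_genotype_proportions_match_hwe(self):
        panel = gx.generate_haplotype_panel(2, [1, 1], 0.0, [0.5] * 2, seed=5, pool_size=100_000)
        spec = gx.LocusSpec("snp0001", panel.alleles[0][1], 0.5, 2.0, 0.5)
        pop = gx.sample_individuals(panel, 50_000, seed=6, dpl_a=spec)
        props = np.bincount(pop.genotype_a, minlength=4)[1:] / pop.n
        assert props == pytest.approx((0.25, 0.5, 0.25), abs=0.015)

    def test_hwe_population_proportions_and_independence(self):
        a = gx.LocusSpec("d1", "A", 0.3, 1.6, 0.5)
        b = gx.LocusSpec("d2", "C", 0.3, 1.6, 0.5)
        pop = gx.sample_hwe_population(a, b, 200_000, seed=2)
        props = np.bincount(pop.genotype_a, minlength=4)[1:] / pop.n
        assert props == pytest.approx((0.49, 0.42, 0.09), abs=0.01)
        # cross-locus genotype codes are uncorrelated
        r = np.corrcoef(pop.genotype_a, pop.genotype_b)[0, 1]
        assert abs(r) < 0.01

    def test_dpls_in_distinct_blocks_not_in_ld(self):
        panel = gx.generate_haplotype_panel(
            4, [2, 2], 0.9, [0.3] * 4, seed=8, pool_size=20_000
        )
        assert _pairwise_r2(panel.haplotypes, 0, 2) < 0.01


class TestExposures:
    def _pop(self, n=1000, seed=1):
        a = gx.LocusSpec("d1", "A", 0.3, 1.6, 0.5)
        b = gx.LocusSpec("d2", "C", 0.3, 1.6, 0.5)
        return gx.sample_hwe_population(a, b, n, seed=seed)

    def test_degenerate_sd_collapses_to_mean(self):
        pop = gx.assign_exposures(self._pop(), gx.EnvironmentSpec(2.0, 1e-9), [], seed=1)
        assert pop.exposure == pytest.approx(2.0, abs=1e-6)

    def test_gaussian_moments(self):
        pop = gx.assign_exposures(
            self._pop(100_000), gx.EnvironmentSpec(0.0, 1.0), [], seed=2
        )
        assert pop.exposure.mean() == pytest.approx(0.0, abs=0.02)
        assert pop.exposure.std() == pytest.approx(1.0, abs=0.02)

    def test_noise_families(self):
        noise = [
            gx.NoiseVariableSpec("smoke", "binomial", {"n": 1, "p": 0.3}),
            gx.NoiseVariableSpec("diet", "uniform", {"low": -1.0, "high": 1.0}),
            gx.NoiseVariableSpec("bmi", "gaussian", {"mean": 25.0, "sd": 4.0}),
        ]
        pop = gx.assign_exposures(
            self._pop(100_000), gx.EnvironmentSpec(0.0, 1.0), noise, seed=3
        )
        assert pop.noise_exposures["smoke"].mean() == pytest.approx(0.3, abs=0.01)
        assert pop.noise_exposures["diet"].mean() == pytest.approx(0.0, abs=0.02)
        assert pop.noise_exposures["bmi"].mean() == pytest.approx(25.0, abs=0.05)
        assert set(np.unique(pop.gender)) <= {1, 2}

    def test_invalid_noise_params_rejected(self):
        with pytest.raises(ValidationError):
            gx.NoiseVariableSpec("bad", "gaussian", {"mean": 0.0, "sd": -1.0})
        with pytest.raises(ValidationError):
            gx.NoiseVariableSpec("bad", "poisson", {"lam": 2.0})

    def test_reproducible_bit_for_bit(self):
        env = gx.EnvironmentSpec(0.0, 1.0)
        noise = [gx.NoiseVariableSpec("u", "uniform", {"low": 0, "high": 1})]
        p1 = gx.assign_exposures(self._pop(seed=5), env, noise, seed=11)
        p2 = gx.assign_exposures(self._pop(seed=5), env, noise, seed=11)
        assert np.array_equal(p1.exposure, p2.exposure)
        assert np.array_equal(p1.noise_exposures["u"], p2.noise_exposures["u"])
        assert np.array_equal(p1.gender, p2.gender)


class TestEstimateFreqs:
    def test_all_heterozygotes(self):
        pop = gx.Population(
            n=4,
            genotype_a=np.full(4, 2, dtype=np.int8),
            genotype_b=np.full(4, 2, dtype=np.int8),
        )
        assert gx.estimate_dpl_freqs(pop, "a").p == (0.0, 1.0, 0.0)

    def test_direct_counting(self):
        g = np.array([1] * 49 + [2] * 42 + [3] * 9, dtype=np.int8)
        pop = gx.Population(n=100, genotype_a=g, genotype_b=g)
        assert gx.estimate_dpl_freqs(pop, "b").p == pytest.approx((0.49, 0.42, 0.09), abs=1e-15)

    def test_frequencies_sum_to_one_exactly(self, rng):
        g = rng.integers(1, 4, size=997).astype(np.int8)
        pop = gx.Population(n=997, genotype_a=g, genotype_b=g)
        assert sum(gx.estimate_dpl_freqs(pop, "a").p) == pytest.approx(1.0, abs=1e-15)

    def test_empty_population_rejected(self):
        pop = gx.Population(
            n=0,
            genotype_a=np.empty(0, dtype=np.int8),
            genotype_b=np.empty(0, dtype=np.int8),
        )
        with pytest.raises(ValidationError):
            gx.estimate_dpl_freqs(pop, "a")

    def test_unknown_selector_rejected(self):
        pop = gx.Population(
            n=1,
            genotype_a=np.array([1], dtype=np.int8),
            genotype_b=np.array([1], dtype=np.int8),
        )
        with pytest.raises(ValidationError):
            gx.estimate_dpl_freqs(pop, "c")
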