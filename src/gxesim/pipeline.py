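"""End-to-end orchestration of a simulation run.

The run has two branches that join at status assignment:

* left branch — generate (or ingest) genotypes, then draw exposures;
* right branch — translate the epidemiological parameters into the
  multi-logistic coefficients: Hardy-Weinberg (or observed) genotype
  frequencies -> marginal risks -> independent penetrance matrix ->
  epistatic deformation -> per-genotype logistic coefficients.

Genotype frequencies used by the right branch are estimated from the
generated population whenever one exists, so the designed risks refer to the
sample actually simulated.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .epistasis import DeltaMatrix, apply_delta, complete_delta
from .errors import ValidationError
from .gxe import GxeModel, PrevalenceReport, beta_from_or, check_prevalence, solve_coefficients
from .io import RunConfig
from .penetrance import (
    MarginalRisks,
    MlmCoefficients,
    PenetranceMatrix,
    independent_tr,
    marginal_risks_from_rr,
)
from .population import (
    GenotypeFrequencies,
    HaplotypePanel,
    Population,
    assign_exposures,
    estimate_dpl_freqs,
    generate_haplotype_panel,
    hwe_genotype_freqs,
    sample_hwe_population,
    sample_individuals,
)
from .simulate import CaseControlSample, assign_status, subsample_case_control


@dataclass
class RunArtifacts:
    """Every intermediate quantity of the parameterization, for the run log."""

    config_echo: dict
    freqs_a: GenotypeFrequencies
    freqs_b: GenotypeFrequencies
    marg: MarginalRisks
    tri: PenetranceMatrix
    delta: DeltaMatrix
    tre: PenetranceMatrix
    coeffs: MlmCoefficients
    prevalence_report: PrevalenceReport
    notes: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)


def _config_echo(config: RunConfig) -> dict:
    echo = {
        "seed": config.seed,
        "prevalence": config.prevalence,
        "gxe_model": config.gxe_model.value,
        "environment": f"Gaussian(mean={config.environment.mean}, sd={config.environment.sd}), OR={config.environment.or_per_unit}",
        "n_individuals": config.n_individuals,
        "output_format": config.output_format,
    }
    for tag, spec in zip("ab", config.loci):
        echo[f"dpl_{tag}"] = (
            f"{spec.marker_id} high_risk={spec.high_risk_allele} "
            f"freq={spec.allele_freq} rr={spec.rr} w={spec.w}"
        )
    echo["epistasis"] = [
        (e.row, e.col, e.percent) for e in config.epistasis.entries
    ] or "none"
    echo["noise"] = [f"{nv.name}({nv.family})" for nv in config.noise] or "none"
    return echo


def parameterize(
    config: RunConfig,
    freqs_a: GenotypeFrequencies | None = None,
    freqs_b: GenotypeFrequencies | None = None,
) -> RunArtifacts:
    """Right branch: epidemiological parameters -> logistic coefficients.

    When genotype frequencies are not supplied they are taken as
    Hardy-Weinberg proportions of the configured allele frequencies.
    """
    t0 = time.perf_counter()
    spec_a, spec_b = config.loci
    if freqs_a is None:
        freqs_a = hwe_genotype_freqs(spec_a.allele_freq)
    if freqs_b is None:
        freqs_b = hwe_genotype_freqs(spec_b.allele_freq)
    marg = marginal_risks_from_rr(spec_a, spec_b, freqs_a, freqs_b, config.prevalence)
    tri = independent_tr(marg)
    delta = complete_delta(tri, freqs_a, freqs_b, config.epistasis)
    tre = apply_delta(tri, delta)
    beta_ab = beta_from_or(config.environment.or_per_unit)
    coeffs = solve_coefficients(tre, config.environment, config.gxe_model, beta_ab)
    report = check_prevalence(coeffs, freqs_a, freqs_b, config.environment, config.prevalence)
    artifacts = RunArtifacts(
        config_echo=_config_echo(config),
        freqs_a=freqs_a,
        freqs_b=freqs_b,
        marg=marg,
        tri=tri,
        delta=delta,
        tre=tre,
        coeffs=coeffs,
        prevalence_report=report,
        notes=list(delta.notes),
    )
    artifacts.timings["parameterize"] = time.perf_counter() - t0
    return artifacts


def build_population(config: RunConfig) -> Population:
    """Left branch: genotypes (panel-based or direct HWE) plus exposures."""
    spec_a, spec_b = config.loci
    if config.use_panel:
        panel = build_panel(config)
        pop = sample_individuals(
            panel, config.n_individuals, config.seed, dpl_a=spec_a, dpl_b=spec_b
        )
    else:
        pop = sample_hwe_population(spec_a, spec_b, config.n_individuals, config.seed)
    return assign_exposures(pop, config.environment, list(config.noise), config.seed)


def build_panel(config: RunConfig) -> HaplotypePanel:
    """Generate the background haplotype panel described by the config.

    The two DPLs keep their configured high-risk alleles and allele
    frequencies; other loci default to frequency 0.3 unless given.
    """
    n_loci = config.panel_n_loci
    if config.panel_allele_freqs is not None:
        freqs = list(config.panel_allele_freqs)
    else:
        freqs = [0.3] * n_loci
    ids = [f"snp{j + 1:04d}" for j in range(n_loci)]
    dpl_idx = {}
    for spec in config.loci:
        j = ids.index(spec.marker_id)
        freqs[j] = spec.allele_freq  # allele 1 at a DPL is its high-risk allele
        dpl_idx[j] = spec
    block_of = np.repeat(
        np.arange(len(config.panel_block_lengths)), config.panel_block_lengths
    )
    ja, jb = sorted(dpl_idx)
    if block_of[ja] == block_of[jb] and config.panel_within_block_r2 > 0:
        raise ValidationError(
            "the two DPLs must lie in different LD blocks (they are assumed "
            "not to be in LD)"
        )
    panel = generate_haplotype_panel(
        n_loci=n_loci,
        block_lengths=list(config.panel_block_lengths),
        within_block_r2=config.panel_within_block_r2,
        allele_freqs=freqs,
        seed=config.seed,
        pool_size=config.panel_pool_size,
        marker_ids=ids,
    )
    for j, spec in dpl_idx.items():
        other = next(a for a in "ACGT" if a != spec.high_risk_allele)
        panel.alleles[j] = (other, spec.high_risk_allele)
    return panel


def run(config: RunConfig) -> tuple[Population, RunArtifacts, list[CaseControlSample]]:
    """Full pipeline: population, solved model, status, optional subsamples."""
    t0 = time.perf_counter()
    pop = build_population(config)
    t1 = time.perf_counter()
    artifacts = parameterize(
        config,
        freqs_a=estimate_dpl_freqs(pop, "a"),
        freqs_b=estimate_dpl_freqs(pop, "b"),
    )
    t2 = time.perf_counter()
    assign_status(pop, artifacts.coeffs, config.seed)
    samples: list[CaseControlSample] = []
    if config.n_cases is not None and config.n_controls is not None:
        samples = subsample_case_control(
            pop, config.n_cases, config.n_controls, config.n_replicates, config.seed
        )
    artifacts.timings["population"] = t1 - t0
    artifacts.timings["status+subsample"] = time.perf_counter() - t2
    return pop, artifacts, samples
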