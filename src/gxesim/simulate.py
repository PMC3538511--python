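"""Join genotypes, exposures and the solved risk model into disease status.

Each individual's risk is the logistic curve of its combined genotype
evaluated at its exposure; status is affected when a uniform(0,1) draw falls
below the risk.  Case-control datasets of fixed sizes are then drawn without
replacement, independently across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import rng_for
from .errors import ValidationError
from .penetrance import MlmCoefficients, _sigmoid
from .population import Population


@dataclass(frozen=True)
class CaseControlSample:
    """Index sets of one case-control replicate drawn from a population."""

    cases: np.ndarray
    controls: np.ndarray
    replicate_id: int


def individual_risks(pop: Population, coeffs: MlmCoefficients) -> np.ndarray:
    """Per-individual disease risk under the multi-logistic model."""
    if pop.exposure is None:
        raise ValidationError("exposures must be assigned before computing risks")
    ia = pop.genotype_a - 1
    ib = pop.genotype_b - 1
    return _sigmoid(coeffs.alpha[ia, ib] + coeffs.beta[ia, ib] * pop.exposure)


def assign_status(pop: Population, coeffs: MlmCoefficients, seed: int) -> Population:
    """Assign affected (1) / unaffected (0) status by a per-individual
    uniform draw compared against the modelled risk."""
    risk = individual_risks(pop, coeffs)
    u = rng_for(seed, "status").random(pop.n)
    pop.status = (u < risk).astype(np.int8)
    return pop


@dataclass(frozen=True)
class PenetranceEstimate:
    """Observed affected fraction per combined genotype, with carrier counts.

    Cells with no carriers hold NaN in ``fraction`` and are flagged in
    ``empty``.
    """

    fraction: np.ndarray
    carriers: np.ndarray
    empty: np.ndarray


def empirical_penetrance(pop: Population) -> PenetranceEstimate:
    """Observed penetrance of each combined genotype in a simulated population."""
    if pop.status is None:
        raise ValidationError("disease status must be assigned first")
    carriers = np.zeros((3, 3), dtype=np.int64)
    affected = np.zeros((3, 3), dtype=np.int64)
    ia = pop.genotype_a - 1
    ib = pop.genotype_b - 1
    np.add.at(carriers, (ia, ib), 1)
    np.add.at(affected, (ia, ib), pop.status.astype(np.int64))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(carriers > 0, affected / np.maximum(carriers, 1), np.nan)
    return PenetranceEstimate(fraction=frac, carriers=carriers, empty=carriers == 0)


def marginal_penetrance(pop: Population, which: str) -> np.ndarray:
    """Observed affected fraction by genotype code at one DPL ('a' or 'b')."""
    if pop.status is None:
        raise ValidationError("disease status must be assigned first")
    if which not in ("a", "b"):
        raise ValidationError(f"locus selector must be 'a' or 'b', got {which!r}")
    g = pop.genotype_a if which == "a" else pop.genotype_b
    out = np.full(3, np.nan)
    for code in (1, 2, 3):
        mask = g == code
        if mask.any():
            out[code - 1] = pop.status[mask].mean()
    return out


def subsample_case_control(
    pop: Population,
    n_cases: int,
    n_controls: int,
    n_replicates: int,
    seed: int,
) -> list[CaseControlSample]:
    """Draw case-control replicates without replacement within a replicate.

    Replicates are independent draws from the same simulated population
    (sampling from an ideal infinite population with the designed features),
    enabling bootstrap-style repetition of an analysis.
    """
    if pop.status is None:
        raise ValidationError("disease status must be assigned before subsampling")
    if n_cases < 1 or n_controls < 1 or n_replicates < 1:
        raise ValidationError("case, control and replicate counts must all be >= 1")
    case_idx = np.flatnonzero(pop.status == 1)
    control_idx = np.flatnonzero(pop.status == 0)
    if case_idx.size < n_cases or control_idx.size < n_controls:
        raise ValidationError(
            f"population holds {case_idx.size} cases and {control_idx.size} "
            f"controls; requested {n_cases}+{n_controls}. Re-simulate with a "
            "larger base population."
        )
    out = []
    for r in range(n_replicates):
        rng = rng_for(seed, "subsample", r)
        cases = np.sort(rng.choice(case_idx, size=n_cases, replace=False))
        controls = np.sort(rng.choice(control_idx, size=n_controls, replace=False))
        out.append(CaseControlSample(cases=cases, controls=controls, replicate_id=r))
    return out
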