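"""The multi-logistic penetrance model and the independent two-locus matrix.

Each combined genotype (g_a, g_b), with codes 1..3 per locus and 3 the
high-risk homozygote, carries its own logistic risk curve in the exposure x:

    P(affected | g_a, g_b, x) = 1 / (1 + exp(-(alpha(g_a,g_b) + beta(g_a,g_b) x)))

Sign convention: risk INCREASES in alpha + beta*x, so beta equals the natural
log of the odds ratio per unit exposure — odds(x+1)/odds(x) = exp(beta)
exactly.

The total risk (penetrance) of a combined genotype is the expectation of that
curve over the Gaussian exposure density; it is evaluated here by
Gauss-Hermite quadrature.  From prevalence, per-locus relative risks and
dominance weights we build per-locus marginal risks, and from those the
independent (no-epistasis) 3x3 penetrance matrix TR_I(ga,gb) =
TR_ga * TR_gb / m, which reproduces the prevalence and both sets of marginals
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InfeasibleParametersError, ValidationError
from .population import EnvironmentSpec, GenotypeFrequencies, LocusSpec

# 256-node Gauss-Hermite rule: worst-case error below 1e-8 for the
# Gaussian-weighted logistic integrand with |beta|*sd up to ~6.
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(256)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(np.pi)


class CombinedGenotype(NamedTuple):
    """Pair of genotype codes, each in {1, 2, 3}; 3 is the high-risk homozygote."""

    ga: int
    gb: int


@dataclass(frozen=True)
class MlmCoefficients:
    """Per-combined-genotype logistic coefficients.

    ``alpha`` and ``beta`` are 3x3 arrays indexed [ga-1, gb-1]; ``beta_ab`` is
    the conventionally fixed slope attached to the highest-risk combined
    genotype, equal to ln(OR) of the environmental exposure.
    """

    alpha: np.ndarray
    beta: np.ndarray
    beta_ab: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            m = getattr(self, name)
            if np.asarray(m).shape != (3, 3) or not np.all(np.isfinite(m)):
                raise ValidationError(f"{name} must be a finite 3x3 matrix")


@dataclass(frozen=True)
class PenetranceMatrix:
    """3x3 total risks TR(ga, gb); ``kind`` tags its provenance."""

    tr: np.ndarray
    kind: str = "independent"  # independent | epistatic | user

    def __post_init__(self) -> None:
        t = np.asarray(self.tr, dtype=float)
        if t.shape != (3, 3):
            raise ValidationError("penetrance matrix must be 3x3")
        if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
            raise ValidationError("penetrance entries must lie in [0,1]")
        object.__setattr__(self, "tr", t)


@dataclass(frozen=True)
class MarginalRisks:
    """Per-locus marginal penetrances and the prevalence they average to."""

    tr_a: np.ndarray
    tr_b: np.ndarray
    m: float

    def validate(self, freqs_a: GenotypeFrequencies, freqs_b: GenotypeFrequencies) -> None:
        for tr, fr, tag in ((self.tr_a, freqs_a, "A"), (self.tr_b, freqs_b, "B")):
            if abs(float(tr @ fr.as_array()) - self.m) > 1e-10:
                raise ValidationError(
                    f"marginal risks of locus {tag} do not average to the prevalence"
                )


def logistic_risk(coeffs: MlmCoefficients, g: CombinedGenotype, x: float) -> float:
    """Disease risk of combined genotype ``g`` at exposure ``x``."""
    a = coeffs.alpha[g.ga - 1, g.gb - 1]
    b = coeffs.beta[g.ga - 1, g.gb - 1]
    return _sigmoid(a + b * np.asarray(x, dtype=float))


def _sigmoid(t):
    # numerically stable logistic, scalar in -> float out
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        ex = np.exp(t)
        res = np.where(t >= 0, 1.0 / (1.0 + np.exp(-t)), ex / (1.0 + ex))
    return float(res) if res.ndim == 0 else res


def expected_penetrance(alpha: float, beta: float, env: EnvironmentSpec) -> float:
    """Expectation of the logistic risk over the Gaussian exposure density.

    Gauss-Hermite quadrature on the untruncated real line with the change of
    variables x = mean + sqrt(2)*sd*t.
    """
    x = env.mean + np.sqrt(2.0) * env.sd * _GH_NODES
    return float(_GH_WEIGHTS @ _sigmoid(alpha + beta * x))


def marginal_risks_from_rr(
    spec_a: LocusSpec,
    spec_b: LocusSpec,
    freqs_a: GenotypeFrequencies,
    freqs_b: GenotypeFrequencies,
    m: float,
) -> MarginalRisks:
    """Translate per-locus RR and dominance into marginal penetrances.

    Per locus the three genotype risks are (t, [w + (1-w)*rr]*t, rr*t): the
    dominance weight w linearly interpolates the heterozygote risk between
    the high-risk homozygote (w=0, dominant) and the low-risk homozygote
    (w=1, recessive).  The scale t is fixed by requiring the
    frequency-weighted risks to average to the prevalence m.
    """
    if not 0.0 < m < 1.0:
        raise ValidationError(f"prevalence must be in (0,1), got {m}")
    out = []
    for spec, freqs in ((spec_a, freqs_a), (spec_b, freqs_b)):
        c = np.array([1.0, spec.w + (1.0 - spec.w) * spec.rr, spec.rr])
        t = m / float(c @ freqs.as_array())
        tr = c * t
        if np.any(tr > 1.0 + 1e-12):
            raise InfeasibleParametersError(
                f"locus {spec.marker_id!r}: implied genotype risk "
                f"{tr.max():.4f} exceeds 1 (rr={spec.rr}, w={spec.w}, m={m})"
            )
        out.append(tr)
    marg = MarginalRisks(tr_a=out[0], tr_b=out[1], m=float(m))
    marg.validate(freqs_a, freqs_b)
    return marg


def independent_tr(marg: MarginalRisks) -> PenetranceMatrix:
    """Independent-model penetrance matrix TR_I(ga,gb) = TR_ga * TR_gb / m."""
    tr = np.outer(marg.tr_a, marg.tr_b) / marg.m
    if np.any(tr > 1.0 + 1e-12):
        i, j = np.unravel_index(int(np.argmax(tr)), tr.shape)
        raise InfeasibleParametersError(
            f"independent-model penetrance at combined genotype ({i + 1},{j + 1}) "
            f"is {tr[i, j]:.4f} > 1; reduce RRs or prevalence"
        )
    return PenetranceMatrix(tr=tr, kind="independent")


def prevalence_of(
    tr: PenetranceMatrix | np.ndarray,
    freqs_a: GenotypeFrequencies,
    freqs_b: GenotypeFrequencies,
) -> float:
    """Population prevalence implied by a penetrance matrix."""
    t = tr.tr if isinstance(tr, PenetranceMatrix) else np.asarray(tr, dtype=float)
    return float(freqs_a.as_array() @ t @ freqs_b.as_array())


def marginals_of(
    tr: PenetranceMatrix | np.ndarray,
    freqs_a: GenotypeFrequencies,
    freqs_b: GenotypeFrequencies,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus marginal penetrances implied by a penetrance matrix."""
    t = tr.tr if isinstance(tr, PenetranceMatrix) else np.asarray(tr, dtype=float)
    return t @ freqs_b.as_array(), t.T @ freqs_a.as_array()
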