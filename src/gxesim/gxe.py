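"""Translate a target penetrance matrix into multi-logistic coefficients.

Every combined genotype must satisfy the integral constraint

    E_x[ sigmoid(alpha(g) + beta(g) x) ] = TR(g),   x ~ Gaussian exposure,

which alone leaves one degree of freedom per cell.  The chosen gene-by-
environment model closes the system:

GEN   genetics only:      beta(g) = 0, alpha(g) = logit(TR(g))        (closed form)
ENV   environment only:   one shared (alpha, beta = beta_AB); requires a
                          constant TR matrix (no genetic effect)
ADD   additive:           beta(g) = beta_AB for all cells; per-cell alpha
GEM   modulative:         shared alpha; per-cell beta, with beta_AB pinned
                          at the highest-risk combined genotype

beta_AB = ln(environmental odds ratio per unit exposure) is attached by
convention to the highest-risk cell of the final TR matrix.

The ADD and ENV solves are independent 1-D root-finds in alpha (the expected
penetrance is strictly increasing in alpha).  GEM looks like a 9-unknown
system but is triangular: the pinned cell's equation involves only the shared
alpha, and every remaining equation involves only alpha and its own beta, so
sequential Brent root-finds give the exact solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, ModelInconsistencyError, ValidationError
from .penetrance import (
    MlmCoefficients,
    PenetranceMatrix,
    _sigmoid,
    expected_penetrance,
)
from .population import EnvironmentSpec, GenotypeFrequencies

_ALPHA_TOL = 1e-12
_ENV_CONST_TOL = 1e-9


class GxeModel(str, Enum):
    """The four predefined gene-environment interaction models."""

    GEN = "GEN"  # risk depends on genetics only
    ENV = "ENV"  # risk depends on environment only
    GEM = "GEM"  # genetics modulates the environmental effect
    ADD = "ADD"  # genetic and environmental effects add on the logit scale


def beta_from_or(or_per_unit: float) -> float:
    """ln(OR) per unit exposure — the slope pinned at the highest-risk genotype."""
    if not or_per_unit > 0:
        raise ValidationError(f"odds ratio must be > 0, got {or_per_unit}")
    return float(np.log(or_per_unit))


def highest_risk_cell(tr: np.ndarray) -> tuple[int, int]:
    """Argmax cell of a TR matrix, 0-based; ties prefer (3,3) then row-major."""
    mx = tr.max()
    if tr[2, 2] == mx:
        return 2, 2
    flat = int(np.argmax(tr))
    return flat // 3, flat % 3


def _solve_alpha(target: float, beta: float, env: EnvironmentSpec) -> float:
    """alpha such that the expected penetrance equals ``target`` (monotone)."""
    lo, hi = -40.0, 40.0
    f = lambda a: expected_penetrance(a, beta, env) - target
    while f(lo) > 0 and lo > -1e4:
        lo *= 2
    while f(hi) < 0 and hi < 1e4:
        hi *= 2
    if f(lo) > 0 or f(hi) < 0:
        raise ConvergenceError(
            f"cannot bracket alpha for target risk {target} with beta={beta}"
        )
    return float(brentq(f, lo, hi, xtol=_ALPHA_TOL))


def _solve_beta(target: float, alpha: float, sign: float, env: EnvironmentSpec) -> float:
    """|beta| (signed by ``sign``) such that E[risk] = target at fixed alpha.

    At beta=0 the expectation is sigmoid(alpha); growing |beta| moves it
    monotonically toward the large-slope limit.  Targets outside that band
    are unattainable at this alpha and raise a diagnostic error.
    """
    if sign == 0.0:
        sign = 1.0
    limits = []
    for s in (sign, -sign):  # prefer the pinned slope's sign, then the other
        f = lambda b: expected_penetrance(alpha, s * b, env) - target
        at0 = f(0.0)
        if abs(at0) < 1e-14:
            return 0.0
        hi = 1.0
        while f(hi) * at0 > 0 and hi < 1e4:
            hi *= 2
        if f(hi) * at0 > 0:
            limits.append(expected_penetrance(alpha, s * hi, env))
            continue
        return float(s * brentq(f, 0.0, hi, xtol=_ALPHA_TOL))
    lo = min([_sigmoid(alpha), *limits])
    hi_r = max([_sigmoid(alpha), *limits])
    raise ConvergenceError(
        f"target risk {target:.6f} is unattainable at shared alpha={alpha:.4f}: "
        f"attainable range is [{lo:.6f}, {hi_r:.6f}] for any slope"
    )


def solve_coefficients(
    tr: PenetranceMatrix,
    env: EnvironmentSpec,
    model: GxeModel,
    beta_ab: float,
) -> MlmCoefficients:
    """Find the 3x3 (alpha, beta) pairs realising ``tr`` under ``model``."""
    model = GxeModel(model)
    t = tr.tr
    if np.any(t <= 0.0) or np.any(t >= 1.0):
        raise ConvergenceError(
            "every penetrance entry must lie strictly in (0,1); the logistic "
            "curve cannot attain 0 or 1"
        )

    if model is GxeModel.GEN:
        alpha = np.log(t / (1.0 - t))
        return MlmCoefficients(alpha=alpha, beta=np.zeros((3, 3)), beta_ab=0.0)

    if model is GxeModel.ENV:
        if float(t.max() - t.min()) > _ENV_CONST_TOL:
            raise ModelInconsistencyError(
                "ENV model requires a constant penetrance matrix (no genetic "
                f"effect); spread is {t.max() - t.min():.3e}"
            )
        a = _solve_alpha(float(t.mean()), beta_ab, env)
        return MlmCoefficients(
            alpha=np.full((3, 3), a), beta=np.full((3, 3), beta_ab), beta_ab=beta_ab
        )

    if model is GxeModel.ADD:
        alpha = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                alpha[i, j] = _solve_alpha(t[i, j], beta_ab, env)
        return MlmCoefficients(alpha=alpha, beta=np.full((3, 3), beta_ab), beta_ab=beta_ab)

    # GEM: shared alpha from the pinned highest-risk cell, then per-cell beta
    pin = highest_risk_cell(t)
    a = _solve_alpha(t[pin], beta_ab, env)
    beta = np.empty((3, 3))
    sign = float(np.sign(beta_ab)) or 1.0
    for i in range(3):
        for j in range(3):
            beta[i, j] = beta_ab if (i, j) == pin else _solve_beta(t[i, j], a, sign, env)
    return MlmCoefficients(alpha=np.full((3, 3), a), beta=beta, beta_ab=beta_ab)


@dataclass(frozen=True)
class PrevalenceReport:
    """Diagnostic comparing the coefficient-implied prevalence to the target."""

    implied: float
    target: float
    residual: float
    passed: bool


def check_prevalence(
    coeffs: MlmCoefficients,
    freqs_a: GenotypeFrequencies,
    freqs_b: GenotypeFrequencies,
    env: EnvironmentSpec,
    m: float,
    tol: float = 1e-7,
) -> PrevalenceReport:
    """Recompute prevalence from the solved coefficients and report the residual."""
    ep = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            ep[i, j] = expected_penetrance(coeffs.alpha[i, j], coeffs.beta[i, j], env)
    implied = float(freqs_a.as_array() @ ep @ freqs_b.as_array())
    residual = implied - m
    return PrevalenceReport(
        implied=implied, target=m, residual=residual, passed=abs(residual) < tol
    )
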