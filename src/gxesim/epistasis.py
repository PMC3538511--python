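"""Epistatic deformation of the independent penetrance matrix.

Epistasis is modelled as a departure from the independent two-locus model:
TR_E = TR_I + Delta, where the 3x3 increment matrix Delta must leave every
marginal genotype risk — and hence the prevalence — unchanged.  With P_ga and
P_gb the genotype frequencies of the two loci, that means

    sum_gb Delta(ga, gb) * P_gb = 0   for every row ga,
    sum_ga Delta(ga, gb) * P_ga = 0   for every column gb,

plus the box condition 0 <= TR_I + Delta <= 1 entrywise.

The user pins at most three cells, given as percentage changes of the
independent-model risk, under the placement rule that any pair of pinned
cells shares a row or a column.  Remaining cells are completed by minimising
the variance of the ratios Delta/TR_I over the non-user cells — the flattest
relative perturbation consistent with the constraints — a convex quadratic
program solved exactly by null-space elimination (the feasible set is affine
and tiny), with an SLSQP fallback only if the interior optimum violates a box
bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .errors import InfeasibleParametersError, PlacementError, ValidationError
from .penetrance import PenetranceMatrix
from .population import GenotypeFrequencies

MAX_USER_CELLS = 3
_CONSTRAINT_TOL = 1e-9


@dataclass(frozen=True)
class EpistasisCell:
    """One user-pinned cell: genotype codes (1..3) and a percent risk change."""

    row: int
    col: int
    percent: float

    def __post_init__(self) -> None:
        if self.row not in (1, 2, 3) or self.col not in (1, 2, 3):
            raise ValidationError(
                f"epistatic cell coordinates must be genotype codes 1..3, "
                f"got ({self.row},{self.col})"
            )
        if not self.percent > -100.0:
            raise ValidationError(
                f"percent change must exceed -100 (risk cannot go negative), "
                f"got {self.percent}"
            )


@dataclass(frozen=True)
class EpistasisSpec:
    """Up to three pinned cells; any pair must share a row or a column."""

    entries: tuple[EpistasisCell, ...] = ()

    @classmethod
    def from_dicts(cls, entries: list[dict]) -> "EpistasisSpec":
        return cls(tuple(EpistasisCell(int(e["row"]), int(e["col"]), float(e["percent"])) for e in entries))


@dataclass
class DeltaMatrix:
    """The epistatic increments and the mask of user-pinned cells."""

    delta: np.ndarray
    user_mask: np.ndarray
    notes: list[str] = field(default_factory=list)

    def validate(
        self,
        tri: PenetranceMatrix,
        freqs_a: GenotypeFrequencies,
        freqs_b: GenotypeFrequencies,
        tol: float = _CONSTRAINT_TOL,
    ) -> None:
        """Raise unless the marginal-preservation and box conditions hold."""
        d = self.delta
        pa, pb = freqs_a.as_array(), freqs_b.as_array()
        if np.max(np.abs(d @ pb)) > tol or np.max(np.abs(d.T @ pa)) > tol:
            raise InfeasibleParametersError(
                "increment matrix does not preserve the marginal risks"
            )
        tre = tri.tr + d
        if np.any(tre < -tol) or np.any(tre > 1.0 + tol):
            raise InfeasibleParametersError(
                "deformed penetrance leaves [0,1] at cell "
                f"{np.unravel_index(int(np.argmax(np.abs(tre - 0.5))), (3, 3))}"
            )


def validate_epistasis_spec(spec: EpistasisSpec) -> EpistasisSpec:
    """Enforce the cell-count, duplication and placement rules."""
    entries = spec.entries
    if len(entries) > MAX_USER_CELLS:
        raise ValidationError(
            f"at most {MAX_USER_CELLS} epistatic cells may be specified, "
            f"got {len(entries)}"
        )
    seen = set()
    for e in entries:
        if (e.row, e.col) in seen:
            raise ValidationError(f"duplicate epistatic cell ({e.row},{e.col})")
        seen.add((e.row, e.col))
    for i, e1 in enumerate(entries):
        for e2 in entries[i + 1 :]:
            if e1.row != e2.row and e1.col != e2.col:
                raise PlacementError(
                    f"epistatic cells ({e1.row},{e1.col}) and ({e2.row},{e2.col}) "
                    "share neither a row nor a column"
                )
    return spec


def _constraint_system(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """6x9 matrix of the row/column zero-sum conditions, cells row-major."""
    a = np.zeros((6, 9))
    for r in range(3):
        a[r, 3 * r : 3 * r + 3] = pb
    for c in range(3):
        a[3 + c, c::3] = pa
    return a


def _ratio_variance(d_free: np.ndarray, tr_free: np.ndarray) -> float:
    r = d_free / tr_free
    return float(np.var(r))


def complete_delta(
    tri: PenetranceMatrix,
    freqs_a: GenotypeFrequencies,
    freqs_b: GenotypeFrequencies,
    spec: EpistasisSpec,
) -> DeltaMatrix:
    """Complete the increment matrix from the user-pinned cells.

    User cells are honoured exactly; free cells solve the variance-of-ratios
    program subject to the marginal-preservation equalities and the [0,1]
    box on the deformed penetrance.  The solution is unique and deterministic:
    the objective is convex quadratic on an affine feasible set (the minimum-
    norm minimiser is returned when the quadratic is degenerate along the
    feasible directions).
    """
    spec = validate_epistasis_spec(spec)
    tr = tri.tr.flatten()
    pa, pb = freqs_a.as_array(), freqs_b.as_array()
    a_full = _constraint_system(pa, pb)

    notes: list[str] = []
    fixed = np.full(9, np.nan)
    user_mask = np.zeros(9, dtype=bool)
    for e in spec.entries:
        k = 3 * (e.row - 1) + (e.col - 1)
        fixed[k] = (e.percent / 100.0) * tr[k]
        user_mask[k] = True
    # cells with zero independent risk have an undefined ratio: pin them to 0
    for k in np.flatnonzero((tr == 0.0) & ~user_mask):
        fixed[k] = 0.0
        user_mask[k] = True
        notes.append(
            f"cell ({k // 3 + 1},{k % 3 + 1}) has zero independent risk; "
            "increment pinned to 0"
        )

    lo = -tr
    hi = 1.0 - tr
    bad = np.flatnonzero(
        user_mask & ((fixed < lo - _CONSTRAINT_TOL) | (fixed > hi + _CONSTRAINT_TOL))
    )
    if bad.size:
        k = int(bad[0])
        raise InfeasibleParametersError(
            f"user increment at cell ({k // 3 + 1},{k % 3 + 1}) pushes the "
            f"penetrance outside [0,1] (value {tr[k] + fixed[k]:.4f})"
        )

    free = ~user_mask
    b = -a_full[:, user_mask] @ fixed[user_mask]
    a_f = a_full[:, free]

    if not free.any():
        d = fixed.copy()
        resid = a_full @ d
        if np.max(np.abs(resid)) > _CONSTRAINT_TOL:
            raise InfeasibleParametersError(
                "user increments violate marginal preservation; worst residual "
                f"{np.max(np.abs(resid)):.3e} on constraint {int(np.argmax(np.abs(resid)))}"
            )
        return _package(d, user_mask, tri, freqs_a, freqs_b, notes)

    # minimum-norm particular solution of the equality system
    u0, *_ = np.linalg.lstsq(a_f, b, rcond=None)
    resid = a_f @ u0 - b
    if np.max(np.abs(resid)) > _CONSTRAINT_TOL:
        worst = int(np.argmax(np.abs(resid)))
        kind = "row" if worst < 3 else "column"
        raise InfeasibleParametersError(
            f"user increments are inconsistent with marginal preservation: "
            f"{kind} constraint {worst % 3 + 1} has residual {resid[worst]:.3e}"
        )

    nsp = scipy.linalg.null_space(a_f)
    tr_free = tr[free]
    if nsp.shape[1] == 0:
        u = u0
        notes.append("equality constraints fully determine the free cells")
    else:
        # variance of ratios r = D(u0 + N z):  min over z of r' M r with
        # M = (I - 11'/k)/k; convex quadratic, solved by least squares.
        k = tr_free.size
        m_c = (np.eye(k) - np.ones((k, k)) / k) / k
        dmat = np.diag(1.0 / tr_free)
        h = nsp.T @ dmat @ m_c @ dmat @ nsp
        g = nsp.T @ dmat @ m_c @ dmat @ u0
        z, *_ = np.linalg.lstsq(h, -g, rcond=None)
        u = u0 + nsp @ z

    d = fixed.copy()
    d[free] = u
    slack = 1e-12
    if np.any(d < lo - slack) or np.any(d > hi + slack):
        d = _box_constrained_solve(a_f, b, nsp, u0, tr_free, lo, hi, free, fixed)
        notes.append("box constraints active; solved with SLSQP fallback")
    return _package(d, user_mask, tri, freqs_a, freqs_b, notes)


def _box_constrained_solve(a_f, b, nsp, u0, tr_free, lo, hi, free, fixed):
    """Active-box fallback: minimise the ratio variance with SLSQP."""

    def obj(u):
        return _ratio_variance(u, tr_free)

    def jac(u):
        r = u / tr_free
        k = r.size
        return (2.0 / k) * (r - r.mean()) / tr_free

    start = np.clip(u0, lo[free] + 1e-12, hi[free] - 1e-12)
    res = scipy.optimize.minimize(
        obj,
        start,
        jac=jac,
        method="SLSQP",
        bounds=list(zip(lo[free], hi[free])),
        constraints=[{"type": "eq", "fun": lambda u: a_f @ u - b, "jac": lambda u: a_f}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    u = res.x
    if np.max(np.abs(a_f @ u - b)) > _CONSTRAINT_TOL:
        raise InfeasibleParametersError(
            "no increment matrix satisfies the marginal-preservation and [0,1] "
            "conditions with the requested user cells (binding box constraint)"
        )
    d = fixed.copy()
    d[free] = u
    return d


def _package(d, user_mask, tri, freqs_a, freqs_b, notes) -> DeltaMatrix:
    out = DeltaMatrix(
        delta=d.reshape(3, 3), user_mask=user_mask.reshape(3, 3), notes=notes
    )
    out.validate(tri, freqs_a, freqs_b)
    return out


def apply_delta(tri: PenetranceMatrix, delta: DeltaMatrix) -> PenetranceMatrix:
    """Deform the independent matrix: TR_E = TR_I + Delta, entrywise."""
    tre = tri.tr + delta.delta
    if np.any(tre < -_CONSTRAINT_TOL) or np.any(tre > 1.0 + _CONSTRAINT_TOL):
        raise InfeasibleParametersError("deformed penetrance leaves [0,1]")
    return PenetranceMatrix(tr=np.clip(tre, 0.0, 1.0), kind="epistatic")
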