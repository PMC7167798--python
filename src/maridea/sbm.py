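"""Non-oriented slacks-based measure (SBM) of efficiency.

The SBM score of a unit (x0, y0) against a technology spanned by reference
observations (X, Y) is the fractional program

    rho = min  (1 - (1/m) Σ_i s-_i / x0_i) / (1 + (1/q) Σ_r s+_r / y0_r)
    s.t.  x0 = Xλ + s-,   y0 = Yλ - s+,   λ, s-, s+ >= 0
          (Σλ = 1 under variable returns)

rho lies in (0, 1] and equals 1 exactly when all slacks vanish, i.e. the
unit sits on the frontier.  The score is non-radial (it penalises every
individual input excess and output shortfall) and units-invariant.

The fractional program is linearized by the Charnes-Cooper substitution:
multiply all variables by a scalar t chosen so the denominator equals 1.
We additionally normalize the data by the target (a_ij = x_ij / x0_i,
b_rj = y_rj / y0_r), which makes the LP coefficient matrix literally
independent of measurement units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .panel import ReferenceSet

__all__ = ["SBMResult", "sbm_score", "SLACK_TOL"]

#: slacks below this (in normalized units) count as zero when classifying
SLACK_TOL = 1e-6


@dataclass(frozen=True)
class SBMResult:
    """Optimal SBM score with supporting slacks and intensity weights.

    ``input_slacks`` (s-) and ``output_slacks`` (s+) are in the original
    units of each indicator; ``weights`` is the intensity vector λ over the
    reference members.  At an optimum the feasibility identities
    ``x0 = Xλ + s-`` and ``y0 = Yλ - s+`` hold to solver tolerance.
    """

    score: float
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    weights: np.ndarray
    solver_status: str  # "optimal" | "infeasible" | "numeric-failure"

    @property
    def is_efficient(self) -> bool:
        return self.solver_status == "optimal" and self.score >= 1.0 - SLACK_TOL


def _check_target(x0: np.ndarray, y0: np.ndarray, reference: ReferenceSet) -> None:
    if x0.shape != (reference.X.shape[0],) or y0.shape != (reference.Y.shape[0],):
        raise ValueError(
            f"dimension mismatch: target ({x0.shape[0]} in / {y0.shape[0]} out) vs "
            f"reference ({reference.X.shape[0]} in / {reference.Y.shape[0]} out)"
        )
    if not (np.all(x0 > 0) and np.all(y0 > 0)):
        raise ValueError("target inputs and outputs must be strictly positive")


def sbm_score(target: tuple[np.ndarray, np.ndarray],
              reference: ReferenceSet) -> SBMResult:
    """Score a unit with the non-oriented SBM model.

    Parameters
    ----------
    target
        ``(x0, y0)`` input and output vectors of the evaluated unit.
    reference
        Observations spanning the technology; the returns-to-scale
        assumption is taken from ``reference.rts``.  The target itself is
        normally among the members (scores are then <= 1).
    """
    x0 = np.asarray(target[0], dtype=float)
    y0 = np.asarray(target[1], dtype=float)
    _check_target(x0, y0, reference)
    m, q, k = x0.size, y0.size, reference.n_members

    A = reference.X / x0[:, None]  # (m, k), units-free
    B = reference.Y / y0[:, None]  # (q, k)

    # variables: [Λ (k), u (m) = s-/x0 scaled, v (q) = s+/y0 scaled, t]
    n_var = k + m + q + 1
    c = np.zeros(n_var)
    c[k:k + m] = -1.0 / m
    c[-1] = 1.0

    # equalities: denominator normalization; AΛ + u - t = 0; BΛ - v - t = 0
    rows = 1 + m + q + (1 if reference.rts == "vrs" else 0)
    A_eq = np.zeros((rows, n_var))
    b_eq = np.zeros(rows)
    A_eq[0, k + m:k + m + q] = 1.0 / q
    A_eq[0, -1] = 1.0
    b_eq[0] = 1.0
    A_eq[1:1 + m, :k] = A
    A_eq[1:1 + m, k:k + m] = np.eye(m)
    A_eq[1:1 + m, -1] = -1.0
    A_eq[1 + m:1 + m + q, :k] = B
    A_eq[1 + m:1 + m + q, k + m:k + m + q] = -np.eye(q)
    A_eq[1 + m:1 + m + q, -1] = -1.0
    if reference.rts == "vrs":
        A_eq[-1, :k] = 1.0
        A_eq[-1, -1] = -1.0

    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    nan = np.full(0, np.nan)
    if res.status == 2:
        return SBMResult(np.nan, nan, nan, nan, "infeasible")
    if not res.success:
        return SBMResult(np.nan, nan, nan, nan, "numeric-failure")

    z = res.x
    t = z[-1]
    if t <= 0:  # cannot de-homogenize; positive data should never get here
        return SBMResult(np.nan, nan, nan, nan, "numeric-failure")
    lam = z[:k] / t
    s_in = z[k:k + m] / t * x0
    s_out = z[k + m:k + m + q] / t * y0
    return SBMResult(float(res.fun), s_in, s_out, lam, "optimal")
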