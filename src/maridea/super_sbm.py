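"""Super-efficiency SBM: ranking units that sit on the frontier.

Plain SBM caps every frontier unit at a score of 1, so efficient units are
mutually incomparable.  Super-efficiency removes the evaluated unit from its
own reference set and measures the weighted l1 distance from (x0, y0) to the
remaining technology, restricted to points using at least as much input and
producing at most as much output:

    theta* = min  ((1/m) Σ_i xbar_i / x0_i) / ((1/q) Σ_r ybar_r / y0_r)
    s.t.   xbar >= Xλ,  ybar <= Yλ   (λ over the exclusion reference)
           xbar >= x0,  0 <= ybar <= y0,  λ >= 0
           (Σλ = 1 under variable returns)

theta* >= 1 for any SBM-efficient unit; the further the frontier retreats
when the unit is removed, the larger the score.  The combined convention
used throughout (score tables mixing values above and below 1) is: report
the SBM score if the unit is inefficient, otherwise its super-efficiency
score, and classify as SBM-efficient iff the reported score >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import PanelDataset, ReferenceSet, exclusion_reference, global_reference, period_reference
from .sbm import SBMResult, sbm_score

__all__ = [
    "SuperSBMResult",
    "ScoreRecord",
    "CLASSIFICATION_TOL",
    "super_sbm_score",
    "classify_status",
    "combined_score",
    "score_panel",
    "rank_scores",
]

#: |theta - 1| below this counts as exactly 1 when classifying
CLASSIFICATION_TOL = 1e-6

EFFICIENT = "SBM-efficient"
INEFFICIENT = "SBM-inefficient"


@dataclass(frozen=True)
class SuperSBMResult:
    """Super-efficiency score with the frontier projection point.

    ``projection_inputs`` (xbar >= x0) and ``projection_outputs``
    (ybar <= y0) locate the nearest point of the technology that remains
    after the unit is excluded.  Infeasibility (possible under variable
    returns only) is reported as an infinite score with a flagged status.
    """

    score: float
    projection_inputs: np.ndarray
    projection_outputs: np.ndarray
    weights: np.ndarray
    solver_status: str


@dataclass(frozen=True)
class ScoreRecord:
    """One DMU-period row of a combined score table."""

    dmu: str
    period: str
    score: float
    status: str
    rank: int | None = None


def super_sbm_score(target: tuple[np.ndarray, np.ndarray],
                    reference: ReferenceSet) -> SuperSBMResult:
    """Score an efficient unit against its exclusion reference set.

    The caller guarantees the target is absent from ``reference`` (use
    :func:`maridea.panel.exclusion_reference`); :func:`combined_score`
    additionally guarantees it is SBM-efficient, so theta* >= 1.
    """
    x0 = np.asarray(target[0], dtype=float)
    y0 = np.asarray(target[1], dtype=float)
    if x0.shape != (reference.X.shape[0],) or y0.shape != (reference.Y.shape[0],):
        raise ValueError("dimension mismatch between target and reference")
    if not (np.all(x0 > 0) and np.all(y0 > 0)):
        raise ValueError("target inputs and outputs must be strictly positive")
    m, q, k = x0.size, y0.size, reference.n_members

    A = reference.X / x0[:, None]
    B = reference.Y / y0[:, None]

    # Charnes-Cooper: variables [Λ (k), xi (m) = t*xbar/x0, eta (q) = t*ybar/y0, t]
    n_var = k + m + q + 1
    c = np.zeros(n_var)
    c[k:k + m] = 1.0 / m

    # equality: (1/q) Σ eta = 1  (+ VRS: ΣΛ - t = 0)
    n_eq = 1 + (1 if reference.rts == "vrs" else 0)
    A_eq = np.zeros((n_eq, n_var))
    b_eq = np.zeros(n_eq)
    A_eq[0, k + m:k + m + q] = 1.0 / q
    b_eq[0] = 1.0
    if reference.rts == "vrs":
        A_eq[1, :k] = 1.0
        A_eq[1, -1] = -1.0

    # inequalities (<= 0 form):
    #   AΛ - xi <= 0          (xbar envelops the reference inputs)
    #   eta - BΛ <= 0         (ybar is enveloped by the reference outputs)
    #   t - xi <= 0           (xbar >= x0)
    #   eta - t <= 0          (ybar <= y0)
    A_ub = np.zeros((m + q + m + q, n_var))
    A_ub[:m, :k] = A
    A_ub[:m, k:k + m] = -np.eye(m)
    A_ub[m:m + q, :k] = -B
    A_ub[m:m + q, k + m:k + m + q] = np.eye(q)
    A_ub[m + q:m + q + m, k:k + m] = -np.eye(m)
    A_ub[m + q:m + q + m, -1] = 1.0
    A_ub[m + q + m:, k + m:k + m + q] = np.eye(q)
    A_ub[m + q + m:, -1] = -1.0
    b_ub = np.zeros(m + q + m + q)

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs")
    nan = np.full(0, np.nan)
    if res.status == 2:
        return SuperSBMResult(np.inf, nan, nan, nan, "infeasible")
    if not res.success:
        return SuperSBMResult(np.nan, nan, nan, nan, "numeric-failure")
    z = res.x
    t = z[-1]
    if t <= 0:
        return SuperSBMResult(np.nan, nan, nan, nan, "numeric-failure")
    xbar = z[k:k + m] / t * x0
    ybar = z[k + m:k + m + q] / t * y0
    lam = z[:k] / t
    return SuperSBMResult(float(res.fun), xbar, ybar, lam, "optimal")


def classify_status(score: float) -> str:
    """Efficiency status from a combined score: efficient iff score >= 1.

    A classification tolerance absorbs LP round-off at the boundary.
    """
    if not np.isfinite(score) or score <= 0:
        raise ValueError(f"score must be finite and positive, got {score!r}")
    return EFFICIENT if score >= 1.0 - CLASSIFICATION_TOL else INEFFICIENT


def combined_score(panel: PanelDataset, dmu: str, period: str,
                   rts: str = "crs", pooling: str = "within") -> ScoreRecord:
    """SBM score for inefficient units, super-efficiency score otherwise.

    The unit is first scored against the full reference pool (its own
    period's cross-section, or the whole panel under global pooling).  Units
    off the frontier keep that score; frontier units are re-scored with
    themselves excluded, which yields a value >= 1 and makes efficient units
    rankable.
    """
    x0, y0 = panel.observation(dmu, period)
    if pooling == "within":
        full = period_reference(panel, period, rts)
    elif pooling == "global":
        full = global_reference(panel, rts)
    else:
        raise ValueError(f"pooling must be 'within' or 'global', got {pooling!r}")

    base: SBMResult = sbm_score((x0, y0), full)
    if base.solver_status != "optimal":
        raise RuntimeError(f"SBM solve failed for ({dmu}, {period}): {base.solver_status}")
    if not base.is_efficient:
        return ScoreRecord(dmu, period, base.score, classify_status(base.score))

    excl = exclusion_reference(panel, dmu, period, rts=rts, pooling=pooling)
    sup = super_sbm_score((x0, y0), excl)
    if sup.solver_status == "infeasible":
        return ScoreRecord(dmu, period, np.inf, EFFICIENT)
    if sup.solver_status != "optimal":
        raise RuntimeError(f"super-SBM solve failed for ({dmu}, {period})")
    # an SBM-efficient unit can score marginally below 1 through LP round-off
    score = max(sup.score, 1.0)
    return ScoreRecord(dmu, period, score, classify_status(score))


def rank_scores(records: list[ScoreRecord]) -> list[ScoreRecord]:
    """Attach descending ranks 1..n within one period; ties break by DMU id."""
    if not records:
        return []
    periods = {r.period for r in records}
    if len(periods) > 1:
        raise ValueError(f"records span multiple periods: {sorted(periods)}")
    if len({r.dmu for r in records}) != len(records):
        raise ValueError("duplicate DMU among score records")
    ordered = sorted(records, key=lambda r: (-r.score, r.dmu))
    ranked = {r.dmu: i + 1 for i, r in enumerate(ordered)}
    return [ScoreRecord(r.dmu, r.period, r.score, r.status, ranked[r.dmu])
            for r in records]


def score_panel(panel: PanelDataset, rts: str = "crs",
                pooling: str = "within") -> pd.DataFrame:
    """Combined scores with per-period ranks for every DMU-period cell.

    Returns a frame with columns ``period, dmu, score, status, rank``.
    """
    rows = []
    for period in panel.period_ids:
        recs = [combined_score(panel, dmu, period, rts=rts, pooling=pooling)
                for dmu in panel.dmu_ids]
        rows.extend(rank_scores(recs))
    return pd.DataFrame(
        {"period": [r.period for r in rows], "dmu": [r.dmu for r in rows],
         "score": [r.score for r in rows], "status": [r.status for r in rows],
         "rank": [r.rank for r in rows]}
    )
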