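"""Global Malmquist productivity index with its catch-up / frontier-shift split.

Productivity change of a DMU between periods t and t+1 is measured against a
single *global* benchmark technology — the constant-returns hull of all
observations of all periods pooled together:

    M^G = D^G(x_{t+1}, y_{t+1}) / D^G(x_t, y_t)

where D^G is the Shephard output distance function on the global technology.
Because only one benchmark exists, no geometric mean of two adjacent-period
indices is needed, the index is circular (M(t->t+2) = M(t->t+1) * M(t+1->t+2)),
and every distance LP is feasible for positive data under constant returns.

The decomposition uses the contemporaneous technology of each period:

    TE_s  = D^s(x_s, y_s)            technical efficiency within period s
    BPG_s = D^G(x_s, y_s) / D^s(x_s, y_s)   best-practice gap, in (0, 1]
    EC    = TE_{t+1} / TE_t          efficiency change (catch-up)
    BPC   = BPG_{t+1} / BPG_t        best-practice change (frontier shift)
    M^G   = EC * BPC                 (an identity, by construction)

A BPC above 1 means the period's own frontier moved closer to the global
(all-time best) frontier, i.e. technical progress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import PanelDataset, ReferenceSet, global_reference, period_reference

__all__ = [
    "GlobalTechnology",
    "MalmquistRecord",
    "output_distance",
    "malmquist_record",
    "malmquist_panel",
    "geometric_mean_indices",
]

OVERALL_LABEL = "Overall"


def output_distance(point: tuple[np.ndarray, np.ndarray],
                    reference: ReferenceSet) -> float:
    """Shephard output distance of a point to a constant-returns technology.

    Computed from the radial output-expansion LP

        phi* = max { phi : Xλ <= x0, Yλ >= phi * y0, λ >= 0 }

    and returned as 1/phi*.  The value lies in (0, 1] for any point inside
    the technology and equals 1 exactly on the frontier.
    """
    x0 = np.asarray(point[0], dtype=float)
    y0 = np.asarray(point[1], dtype=float)
    if x0.shape != (reference.X.shape[0],) or y0.shape != (reference.Y.shape[0],):
        raise ValueError("dimension mismatch between point and reference")
    if reference.rts != "crs":
        raise ValueError("output distance is defined on the constant-returns technology")
    m, q, k = x0.size, y0.size, reference.n_members

    A = reference.X / x0[:, None]  # units-free
    B = reference.Y / y0[:, None]

    # variables [Λ (k), phi]; maximize phi
    c = np.zeros(k + 1)
    c[-1] = -1.0
    A_ub = np.zeros((m + q, k + 1))
    A_ub[:m, :k] = A                       # AΛ <= 1
    A_ub[m:, :k] = -B                      # phi - BΛ <= 0
    A_ub[m:, -1] = 1.0
    b_ub = np.concatenate([np.ones(m), np.zeros(q)])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"output-distance LP failed: status {res.status}")
    phi = -res.fun
    if phi <= 0:
        raise RuntimeError("degenerate expansion: phi <= 0 on positive data")
    return 1.0 / phi


@dataclass(frozen=True)
class GlobalTechnology:
    """Pooled global reference plus the per-period contemporaneous ones."""

    pooled: ReferenceSet
    per_period: dict[str, ReferenceSet]

    @classmethod
    def from_panel(cls, panel: PanelDataset) -> "GlobalTechnology":
        return cls(
            pooled=global_reference(panel, rts="crs"),
            per_period={p: period_reference(panel, p, rts="crs")
                        for p in panel.period_ids},
        )


@dataclass(frozen=True)
class MalmquistRecord:
    """Productivity change of one DMU over one period pair."""

    dmu: str
    period_from: str
    period_to: str
    gmi: float
    ec: float
    bpc: float
    te_from: float
    te_to: float
    bpg_from: float
    bpg_to: float
    adjacent: bool = True


def _components(panel: PanelDataset, tech: GlobalTechnology,
                dmu: str, period: str) -> tuple[float, float, float]:
    """(global distance, contemporaneous TE, best-practice gap) of one cell."""
    obs = panel.observation(dmu, period)
    d_global = output_distance(obs, tech.pooled)
    te = output_distance(obs, tech.per_period[period])
    return d_global, te, d_global / te


def malmquist_record(panel: PanelDataset, dmu: str,
                     period_from: str, period_to: str,
                     tech: GlobalTechnology | None = None) -> MalmquistRecord:
    """GMI with its EC x BPC decomposition for one DMU and period pair.

    Non-adjacent pairs are allowed (the global index is circular) and are
    flagged via ``adjacent=False``.  ``tech`` may be passed to reuse the
    reference sets across many records.
    """
    if tech is None:
        tech = GlobalTechnology.from_panel(panel)
    t0 = panel.period_index(period_from)
    t1 = panel.period_index(period_to)
    d0, te0, bpg0 = _components(panel, tech, dmu, period_from)
    d1, te1, bpg1 = _components(panel, tech, dmu, period_to)
    return MalmquistRecord(
        dmu=dmu, period_from=period_from, period_to=period_to,
        gmi=d1 / d0, ec=te1 / te0, bpc=bpg1 / bpg0,
        te_from=te0, te_to=te1, bpg_from=bpg0, bpg_to=bpg1,
        adjacent=(t1 == t0 + 1),
    )


def malmquist_panel(panel: PanelDataset) -> pd.DataFrame:
    """Adjacent-pair records for every DMU (T-1 pairs per DMU).

    Distances are computed once per cell and reused across pairs.
    """
    if panel.n_periods < 2:
        raise ValueError("Malmquist index needs at least two periods")
    tech = GlobalTechnology.from_panel(panel)
    comp = {(d, p): _components(panel, tech, d, p)
            for d in panel.dmu_ids for p in panel.period_ids}
    rows = []
    for dmu in panel.dmu_ids:
        for t in range(panel.n_periods - 1):
            p0, p1 = panel.period_ids[t], panel.period_ids[t + 1]
            d0, te0, bpg0 = comp[(dmu, p0)]
            d1, te1, bpg1 = comp[(dmu, p1)]
            rows.append({"dmu": dmu, "period_from": p0, "period_to": p1,
                         "gmi": d1 / d0, "ec": te1 / te0, "bpc": bpg1 / bpg0,
                         "te_from": te0, "te_to": te1,
                         "bpg_from": bpg0, "bpg_to": bpg1})
    return pd.DataFrame(rows)


def _geomean(v: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(v))))


def geometric_mean_indices(records: pd.DataFrame,
                           axis: str = "over-periods",
                           overall: bool = True) -> pd.DataFrame:
    """Geometric-mean summary of GMI, EC and BPC.

    ``axis='over-periods'`` produces one row per DMU (its mean change rate
    per period step), plus an ``Overall`` row that is the geometric mean of
    the per-DMU rows — the cross-DMU convention, under which the identity
    mean-GMI = mean-EC x mean-BPC carries over exactly.
    ``axis='over-dmus'`` produces one row per period pair instead.
    """
    if len(records) == 0:
        raise ValueError("no records to summarize")
    if axis not in ("over-periods", "over-dmus"):
        raise ValueError(f"axis must be 'over-periods' or 'over-dmus', got {axis!r}")
    if (records[["gmi", "ec", "bpc"]] <= 0).any().any():
        raise ValueError("all index values must be strictly positive")
    if axis == "over-periods":
        key, label = "dmu", "dmu"
        keys = list(dict.fromkeys(records["dmu"]))
    else:
        records = records.assign(pair=records["period_from"] + "->" + records["period_to"])
        key, label = "pair", "period_pair"
        keys = list(dict.fromkeys(records["pair"]))
    rows = []
    for val in keys:
        sub = records[records[key] == val]
        rows.append({label: val,
                     "gmi": _geomean(sub["gmi"].to_numpy()),
                     "ec": _geomean(sub["ec"].to_numpy()),
                     "bpc": _geomean(sub["bpc"].to_numpy())})
    out = pd.DataFrame(rows)
    if overall and axis == "over-periods":
        out = pd.concat([out, pd.DataFrame([{
            label: OVERALL_LABEL,
            "gmi": _geomean(out["gmi"].to_numpy()),
            "ec": _geomean(out["ec"].to_numpy()),
            "bpc": _geomean(out["bpc"].to_numpy()),
        }])], ignore_index=True)
    return out
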