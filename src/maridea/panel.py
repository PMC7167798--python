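"""Panel data model for DEA efficiency analysis.

A panel is a rectangular DMU x period grid of strictly positive input and
output vectors (every estimator in this package assumes ``X > 0, Y > 0``).
The on-disk format is long CSV with a self-describing header::

    dmu,period,input:<name>,...,output:<name>,...

Column roles are taken from the ``input:`` / ``output:`` prefixes, so column
order never matters; an explicit schema mapping may override the prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "ReferenceSet",
    "PanelError",
    "SchemaError",
    "StructureError",
    "ValidationError",
    "load_panel",
    "panel_from_frame",
    "aggregate_dmus",
    "period_reference",
    "global_reference",
    "exclusion_reference",
]


class PanelError(ValueError):
    """Base class for panel construction problems."""


class SchemaError(PanelError):
    """The column-role schema does not match the file."""


class StructureError(PanelError):
    """The panel is not a full rectangular DMU x period grid."""


class ValidationError(PanelError):
    """A cell value violates the positivity requirement."""


@dataclass(frozen=True)
class PanelDataset:
    """Rectangular panel of positive inputs and outputs.

    Arrays are indexed ``[dmu, period, indicator]``; ``dmu_ids`` and
    ``period_ids`` fix the ordering.  Instances are immutable; derived panels
    (aggregation, exclusion) return new objects.
    """

    dmu_ids: tuple[str, ...]
    period_ids: tuple[str, ...]
    inputs: np.ndarray  # shape (n, T, m), strictly positive
    outputs: np.ndarray  # shape (n, T, q), strictly positive
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n, T, m = self.inputs.shape
        n2, T2, q = self.outputs.shape
        if (n, T) != (n2, T2):
            raise StructureError("input and output arrays disagree on panel shape")
        if n != len(self.dmu_ids) or T != len(self.period_ids):
            raise StructureError("identifier lists do not match array shape")
        if m != len(self.input_names) or q != len(self.output_names):
            raise StructureError("indicator name lists do not match array shape")
        if min(n, T, m, q) < 1:
            raise StructureError("panel needs at least one DMU, period, input and output")
        if len(set(self.dmu_ids)) != n:
            raise StructureError("duplicate DMU identifiers")
        if len(set(self.period_ids)) != T:
            raise StructureError("duplicate period identifiers")
        for arr, names, role in ((self.inputs, self.input_names, "input"),
                                 (self.outputs, self.output_names, "output")):
            bad = ~(np.isfinite(arr) & (arr > 0))
            if bad.any():
                i, t, k = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"non-positive or missing value for dmu={self.dmu_ids[i]!r}, "
                    f"period={self.period_ids[t]!r}, {role}={names[k]!r}: {arr[i, t, k]!r}"
                )
        self.inputs.setflags(write=False)
        self.outputs.setflags(write=False)

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_dmus(self) -> int:
        return len(self.dmu_ids)

    @property
    def n_periods(self) -> int:
        return len(self.period_ids)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    @property
    def n_outputs(self) -> int:
        return len(self.output_names)

    def dmu_index(self, dmu: str) -> int:
        try:
            return self.dmu_ids.index(dmu)
        except ValueError:
            raise KeyError(f"unknown DMU {dmu!r}") from None

    def period_index(self, period: str) -> int:
        try:
            return self.period_ids.index(period)
        except ValueError:
            raise KeyError(f"unknown period {period!r}") from None

    def observation(self, dmu: str, period: str) -> tuple[np.ndarray, np.ndarray]:
        """Return the (input-vector, output-vector) of one cell."""
        i, t = self.dmu_index(dmu), self.period_index(period)
        return self.inputs[i, t].copy(), self.outputs[i, t].copy()

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with ``input:``/``output:`` prefixed columns."""
        rows = []
        for i, d in enumerate(self.dmu_ids):
            for t, p in enumerate(self.period_ids):
                row: dict[str, object] = {"dmu": d, "period": p}
                row.update({f"input:{nm}": self.inputs[i, t, k]
                            for k, nm in enumerate(self.input_names)})
                row.update({f"output:{nm}": self.outputs[i, t, k]
                            for k, nm in enumerate(self.output_names)})
                rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        # repr-precision floats so write -> load round-trips bit-exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class ReferenceSet:
    """Observations spanning a production possibility set.

    ``X`` is (m, k) and ``Y`` is (q, k) over k member observations.  Under
    constant returns the technology is the cone ``{(x, y) : x >= Xλ,
    y <= Yλ, λ >= 0}``; variable returns add the convexity constraint
    ``Σλ = 1``.  ``excluded`` tags the (dmu, period) removed from the pool,
    if any (super-efficiency reference sets).
    """

    X: np.ndarray
    Y: np.ndarray
    rts: str = "crs"
    members: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    excluded: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.rts not in ("crs", "vrs"):
            raise ValueError(f"rts must be 'crs' or 'vrs', got {self.rts!r}")
        if self.X.ndim != 2 or self.Y.ndim != 2 or self.X.shape[1] != self.Y.shape[1]:
            raise ValueError("X and Y must be 2-D with matching member counts")
        if self.X.shape[1] == 0:
            raise ValueError("empty reference set")
        if self.members and len(self.members) != self.X.shape[1]:
            raise ValueError("member tags do not match member count")
        if self.excluded is not None and self.excluded in self.members:
            raise ValueError("excluded observation still present among members")

    @property
    def n_members(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# construction

def _resolve_schema(columns: Sequence[str],
                    schema: Mapping[str, str] | None) -> tuple[str, str, list[str], list[str]]:
    if schema is not None:
        unknown = set(schema) - set(columns)
        if unknown:
            raise SchemaError(f"schema names unknown column(s): {sorted(unknown)}")
        dmu_cols = [c for c, r in schema.items() if r == "dmu"]
        per_cols = [c for c, r in schema.items() if r == "period"]
        in_cols = [c for c in columns if schema.get(c) == "input"]
        out_cols = [c for c in columns if schema.get(c) == "output"]
        if len(dmu_cols) != 1 or len(per_cols) != 1:
            raise SchemaError("schema must name exactly one dmu and one period column")
        dmu_col, per_col = dmu_cols[0], per_cols[0]
    else:
        if "dmu" not in columns or "period" not in columns:
            raise SchemaError("expected 'dmu' and 'period' columns")
        dmu_col, per_col = "dmu", "period"
        in_cols = [c for c in columns if c.startswith("input:")]
        out_cols = [c for c in columns if c.startswith("output:")]
        stray = [c for c in columns
                 if c not in (dmu_col, per_col) and c not in in_cols and c not in out_cols]
        if stray:
            raise SchemaError(f"column(s) without a role: {stray}")
    if not in_cols or not out_cols:
        raise SchemaError("need at least one input and one output column")
    return dmu_col, per_col, in_cols, out_cols


def panel_from_frame(frame: pd.DataFrame,
                     schema: Mapping[str, str] | None = None,
                     period_order: Sequence[str] | None = None) -> PanelDataset:
    """Build a validated :class:`PanelDataset` from a long-format frame.

    Row order is irrelevant.  DMU identifiers keep first-appearance order;
    periods sort lexicographically unless ``period_order`` is given.
    """
    dmu_col, per_col, in_cols, out_cols = _resolve_schema(list(frame.columns), schema)
    dmus = list(dict.fromkeys(frame[dmu_col].astype(str)))
    periods_seen = sorted(set(frame[per_col].astype(str)))
    if period_order is not None:
        period_order = [str(p) for p in period_order]
        if sorted(period_order) != periods_seen:
            raise StructureError("explicit period order does not match periods in data")
        periods = list(period_order)
    else:
        periods = periods_seen

    n, T = len(dmus), len(periods)
    if len(frame) != n * T:
        raise StructureError(
            f"panel is not rectangular: {len(frame)} rows, expected {n}x{T}={n * T}"
        )
    key = frame[dmu_col].astype(str) + "\x00" + frame[per_col].astype(str)
    if key.duplicated().any():
        dup = frame.loc[key.duplicated(), [dmu_col, per_col]].iloc[0]
        raise StructureError(f"duplicate observation for dmu={dup[dmu_col]!r}, "
                             f"period={dup[per_col]!r}")

    di = {d: i for i, d in enumerate(dmus)}
    ti = {p: t for t, p in enumerate(periods)}
    inputs = np.full((n, T, len(in_cols)), np.nan)
    outputs = np.full((n, T, len(out_cols)), np.nan)
    for _, row in frame.iterrows():
        i, t = di[str(row[dmu_col])], ti[str(row[per_col])]
        inputs[i, t] = [row[c] for c in in_cols]
        outputs[i, t] = [row[c] for c in out_cols]

    strip = lambda c: c.split(":", 1)[1] if ":" in c else c
    return PanelDataset(
        dmu_ids=tuple(dmus),
        period_ids=tuple(periods),
        inputs=inputs,
        outputs=outputs,
        input_names=tuple(strip(c) for c in in_cols),
        output_names=tuple(strip(c) for c in out_cols),
    )


def load_panel(path: str | Path,
               schema: Mapping[str, str] | None = None,
               period_order: Sequence[str] | None = None) -> PanelDataset:
    """Read and validate a long-format panel CSV."""
    frame = pd.read_csv(path, float_precision="round_trip")
    return panel_from_frame(frame, schema=schema, period_order=period_order)


# ---------------------------------------------------------------------------
# manipulations

def aggregate_dmus(panel: PanelDataset, groups: Mapping[str, str]) -> PanelDataset:
    """Merge DMUs into groups by element-wise summation per period.

    Every DMU must be assigned to exactly one group; a national total, for
    example, maps all provinces onto a single group label.
    """
    if not groups:
        raise PanelError("empty group mapping")
    missing = set(panel.dmu_ids) - set(groups)
    if missing:
        raise PanelError(f"DMU(s) without a group: {sorted(missing)}")
    order = list(dict.fromkeys(groups[d] for d in panel.dmu_ids))
    gi = {g: j for j, g in enumerate(order)}
    n_g = len(order)
    inputs = np.zeros((n_g, panel.n_periods, panel.n_inputs))
    outputs = np.zeros((n_g, panel.n_periods, panel.n_outputs))
    for i, d in enumerate(panel.dmu_ids):
        j = gi[groups[d]]
        inputs[j] += panel.inputs[i]
        outputs[j] += panel.outputs[i]
    return PanelDataset(tuple(order), panel.period_ids, inputs, outputs,
                        panel.input_names, panel.output_names)


def _pool(panel: PanelDataset,
          cells: Iterable[tuple[int, int]],
          rts: str,
          excluded: tuple[str, str] | None = None) -> ReferenceSet:
    cells = list(cells)
    if not cells:
        raise PanelError("empty reference set")
    X = np.column_stack([panel.inputs[i, t] for i, t in cells])
    Y = np.column_stack([panel.outputs[i, t] for i, t in cells])
    members = tuple((panel.dmu_ids[i], panel.period_ids[t]) for i, t in cells)
    return ReferenceSet(X=X, Y=Y, rts=rts, members=members, excluded=excluded)


def period_reference(panel: PanelDataset, period: str, rts: str = "crs") -> ReferenceSet:
    """All DMUs of one period (the contemporaneous technology)."""
    t = panel.period_index(period)
    return _pool(panel, ((i, t) for i in range(panel.n_dmus)), rts)


def global_reference(panel: PanelDataset, rts: str = "crs") -> ReferenceSet:
    """All observations of all periods (the pooled global technology)."""
    return _pool(panel, ((i, t) for i in range(panel.n_dmus)
                         for t in range(panel.n_periods)), rts)


def exclusion_reference(panel: PanelDataset, dmu: str, period: str,
                        rts: str = "crs", pooling: str = "within") -> ReferenceSet:
    """Reference set with one observation removed (super-efficiency pool).

    ``pooling='within'`` keeps only the target period's cross-section
    (n - 1 members); ``pooling='global'`` keeps every other observation of
    the whole panel (n*T - 1 members).
    """
    if pooling not in ("within", "global"):
        raise ValueError(f"pooling must be 'within' or 'global', got {pooling!r}")
    i0, t0 = panel.dmu_index(dmu), panel.period_index(period)
    if pooling == "within":
        cells = [(i, t0) for i in range(panel.n_dmus) if i != i0]
    else:
        cells = [(i, t) for i in range(panel.n_dmus)
                 for t in range(panel.n_periods) if (i, t) != (i0, t0)]
    if not cells:
        raise PanelError("empty reference set: cannot exclude the only observation")
    return _pool(panel, cells, rts, excluded=(dmu, period))
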