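"""End-to-end efficiency analysis of a DMU x period panel.

Three stages, mirroring the standard provincial/national workflow:

1. *national* — all DMUs are summed into one aggregate per period; each
   period is then treated as a DMU and scored (combined super-SBM) against
   the cross-section of all periods, yielding one score and status per year.
2. *cross-section* — every DMU is scored within its own period and ranked.
3. *productivity* — adjacent-period global Malmquist records with the
   EC x BPC decomposition, plus per-DMU geometric means and a cross-DMU
   Overall row.

All internal math is full precision; rounding happens only when report
files are written.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .malmquist import geometric_mean_indices, malmquist_panel
from .panel import PanelDataset, aggregate_dmus
from .super_sbm import EFFICIENT, ScoreRecord, combined_score, rank_scores, score_panel

__all__ = ["AnalysisConfig", "ReportBundle", "national_scores", "run_full_analysis"]

#: decimals per report, matching the usual presentation of such tables
_ROUNDING = {"scores": 2, "national": 4, "malmquist": 4, "summary": 4}


@dataclass(frozen=True)
class AnalysisConfig:
    """Options of a full analysis run."""

    rts: str = "crs"  # "crs" | "vrs"
    pooling: str = "within"  # "within" | "global", for the cross-section stage
    groups: dict[str, str] | None = None  # dmu -> group; None = one national total
    national_label: str = "National"
    summary_axis: str = "over-periods"
    rounding: dict[str, int] = field(default_factory=lambda: dict(_ROUNDING))
    seed: int | None = None  # echoed into the manifest only

    def __post_init__(self) -> None:
        if self.rts not in ("crs", "vrs"):
            raise ValueError(f"rts must be 'crs' or 'vrs', got {self.rts!r}")
        if self.pooling not in ("within", "global"):
            raise ValueError(f"pooling must be 'within' or 'global', got {self.pooling!r}")
        if self.summary_axis not in ("over-periods", "over-dmus"):
            raise ValueError(f"unknown summary axis {self.summary_axis!r}")


@dataclass(frozen=True)
class ReportBundle:
    """All result tables of one analysis run."""

    scores: pd.DataFrame  # period, dmu, score, status, rank
    national: pd.DataFrame  # period, score, status
    malmquist: pd.DataFrame | None  # per-DMU period-pair records
    summary: pd.DataFrame | None  # per-DMU geometric means + Overall
    manifest: dict[str, object]

    def write(self, outdir: str | Path, rounding: dict[str, int] | None = None) -> list[Path]:
        """Write the report CSVs and the run manifest; returns written paths."""
        rounding = rounding or _ROUNDING
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def _dump(frame: pd.DataFrame, name: str, decimals: int) -> None:
            path = outdir / f"{name}.csv"
            frame.round(decimals).to_csv(path, index=False)
            written.append(path)

        _dump(self.scores, "scores", rounding["scores"])
        _dump(self.national, "national", rounding["national"])
        if self.malmquist is not None:
            _dump(self.malmquist, "malmquist", rounding["malmquist"])
        if self.summary is not None:
            _dump(self.summary, "malmquist_summary", rounding["summary"])
        manifest = outdir / "manifest.txt"
        with open(manifest, "w") as fh:
            for key, val in self.manifest.items():
                fh.write(f"{key} = {val}\n")
        written.append(manifest)
        return written


def national_scores(panel: PanelDataset, rts: str = "crs",
                    groups: dict[str, str] | None = None,
                    label: str = "National") -> pd.DataFrame:
    """Years-as-DMUs scoring of the aggregated panel.

    DMUs are summed per period (all into one group by default), then the
    per-period totals form a single cross-section in which each *period*
    plays the role of a DMU and is scored against all the others.
    """
    if groups is None:
        groups = {d: label for d in panel.dmu_ids}
    agg = aggregate_dmus(panel, groups)
    rows = []
    for group in agg.dmu_ids:
        # reshape: periods become DMUs of a one-period pseudo-panel
        years = PanelDataset(
            dmu_ids=agg.period_ids,
            period_ids=("all",),
            inputs=agg.inputs[agg.dmu_index(group)][:, None, :],
            outputs=agg.outputs[agg.dmu_index(group)][:, None, :],
            input_names=agg.input_names,
            output_names=agg.output_names,
        )
        if years.n_dmus == 1:
            # a lone period has no comparator: frontier by itself
            recs = [ScoreRecord(years.dmu_ids[0], "all", 1.0, EFFICIENT, 1)]
        else:
            recs = rank_scores([combined_score(years, p, "all", rts=rts)
                                for p in years.dmu_ids])
        for rec in recs:
            row = {"period": rec.dmu, "score": rec.score, "status": rec.status}
            if len(agg.dmu_ids) > 1:
                row = {"group": group, **row}
            rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(panel: PanelDataset,
                      config: AnalysisConfig | None = None) -> ReportBundle:
    """Run all three stages and collect the report tables."""
    config = config or AnalysisConfig()
    scores = score_panel(panel, rts=config.rts, pooling=config.pooling)
    national = national_scores(panel, rts=config.rts, groups=config.groups,
                               label=config.national_label)
    if panel.n_periods >= 2:
        malm = malmquist_panel(panel)
        summary = geometric_mean_indices(malm, axis=config.summary_axis)
    else:
        warnings.warn("single-period panel: productivity stage skipped", stacklevel=2)
        malm = summary = None
    manifest = {
        "software": f"maridea {__version__}",
        "rts": config.rts,
        "pooling": config.pooling,
        "summary_axis": config.summary_axis,
        "n_dmus": panel.n_dmus,
        "n_periods": panel.n_periods,
        "n_inputs": panel.n_inputs,
        "n_outputs": panel.n_outputs,
        "seed": config.seed if config.seed is not None else "none",
    }
    return ReportBundle(scores=scores, national=national,
                        malmquist=malm, summary=summary, manifest=manifest)
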