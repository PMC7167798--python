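"""Synthetic DEA panels with a known frontier and known inefficiency.

Real provincial aquaculture input-output tables are not redistributable, so
estimator behaviour is verified on generated panels whose truth is known by
construction.  The generator uses a constant-returns Cobb-Douglas frontier

    f_t(x) = (1 + g)^t * prod_i x_i^alpha_i,      sum_i alpha_i = 1

with Hicks-neutral technical progress at rate g per period and multiplicative
inefficiency u in (0, 1] on the output side:

    y_1 = u * f_t(x),       y_2 = price * y_1

Because sum(alpha) = 1 the true technology is a convex cone, the estimated
CRS hull is nested inside it, and every u = 1 observation is exactly on both
frontiers — so true efficiencies and the frontier-shift rate (1 + g) are
recoverable targets for the SBM and Malmquist estimators.

The default configuration mirrors a nine-province, thirteen-year coastal
aquaculture panel: 3 inputs (farmed area in hm2, workers, vessel tonnage in
t) and 2 outputs (yield in t, production value in 1e4 yuan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelDataset

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate_panel"]

_DEFAULT_RANGES = (
    ("area_hm2", (1.0e4, 1.0e5)),
    ("workers", (1.0e4, 1.0e5)),
    ("vessel_t", (1.0e4, 1.0e5)),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that determines a synthetic panel.

    Parameters
    ----------
    n_dmus, n_periods, m_inputs, q_outputs
        Panel dimensions; defaults match the 9 x 13 provincial panel with
        3 inputs and 2 outputs.
    exponents
        Cobb-Douglas frontier exponents; must be positive and sum to 1
        (constant returns).  ``None`` uses (0.4, 0.3, 0.3)-style weights:
        0.4 on the first input, the rest split evenly.
    progress_rate
        Per-period multiplicative frontier shift g >= 0.  Default 0.05,
        i.e. 5% technical progress per period — the order of magnitude of
        observed frontier-shift rates in coastal aquaculture panels.
    inefficiency
        Family of the multiplicative efficiency draw u in (0, 1]:
        ``"lognormal"`` (truncated to (0, 1]; params mu, sigma of the
        underlying normal), ``"uniform"`` (params low, high), or
        ``"constant"`` (param value).
    inefficiency_params
        Family parameters; defaults to ``(-0.35, 0.3)`` for lognormal.
    time_constant
        Draw u once per DMU and hold it over periods (default) or redraw
        every period.
    efficient_fraction
        Share of DMUs forced onto the frontier (u = 1) in every period.
    input_ranges
        ``(name, (low, high))`` pairs per input; values are drawn
        log-uniformly within each range.
    price_factor
        Constant linking the second output to the first (unit value of
        production); with q_outputs = 1 it is unused.
    seed
        Seed of the single pseudo-random source.
    first_year
        Integer label of the first period (periods are labelled as years).
    """

    n_dmus: int = 9
    n_periods: int = 13
    m_inputs: int = 3
    q_outputs: int = 2
    exponents: tuple[float, ...] | None = None
    progress_rate: float = 0.05
    inefficiency: str = "lognormal"
    inefficiency_params: tuple[float, ...] = (-0.35, 0.3)
    time_constant: bool = True
    efficient_fraction: float = 0.2
    input_ranges: tuple[tuple[str, tuple[float, float]], ...] = _DEFAULT_RANGES
    price_factor: float = 1.5
    seed: int = 0
    first_year: int = 2004

    def resolved_exponents(self) -> np.ndarray:
        if self.exponents is not None:
            a = np.asarray(self.exponents, dtype=float)
        elif self.m_inputs == 1:
            a = np.array([1.0])
        else:
            rest = 0.6 / (self.m_inputs - 1)
            a = np.array([0.4] + [rest] * (self.m_inputs - 1))
        return a

    def validate(self) -> None:
        if min(self.n_dmus, self.n_periods, self.m_inputs) < 1 or self.q_outputs not in (1, 2):
            raise ValueError("dimensions must be >= 1 and q_outputs in {1, 2}")
        a = self.resolved_exponents()
        if a.size != self.m_inputs or np.any(a <= 0) or abs(a.sum() - 1.0) > 1e-12:
            raise ValueError("exponents must be positive and sum to 1 (constant returns)")
        if self.progress_rate < 0:
            raise ValueError("progress_rate must be >= 0")
        if not 0.0 <= self.efficient_fraction <= 1.0:
            raise ValueError("efficient_fraction must lie in [0, 1]")
        if len(self.input_ranges) != self.m_inputs:
            raise ValueError("need one input range per input")
        for name, (lo, hi) in self.input_ranges:
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for input {name!r}: ({lo}, {hi})")
        if self.inefficiency not in ("lognormal", "uniform", "constant"):
            raise ValueError(f"unknown inefficiency family {self.inefficiency!r}")
        if self.price_factor <= 0:
            raise ValueError("price_factor must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated panel, for recovery tests."""

    dmu_ids: tuple[str, ...]
    period_ids: tuple[str, ...]
    efficiency: np.ndarray  # u, shape (n, T), values in (0, 1]
    shift_factor: float  # frontier multiplier per period step, 1 + g
    exponents: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = [{"dmu": d, "period": p, "true_u": self.efficiency[i, t]}
                for i, d in enumerate(self.dmu_ids)
                for t, p in enumerate(self.period_ids)]
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _draw_u(rng: np.random.Generator, cfg: GeneratorConfig, size: int) -> np.ndarray:
    fam, p = cfg.inefficiency, cfg.inefficiency_params
    if fam == "constant":
        (val,) = p
        if not 0 < val <= 1:
            raise ValueError("constant efficiency must lie in (0, 1]")
        return np.full(size, float(val))
    if fam == "uniform":
        lo, hi = p
        if not 0 < lo <= hi <= 1:
            raise ValueError("uniform efficiency bounds must satisfy 0 < low <= high <= 1")
        return rng.uniform(lo, hi, size)
    # lognormal truncated to (0, 1] by resampling
    mu, sigma = p
    u = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.lognormal(mu, sigma, todo.size)
        ok = draw <= 1.0
        u[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return u


def generate_panel(config: GeneratorConfig) -> tuple[PanelDataset, SyntheticTruth]:
    """Sample a panel and return it with its ground truth.

    Identical configurations (including seed) give identical panels.  The
    first ``ceil(efficient_fraction * n)`` DMUs (after a seeded shuffle of
    identities) have u = 1 in every period, guaranteeing the frontier is
    attained whenever ``efficient_fraction > 0``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T, m, q = config.n_dmus, config.n_periods, config.m_inputs, config.q_outputs
    alphas = config.resolved_exponents()

    dmu_ids = tuple(f"D{i + 1:02d}" for i in range(n))
    period_ids = tuple(str(config.first_year + t) for t in range(T))

    # inputs: log-uniform within each indicator's range, per cell
    inputs = np.empty((n, T, m))
    for k, (_name, (lo, hi)) in enumerate(config.input_ranges):
        inputs[:, :, k] = np.exp(rng.uniform(np.log(lo), np.log(hi), (n, T)))

    # efficiency: frontier DMUs first, then sampled inefficiency
    n_eff = int(np.ceil(config.efficient_fraction * n)) if config.efficient_fraction > 0 else 0
    u = np.ones((n, T))
    n_rest = n - n_eff
    if n_rest > 0:
        if config.time_constant:
            u[n_eff:, :] = _draw_u(rng, config, n_rest)[:, None]
        else:
            u[n_eff:, :] = _draw_u(rng, config, n_rest * T).reshape(n_rest, T)
    perm = rng.permutation(n)
    u = u[perm]  # decouple frontier membership from identifier order

    shift = (1.0 + config.progress_rate) ** np.arange(T)
    frontier = np.prod(inputs ** alphas[None, None, :], axis=2) * shift[None, :]
    y1 = u * frontier
    outputs = y1[:, :, None] if q == 1 else np.stack([y1, config.price_factor * y1], axis=2)

    input_names = tuple(name for name, _ in config.input_ranges)
    output_names = ("yield_t",) if q == 1 else ("yield_t", "value_1e4yuan")
    panel = PanelDataset(dmu_ids, period_ids, inputs, outputs, input_names, output_names)
    truth = SyntheticTruth(dmu_ids, period_ids, u, 1.0 + config.progress_rate, alphas)
    return panel, truth
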