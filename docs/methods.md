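# Methods

## Models

### Production technology

All estimators work on a reference set of k observed units with input matrix
X (m × k) and output matrix Y (q × k), all entries strictly positive. Under
constant returns to scale (CRS, the default everywhere) the technology is
the polyhedral cone {(x, y) : x ≥ Xλ, y ≤ Yλ, λ ≥ 0}; variable returns
(VRS) add Σλ = 1. Strict positivity is enforced at load time and panels
must be rectangular — unbalanced panels are rejected rather than imputed,
because every reference-set construction below assumes a full grid.

### SBM score

The non-oriented slacks-based measure minimizes a ratio of the average
proportional input excess to the average proportional output shortfall. It
is solved as a single LP via the Charnes–Cooper transformation: a scalar t
scales all variables so the denominator equals one, turning the fractional
objective into a linear one; scores and slacks are recovered by dividing by
the optimal t (always positive for positive data with the target in the
reference set). The LP is assembled in *ratio-normalized* form — reference
columns divided element-wise by the target's own inputs/outputs — so the
constraint matrix is mathematically identical under any rescaling of an
indicator's measurement units. Units invariance therefore holds to solver
precision (observed ≤ 1e-15), not merely to an analytical argument about
equivalent programs.

CRS is the default returns-to-scale assumption for both the plain and the
super model: the plain SBM technology carries no convexity constraint, and
using CRS for both keeps the combined score internally consistent and the
exclusion program well-behaved. VRS is available as an option on every
entry point.

### Super-efficiency and the combined score

The super-SBM program measures how far the frontier retreats when an
efficient unit is removed: the nearest admissible point must use at least
the unit's inputs and produce at most its outputs, within the cone of the
remaining units. The same Charnes–Cooper device linearizes it. Two
practical notes:

- The non-oriented exclusion program is feasible for any positive data,
  under CRS *and* VRS (projected inputs are unbounded above and projected
  outputs may fall toward the denominator normalization). The solver-status
  field still distinguishes `infeasible` defensively, and an infeasible
  outcome would be reported as an infinite score rather than clamped.
- An SBM-efficient unit's super score can come out marginally below 1
  through LP round-off; the combined score floors it at 1 so classification
  and scoring never disagree.

Classification uses θ ≥ 1 with a tolerance of 1e-6 on |θ − 1|; slacks below
1e-6 (in target-relative units) count as zero. Ranks are assigned per
period, descending in score, ties broken deterministically by DMU
identifier. Optimal slacks and intensity weights are reported as the
solver's optimum; they are not unique at degenerate vertices and no
secondary lexicographic refinement is applied.

### Global Malmquist index

The Shephard output distance is computed from the radial expansion LP
max{φ : Xλ ≤ x₀, Yλ ≥ φy₀, λ ≥ 0} and inverted — this avoids a fractional
program entirely and is exact under CRS. The global index divides the
pooled-technology distances of a unit at two dates; the decomposition into
efficiency change (contemporaneous-technology distances) and best-practice
change (global/contemporaneous gap ratios) is an algebraic identity, which
tests assert to 1e-9 together with circularity. Envelopment (the pooled
technology contains every period technology) guarantees best-practice gaps
in (0, 1].

Adjacent period pairs are the default (T − 1 records per unit);
non-adjacent pairs are allowed — the index is circular — and flagged. All
summary means are geometric, never arithmetic: geometric means preserve the
gmi = ec × bpc identity along any axis. The `Overall` row is the
cross-DMU geometric mean of the per-DMU geometric means. This convention
was adopted because it is the one the published provincial change-rate
table is internally consistent with (the cross-province geometric mean of
the nine per-province rows reproduces the published Overall row to its
printed precision, verified in the tests); aggregating a pooled national
panel first is available through the pipeline as an alternative.

### National stage (years as DMUs)

Provincial indicators are summed element-wise into one national bundle per
year; the yearly bundles then form a single cross-section in which each
year is scored (combined SBM / super-SBM, CRS, within the set of all years)
against the other years. A single-period panel degenerates to a lone year
with no comparator; it is reported at score 1, SBM-efficient, rather than
erroring, so the other pipeline stages still run.

## Synthetic generator

The generator emulates a nine-province × thirteen-year aquaculture panel:
3 inputs (farmed area hm², workers, vessel tonnage t) and 2 outputs (yield
t, production value 10⁴ yuan), with inputs drawn log-uniformly within
1e4–1e5 per indicator so invariance tests exercise realistically
heterogeneous scales. Output one follows a Cobb–Douglas frontier
u · (1+g)ᵗ · Π xᵢ^αᵢ with exponents α = (0.4, 0.3, 0.3) summing to one
(constant returns — chosen so the true technology is a convex cone, the DEA
hull is nested inside it, and closed-form truth is assertable); output two
is a constant price factor (1.5) times output one, mirroring a stable unit
value of production. Defaults: g = 0.05 per period (the order of magnitude
of observed frontier-shift rates in this sector), inefficiency u drawn from
a lognormal(μ = −0.35, σ = 0.3) truncated to (0, 1] and held constant over
time per DMU, 20% of DMUs forced onto the frontier so the frontier is
attained every period. A single `numpy` Generator seeded from the config is
the only randomness source.

What passing recovery tests show — and what they do not: because the true
frontier is a smooth cone and the estimated one a polyhedral subset,
estimated efficiencies are biased upward at finite n; recovery assertions
therefore target rank correlation (> 0.9 at n = 100), the frontier-shift
rate (overall BPC within [1.03, 1.07] of the true 1.05 at n = 50, T = 10)
and catch-up neutrality (EC within 0.02 of 1 under time-constant u), not
pointwise score equality. With more than one input, a unit with u below the
period maximum can still be undominated by the finite sample at an extreme
input mix and receive a combined score above 1; only in the single-input
case does the closed form score = u/u_max hold exactly, and that is the
regime in which it is asserted. The generator does not attempt
province-specific output composition, policy shocks, or input correlation
over time (each cell's inputs are drawn independently), so it validates the
estimators, not distributional realism of any specific real panel.

## Numerical choices

- LP solver: HiGHS via `scipy.optimize.linprog`, default (dual simplex)
  settings; feasibility/optimality at HiGHS defaults (~1e-9 scale, one
  order tighter than the 1e-6 classification/slack tolerances built on it).
- De-homogenization guards: optimal t ≤ 0 is reported as `numeric-failure`
  rather than producing nonsense scores (unreachable for positive data).
- Rounding only at report writing: 2 decimals for cross-section score
  tables, 4 for national and productivity tables; all internal math is full
  precision, so report files are byte-reproducible for identical inputs.
- CSV round-trips are exact: floats are written at 17 significant digits
  and read back with `float_precision="round_trip"`.

## Problem sizes used in the checks

Oracle suites run 200 randomized 1-input/1-output panels; invariance checks
rescale 3 × 2-indicator panels of 9 units by factors spanning 1e-3–1e3;
index identities use 10-DMU × 5-period panels; recovery uses five panels of
50 DMUs × 10 periods (≈ 1800 LPs each). These sizes give sampling error
comfortably inside the asserted bands while keeping the full suite fast on
one CPU.

## Known limitations

- Published per-province efficiency score tables cannot be reproduced
  numerically: the underlying provincial yearbook inputs are not available
  in machine-readable form. The package instead validates its conventions
  (classification, ranking, geometric-mean aggregation, decomposition)
  against the published score summaries, which are fully self-consistent.
- No oriented SBM variants, undesirable outputs, scale-efficiency
  decomposition, or contemporaneous (two-benchmark geometric mean)
  Malmquist index.
- Slacks and intensity weights at alternate optima are solver-dependent.
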