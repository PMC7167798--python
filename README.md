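# maridea

Slacks-based DEA efficiency, super-efficiency and global Malmquist
productivity analysis for positive input–output panels — built for
provincial/national production-efficiency studies such as China's coastal
mariculture sector (inputs: farmed area in hm², workers, vessel tonnage;
outputs: yield in t, production value in 10⁴ yuan), but applicable to any
rectangular DMU × period panel with strictly positive data.

## What it computes

**SBM efficiency.** For a decision-making unit (x₀, y₀) against observed
technology (X, Y), the non-oriented slacks-based measure is

    ρ = min (1 − (1/m) Σᵢ sᵢ⁻/xᵢ₀) / (1 + (1/q) Σᵣ sᵣ⁺/yᵣ₀)
    s.t. x₀ = Xλ + s⁻,  y₀ = Yλ − s⁺,  λ, s⁻, s⁺ ≥ 0

ρ ∈ (0, 1] penalises every individual input excess s⁻ and output shortfall
s⁺, is units-invariant, and equals 1 exactly on the frontier. The fractional
program is linearized by the Charnes–Cooper substitution and solved with
HiGHS (`scipy.optimize.linprog`).

**Super-efficiency.** Frontier units (ρ = 1) are re-scored with themselves
excluded from the reference set:

    θ* = min ((1/m) Σᵢ x̄ᵢ/xᵢ₀) / ((1/q) Σᵣ ȳᵣ/yᵣ₀)
    s.t. x̄ ≥ Xλ, ȳ ≤ Yλ, x̄ ≥ x₀, 0 ≤ ȳ ≤ y₀, λ ≥ 0

θ* ≥ 1 ranks efficient units. The *combined* convention reports ρ for
inefficient units and θ* for efficient ones; a unit is SBM-efficient iff its
combined score ≥ 1.

**Global Malmquist index.** Productivity change between periods t and t+1
is measured against one benchmark pooled over all periods:

    M^G = D^G(x_{t+1}, y_{t+1}) / D^G(x_t, y_t) = EC × BPC

with Shephard output distances D, efficiency change EC = TE_{t+1}/TE_t
(catch-up to the period frontier) and best-practice change
BPC = BPG_{t+1}/BPG_t (frontier shift, technical change). The global index
is circular and free of LP infeasibility under constant returns.

A synthetic generator (`maridea.synthetic`) draws panels from a known
constant-returns Cobb–Douglas frontier with Hicks-neutral technical progress
and multiplicative inefficiency, so every estimator is testable against
ground truth without restricted yearbook data.

## Worked example

```sh
python examples/03_productivity_change.py
```

generates a 9-unit × 13-year panel with a true 5% per-period frontier shift
and prints the per-unit geometric-mean change rates:

```
    dmu    gmi     ec    bpc
    D01 1.0439 1.0000 1.0439
    D02 1.0533 0.9814 1.0733
    ...
Overall 1.0452 0.9923 1.0533
```

`gmi` > 1 means the unit's productivity grew (D02: +5.3% per year on
average); `bpc` isolates the frontier shift, which tracks the true 1.05, and
`ec` the catch-up component, near 1 because inefficiency was held constant.
Each row satisfies gmi = ec × bpc exactly, and the `Overall` row is the
cross-unit geometric mean. The other examples cover cross-section scoring
and ranking (`01`), the national years-as-DMUs stage (`02`) and truth
recovery on a 100-unit cross-section (`04`).

The same workflow is available from the shell:

```sh
maridea simulate --seed 7 --out data/
maridea analyze --in data/panel.csv --out reports/
```

which writes `scores.csv`, `national.csv`, `malmquist.csv`,
`malmquist_summary.csv` and a run manifest.

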