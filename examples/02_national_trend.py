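"""National stage: aggregate all units per period, then score the years.

Provincial inputs and outputs are summed into one national total per year;
the yearly totals then form a single cross-section in which each *year* is a
decision-making unit scored against all the other years — revealing which
years were nationally efficient.
"""

from maridea import GeneratorConfig, generate_panel, national_scores

panel, _ = generate_panel(GeneratorConfig(seed=42))  # 9 DMUs x 13 years
table = national_scores(panel, rts="crs")
print(table.round(4).to_string(index=False))
print()
print("Each row scores that year's national input-output bundle against the")
print("other twelve years; 'SBM-efficient' years lie on the inter-year")
print("frontier (score is then the super-efficiency margin above the rest).")
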