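"""Simulate a natality-like birth cohort with a known maternal age effect.

The generator draws parental age pairs from a discretised bivariate
normal (maternal mean 29 y, paternal mean 32 y, correlation 0.8) and
assigns each cell a rare-event probability from a known log-odds curve:
here the maternal risk ramps up 2 log-odds units between ages 30 and 45
(odds ratio ~7.4 at the top) while the paternal curve is flat.
"""

import numpy as np

from parage import AgeCurve, SimScenario, simulate_crosstab

scenario = SimScenario(
    total_births=2_000_000,
    maternal_curve=AgeCurve(kind="ramp", start=30, stop=45, height=2.0),
    seed=11,
)
tab, truth = simulate_crosstab(scenario)

print(f"cohort: {tab.total_births:,} births, {tab.total_cases:,} cases "
      f"({1e4 * tab.total_cases / tab.total_births:.1f} per 10,000)")
print(f"grid: {tab.shape[0]} maternal ages x {tab.shape[1]} paternal ages")
print(f"true maternal OR, 45 vs 15: "
      f"{np.exp(truth.maternal_effects[45 - 15] - truth.maternal_effects[0]):.2f}")
print("the sparse corners (old fathers x young mothers) hold almost no births:")
print("births in cells (maternal<20, paternal>55):",
      int(tab.births[:5, -10:].sum()))
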