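"""Full pipeline: simulate several conditions, analyze, and compare.

Runs the simulate -> segment -> register -> metrics -> stats pipeline on
three condition presets and prints the condition summary plus the
ANOVA/Bonferroni comparison of fluctuation amplitudes.
"""

import json

from nucdyn.pipeline import RunConfig, run

cfg = RunConfig(
    conditions=("unstrained_1h", "strained_24h", "strained_48h"),
    cells_per_condition=5,
    zstacks_per_condition=0,
    frames=30,           # shortened movies keep this demo quick
    seed=0,
    out_dir="scratch/example_run",
)
report = run(cfg)

print(report["tables"]["condition_summary"].to_string(index=False))
print()
print("ANOVA p (amplitude):", f"{report['stats']['anova_p']:.4g}")
for pair, ps in report["stats"].get("pairwise", {}).items():
    print(f"  {pair}: Bonferroni p = {ps['p_bonferroni']:.4g}")
print("outputs written to", report["out_dir"])
# amp_sd_mean should sit near 3% for unstrained_1h and 2% for the strained
# conditions; the pairwise comparisons flag the amplitude drop.
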