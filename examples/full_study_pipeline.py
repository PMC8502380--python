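"""A complete two-treatment study, simulated and analysed end to end.

Simulates the default arena experiment (29 control + 21 predator-cue
animals in a 3 m circular arena, 30 s frames), runs the full analysis,
and prints the per-group summaries and treatment-comparison statistics.
"""

from urchinwalk import StudyConfig, analyze_study, simulate_study

dataset = simulate_study(StudyConfig(seed=1))
report = analyze_study(dataset)

print("group sizes:", dataset.group_sizes())
print()
print("per-group means (control vs predator):")
for metric, diff in report.group_summaries["percent_difference"].items():
    by = report.group_summaries["by_treatment"]
    c = by["control"][metric]["mean"]
    p = by["predator"][metric]["mean"]
    print(f"  {metric:<13} {c:8.3f} -> {p:8.3f}   ({diff:+.1f}%)")
print()
print("treatment-comparison models:")
for name, model in report.models.items():
    eff = model.effects[0]
    print(f"  {model.response:<20} {eff.statistic_name} = {eff.statistic:7.2f}, "
          f"p = {eff.p_value:.4f}")
print(f"  Levene (zeta slope)  W = {report.levene['statistic']:7.2f}, "
      f"p = {report.levene['p_value']:.4f}")
print()
print("Predator-cue animals move faster and straighter, their diffusion")
print("slopes cluster near the ballistic line (hence the significant Levene")
print("test for unequal variances), and their turning-angle entropy is")
print("lower: escape paths are more stereotyped, not more erratic.")
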