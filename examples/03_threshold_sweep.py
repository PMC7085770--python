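"""Grid-search the detection thresholds on a small labelled suite.

Reproduces the operating-point selection procedure: among all grid
points, pick the one maximising specificity subject to 100% fall
sensitivity.
"""

from prefall import standard_suite, sweep_thresholds

trials = standard_suite(n_subjects=2, seed=11)
print(f"suite: {len(trials)} trials "
      f"({sum(t.label.is_fall for t in trials)} falls)")

result = sweep_thresholds(
    trials,
    {
        "th_asvm": [0.7, 0.82, 0.95],
        "th_pitch": [40.0, 45.0, 50.0],
    },
)
print(f"\nevaluated {len(result.table)} grid points; top rows by specificity:")
print(result.table.sort_values("specificity", ascending=False).head(5).to_string(index=False))

b = result.best
print(f"\nselected: aSVM<{b['th_asvm']:g} g, pitch>{b['th_pitch']:g} deg -> "
      f"sensitivity {b['sensitivity']:.2f}%, specificity {b['specificity']:.2f}%")
print("(sensitivity is pinned at 100% because a missed fall means an "
      "uninflated airbag; specificity is then maximised.)")
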