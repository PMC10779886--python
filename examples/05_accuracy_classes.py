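"""Accuracy classes and overall accuracy estimation for a screening set.

Without experimental solubilities, interval half-widths are the only
handle on accuracy: a compound whose 90% interval is narrower than
±1 Log(S) sits in the strongest class.  Cumulative fractions across
confidence levels combine into one estimated %LogS±1 for the whole set.
"""

from collections import Counter

from confsol import (
    GridSpec,
    SplitRule,
    SynthSpec,
    accuracy_profile,
    classify_compounds,
    combine_models,
    conformal_intervals,
    generate_dataset,
    grid_search_cv,
    sequential_split,
)

table = generate_dataset(SynthSpec(n_samples=600, seed=9))
tr, te = sequential_split(table, SplitRule(period=3, start_offsets=(2,)))
train, screen = table.subset(tr), table.subset(te)
cols = [f"inf_{i}" for i in range(1, 6)]

grid = GridSpec(max_depth_values=(3,), eta_values=(0.3,), max_rounds=60, n_folds=20)
tuned = grid_search_cv(train.X[cols], train.y, grid, seed=9)
intervals = conformal_intervals(
    train.X[cols], train.y, screen.X[cols], screen.ids, tuned,
    nc_type="ARSS", beta=0.5, levels=(95, 90, 80, 70),
)

classes = classify_compounds(intervals)
counts = Counter(classes.class_label)
print("accuracy classes over", len(screen), "screening compounds:")
for label in ("acc.>90%", "80–90%", "70–80%", "acc.<70%"):
    print(f"  {label:9s}: {counts.get(label, 0):4d}")

profile = accuracy_profile(intervals, levels=(90, 80, 70))
print("fraction with half-width < 1 Log(S):",
      {f"{lv}%": f"{frac:.2f}" for lv, frac in profile.fractions.items()})
print(f"estimated overall accuracy: {profile.overall_accuracy:.1f}% LogS±1")

# combining two models covering disjoint compound sets
combined = combine_models([len(screen), 120], [profile.overall_accuracy, 65.0])
print(f"combined with a 120-compound heavier-set model at 65.0%: "
      f"{combined:.1f}% overall")
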