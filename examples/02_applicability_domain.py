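"""Fit a kNN applicability domain and check which compounds it trusts.

A query compound is inside the AD when its scaled Euclidean distance to at
least one training compound falls under that compound's kNN-derived
threshold; predictions outside the AD should not be trusted.
"""

from confsol import (
    SplitRule,
    SynthSpec,
    ad_coverage,
    apply_preprocessor,
    check_ad,
    fit_ad,
    fit_preprocessor,
    generate_dataset,
    pca_projection,
    sequential_split,
)

table = generate_dataset(SynthSpec(n_samples=450, seed=11))
tr, te = sequential_split(table, SplitRule(period=3, start_offsets=(2,)))
train, test = table.subset(tr), table.subset(te)
prep = fit_preprocessor(train)
Z_train, Z_test = apply_preprocessor(prep, train), apply_preprocessor(prep, test)

model = fit_ad(Z_train, k_fraction=0.375)
print(f"k = {model.k_neighbors} neighbours (37.5% of {len(Z_train)} training rows)")
print(f"training self-coverage: {check_ad(model, Z_train).mean() * 100:.1f}% inside")
print(f"test compounds outside the AD: {ad_coverage(model, Z_test):.2f}% "
      f"(< 0.5% would approve this split)")

# a far-shifted cluster is recognised as foreign chemistry
far = Z_test + 25.0
print(f"far-shifted queries outside: {ad_coverage(model, far):.0f}%")

# PCA projection for coverage diagnostics (never part of the AD decision)
scores_train, scores_test = pca_projection(Z_train, Z_test, n_components=3)
print(f"first 3 PC scores span train [{scores_train[:, 0].min():.1f}, "
      f"{scores_train[:, 0].max():.1f}] vs test [{scores_test[:, 0].min():.1f}, "
      f"{scores_test[:, 0].max():.1f}] on PC1")
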