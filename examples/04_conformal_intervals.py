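"""Cross-conformal prediction intervals: normalized ARSS vs constant AR.

Every training compound doubles as a calibration compound via a repeated
20-fold CV.  The ARSS nonconformity normalizes each residual by the SD of
that compound's repeated CV predictions, so hard-to-predict compounds get
wider intervals; AR gives everyone the same width.
"""

import numpy as np

from confsol import (
    GridSpec,
    SplitRule,
    SynthSpec,
    conformal_intervals,
    efficiency,
    generate_dataset,
    grid_search_cv,
    repeated_cv_predictions,
    residual_interval_correlation,
    sequential_split,
)
from confsol.validation import validate_intervals

table = generate_dataset(SynthSpec(n_samples=600, seed=5))
tr, te = sequential_split(table, SplitRule(period=3, start_offsets=(2,)))
train, test = table.subset(tr), table.subset(te)
cols = [f"inf_{i}" for i in range(1, 6)] + ["noise_1", "noise_2", "noise_3"]

grid = GridSpec(max_depth_values=(3,), eta_values=(0.3,), max_rounds=60, n_folds=20)
tuned = grid_search_cv(train.X[cols], train.y, grid, seed=5)
cvp = repeated_cv_predictions(train.X[cols], train.y, tuned, n_repeats=20)

arss = conformal_intervals(train.X[cols], train.y, test.X[cols], test.ids,
                           tuned, nc_type="ARSS", beta=0.5, cvp=cvp)
ar = conformal_intervals(train.X[cols], train.y, test.X[cols], test.ids,
                         tuned, nc_type="AR", cvp=cvp)

report = validate_intervals(arss, test.y)
print("ARSS error rates (observed vs allowed, t-test at p<0.01):")
for lv, r in sorted(report.levels.items(), reverse=True):
    print(f"  {lv}%: {r.error_rate * 100:5.1f}% vs {r.expected_rate * 100:4.1f}% "
          f"-> {'valid' if r.passed else 'FAILED'} (p = {r.p_value:.3f})")

eff = efficiency({"ARSS": arss}, ar)
e90 = eff.lookup("ARSS", 90)
print(f"median 90% half-width: ARSS {e90.median_hw:.3f} vs AR "
      f"{np.median(ar.halfwidth[90]):.3f} Log(S) "
      f"-> efficiency gain {e90.gain_vs_ar * 100:+.1f}%")

r, r2, p = residual_interval_correlation(arss, test.y, 90)
print(f"half-width vs |residual| correlation: R = {r:.3f} (p = {p:.2g}) — "
      f"wider intervals flag less reliable predictions")
i = int(np.argmin(arss.halfwidth[90]))
print(f"most precisely estimated compound: {arss.ids[i]} "
      f"Log(S) = {arss.center[i]:.2f} ± {arss.halfwidth[90][i]:.3f} (90% conf)")
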