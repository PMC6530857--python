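"""Trial-size effect: CIs shrink with cohort size but the bias stays.

At a fixed 5% comparator misclassification rate, growing the trial narrows
the spread of the apparent AUC without moving its median back toward the
true value - a larger trial makes the *biased* estimate more precise.
"""

import refnoise as rn

scenario = rn.ScenarioSpec(50, 50, "perfect")
sizes = [(50, 50), (100, 100), (200, 200), (400, 400)]
res = rn.size_sweep(scenario, sizes, rn.NoiseSpec.uniform(0.05), n_iter=100, seed=6)

print("n_total  median_AUC  CI_width")
for _, row in res.metric_series("auc").iterrows():
    print(
        f"{int(row['level']):7d}  {row['median']:.4f}      {row['ci_upper'] - row['ci_lower']:.4f}"
    )
print(
    "\nThe median stays near the 0.95 ceiling at every size while the CI width"
    "\nfalls roughly as 1/sqrt(n): under-estimation from comparator noise is a"
    "\nbias, not sampling error, and cannot be averaged away."
)
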