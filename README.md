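# refnoise

Diagnostic tests are rarely evaluated against truth. The reference they are
judged against — the *comparator*, often called a gold standard — is itself a
test or an adjudicated clinical diagnosis, and it misclassifies some
patients. `refnoise` quantifies what that does to the numbers a trial
reports: even a **perfect** test appears degraded when scored against a
noisy comparator, and the distortion is a bias that larger trials make more
precise, not smaller.

The package is for biostatisticians and trial designers who need to know,
before or after a diagnostic accuracy study, how much of the apparent
imperfection of a test can be explained by reference error alone.

## The model

A cohort of `n⁻` truly negative and `n⁺` truly positive patients carries a
continuous test score (and/or a thresholded binary call). The comparator's
labels are the true labels with a controlled number of flips:

* **uniform** — exactly `round(ε·N)` patients flipped, drawn from the pooled
  cohort;
* **class rates** — exactly `round(fp·n⁻)` negatives and `round(fn·n⁺)`
  positives flipped;
* **weighted** — flips drawn without replacement with probability
  proportional to a per-patient weight (e.g. expert-panel uncertainty).

Against any label set the package computes the Mann–Whitney AUC and the
agreement metrics PPA, NPA, PPV, NPV (PPA/NPA are computed exactly like
sensitivity/specificity; the names acknowledge that the reference may be
wrong). A Monte-Carlo engine repeats the injection (default 100 cycles) and
reports medians with empirical 95% intervals, swept over noise level or
trial size.

Closed forms accompany the simulator. Each comparator class is a mixture of
truly-positive and truly-negative patients, which gives, e.g.,

    PPA′ = [(1−fn)·n⁺·se + fp·n⁻·(1−sp)] / [(1−fn)·n⁺ + fp·n⁻]
    AUC′ = (1−a)(1−b)·A + [(1−a)b + a(1−b)]/2 + ab·(1−A)

with `a`, `b` the contaminated fractions of the comparator-positive and
-negative groups. For a perfect balanced test at overall flip rate ε the
apparent AUC is capped at `1 − ε` — the **AUC ceiling**. An exact binomial
tail gives the probability that a perfect test *fails* a fixed agreement
requirement (say, 99% PPA) purely because of comparator error.

An expert-panel module models adjudicated comparators: three blinded
panelists each call a patient positive / negative / indeterminate
(mapped to 1 / 0 / ½); their simple average is the patient's classification
confidence, patients stratify into nested agreement groups
(super-unanimous ⊆ unanimous ⊆ consensus ⊆ forced), and the residual
uncertainty `1 − max(c, 1−c)` yields per-patient flip weights and
comparator FP/FN rate estimates.

## Worked example

```bash
python examples/auc_ceiling.py
```

```
rate  median_AUC  95%_empirical_CI      analytic_ceiling
0.00  1.0000      (1.0000, 1.0000)    1.0000
0.05  0.9493      (0.9297, 0.9649)    0.9500
0.10  0.9028      (0.8825, 0.9259)    0.9000
0.15  0.8519      (0.8256, 0.8757)    0.8500
0.20  0.8006      (0.7697, 0.8286)    0.8000
```

A test with true AUC 1.0 evaluated against a comparator that misclassifies
10% of patients shows a median apparent AUC of about 0.90: reporting such a
test as "AUC 0.90" without qualification would understate a perfect test.
The other examples (`worked_table.py`, `trial_size.py`,
`panel_workflow.py`) print the 2×2-table worked example under 5% noise
(PPA falls from 0.970 to ≈0.929), the shrink-but-don't-move effect of trial
size, and the panel pipeline end to end.

The same workflows are available from a thin CLI:

```bash
refnoise sweep --n-neg 100 --n-pos 100 --shape perfect \
    --levels 0:0.2:0.01 --iters 100 --seed 42 --out sweep
refnoise analytic --levels 0,0.05,0.1,0.2 --required-level 0.99 --out limits
refnoise simulate-panel --n-neg 100 --n-pos 100 --out panel.csv
refnoise panel --input panel.csv --out report
```

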