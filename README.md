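# erdodi

A toolkit for **multivariate performance-validity assessment** with the
Erdodi Index (EI) — plus the diagnostic-accuracy machinery needed to
validate any scalar validity index against criterion performance
validity tests (PVTs), and a synthetic-cohort generator so the whole
pipeline is testable without clinical data.

## The problem and the model

Neuropsychological test interpretation assumes the examinee performed
credibly. Embedded validity indicators (EVIs) — validity cutoffs nested
inside ordinary ability tests — monitor that assumption inconspicuously,
but a single EVI at a single cutoff imposes an artificial Pass/Fail
dichotomy on an inherently continuous construct and has weak accuracy on
its own.

The EI model aggregates *k* heterogeneous EVIs by recoding each raw
score onto a common 4-point ordinal *level of failure* scale using
three published cutoffs per indicator, ordered liberal to
ultra-conservative:

| Level | Meaning | Typical calibration |
|------:|---------|---------------------|
| 0 | passed the most liberal cutoff | — |
| 1 | failed the liberal cutoff | specificity ≥ .84 |
| 2 | failed a more conservative cutoff | base rate of failure ≈ 10% |
| 3 | failed an ultra-conservative cutoff | base rate ≈ 5% |

The index value is the unweighted sum

```
EI = Σⱼ levelⱼ   ∈ {0, …, 3k}
```

and is trichotomized: for the standard five-component index (EI-5,
range 0–15), **Pass** ≤ 1, **Borderline** 2–3, **Fail** ≥ 4. The
Borderline band is a legitimate third outcome, excluded from analyses
that need a dichotomy. Reaching Fail requires at least four failures at
the liberal cutoffs or at least two at the conservative cutoffs — the
composite captures both the *number* and the *extent* of failures.

The default battery ships with the package (WAIS Coding ACSS, Rey
Complex Figure copy, WCST failures-to-maintain-set, Reliable Digit
Span, CVLT recognition hits); custom batteries are plain YAML/JSON.

The `diagnostics` module provides the evaluation vocabulary of this
literature: confusion metrics at inclusive cutoffs (sensitivity,
specificity, overall correct classification OCC, multivariate base rate
of failure BR_Fail), cutoff sweeps, the Mann–Whitney AUC with a
Hanley–McNeil confidence interval, band-wise likelihood ratios
(LR = ratio of criterion BR_Fail between two index ranges), and the
field's effect-size conventions (Cohen's *d* with the average-variance
denominator, Φ² = χ²/N).

## Worked example

```python
import pandas as pd
from erdodi import default_battery, score_cohort

battery = default_battery()
cohort = pd.DataFrame({
    "CD":        [10, 6, 5],
    "RCFT_Copy": [34.0, 28.0, 24.0],
    "FMS_WCST":  [0, 3, 4],
    "RDS":       [12, 8, 6],
    "RH_CVLT":   [15, 13, 12],
})
print(score_cohort(cohort, battery)[["ei_total", "ei_band"]])
```

prints

```
 ei_total    ei_band
        0       Pass
        3 Borderline
        9       Fail
```

Row 1 passes every liberal cutoff (total 0 → Pass); row 2 accumulates
three marginal level-1 failures (total 3 → Borderline, too much
evidence to call valid, not enough to call invalid); row 3 fails four
indicators at conservative cutoffs (total 9 → Fail).

The `examples/` directory holds one short script per capability:
scoring, cutoff sweeps, band-wise likelihood ratios, and
simulation-based recovery. Running
`python examples/04_simulation_recovery.py` prints

```
shift 0.5 SD: AUC vs truth = 0.742 [0.718, 0.766], sens/spec at >= 4 = 0.58/0.86
shift 1.0 SD: AUC vs truth = 0.838 [0.818, 0.859], sens/spec at >= 4 = 0.78/0.86
shift 2.0 SD: AUC vs truth = 0.956 [0.945, 0.968], sens/spec at >= 4 = 0.96/0.86
```

— the index's discrimination of a planted non-credible state grows with
the planted effect size, the generator's own validity check.

A thin CLI mirrors the library:

```bash
erdodi simulate --n 452 --prevalence 0.2 --seed 7 --out cohort.csv
erdodi score --cohort cohort.csv --out scored.csv
erdodi roc --cohort scored.csv --score ei_total --criterion wmt_fail --cutoffs 1:7
erdodi ranges --cohort cohort.csv --criteria wmt_fail,msvt_fail
```

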