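# sepsispanel

Evaluation of immune dysregulation in sepsis with a composite marker-gene
panel, as a tested, reusable Python pipeline.

Sepsis combines hyper-inflammation (neutrophil degranulation, interferon
signaling) with immunosuppression (loss of MHC class II expression,
lymphopenia). `sepsispanel` quantifies both arms from peripheral-blood bulk
RNA-seq using five small gene sets:

| panel | genes | arm | direction in sepsis |
|-------|-------|-----|---------------------|
| NDrG | S100A12, CD177, HP, ANXA3, ARG1 | neutrophil degranulation | activated (+1) |
| ISGa | IFI27, RSAD2, IFI44L, ISG15, IFITM3 | type I interferon | bidirectional (0) |
| GBPs | GBP1–GBP5 | type II interferon | bidirectional (0) |
| HLAd | HLA-DRA, HLA-DRB1, HLA-DMA, HLA-DMB, HLA-DPA1 | MHC class II | suppressed (−1) |
| LYMd | CD4, CD8A, CD79A, CD27, KLRF1, FCER1A | lymphocytes / dendritic cells | suppressed (−1) |

A panel score is the mean log2-normalized expression of its member genes in
a sample; raw counts are first converted to log2(CPM + 1). The **composite
score** is NDrG − HLAd. Low composite values identify likely survivors among
ICU sepsis patients: the core decision rule predicts *survivor* when
composite < 1.50 (strict), optionally OR-combined with SOFA < 8 and an
exploratory GBPs > 8.5 clause. The package provides:

- scoring (`score_samples`) and I/O for delimited expression/metadata tables;
- cohort statistics: Welch and paired t contrasts, Tukey–Kramer HSD,
  panel–SOFA Pearson correlation, PCA over the five standardized scores;
- outcome rules: rule application, confusion-matrix evaluation,
  zero-false-positive threshold search, threshold sweeps;
- serial monitoring: per-subject panel deltas across ICU time points and
  reversal-of-dysregulation flags;
- a seeded negative-binomial synthetic-cohort generator whose presets mirror
  the published study designs and effect sizes, so everything runs at desk
  scale with no downloads.

## Worked example

```python
from sepsispanel import (preset, simulate_cohort, score_samples,
                         two_group_contrast, score_sofa_correlation)
from sepsispanel.io import normalize_log2
from sepsispanel.rules import RuleSpec, apply_rule, evaluate_rule, zero_fp_threshold

# an ICU outcome cohort: 60 survivors, 18 non-survivors, 44 healthy controls
matrix, records = simulate_cohort(preset("icu_outcome"), seed=1)
scores = score_samples(normalize_log2(matrix))

contrast = two_group_contrast(scores, records, "non_survivor", "survivor", "NDrG")
print(f"NDrG survivor - non-survivor: {contrast.mean_diff:+.2f} log2 units "
      f"(Welch t = {contrast.statistic:.2f}, p = {contrast.p_value:.2e})")

corr = score_sofa_correlation(scores, records, "NDrG",
                              groups=["survivor", "non_survivor"])
print(f"NDrG vs SOFA: Pearson r = {corr.r:.3f} (n = {corr.n})")

rule = RuleSpec.parse("composite<1.5,sofa<8")
ev = evaluate_rule(apply_rule(scores, records, rule), records)
print(f"rule [{rule.describe()}]: sensitivity {ev.sensitivity:.2f}, "
      f"false positives {ev.false_positives} of {ev.fp + ev.tn} non-survivors")

zf = zero_fp_threshold(scores, records)
print(f"zero-false-positive composite threshold: {zf.threshold:.2f} "
      f"(identifies {zf.sensitivity:.0%} of survivors)")
```

Output:

```
NDrG survivor - non-survivor: -1.81 log2 units (Welch t = -6.02, p = 3.88e-06)
NDrG vs SOFA: Pearson r = 0.486 (n = 78)
rule [composite<1.5 OR sofa<8]: sensitivity 0.40, false positives 1 of 18 non-survivors
zero-false-positive composite threshold: 3.96 (identifies 77% of survivors)
```

The first line recovers the configured survivor-vs-non-survivor NDrG
difference (−1.71 configured; one 78-patient cohort estimates it with
sampling noise). The correlation reflects the calibrated SOFA model
(target 0.508). The rule line shows the combined composite/SOFA rule's
confusion metrics on this cohort — note that absolute score levels (and
hence the 1.50 cutoff) are platform-dependent, which is why the
zero-false-positive threshold search on the last line matters: on each
dataset it finds the largest composite cutoff admitting no non-survivor.

The same pipeline is available from the shell:

```bash
sepsispanel simulate --preset icu_outcome --seed 7 --out sim/
sepsispanel run --expression sim/expression.tsv --metadata sim/metadata.tsv \
    --raw-counts --contrast non_survivor:survivor \
    --rule "composite<1.5,sofa<8" --out results/
sepsispanel run --preset shock_timecourse --seed 1 --paired T1:T3 --out shock/
```

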