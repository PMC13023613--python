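# Methods

## Scoring model

Each marker panel is scored per sample as the arithmetic mean of its member
genes' log2-normalized expression. Raw counts are normalized as
log2(CPM + 1), where CPM[g, s] = count[g, s] / total(s) × 10⁶; matrices
declared already log2-normalized are used as-is, with no re-normalization or
per-dataset z-scaling. "Normalized counts" admits several conventions;
counts-per-million with a pseudocount of one is the simplest choice
consistent with a log2 transform of library-size-corrected counts, and the
normalization is isolated in one function so median-of-ratios or similar
could be slotted in.

The composite score is NDrG − HLAd. LYMd is deliberately excluded from the
composite: patients with favorable LYMd values also have low composite
values, so the two-panel difference is the simpler model. Being a
difference of two mean-log2 scores, the composite is invariant to any
per-sample additive shift on the log2 scale (equivalently, to per-sample
rescaling of expression), which is why no reference genes are needed.

Missing-data policy: gene-symbol matching is exact and case-insensitive
(both sides uppercased), with no alias expansion — alias maps drift across
annotation releases and would make scores irreproducible. A panel with some
members absent is scored over the available members; the per-panel coverage
fraction is reported and each absent symbol warned about. Only a panel with
zero coverage is an error (or NaN under `missing_panel="nan"`). Duplicate
gene symbols in an input matrix are collapsed by the per-sample maximum,
which avoids diluting the dominant isoform's signal and is deterministic.

## Statistics

* Unpaired contrasts use the Welch unequal-variance t test
  (Welch–Satterthwaite df). Mean differences and the statistic are oriented
  second-group-minus-first throughout.
* Paired contrasts are t tests on per-subject deltas over complete pairs;
  subjects missing either time point are dropped with a logged count. A
  zero-variance delta vector is reported as a degenerate-input error rather
  than an infinite statistic.
* Multi-group comparisons use Tukey HSD on the studentized-range
  distribution with the Tukey–Kramer unequal-n correction (pooled error
  variance). A seeded max-statistic permutation FWER procedure is provided
  as an independent validation route; it is somewhat conservative relative
  to the studentized-range adjustment at small n.
* Panel–SOFA association is the Pearson correlation on complete cases
  (≥ 3 required).
* PCA operates on the five panel scores (not the 26 genes), centered and
  scaled to unit variance, via SVD. Component signs are fixed so each
  component's largest-magnitude loading is positive. Two-sided p-values
  throughout; no cross-panel multiplicity correction (panels are reported
  individually).

## Outcome rules

All rule inequalities are strict, exactly as stated: composite < θc
(default 1.50), SOFA < θs (default 8), GBPs > θg (default 8.5), combined by
OR. Boundary values are never identified as survivors. A sample missing the
input of any *enabled* clause is unevaluable and excluded from confusion
counts (tallied separately), as is any sample with unknown outcome.

Because "false positive rate" has two natural denominators here, the
evaluation reports both explicitly — FP/(TP+FP) among positive predictions
and FP/(FP+TN) among known non-survivors — and names neither one "the" FPR.

The zero-false-positive threshold search returns θ\* = the minimum composite
value among known non-survivors: `composite < θ\*` then admits no false
positive, and no larger threshold can. The threshold sweep tabulates
sensitivity and FP count over a grid (always including 1.50); both are
non-decreasing in θ by construction. The cutoff itself is
platform-dependent, so the search and sweep, not the fixed 1.50, are the
portable tools.

## Serial monitoring

A reversal of dysregulation is a strictly nonzero per-subject delta whose
sign opposes the panel's sepsis direction (NDrG decreasing; HLAd or LYMd
increasing). No magnitude threshold is imposed, since none is established.
ISGa and GBPs are bidirectional across patients, so reversal is undefined
for them: they are left unflagged and excluded from reversal summaries.
Responder analyses combine within-group paired contrasts with the
cross-group contrast of the responders at the later time point against the
non-responders at the earlier one, the most discriminative comparison in
the source designs.

## Synthetic cohort generator

The published analyses report panel-score effects, not per-gene data, so
the generator is built so that *configured score-scale effects survive the
full count round trip*:

1. latent panel score L ~ Normal(μ_p(group), σ_p²) per sample, on the
   log2(CPM+1) scale; bidirectional panels draw a mixture offset first
   (e.g. GBPs suppressed by −1.5 in 10/14 of sepsis samples in the
   sepsis-vs-control preset);
2. member-gene targets L + β_g + ε with fixed zero-sum offsets β
   (evenly spaced over ±0.8) and ε ~ Normal(0, τ²);
3. background genes (default 2,000, fixed means uniform on [2, 9] log2
   units) get independent targets;
4. expected CPM = max(2^target − 1, 0); background CPMs are rescaled per
   sample so expected CPMs sum to exactly 10⁶ — this makes recovery of the
   configured means unbiased through CPM normalization;
5. counts ~ NB(mean = CPM·library/10⁶, dispersion φ), library sizes uniform
   on [5×10⁶, 2×10⁷]. φ = 0 means deterministic rounded expected counts
   (the exact noiseless limit used in tests); the NB Jensen bias on the
   log2 scale (≈ −φ/(2 ln 2) per gene at high counts) is nearly constant
   across groups and cancels in contrasts.

Defaults σ_p = 1.0, τ = 0.5, φ = 0.1 are plausible bulk RNA-seq magnitudes.
Longitudinal designs reuse a subject's baseline latents and add the
configured cumulative per-panel delta for each later time point plus
Normal(0, delta_sd²) subject noise (delta_sd = 0.4). One integer seed
drives a single `numpy.random.Generator`; identical seeds give
bitwise-identical cohorts.

**SOFA model.** For sepsis groups, SOFA = clip(round(a + b·L_NDrG +
Normal(0, s²)), 0, 24); healthy controls carry no SOFA. For the ICU-outcome
preset, b is fixed at 1.2 per log2 unit and s is solved in closed form so
the pooled NDrG-score/SOFA Pearson correlation over the 60 + 18 patients
targets 0.508, using the group-mixture latent variance, an estimate of the
score measurement variance (τ²/5 + φ/ln²2/5), and the 1/12 rounding
variance; clipping is ignored (≈ 4 SD from the bounds). The intercept sets
the mean sepsis SOFA to 8.2, a typical ICU admission severity.

**Preset calibration.** Group sizes match the source cohorts (e.g.
ICU outcome 60/18/44; septic shock 21 subjects × 3 time points; responders
17/14 and 23/14). NDrG/HLAd/LYMd between-group offsets and longitudinal
deltas equal the published mean differences; responder baselines are offset
so the cross-group responder-late vs non-responder-early contrasts also
match. The hyper-vs-hypo-inflammation and post-surgery CRP effect sizes are
not published numerically; the preset values (e.g. hyper−hypo NDrG +1.5,
HLAd −1.0, LYMd −1.0) are this package's choices, picked once as magnitudes
intermediate between the sepsis-vs-control and outcome contrasts. Healthy
baselines (NDrG 7.5, ISGa 8.0, GBPs 8.0, HLAd 9.5, LYMd 8.5 log2(CPM+1))
reflect that MHC-II genes are highly expressed in healthy blood while
NDrG genes are strongly induced in sepsis.

**What the generator does not emulate:** per-gene realism beyond panel
structure (no gene–gene correlation outside panels), batch effects,
platform differences, or sequencing-error models. Passing recovery tests
therefore demonstrates that the pipeline estimates panel-level effects
without bias at realistic noise levels — not that the fixed 1.50 cutoff or
any specific sensitivity transfers to a new platform.

## Problem sizes and numerical choices

Recovery checks run 50 replicate cohorts per preset at the source cohort
sizes (~29–122 samples × 2,026 genes), which bounds Monte-Carlo error of
the averaged mean differences at roughly ±0.05 log2 units (SE) and runs in
seconds. Null calibration of the tests uses 1,000 replicate null cohorts at
the score level. Text outputs carry 6 significant digits. Degenerate inputs
(zero-coverage panels, zero-total samples, zero-variance groups, < 2
complete pairs, empty threshold grids) raise typed errors rather than
returning NaN.

## Known limitations

* The composite cutoff 1.50 and GBPs cutoff 8.5 are assay-specific; only
  the threshold-search machinery, not the constants, should be expected to
  transfer.
* Tukey HSD assumes equal within-group variances (pooled MSE); the Welch
  route does not, so two-group questions should prefer it.
* The generator's SOFA model is linear in the NDrG latent with Gaussian
  noise — adequate for correlation-level calibration, not a clinical model
  of organ failure.
* Responder/non-responder labels are taken as given metadata; no SOFA-change
  cutoff is imposed to derive them.
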