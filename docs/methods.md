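# Methods

`rasosig` reimplements, as a tested pipeline, a PBMC transcriptional-signature
analysis for RASopathy mutation groups: bulk expression profiles from
peripheral blood mononuclear cells of four sample groups — healthy controls
and carriers of germline mutations in *PTPN11*, *SOS1* or *SHOC2* — are
filtered, compared against the controls with a three-part differential
expression criterion, the resulting signatures are audited by permutation,
used for leave-one-out classification, and mined for gene-set enrichment and
transcription-factor circuits.

## Preprocessing

Input is a probes × samples matrix of instrument-normalized linear
intensities with per-probe/per-sample detection p-values, plus a sample
sheet carrying the group label and the known confounders of bulk PBMC
expression: age, sex, and the five-part differential leukocyte count
(neutrophil/lymphocyte/monocyte/eosinophil/basophil fractions — cell
composition is the dominant nuisance signal in whole-PBMC profiling).

1. **Scaling and log2.** Each sample column is rescaled to a common mean
   intensity (default: the grand mean of the column means, so the overall
   scale is preserved), clipped from below at 1 intensity unit, and
   log2-transformed. Mean scaling is deliberately simple — spline
   normalization is assumed to have been applied upstream by the instrument
   software.
2. **Detection filter.** A probe is kept if its detection p-value is < 0.01
   in at least 50% of the samples of at least one group. The per-group
   variant (default) keeps group-specifically expressed probes that a pooled
   fraction would discard.
3. **Confounder filter.** Each probe is tested for association with the
   seven confounders: Pearson correlation for age and each leukocyte
   fraction, point-biserial (Pearson against the 0/1 code) for sex. Any
   association with p < 0.01 removes the probe (any-hit rule); the report
   records which confounder fired. Under the null this removes
   1 − 0.99⁷ ≈ 6.8% of probes — the price of a conservative screen.
   Constant probes and constant confounders yield undefined correlations;
   they are retained/skipped with a logged note, using a relative variance
   tolerance so that values constant up to float rounding count as constant.
4. **Log2-ratio.** Per probe, the mean over control samples is subtracted;
   control rows are zero-mean by construction, and a case sample's value is
   its log2 fold change against the control average.

## Signature selection

For a comparison of case group(s) vs controls, a probe enters the signature
iff it passes all three criteria (strict inequalities):

* |mean case log2-ratio| > 0.5 (fold change above √2×),
* two-sample t-test p < 0.01 (Welch by default; pooled-variance Student
  available via `Thresholds(equal_var=True)`),
* |SNR| > 0.5, where SNR = (x̄_case − x̄_ctrl)/(s_case + s_ctrl) with
  sample (ddof = 1) standard deviations — the Golub-style signal-to-noise
  statistic standard in expression classification.

The three thresholds are the classical defaults for this kind of analysis
and are exposed in `Thresholds`. The four standard comparisons are
PTPN11-vs-control, SOS1-vs-control, SHOC2-vs-control, and the pooled
"NS+NS/LAH" comparison whose case arm is the union of the three mutation
groups. Degenerate probes (zero variance in both arms) get SNR 0 for equal
means and signed infinity otherwise, so a genuine constant offset always
clears the magnitude threshold while a constant probe never does.

No multiple-testing correction is applied beyond the permutation audit
below; the triple criterion is intentionally a filter, not an inference.

## Permutation FDR

The false-positive content of a signature is estimated by Monte Carlo:
case/control labels are shuffled among the samples of the comparison
(group sizes preserved; 2,000 permutations by default), the full triple
criterion is re-run each time, and

    fdr_estimate = mean(null hit count) / observed hit count.

Zero observed hits reports NaN (not applicable) with the null counts still
returned. Confound filtering is not re-run per permutation — it does not
involve the group labels. The permutation pool is ordered canonically
(sorted sample ids) so the estimate is bit-reproducible and invariant to
the storage order of probes and samples.

## Leave-one-out classification

Each sample is held out in turn; all four signatures are re-derived from
scratch on the remaining samples, and the held-out sample gets one weighted
average score per signature:

    score = Σ_g w_g (x_g − b_g) / Σ_g |w_g|

with w_g the probe's training-fold SNR and b_g the midpoint of the two
training-group means (Golub weighted voting — the canonical score for
SNR-selected signatures; it is isolated in `weighted_score` so alternatives
can be swapped). Positive scores vote for the case group. A fold whose
signature comes out empty scores 0 and is flagged. Every fold statistic is
computed from training columns only and is invariant to per-probe constant
shifts, so scoring behaves identically on log2 or log2-ratio input and the
held-out sample can never leak into its own fold's model.

Group separation of the pooled LOO scores is assessed with a two-sided
Welch t-test, and an "optimal" threshold is chosen to maximize balanced
accuracy (the midpoint of the best cut interval; with several equally good
intervals, the middle one).

**Known limitation — the separation t-test is anti-conservative under the
null.** LOO folds share all but one training sample, so the per-fold
re-selected signatures converge on the same chance-selected probe axis and
all samples' scores project onto it: the scores are correlated across
samples, violating the independence assumption of the t-test. On global-null
or label-permuted simulations the nominal 5% test rejects in roughly 30–40%
of replicates, with a random per-replicate sign of the group gap. This is a
property of the procedure itself (per-fold feature re-selection followed by
a t-test on pooled cross-validation scores), not of this implementation —
leakage is exactly zero by construction. Separation p-values should
therefore be read as descriptive on real data; a calibrated test would need
an outer label-permutation null for the separation statistic itself. The
acceptance test stating the nominal property is kept and fails, and the
acceptance script reports the measured fraction.

## Enrichment and TF/target circuits

Signature data mining is one local statistic over user-supplied GMT
collections (kinase substrates, functional keywords, TF targets): the
upper-tail hypergeometric probability of the observed overlap between the
signature and each set, with the universe defaulting to the union of the
collection (recommended: the detected-and-unconfounded probes mapped to
genes — the hypothesis space actually tested). Direction-stratified testing
(up-only / down-only) is a flag. Results are reported at p < 0.01.

A transcriptional circuit is called when a TF is itself in a signature,
≥ 3 of its annotated targets are in the same signature, and the targets'
up/down split is biased by a two-sided exact binomial test (p₀ = 0.5) at
p < 0.05. Orientation (target majority matching or opposing the TF's own
direction) is reported, not filtered — anti-correlated circuits are
biologically meaningful (e.g. feedback).

## Unsupervised exploration

Samples are clustered hierarchically (default 1 − Pearson correlation over
probes, average linkage, tree cut at k = 4 — the number of groups), and
each cluster is tested for enrichment in each group label by one-sided
Fisher exact test; the dendrogram exports to Newick. On synthetic data the
correlation-distance tree is degenerate near the root: simulated controls
share no correlated structure, so everything sits at distance ≈ 1 and the
k-cut isolates noise outliers rather than the planted groups, while Ward on
Euclidean recovers them exactly. Real PBMC data have correlated structure
among controls, so the correlation default is kept; both options are
configuration.

The heatmap export mirrors the usual presentation: signature-blocked rows,
group-ordered columns, diverging green–black–red scale centred at 0.

## Synthetic data generator

The generator emulates an Illumina BeadChip-style experiment with the study
design: 20,589 probes; 21 controls, 17 PTPN11, 6 SOS1, 5 SHOC2 samples. Per
probe g and sample s on the log2 scale

    x_gs = μ_g + δ_g·sign_g·1[s ∈ group(g)] + β·c_s·1[g confound probe] + ε_gs

with μ_g ~ N(8, 2²) (log2 intensity baseline typical of bead arrays),
ε_gs ~ N(0, 0.5²), planted effects δ of 1.0 log2 units split half up/half
down, and confounder slopes β = 0.5 log2 units per confounder SD (150
probes each for age, sex and the leukocyte fractions — strong enough for
the confound screen to find). Ages are uniform on 2–18 years (a pediatric
cohort), sex is Bernoulli(0.5), and the leukocyte five-part differential is
Dirichlet with concentration (25, 19, 4, 1.5, 0.5), centred on typical
pediatric proportions. Planted and confound probes are drawn disjointly
from the probes above the low-expression quantile so detection filtering
cannot silently delete the truth. Detection p-values are U(0, 0.01) for
detected pairs; probes in the lowest 70% of baseline expression drop out
per-sample with probability 0.85, receiving U(0.05, 1) — with the default
detection rule this leaves ~30% of probes, and after confound removal a
surviving count of the same order as a real PBMC array experiment (the
acceptance script measures ~6,300 of 20,589). The emitted matrix is the
linear intensity 2^x times a per-array scale factor (2^N(0, 0.1²)), which
per-column mean scaling removes exactly.

Residual variance is homoscedastic by default; real array data are
heteroscedastic, so `variance_shape` optionally draws per-probe variances
from an inverse-gamma (mean held at `residual_sd²`; shape ≈ 3–5 gives a
realistic spread). What the generator does not emulate: probe effects
correlated between genes, batch structure, or correlated structure among
control samples. Passing tests therefore demonstrate calibration and
power of the statistics under an idealized null, not robustness to array
artifacts.

## Acceptance harness problem sizes

`scripts/acceptance.py` measures the calibration/power properties on
5,000-probe simulations of the full 49-sample design: 20 global-null
replicates for the type-I error of the triple criterion; 20 planted
replicates (200 planted probes, effect 1.0, residual SD 0.5) for FDR
calibration (200 permutations each) and sensitivity, against the analytic
noncentral-t Welch power oracle; 20 planted and 40 label-permuted
replicates for LOO separation; and a 600-probe full-pipeline double run
for byte-level determinism. These simulations feed the selection statistics
the generator's exact log2 signal (no scale wobble), so measured
calibration reflects the statistics rather than interactions with mean
scaling, which is validated separately. Exact-oracle checks (SNR, weighted
score, hypergeometric by exhaustive draw enumeration, binomial by outcome
enumeration) run alongside.
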