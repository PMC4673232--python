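# Methods

`csfmir` re-implements, as a tested pipeline over synthetic data, a CSF
(cerebrospinal fluid) microRNA diagnostic analysis for central nervous
system tumors: a NanoString-style screening stage, an RT-PCR (TaqMan)
validation stage based on 2^-ΔΔCt relative quantification, and an
executable rule chart that turns a five-miRNA CSF profile (miR-451,
miR-711, miR-935, miR-223, miR-125b) into a diagnostic call.

## Cohort model

The cohort is fixed by design: 48 patients in seven diagnosis groups
(Normal 14, Benign 15, Glioblastoma 4, Medulloblastoma 3, lung metastasis
4, breast metastasis 5, primary CNS lymphoma 3) contributing 82 CSF
samples; some neoplastic patients have repeated post-surgical lumbar
punctures (up to 7 per patient). The Benign group pools glioma, ependymoma
and meningioma patients; histology is kept in the patient id so other
groupings remain expressible. Two derived groups are computed, never
stored: `Metastasis` (lung ∪ breast) and `Malignant` (glioblastoma,
medulloblastoma, both metastases).

## Effect table: one generative truth from pairwise fold changes

The validated comparison table reports pairwise fold changes FC = 2^-ΔΔCt
between groups, plus three qualitative rows stating miR-935 is entirely
not expressed in glioblastoma, medulloblastoma and lymphoma. Each numeric
row contributes a linear equation on the log2 expression scale,

    offset(up) − offset(ref) = log2(FC),

with a derived `Metastasis` label entering with weight 1/2 per metastasis
subgroup. The per-miRNA system is over-determined (e.g. the miR-223 rows
disagree by ~0.1 log2 between the direct glioblastoma-vs-medulloblastoma
row and the difference of the two vs-Normal rows), so offsets are fit by
minimum-norm least squares; residuals are reported, and rows whose fitted
residual exceeds 0.25 log2 raise a consistency error naming the violators.
Components disconnected from the reference group keep the mean-zero
minimum-norm anchoring. One anchor row (miR-935, Normal vs Benign, FC = 1)
encodes the reported absence of deregulation between those groups and ties
Normal into the otherwise disconnected miR-935 component. Fitted truths
for derived groups are patient-weighted means of the constituent offsets,
matching how the quantification stage pools patients, so noise-free
estimates reproduce the truths to machine precision.

## Ct generator

Per miRNA and patient, mean Ct = baseline − offset + N(0, σ_patient); each
longitudinal sample adds N(0, σ_within); each of three technical
replicates adds N(0, σ_rep). The cel-miR-248 spike-in (an exogenous
C. elegans miRNA added at fixed amount before extraction) is drawn
independently of group around 20 cycles. All values are censored at
ct_max = 40 cycles; absent (miRNA, group) pairs emit ct_max for every
replicate. Defaults (all configurable, Ct units): σ_patient = 1.0,
σ_within = 0.5, σ_rep = 0.3, spike-in sd 0.15. σ_patient = 1.0 is
consistent with the published significance levels: e.g. a 3.19-fold
(1.67 log2) difference at n = 4 vs 3 with one-tailed p = 0.031 implies a
patient-level sd near 0.95 Ct. Baseline Cts (22–35) place every detected
group within the detectable range. Randomness is per-(stream, miRNA):
each miRNA, the spike-in, and each count tag draws from its own named
child stream of the root seed, so adding a miRNA never perturbs existing
values and equal seeds give bit-identical datasets.

## Count generator

A NanoString-like panel of 300 tags (≥ 100 required by the normalization)
embeds the five targets in a null background whose log2 baselines are
uniform on (3, 11). Expected count = 2^(baseline + offset) × library-size
factor (uniform on (0.7, 1.3) per sample); counts are negative binomial
with var = μ + φμ². The dispersion default φ = 0.02 (CV ≈ 14 % at high
counts) models the technical precision of digital counting and was chosen
by power analysis so that the embedded truths are detectable at the study
group sizes — the regime the screening stage is reported to have operated
in. φ = 0 means deterministic rounded expected counts (the noise-free
limit). Absent pairs get a floor expectation of 0.5 counts. The generator
has no patient-level random effect in the counts; φ absorbs both technical
and residual biological variation, which understates between-patient
correlation of real repeated samples.

## Screening stage

Normalization: per sample, g_s = geometric mean of that sample's 100
largest counts; scale factor = mean_s(g_s)/g_s. When all top-100 counts
are positive the factor is exactly scale-equivariant, making
renormalization the identity to machine precision; a sample with zeros in
its top set gets a +1 pseudo-count and a QC flag. A global-top-100 mode is
available. The log2 layer is log2(scaled + 1).

Differential expression: repeated samples are collapsed to patient means
of the log2 layer (patients, not punctures, are the experimental units),
then a two-group cell-means model per tag gives effect = mean difference,
pooled residual variance s² with d degrees of freedom. Empirical-Bayes
moderation shrinks s² toward a prior: s̃² = (d₀s₀² + ds²)/(d₀ + d), with
(d₀, s₀²) estimated by moment-matching the scaled-F distribution of the s²
via digamma/trigamma inversion (Newton with a bisection fallback); the
moderated t = effect/(s̃·√(1/n_A + 1/n_B)) has d₀ + d degrees of freedom.
Degenerate inputs: all s² equal ⇒ d₀ = ∞ (complete shrinkage); d₀ forced
to 0 reproduces the ordinary pooled t exactly. The implementation agrees
with the Bioconductor reference to ~1e-8 on a shared fixture (tested via
Rscript) but never calls it.

P-values are adjusted per contrast by the Benjamini–Hochberg step-up.
The screening battery runs 17 contrasts — Normal vs all others pooled,
all 15 pairs among the six analysis groups (metastases pooled), and lung
vs breast metastasis — and keeps tags with q < 0.05 in at least a strict
majority (9) of contrasts, ranked by number of significant contrasts then
best q.

## RT-PCR quantification

Triplicates are collapsed by arithmetic mean. A mean Ct ≥ 39 cycles
(configurable; the boundary counts as undetected) flags the miRNA as not
expressed in that sample — a conservative reading of "close or equal to
40". ΔCt = Ct(miRNA) − Ct(spike-in) per sample; a sample whose spike-in is
undetected fails QC and is excluded with a record. Patients with repeated
samples contribute the mean ΔCt over their detected time points.
Comparisons report ΔΔCt = mean ΔCt(up) − mean ΔCt(ref), FC = 2^-ΔΔCt, and
a one-tailed Welch t-test with the alternative fixed by the hypothesized
up-regulated group (never by the observed data; a two-tailed and a pooled
variant exist by flag). Undetected values are excluded from means rather
than imputed at the ceiling; a group entirely undetected yields a
"(not expressed)" annotation instead of a finite fold change. Zero
within-group variance with equal means gives p = 0.5 (the symmetric
null); with separated means, the numerical floor. The default battery is
the printed table: 25 numeric rows + 3 not-expressed rows.

## Diagnostic chart

Each miRNA is binned into absent / low / moderate / high. The chart's
published levels are qualitative, so numeric boundaries are calibrated
from a labeled cohort: per miRNA, group centers are log-scale means of
2^-ΔCt; each group is assigned its chart level (a transcription of the
chart's wording, `CHART_LEVELS`); each boundary is the log2 midpoint
between the adjacent levels' extreme means. An empty adjacent level places
the boundary 2 log2 units beyond the occupied range; inverted levels in a
noisy cohort fall back to level-mean midpoints with a note. A purely
unsupervised mode (largest-gap merging) is provided for comparison but is
not the default: with the published effect sizes it provably assigns
Normal's miR-935 to "low", which contradicts the chart's own level for
Normal and breaks noise-free self-classification. Values exactly on a
boundary go to the upper bin. The lung/breast sub-boundary is the midpoint
of the two metastasis groups' miR-935 centers.

Classification walks rules R1–R5 first-match-wins (R3 before R4: both
need absent miR-935 and R3 is stricter), records the full fired/failed
trace and the margin to the nearest boundary, and returns Indeterminate
rather than forcing a nearest class — at most one of R1/R2/R3 can fire
for any category vector (verified by exhaustive enumeration of all 4^5
combinations).

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline recovers the encoded truths
under the stated noise model: hierarchical Gaussian Ct noise, NB counts,
no batch effects, no amplification-efficiency differences (plain 2^-ΔΔCt,
no Pfaffl correction), no positive/negative control probes, and no
nCounter chemistry. They do not show field performance on real CSF. At the
default patient noise (1.0 Ct) the chart's adjacent levels for miR-711 and
miR-935 are ~1.5 and ~0.5–0.8 log2 apart, so per-patient categories are
genuinely uncertain; the chart then abstains (Indeterminate) far more
often than it mislabels — at the study group sizes roughly half of Normal
patients are abstentions while none receive a tumor call. Perfect recall
is recovered when patient noise drops to ~0.3 Ct.

## Problem sizes and numerical choices

Test and acceptance runs use the study-sized cohort (82 samples), a
300-tag panel for screening, a 1000-tag panel for the null-uniformity
(KS, 1 % level) and hyperparameter-recovery checks, and 16 replicate
cohorts in the fold-change recovery harness (per-cohort standard errors
reach 0.76 Ct on the 4-vs-3 comparisons; averaging 16 log2 estimates
brings them to ≤ 0.23). Effect-fit consistency tolerance: 0.25 log2
(printed rows fit to ≤ 0.11). Normalization idempotence holds to 1e-9.
All randomness flows from explicit seeds; no global RNG state is used.
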