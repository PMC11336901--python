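# Methods

This note documents the models implemented in `stith`, the defaults and
their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Data model

An experiment is a gene × ROI matrix of non-negative integer counts, an
aligned negative-probe × ROI count matrix, and per-ROI metadata (patient,
x/y coordinates in µm, segment label). ROIs are the sample unit; patients
group 2–9 ROIs. All matrices are exchanged as TSV with gene rows and ROI
columns.

## QC and normalization

**LOQ.** The limit of quantitation per ROI is
`geomean(negprobes) × geoSD(negprobes)^k` with `k = 2` by default.
Geometric statistics use natural logs and the sample (n−1) SD. A 0.5
offset is added before the logs *only* when an ROI contains a zero
negative-probe count ("auto" mode), so zero-free ROIs obey the textbook
formula exactly; with the offset explicitly disabled, zero counts raise.
A literal ×100 variant (`literal_hundred=True`) is available for audit
against sources that print the rule that way. Genes detected
(count ≥ LOQ) in fewer than `min_fraction_above` of ROIs can be dropped;
the default is 0 — no gene filtering — matching a whole-transcriptome
analysis that retains all panel genes.

**Q3.** Each ROI is scaled so its 75th-percentile gene count equals the
cohort anchor, the geometric mean of per-ROI Q3s (the standard GeoMx
convention; scaling to a common anchor is required for the procedure to
be idempotent). Percentiles use the linear-interpolation definition.
Negative probes are excluded from the percentile. Downstream analysis
uses log₂(x+1) of the normalized values.

## Heterogeneity scores

**DEPTH.** For gene g and ROI j, `z_gj = (x_gj − mean_g) / sd_g` across
ROIs (sample SD; genes whose SD is at float round-off relative to the
mean are treated as constant and get z = 0). The deviating score is
`z²`, and `DEPTH_j` is the sample SD over genes of the deviating scores.
A tumor-only DSP cohort has no normal reference, so z is computed against
the all-ROI cohort by default (the no-normal fallback of the published
method); `scope="patient"` restricts the reference within each tumor.
Degenerate inputs: one ROI is an error (z undefined); one gene yields
DEPTH = 0.

**C-score and SPD.** The concordance of two within-tumor ROIs is the
Spearman ρ of their transcriptome-wide profiles (average ranks on ties,
then Pearson on ranks). SPD is the Euclidean distance between ROI centers
in µm; cross-patient pairs are never formed. The SPD–C-score relationship
is summarized by Spearman correlation with a two-sided p: Student-t
approximation at n ≥ 10 pairs, exact permutation enumeration below.

## ITH phenotyping

Highly variable genes are ranked by the variance captured in the leading
eigenvectors: the sum over the top `n_components` (default 10) principal
components of squared loading × component variance. The reduction used
for gene extraction and the component count were open choices; this
variance-weighted form makes the score exactly the per-gene variance
explained by the retained subspace, and ties break deterministically by
gene symbol. The top 200 genes (default) are standardized per gene and
ROIs are clustered with Ward's criterion on Euclidean distances (the
ward.D2 convention) cut at k = 3. Standardization prevents
high-expression genes from dominating the Ward objective. Clusters are
named h-/m-/l-ITH by descending median DEPTH (mean, then smallest cluster
index, as deterministic tie-breaks); with k = 2 only {h, l} are assigned,
with a warning. t-SNE is provided as a seeded, pluggable 2-D embedding
for visualization only; clustering never consumes embedding coordinates.

## Molecular subtyping

The transcriptional subtype of an ROI is the argmax of the four lineage
factors (ASCL1, NEUROD1, POU2F3, YAP1) on log₂ Q3 expression — the
dominant-factor rule; exact ties resolve by the fixed priority
A > N > P > Y and are flagged. Per-factor cohort z-scoring is available
by flag for cohorts where absolute levels are not comparable. The NE
score correlates an ROI's 50-gene panel vector with NE and non-NE
reference centroids: `NE = (r_NE − r_nonNE)/2`, NE-high when positive.
Centroids are an input asset (two-column TSV per class);
`derive_ne_centroids` builds them as mean panel profiles of labeled
reference samples, which is how the synthetic fixture supplies its own.
Percentages in distribution summaries are rounded half-up to one decimal
to match conventional reporting. SCLC-Y is retained as a possible label
even when a cohort never produces it.

## Patient-level sub-TME classes and outcome statistics

The aggregation rule from ROI phenotypes to a patient class is not
uniquely determined by phenotype percentages alone, so three rules are
implemented and logged: **any-h** (default; ≥1 h-ITH ROI ⇒ HCs-TME) as
the simplest rule consistent with "high-complex", **non-uniform** (any
phenotype mixture ⇒ HCs-TME), and **majority-h**. Survival comparisons
use Kaplan–Meier product-limit estimates and the two-group log-rank test
(chi-square, 1 df) via lifelines; with zero observed events the statistic
is 0 with a warning. Fisher's exact test (two-sided, conditional odds
ratio) covers 2×2 tables; larger tables fall back to the chi-square test
of independence. Rank-based group comparisons use the Wilcoxon rank-sum
(exact for small tie-free groups, otherwise the tie-corrected normal
approximation without continuity correction — which reproduces the
Kruskal–Wallis chi-square form at k = 2) and Kruskal–Wallis for three
groups. Multi-group survival contrasts are pairwise without multiplicity
correction.

## Phenotype signatures

Differential expression is one-vs-rest on the log₂ matrix. Welch's t is
the default; an empirical-Bayes moderated t is available, with the prior
(d₀, s₀²) fit by method-of-moments on log sample variances (trigamma
inversion by Newton iteration). A gene passes at |log₂FC| > log₂ 1.5 and
raw p ≤ 0.05 — thresholds kept raw because the originating analysis
filters on unadjusted p; Benjamini–Hochberg is available by flag. Genes
with zero variance in both groups but unequal means receive the smallest
representable p and a degenerate flag. The co-expression network tests
all unordered pairs from the union of DEG sets by Spearman correlation
across ROIs; pairs with |ρ| ≥ 0.6 and p < 0.01 become undirected edges
and isolated genes are dropped. Note the ρ cut dominates at realistic ROI
counts (at n = 30 the null probability of |ρ| ≥ 0.6 is ~5·10⁻⁴), so the
p < 0.01 cut is a cap, not the operative false-edge rate. Module scores
are unweighted means of log₂ expression over the module genes present
(the MCP-counter marker-averaging principle); missing genes warn, an
empty module errors. Over-representation uses the upper-tail
hypergeometric test against user-supplied GMT sets intersected with the
declared universe.

## ITHtyper

**Gene selection.** Per bootstrap (default 25 at desk scale; 500 at full
scale), 90% of samples are drawn without replacement and a tanh
autoencoder with hidden layers 100/300/100 is trained for 10 epochs on
per-gene standardized expression. Genes are ranked per bootstrap and the
final importance is the mean rank. Two importance readouts exist:

* **reconstruction** (default) — per-gene reconstruction fidelity (low
  mean squared reconstruction error on the standardized scale). A
  capacity-constrained autoencoder spends its bottleneck on the shared
  covariance structure, so genes carrying the planted class factor
  reconstruct well while isolated noise genes cannot; this readout
  recovered 10/10 planted genes in every prototyping seed.
* **garson** — aggregated absolute input-to-output weight-path magnitude.
  At a 10-epoch training budget the weight magnitudes of this
  architecture remain dominated by initialization and the readout failed
  to separate planted from noise genes in prototyping (0/10 across
  seeds, with and without heavy weight decay); it is retained behind
  `method="garson"` for comparison, not as the default.

Training internals not fixed by the architecture (optimizer Adam,
learning rate 0.01, batch size 16, weight decay α = 10) are recorded in
the model file. The strong weight decay is deliberate capacity control:
with ~10² samples and ~2·10⁵ weights, an unregularized network memorizes
sample noise and per-gene fidelity loses contrast.

**Classifier.** XGBoost with objective binary:logistic, 100 rounds,
max depth 5, 80% row and column subsampling (5-fold CV is recorded in the
config as part of the printed recipe; training itself uses the fixed
round count). The 70/30 train/test split is at the patient level whenever
a patient map is supplied, so no patient spans both splits (preventing
leakage; bulk cohorts treat each sample as its own patient). Scores are
P(high-complexity) in [0, 1]; the hi/lo threshold defaults to 0.45.
Cross-platform scoring (an ROI-trained model applied to FPKM/RPKM bulk
profiles) is supported by rank harmonization: per-sample rank scaling of
the signature-gene vector to [0, 1], applied consistently at train and
score time (`harmonize="rank"`), which makes scores invariant to
monotone platform transforms. AUC uses the rank (Mann–Whitney) statistic
with midrank ties. The printed 10-gene reference signature (NKX1-2, TLE2,
TPBG, GPR31, SRSF6, DAZ4, CD274, LYZ, PCP4, ZIC1) ships as an asset for
scoring real SCLC data; models learned on synthetic cohorts carry their
own learned gene lists.

## Synthetic-data generator

The generator emulates the *structure* of a 25-patient DSP study: 2–9
ROIs per patient drawn from a right-skewed distribution with median 3;
ROI centers uniform in a disc of radius 1,600 µm per patient (pairwise
SPD in (0, 3,200] µm, median ≈ 1,800 µm); ~100 negative probes with low
counts and no planted biology; counts negative-binomial (size 10) around
log-normal per-gene baselines (log₂ mean 3, SD 1.2). Planted truth:

* **ITH strata** — every ROI gets one of h/m/l at the default
  prevalences (0.2, 0.4, 0.4), apportioned deterministically
  (largest-remainder) and shuffled across ROIs. The h stratum is kept
  the rarest so that the any-h patient rule splits the cohort close to
  evenly (~55:45), which is what makes the planted survival contrast
  reliably detectable at the default cohort sizes; equal thirds would
  push the classes to ~2:1 and leave the log-rank comparison
  under-powered. Strata act twice: as per-gene, per-ROI log₂ noise SD (1.0 / 0.5 / 0.15,
  strictly ordered — the lever DEPTH responds to) and as stratum
  expression programs (60 genes at 2.0 log₂ for h and l; a 40-gene
  immune module at 2.0 log₂ for m, emulating the "hot" medium-ITH
  microenvironment — the lever clustering responds to). Program sizes
  were set at design time because the negative-binomial sampling noise on
  the log₂ scale has an SD of ~0.7 at these count depths; much smaller
  or weaker programs are mathematically undetectable at 60 ROIs, which
  would defeat the generator's purpose of planting recoverable truth.
* **Subtypes** — each patient draws a dominant subtype with probabilities
  0.49/0.32/0.19/0 (A/N/P/Y); each ROI deviates with probability 0.2
  (≈36% of multi-ROI patients end up mixed). Programs put +2.0 log₂ on
  the lineage TF plus 10 program genes. The four TF baselines are pinned
  to a common level so the argmax call reflects the planted program, not
  a baseline draw. NE class follows the subtype (A/N high, P/Y low) and
  shifts the matching half of the 50-gene NE panel by +1.5 log₂.
* **TME and survival** — patient classes derive from the planted ROI
  strata by the configured rule (default any-h, so the default
  classifier recovers them exactly); HCs patients additionally carry a
  10-gene signature program (+2.0 log₂) in all their ROIs, and bulk
  cohorts plant the same signature. Event times are exponential with the
  HCs hazard = hazard ratio × LCs hazard (default 3; LCs median 60
  months). Censoring is independent Uniform(0, b) with b calibrated per
  group so the expected censored fraction equals `censor_frac`; the
  default is 0.1 — near-complete follow-up — chosen together with the
  stratum prevalences so the planted class effect is reliably detectable
  at the default cohort sizes; heavier censoring is a config switch.

What the generator does **not** emulate: spatial autocorrelation of
expression with distance (the SPD–C-score correlation is null by
construction), cell-level composition, batch or slide effects, count
depth variation between ROIs, and any coupling between subtype and ITH
stratum. Passing recovery tests therefore demonstrates correctness of the
pipeline's inference under the planted model, not robustness to the many
structures real GeoMx data adds.

## Problem sizes used in tests and the acceptance script

Desk-scale defaults keep every run on a laptop-class budget: 500-gene
cohorts (2,000 by default in the API, 18,676 available by config),
60-ROI phenotyping cohorts, 120-sample bulk cohorts, 25 autoencoder
bootstraps, and 100-seed repetitions for the stochastic recovery rates.
The acceptance script completes in well under a minute of compute per
stage; full-scale settings are config switches, not code changes.

## Known limitations

* The DEPTH construction (z², then SD across genes) follows the cited
  method's published description; the within-patient z-scoring scope is
  configurable because the original reference leaves it open.
* The moderated-t prior uses a single pooled method-of-moments fit, not
  limma's exact marginal-likelihood machinery, and no trend or robust
  variants.
* Exact r×c Fisher tests are not implemented (chi-square fallback).
* The autoencoder is a minimal MLP; no early stopping, no GPU path.
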