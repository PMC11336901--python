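# stith — spatial intra-tumoral heterogeneity analysis for DSP transcriptomes

`stith` is a Python toolkit for analysing multi-region digital spatial
profiling (DSP/GeoMx-style) transcriptomes of small cell lung cancer
(SCLC), where each patient contributes several ~600 µm tumor regions of
interest (ROIs) and the scientific question is how much the tumor varies
*within* itself — and whether that intra-tumoral heterogeneity (ITH)
predicts outcome.

It is written for computational biologists working with ROI-level count
matrices (gene × ROI counts, negative-probe counts, ROI coordinates) and
covers the full analysis arc:

1. **QC / normalization** — negative-probe limit of quantitation
   (LOQ = geomean(neg) · geoSD(neg)²), Q3 (75th-percentile) normalization
   anchored to the cohort geometric mean, log₂(x+1) transform, and
   within-patient spatial physical distances (SPD, µm).
2. **Heterogeneity scores** — the DEPTH-style per-ROI score
   (z-score each gene across ROIs, square it, take the SD of the squared
   z's over genes: DEPTH_j = SD_g[(x_gj − µ_g)²/σ_g²]) and the C-score
   (Spearman ρ of two within-tumor ROI transcriptomes), related to SPD.
3. **ITH phenotyping** — top-200 variable genes from the leading
   eigenvectors, Ward (ward.D2) clustering into three clusters, labeled
   h-ITH / m-ITH / l-ITH by descending median DEPTH.
4. **Molecular subtyping** — dominant-transcription-factor SCLC subtype
   (ASCL1 → SCLC-A, NEUROD1 → SCLC-N, POU2F3 → SCLC-P, YAP1 → SCLC-Y) and
   the 50-gene neuroendocrine score
   NE = (corr(x, NE centroid) − corr(x, non-NE centroid))/2.
5. **Patient-level sub-TME classes** — ROI phenotypes aggregate to
   high-complex (HCs-TME) vs low-complex (LCs-TME) patients; Kaplan–Meier
   curves, log-rank tests, Fisher's exact test, rank-based group tests.
6. **Phenotype signatures** — one-vs-rest differential expression
   (|FC| > 1.5, p ≤ 0.05), Spearman co-expression networks (|ρ| ≥ 0.6,
   p < 0.01), marker-mean module scores, hypergeometric ORA over GMT sets.
7. **ITHtyper** — bootstrap-autoencoder gene selection (tanh, hidden
   100/300/100, 10 epochs, 500 bootstraps at full scale) feeding an
   XGBoost classifier (binary:logistic, 100 rounds, depth 5, 80% row and
   column subsampling) that scores samples in [0, 1]; scores ≥ 0.45 call
   the ITHtyper-hi risk phenotype.

A first-class **synthetic-data generator** (`stith.synthetic_data`)
produces DSP-like cohorts with planted ground truth — ITH variance
strata, subtype programs with intra-patient mixing, an immune program in
the m-ITH stratum, patient TME classes with an exponential survival link —
so every stage is testable without access to protected patient data.

## Worked example

```python
import pandas as pd
from stith import (SimulationConfig, generate_experiment, q3_normalize,
                   depth_scores, c_score_table, spd_cscore_correlation,
                   classify_patient_tme, compare_survival)
from stith.phenotyping import assign_phenotypes

cfg = SimulationConfig(n_genes=500, seed=7)     # 25 patients, 2-9 ROIs each
exp, truth = generate_experiment(cfg)

mat = q3_normalize(exp, log2=True).matrix       # gene x ROI, log2 Q3
scores = depth_scores(mat)                      # per-ROI DEPTH
asg = assign_phenotypes(mat, scores)            # HVG -> Ward -> h/m/l-ITH
pairs = c_score_table(mat, exp.rois)            # C-score + SPD per pair
rho, p = spd_cscore_correlation(pairs)

summaries = classify_patient_tme(asg.phenotype, exp.patient_map, c_scores=pairs)
groups = pd.Series({s.patient_id: s.tme_class for s in summaries})
cmp = compare_survival(truth.survival, groups)
```

With this seed the run prints:

```
ROIs: 100  patients: 25
DEPTH range: 0.79-2.69
{'l-ITH': 40, 'm-ITH': 40, 'h-ITH': 20}
SPD vs C-score: rho=0.049 p=0.49 (n=201 pairs)
{'HCs-TME': 15, 'LCs-TME': 10}
log-rank chi2=3.17 p=0.0752
```

Reading this: 100 ROIs split into the three ITH phenotypes at the
planted prevalences (h-ITH is the rarest); concordance between two
regions of a tumor does not depend on how far apart they sit (ρ ≈ 0.05,
not significant — the generator plants no spatial decay); and patients
whose tumors contain at least one h-ITH region (HCs-TME) trend toward
worse survival under the planted hazard ratio, without reaching
significance at this 25-patient size — survival power arrives at larger
cohort settings (see `scripts/acceptance.py`, which measures the
detection rate at n = 100 patients).

The same steps are available as a CLI for file-based work:

```bash
stith simulate --out cohort/ --seed 7
stith normalize cohort/ --out norm.tsv
stith depth cohort/ --out depth.tsv
stith phenotype cohort/ --out phenotypes.tsv
```

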