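"""Synthetic multi-region DSP cohorts with planted ground truth.

Emulates the structure of a GeoMx whole-transcriptome study of small cell
lung cancer: ~25 patients contributing 2-9 tumor ROIs each (median 3),
negative control probes, ROI coordinates within a tumor-sized disc, three
ITH strata of increasing expression dispersion, per-patient dominant
SCLC transcriptional subtypes (ASCL1 / NEUROD1 / POU2F3 / YAP1 programs)
with occasional intra-patient mixing, a neuroendocrine 50-gene panel, an
immune program enriched in the medium-ITH stratum, a patient-level
high-/low-complexity microenvironment class carrying a planted gene
signature, and exponential survival linked to that class.

Counts are negative-binomial around log-normal per-gene baselines; planted
effects act multiplicatively (additively on log2 means).  All randomness
flows from ``SimulationConfig.seed`` — equal config implies byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from .dsp_io import DSPExperiment, ROIRecord, save_experiment

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_experiment",
    "generate_bulk_cohort",
    "generate_survival",
    "write_fixture",
]

PHENOTYPES = ("h", "m", "l")
SUBTYPES = ("A", "N", "P", "Y")
TF_GENES = {"A": "ASCL1", "N": "NEUROD1", "P": "POU2F3", "Y": "YAP1"}

# ROI-per-patient distribution for the default (2, 9) range: right-skewed
# so the median lands at 3, as in small multi-region FFPE cohorts.
_DEFAULT_ROI_PROBS = (0.25, 0.32, 0.15, 0.10, 0.07, 0.05, 0.03, 0.03)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Marker-gene sets (subtype programs, NE panel, immune module, signature
    genes, per-stratum programs) default to disjoint slices of the gene
    list; pass explicit ids to override.  Effects are log2 fold-changes
    applied to the negative-binomial mean.
    """

    n_patients: int = 25
    roi_count_range: tuple[int, int] = (2, 9)
    n_genes: int = 2000
    n_negprobes: int = 100
    phenotype_dispersions: dict[str, float] = field(
        default_factory=lambda: {"h": 1.0, "m": 0.5, "l": 0.15}
    )
    phenotype_props: tuple[float, float, float] = (0.2, 0.4, 0.4)  # h, m, l
    subtype_programs: dict[str, tuple[tuple[str, ...], float]] | None = None
    mixing_prob: float = 0.2
    ne_panel: tuple[str, ...] | None = None  # 50 ids; first half NE-up, second NE-down
    ne_effect: float = 1.5
    immune_module: tuple[str, ...] | None = None
    immune_effect: float = 2.0
    stratum_programs: dict[str, tuple[tuple[str, ...], float]] | None = None
    signature_genes: tuple[str, ...] | None = None
    signature_effect: float = 2.0
    subtype_probs: tuple[float, float, float, float] = (0.49, 0.32, 0.19, 0.0)
    tme_rule_truth: str = "any-h"
    hazard_ratio: float = 3.0
    median_survival_lcs: float = 60.0  # months, LCs baseline
    censor_frac: float = 0.1
    nb_dispersion: float = 10.0
    coord_extent_um: float = 1600.0
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.2
    bulk_noise_sd: float = 0.8
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.gene_ids = self._build_gene_ids()
        self._assign_default_markers()
        self.validate()

    def _build_gene_ids(self) -> list[str]:
        ids = list(TF_GENES.values())
        ids += [f"G{i:05d}" for i in range(self.n_genes - len(ids))]
        return ids[: self.n_genes]

    def _assign_default_markers(self) -> None:
        pool = iter(g for g in self.gene_ids if g not in TF_GENES.values())

        def take(k: int) -> tuple[str, ...]:
            out = tuple(next(pool) for _ in range(k))
            return out

        try:
            if self.ne_panel is None:
                self.ne_panel = take(50)
            if self.subtype_programs is None:
                self.subtype_programs = {
                    s: ((TF_GENES[s],) + take(10), 2.0) for s in SUBTYPES
                }
            if self.immune_module is None:
                self.immune_module = take(40)
            if self.signature_genes is None:
                self.signature_genes = take(10)
            if self.stratum_programs is None:
                self.stratum_programs = {"h": (take(60), 2.0), "l": (take(60), 2.0)}
        except StopIteration:
            raise ValueError("n_genes too small for the default marker layout") from None

    def validate(self) -> None:
        lo, hi = self.roi_count_range
        if not (1 <= lo <= hi):
            raise ValueError("roi_count_range: need 1 <= min <= max")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_negprobes < 2:
            raise ValueError("n_negprobes must be >= 2")
        d = self.phenotype_dispersions
        if set(d) != {"h", "m", "l"} or not (d["h"] > d["m"] > d["l"] > 0):
            raise ValueError("phenotype_dispersions must satisfy h > m > l > 0")
        for name, p in (("mixing_prob", self.mixing_prob), ("censor_frac", self.censor_frac)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.coord_extent_um <= 0:
            raise ValueError("coord_extent_um must be > 0")
        if abs(sum(self.subtype_probs) - 1.0) > 1e-9:
            raise ValueError("subtype_probs must sum to 1")
        if abs(sum(self.phenotype_props) - 1.0) > 1e-9 or min(self.phenotype_props) <= 0:
            raise ValueError("phenotype_props must be positive and sum to 1")
        genes = set(self.gene_ids)
        marker_sets = {
            "ne_panel": self.ne_panel,
            "immune_module": self.immune_module,
            "signature_genes": self.signature_genes,
        }
        for name, ids in marker_sets.items():
            if not set(ids) <= genes:
                raise ValueError(f"{name}: marker ids must be a subset of gene ids")
        for s, (ids, _) in self.subtype_programs.items():
            if not set(ids) <= genes:
                raise ValueError(f"subtype_programs[{s!r}]: ids not in gene list")
        for s, (ids, _) in self.stratum_programs.items():
            if not set(ids) <= genes:
                raise ValueError(f"stratum_programs[{s!r}]: ids not in gene list")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("gene_ids", None)
        return d


@dataclass
class GroundTruth:
    """Planted labels for every ROI and patient of a synthetic cohort."""

    roi_phenotype: pd.Series  # roi -> {h, m, l}
    roi_subtype: pd.Series  # roi -> {A, N, P, Y}
    roi_ne_class: pd.Series  # roi -> {high, low}
    patient_tme: pd.Series  # patient -> {HCs, LCs}
    survival: pd.DataFrame  # patient_id, time, event


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def _roi_counts(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    lo, hi = cfg.roi_count_range
    values = np.arange(lo, hi + 1)
    if (lo, hi) == (2, 9):
        probs = np.array(_DEFAULT_ROI_PROBS)
    else:
        probs = np.ones(len(values)) / len(values)
    return rng.choice(values, size=cfg.n_patients, p=probs)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_experiment(config: SimulationConfig) -> tuple[DSPExperiment, GroundTruth]:
    """Generate one DSP-like experiment plus its planted ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gene_idx = {g: i for i, g in enumerate(cfg.gene_ids)}

    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    n_rois_per_patient = _roi_counts(rng, cfg)
    roi_patient: list[str] = []
    roi_ids: list[str] = []
    for pid, k in zip(patients, n_rois_per_patient):
        for j in range(k):
            roi_ids.append(f"{pid}_R{j + 1}")
            roi_patient.append(pid)
    n_rois = len(roi_ids)

    # phenotype strata: deterministic proportions (largest-remainder
    # apportionment of phenotype_props), then shuffled across ROIs
    quota = np.array(cfg.phenotype_props) * n_rois
    counts_per = np.floor(quota).astype(int)
    for _ in range(n_rois - counts_per.sum()):
        counts_per[np.argmax(quota - counts_per)] += 1
    phen = np.repeat(PHENOTYPES, counts_per)
    rng.shuffle(phen)

    # dominant subtype per patient; ROI-level mixing draws another NE/non-NE
    # program (SCLC-Y never arises, matching its absence from the cohort)
    dom = {
        pid: rng.choice(SUBTYPES, p=np.array(cfg.subtype_probs)) for pid in patients
    }
    roi_subtype = []
    for pid, roi in zip(roi_patient, roi_ids):
        s = dom[pid]
        if rng.random() < cfg.mixing_prob:
            others = [t for t in SUBTYPES if t != s and cfg.subtype_probs[SUBTYPES.index(t)] > 0]
            s = rng.choice(others)
        roi_subtype.append(s)
    roi_subtype = np.array(roi_subtype)
    ne_class = np.where(np.isin(roi_subtype, ("A", "N")), "high", "low")

    # patient TME truth by the configured aggregation rule
    tme = {}
    for pid in patients:
        ph = phen[np.array(roi_patient) == pid]
        if cfg.tme_rule_truth == "any-h":
            tme[pid] = "HCs" if "h" in ph else "LCs"
        elif cfg.tme_rule_truth == "non-uniform":
            tme[pid] = "HCs" if len(set(ph)) > 1 else "LCs"
        elif cfg.tme_rule_truth == "majority-h":
            tme[pid] = "HCs" if (ph == "h").mean() > 0.5 else "LCs"
        else:
            raise ValueError(f"tme_rule_truth: unknown rule {cfg.tme_rule_truth!r}")

    # coordinates: per-patient center on a sparse grid; ROIs uniform in a
    # disc of radius coord_extent_um (pairwise SPD in (0, 2 * extent])
    centers = {}
    grid = 10 * cfg.coord_extent_um
    for i, pid in enumerate(patients):
        centers[pid] = np.array([(i % 5) * grid, (i // 5) * grid])
    coords = np.empty((n_rois, 2))
    for i, pid in enumerate(roi_patient):
        r = cfg.coord_extent_um * np.sqrt(rng.random())
        theta = 2 * np.pi * rng.random()
        coords[i] = centers[pid] + r * np.array([np.cos(theta), np.sin(theta)])

    # log2 mean matrix: baseline + planted effects + stratum-dependent noise
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    # the four lineage TFs share a common baseline so that planted dominance
    # (not a lucky baseline draw) decides the argmax subtype call
    for tf in TF_GENES.values():
        baseline[gene_idx[tf]] = cfg.baseline_log2_mean
    log2_mu = np.tile(baseline[:, None], (1, n_rois))
    for j in range(n_rois):
        ids, eff = cfg.subtype_programs[roi_subtype[j]]
        for g in ids:
            log2_mu[gene_idx[g], j] += eff
        up = cfg.ne_panel[: len(cfg.ne_panel) // 2]
        dn = cfg.ne_panel[len(cfg.ne_panel) // 2:]
        boosted = up if ne_class[j] == "high" else dn
        for g in boosted:
            log2_mu[gene_idx[g], j] += cfg.ne_effect
        if phen[j] == "m":
            for g in cfg.immune_module:
                log2_mu[gene_idx[g], j] += cfg.immune_effect
        if phen[j] in cfg.stratum_programs:
            ids, eff = cfg.stratum_programs[phen[j]]
            for g in ids:
                log2_mu[gene_idx[g], j] += eff
        if tme[roi_patient[j]] == "HCs":
            for g in cfg.signature_genes:
                log2_mu[gene_idx[g], j] += cfg.signature_effect
        log2_mu[:, j] += rng.normal(0, cfg.phenotype_dispersions[phen[j]], cfg.n_genes)

    counts = _nb_sample(rng, 2.0**log2_mu, cfg.nb_dispersion)

    # negative probes: shared noise model, no planted biology
    neg_base = rng.normal(1.0, 0.5, cfg.n_negprobes)
    neg_mu = np.tile(2.0 ** neg_base[:, None], (1, n_rois))
    negprobes = _nb_sample(rng, neg_mu, cfg.nb_dispersion)

    rois = [
        ROIRecord(roi_id=rid, patient_id=pid, x_um=float(x), y_um=float(y))
        for rid, pid, (x, y) in zip(roi_ids, roi_patient, coords)
    ]
    exp = DSPExperiment(
        counts=pd.DataFrame(counts, index=cfg.gene_ids, columns=roi_ids),
        negprobes=pd.DataFrame(
            negprobes, index=[f"NegProbe{i + 1:03d}" for i in range(cfg.n_negprobes)],
            columns=roi_ids,
        ),
        rois=rois,
    )
    patient_tme = pd.Series(tme, name="tme_class")
    survival = generate_survival(
        patient_tme, cfg.hazard_ratio, cfg.censor_frac,
        seed=int(rng.integers(2**31)), median_survival_lcs=cfg.median_survival_lcs,
    )
    truth = GroundTruth(
        roi_phenotype=pd.Series(phen, index=roi_ids, name="phenotype"),
        roi_subtype=pd.Series(roi_subtype, index=roi_ids, name="subtype"),
        roi_ne_class=pd.Series(ne_class, index=roi_ids, name="ne_class"),
        patient_tme=patient_tme,
        survival=survival,
    )
    return exp, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _uniform_censor_bound(lam: float, censor_frac: float) -> float:
    """Upper bound b of Uniform(0, b) censoring giving P(censored) = frac
    for exponential(lam) event times: (1 - exp(-lam b)) / (lam b) = frac."""
    f = lambda b: (1 - np.exp(-lam * b)) / (lam * b) - censor_frac
    return optimize.brentq(f, 1e-9 / lam, 1e4 / lam)


def generate_survival(
    truth: GroundTruth | pd.Series,
    hazard_ratio: float,
    censor_frac: float,
    seed: int,
    median_survival_lcs: float = 60.0,
) -> pd.DataFrame:
    """Exponential event times with HCs hazard = hazard_ratio x LCs hazard.

    Censoring is independent Uniform(0, b) with b calibrated per group so
    the expected censored fraction equals ``censor_frac``.  Returns a table
    (patient_id, time, event) with event 1 = observed.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not 0.0 <= censor_frac < 1.0:
        raise ValueError("censor_frac must be in [0, 1)")
    classes = truth.patient_tme if isinstance(truth, GroundTruth) else truth
    rng = np.random.default_rng(seed)
    lam_lcs = np.log(2) / median_survival_lcs
    rows = []
    for pid, cls in classes.items():
        lam = lam_lcs * (hazard_ratio if cls == "HCs" else 1.0)
        t_event = rng.exponential(1.0 / lam)
        if censor_frac > 0:
            b = _uniform_censor_bound(lam, censor_frac)
            t_cens = rng.uniform(0, b)
        else:
            t_cens = np.inf
        rows.append(
            {
                "patient_id": pid,
                "time": float(min(t_event, t_cens)),
                "event": int(t_event <= t_cens),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

def generate_bulk_cohort(
    config: SimulationConfig, n_samples: int, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """FPKM-like bulk profiles (one per sample) with the planted signature.

    Samples are assigned HCs-like / LCs-like classes at random; signature
    genes are shifted by ``signature_effect`` log2 in HCs-like samples.
    Values are continuous and non-count (2 ** gaussian log2 expression).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    cls = np.where(rng.integers(0, 2, n_samples) == 1, "HCs", "LCs")
    baseline = rng.normal(cfg.baseline_log2_mean, 1.5, cfg.n_genes)
    log2_x = baseline[:, None] + rng.normal(0, cfg.bulk_noise_sd, (cfg.n_genes, n_samples))
    sig_rows = [cfg.gene_ids.index(g) for g in cfg.signature_genes]
    log2_x[np.ix_(sig_rows, np.flatnonzero(cls == "HCs"))] += cfg.signature_effect
    table = pd.DataFrame(2.0**log2_x, index=cfg.gene_ids, columns=sample_ids)
    patient_tme = pd.Series(cls, index=sample_ids, name="tme_class")
    survival = generate_survival(
        patient_tme, cfg.hazard_ratio, cfg.censor_frac,
        seed=int(rng.integers(2**31)), median_survival_lcs=cfg.median_survival_lcs,
    )
    empty = pd.Series(dtype=object)
    truth = GroundTruth(
        roi_phenotype=empty, roi_subtype=empty.copy(), roi_ne_class=empty.copy(),
        patient_tme=patient_tme, survival=survival,
    )
    return table, truth


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

def write_fixture(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a complete fixture: counts/negprobes/metadata
    TSVs, survival and ground-truth tables, and the config as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp, truth = generate_experiment(config)
    paths = save_experiment(exp, outdir)
    paths["survival"] = outdir / "survival.tsv"
    truth.survival.to_csv(paths["survival"], sep="\t", index=False)
    gt = pd.DataFrame(
        {
            "phenotype": truth.roi_phenotype,
            "subtype": truth.roi_subtype,
            "ne_class": truth.roi_ne_class,
        }
    )
    gt.index.name = "roi_id"
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    gt.to_csv(paths["ground_truth"], sep="\t")
    paths["patient_truth"] = outdir / "patient_truth.tsv"
    truth.patient_tme.rename_axis("patient_id").to_csv(paths["patient_truth"], sep="\t")
    paths["config"] = outdir / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return paths
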