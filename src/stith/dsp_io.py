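"""Reading, QC and normalization of digital-spatial-profiling experiments.

A DSP experiment is a gene x ROI count matrix plus a negative-probe x ROI
count matrix and per-ROI metadata (patient of origin, slide coordinates in
micrometres, segment label).  This module provides the standard GeoMx-style
processing steps: the negative-probe limit of quantitation (LOQ), Q3
(75th-percentile) normalization anchored to the cohort geometric mean,
log2(x+1) transformation, and within-patient spatial physical distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ROIRecord",
    "DSPExperiment",
    "NormalizationResult",
    "load_experiment",
    "save_experiment",
    "compute_loq_filter",
    "q3_normalize",
    "log_transform",
    "spd_matrix",
]


@dataclass(frozen=True)
class ROIRecord:
    """One region of interest: ~600 um tissue region yielding one profile."""

    roi_id: str
    patient_id: str
    x_um: float
    y_um: float
    segment: str = "tumor"

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError(f"ROI {self.roi_id!r}: patient_id must be non-empty")
        if not (np.isfinite(self.x_um) and np.isfinite(self.y_um)):
            raise ValueError(f"ROI {self.roi_id!r}: coordinates must be finite")


@dataclass
class DSPExperiment:
    """Gene x ROI counts with aligned negative probes and ROI metadata."""

    counts: pd.DataFrame
    negprobes: pd.DataFrame
    rois: list[ROIRecord]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        cols = list(self.counts.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate ROI column ids in counts")
        if list(self.negprobes.columns) != cols:
            raise ValueError("negprobe columns must match counts columns (same order)")
        genes = list(self.counts.index)
        dupes = pd.Index(genes)[pd.Index(genes).duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"duplicate gene symbol(s): {dupes}")
        by_id = {r.roi_id: r for r in self.rois}
        missing = [c for c in cols if c not in by_id]
        if missing:
            raise ValueError(f"ROI(s) missing from metadata: {missing}")
        for df, what in ((self.counts, "counts"), (self.negprobes, "negprobe counts")):
            arr = df.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError(f"non-integer {what}")
            if (arr < 0).any():
                raise ValueError(f"negative {what}")

    # -- convenience ----------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def roi_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def patient_map(self) -> pd.Series:
        """roi_id -> patient_id, ordered as the count columns."""
        by_id = {r.roi_id: r.patient_id for r in self.rois}
        return pd.Series({c: by_id[c] for c in self.roi_ids}, name="patient_id")

    def metadata_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "roi_id": r.roi_id,
                    "patient_id": r.patient_id,
                    "x_um": r.x_um,
                    "y_um": r.y_um,
                    "segment": r.segment,
                }
                for r in self.rois
            ]
        )
        return df.set_index("roi_id")


@dataclass
class NormalizationResult:
    """Per-ROI QC/normalization summary plus the transformed matrix.

    ``loq`` holds the negative-probe limit of quantitation, ``q3`` the 75th
    percentile of gene counts, ``scale_factor`` the multiplicative Q3
    factor, ``matrix`` the normalized (optionally log2) gene x ROI values
    and ``flags`` a per-ROI pass/fail indicator.
    """

    matrix: pd.DataFrame
    loq: pd.Series | None = None
    q3: pd.Series | None = None
    scale_factor: pd.Series | None = None
    flags: pd.Series | None = None
    detected: pd.DataFrame | None = None
    detection_rate: pd.Series | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_count_tsv(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate {what} row(s) in {path}: {dupes}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.allclose(arr, np.round(arr)):
        raise ValueError(f"non-integer {what} counts in {path}")
    return df.astype(np.int64)


def load_experiment(
    counts_path: str | Path,
    negprobes_path: str | Path,
    metadata_path: str | Path,
) -> DSPExperiment:
    """Load counts, negative probes and ROI metadata from TSV files.

    Metadata rows are joined on ``roi_id``; their order need not match the
    count columns.  Every count column must have a metadata row.
    """
    counts = _read_count_tsv(counts_path, "gene")
    negprobes = _read_count_tsv(negprobes_path, "negative-probe")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"roi_id": str, "patient_id": str})
    meta = meta.set_index("roi_id")
    missing = [c for c in counts.columns if c not in meta.index]
    if missing:
        raise ValueError(f"ROI(s) in counts missing from metadata: {missing}")
    negprobes = negprobes[counts.columns]
    rois = [
        ROIRecord(
            roi_id=str(c),
            patient_id=str(meta.loc[c, "patient_id"]),
            x_um=float(meta.loc[c, "x_um"]),
            y_um=float(meta.loc[c, "y_um"]),
            segment=str(meta.loc[c].get("segment", "tumor")),
        )
        for c in counts.columns
    ]
    return DSPExperiment(counts=counts, negprobes=negprobes, rois=rois)


def save_experiment(exp: DSPExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write counts/negprobes/metadata TSVs; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "negprobes": outdir / "negprobes.tsv",
        "metadata": outdir / "roi_metadata.tsv",
    }
    exp.counts.to_csv(paths["counts"], sep="\t")
    exp.negprobes.to_csv(paths["negprobes"], sep="\t")
    exp.metadata_frame().to_csv(paths["metadata"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# LOQ
# ---------------------------------------------------------------------------

def compute_loq_filter(
    exp: DSPExperiment,
    sd_exponent: float = 2.0,
    min_fraction_above: float = 0.0,
    offset: float | str = "auto",
    literal_hundred: bool = False,
) -> tuple[NormalizationResult, DSPExperiment]:
    """Negative-probe limit of quantitation per ROI; optional gene filter.

    LOQ_j = geomean(negprobes_j) x geoSD(negprobes_j) ** sd_exponent, with
    geometric statistics on natural logs and the sample (n-1) SD.  A gene is
    "detected" in ROI j when its count >= LOQ_j; genes detected in fewer
    than ``min_fraction_above`` of ROIs are dropped from the returned
    experiment (default 0: no gene is dropped).

    ``offset`` is added to counts before taking logs; the default "auto"
    applies 0.5 only in ROIs containing a zero negative-probe count, so
    zero-free ROIs obey the textbook formula exactly.  ``literal_hundred``
    replaces the geoSD power with a literal x100 factor for audit.
    """
    if exp.negprobes.shape[0] < 2:
        raise ValueError("need >=2 negative probes per ROI for a geometric SD")
    if not 0.0 <= min_fraction_above <= 1.0:
        raise ValueError("min_fraction_above must be in [0, 1]")

    neg = exp.negprobes.to_numpy(dtype=float)
    loq = {}
    for j, roi in enumerate(exp.roi_ids):
        col = neg[:, j]
        if offset == "auto":
            off = 0.5 if (col == 0).any() else 0.0
        else:
            off = float(offset)
        if off == 0.0 and (col == 0).any():
            if (col == 0).all():
                raise ValueError(f"ROI {roi!r}: all-zero negative probes with offset disabled")
            raise ValueError(f"ROI {roi!r}: zero negative-probe count with offset disabled")
        logs = np.log(col + off)
        gm = np.exp(logs.mean())
        gsd = np.exp(logs.std(ddof=1))
        loq[roi] = gm * (100.0 if literal_hundred else gsd**sd_exponent)
    loq = pd.Series(loq, name="loq")

    detected = exp.counts.ge(loq, axis=1)
    detection_rate = detected.mean(axis=1)
    keep = detection_rate >= min_fraction_above
    filtered = exp
    if not keep.all():
        filtered = DSPExperiment(
            counts=exp.counts.loc[keep],
            negprobes=exp.negprobes,
            rois=exp.rois,
        )
    result = NormalizationResult(
        matrix=filtered.counts.astype(float),
        loq=loq,
        flags=pd.Series(True, index=exp.roi_ids, name="qc_pass"),
        detected=detected,
        detection_rate=detection_rate,
    )
    return result, filtered


# ---------------------------------------------------------------------------
# Q3 normalization
# ---------------------------------------------------------------------------

def q3_normalize(
    exp: DSPExperiment | pd.DataFrame,
    log2: bool = False,
) -> NormalizationResult:
    """Scale every ROI so its 75th-percentile count equals the cohort anchor.

    The anchor is the geometric mean over ROIs of the per-ROI Q3 (the
    standard GeoMx convention); scale_factor_j = anchor / Q3_j.  Q3 uses the
    linear-interpolation percentile definition and covers genes only
    (negative probes excluded).
    """
    counts = exp.counts if isinstance(exp, DSPExperiment) else exp
    mat = counts.to_numpy(dtype=float)
    q3 = np.percentile(mat, 75, axis=0)  # linear interpolation
    bad = [c for c, v in zip(counts.columns, q3) if v <= 0]
    if bad:
        raise ValueError(f"ROI(s) with non-positive Q3: {bad}")
    anchor = np.exp(np.mean(np.log(q3)))
    scale = anchor / q3
    matrix = counts * scale
    if log2:
        matrix = log_transform(matrix)
    return NormalizationResult(
        matrix=matrix,
        q3=pd.Series(q3, index=counts.columns, name="q3"),
        scale_factor=pd.Series(scale, index=counts.columns, name="scale_factor"),
        flags=pd.Series(True, index=counts.columns, name="qc_pass"),
    )


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1); entries must be non-negative."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("log_transform requires non-negative entries")
    return np.log2(matrix + 1.0)


# ---------------------------------------------------------------------------
# spatial physical distance
# ---------------------------------------------------------------------------

def spd_matrix(rois: list[ROIRecord]) -> pd.DataFrame:
    """Euclidean distance (um) for every unordered within-patient ROI pair.

    Patients with a single ROI contribute no pairs; cross-patient pairs are
    excluded.  Columns: patient_id, roi_a, roi_b, spd_um.
    """
    rows = []
    by_patient: dict[str, list[ROIRecord]] = {}
    for r in rois:
        by_patient.setdefault(r.patient_id, []).append(r)
    for pid, group in by_patient.items():
        for a, b in itertools.combinations(group, 2):
            d = float(np.hypot(a.x_um - b.x_um, a.y_um - b.y_um))
            rows.append({"patient_id": pid, "roi_a": a.roi_id, "roi_b": b.roi_id, "spd_um": d})
    return pd.DataFrame(rows, columns=["patient_id", "roi_a", "roi_b", "spd_um"])
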