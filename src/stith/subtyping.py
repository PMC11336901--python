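"""SCLC molecular subtype and neuroendocrine (NE) score calling per ROI.

Transcriptional subtype is the dominant of four lineage transcription
factors (ASCL1 -> SCLC-A, NEUROD1 -> SCLC-N, POU2F3 -> SCLC-P, YAP1 ->
SCLC-Y) on log2 normalized expression.  The NE score correlates each ROI's
50-gene panel vector against neuroendocrine and non-neuroendocrine
reference centroids: score = (corr_NE - corr_nonNE) / 2, NE-high when
positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "SubtypeCall",
    "NEScoreResult",
    "DEFAULT_TF_GENES",
    "call_transcriptional_subtype",
    "compute_ne_score",
    "derive_ne_centroids",
    "summarize_subtype_distribution",
    "patient_subtype_concordance",
]

DEFAULT_TF_GENES = {
    "ASCL1": "SCLC-A",
    "NEUROD1": "SCLC-N",
    "POU2F3": "SCLC-P",
    "YAP1": "SCLC-Y",
}
# fixed priority for exact ties
_TF_PRIORITY = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")


@dataclass
class SubtypeCall:
    roi_id: str
    tf_expression: dict[str, float]
    label: str
    tie_flag: bool


@dataclass
class NEScoreResult:
    roi_id: str
    corr_ne: float
    corr_nonne: float
    ne_score: float
    ne_class: str  # {high, low}; "undefined" when the panel vector is constant


def call_transcriptional_subtype(
    matrix: pd.DataFrame,
    tf_genes: dict[str, str] | None = None,
    zscore: bool = False,
) -> list[SubtypeCall]:
    """Dominant-TF subtype per ROI (argmax over the four factors).

    ``zscore=True`` standardizes each TF across the cohort before the
    argmax.  Exact ties break by the fixed priority ASCL1 > NEUROD1 >
    POU2F3 > YAP1 and set ``tie_flag``.
    """
    tf_genes = dict(tf_genes) if tf_genes else dict(DEFAULT_TF_GENES)
    missing = [g for g in tf_genes if g not in matrix.index]
    if missing:
        raise ValueError(f"TF gene(s) missing from matrix: {missing}")
    order = [g for g in _TF_PRIORITY if g in tf_genes] + [
        g for g in tf_genes if g not in _TF_PRIORITY
    ]
    tf = matrix.loc[order].astype(float)
    values = tf.copy()
    if zscore:
        values = values.sub(values.mean(axis=1), axis=0).div(
            values.std(axis=1, ddof=1).replace(0, 1), axis=0
        )
    calls = []
    for roi in matrix.columns:
        col = values[roi]
        best = col.max()
        winners = [g for g in order if col[g] == best]
        calls.append(
            SubtypeCall(
                roi_id=str(roi),
                tf_expression=tf[roi].to_dict(),
                label=tf_genes[winners[0]],
                tie_flag=len(winners) > 1,
            )
        )
    return calls


def compute_ne_score(
    matrix: pd.DataFrame,
    ne_panel: list[str],
    centroids: dict[str, pd.Series],
) -> list[NEScoreResult]:
    """NE score per ROI from Pearson correlations with the two centroids."""
    if not {"ne", "non_ne"} <= set(centroids):
        raise ValueError('centroids must provide "ne" and "non_ne"')
    present = [g for g in ne_panel if g in matrix.index]
    if len(present) < 3:
        raise ValueError("need >=3 NE panel genes present in the matrix")
    for name, c in centroids.items():
        if not set(present) <= set(c.index):
            raise ValueError(f"centroid {name!r} does not cover the panel")
    ne = centroids["ne"].loc[present].to_numpy(dtype=float)
    non = centroids["non_ne"].loc[present].to_numpy(dtype=float)
    results = []
    for roi in matrix.columns:
        v = matrix.loc[present, roi].to_numpy(dtype=float)
        if np.std(v) == 0:
            results.append(
                NEScoreResult(str(roi), np.nan, np.nan, np.nan, "undefined")
            )
            continue
        r1 = float(np.corrcoef(v, ne)[0, 1])
        r2 = float(np.corrcoef(v, non)[0, 1])
        score = (r1 - r2) / 2.0
        results.append(
            NEScoreResult(str(roi), r1, r2, score, "high" if score > 0 else "low")
        )
    return results


def derive_ne_centroids(
    matrix: pd.DataFrame, ne_class: pd.Series, ne_panel: list[str]
) -> dict[str, pd.Series]:
    """Build NE / non-NE reference centroids from labeled profiles.

    Mirrors how the published method derives its centroids: the mean
    panel-gene profile over reference samples of each class.  ``ne_class``
    maps sample -> {"high", "low"}.
    """
    present = [g for g in ne_panel if g in matrix.index]
    if len(present) < 3:
        raise ValueError("need >=3 NE panel genes present in the matrix")
    hi = matrix.columns[ne_class.loc[matrix.columns] == "high"]
    lo = matrix.columns[ne_class.loc[matrix.columns] == "low"]
    if not len(hi) or not len(lo):
        raise ValueError("need reference samples of both NE classes")
    return {
        "ne": matrix.loc[present, hi].mean(axis=1),
        "non_ne": matrix.loc[present, lo].mean(axis=1),
    }


def _round1(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_subtype_distribution(labels: list[str] | pd.Series) -> pd.DataFrame:
    """Counts and percentages per class, descending by count.

    Percentages are 100 x count / total rounded half-up to one decimal.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    counts = pd.Series(labels).value_counts()
    total = counts.sum()
    out = pd.DataFrame(
        {
            "count": counts,
            "percentage": [_round1(100.0 * c / total) for c in counts],
        }
    )
    out.index.name = "class"
    return out


def patient_subtype_concordance(
    labels: pd.Series, patient_map: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Per-patient modal subtype, concordance fraction and purity.

    Concordance is the fraction of a patient's ROIs matching the patient's
    modal label (modal ties resolve to the lexicographically smallest
    label, flagged).  The cohort concordance is the fraction of all ROIs
    matching their patient's modal label.
    """
    missing = [r for r in labels.index if r not in patient_map.index]
    if missing:
        raise ValueError(f"ROI(s) missing from patient map: {missing}")
    rows = []
    matched = 0
    for pid, rois in labels.groupby(patient_map.loc[labels.index]):
        counts = rois.value_counts()
        top = counts.max()
        modal_candidates = sorted(counts.index[counts == top])
        modal = modal_candidates[0]
        conc = float((rois == modal).mean())
        matched += int((rois == modal).sum())
        rows.append(
            {
                "patient_id": pid,
                "majority_label": modal,
                "concordance": conc,
                "purity": "pure" if rois.nunique() == 1 else "mixed",
                "modal_tie": len(modal_candidates) > 1,
                "n_rois": len(rois),
            }
        )
    table = pd.DataFrame(rows).set_index("patient_id")
    cohort_concordance = matched / len(labels)
    return table, cohort_concordance
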