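"""ROI-level heterogeneity scoring.

Two complementary statistics quantify intra-tumoral heterogeneity (ITH) in
a multi-region experiment:

* the DEPTH-style score — for each ROI, z-score every gene against the
  cohort, square the z (the "deviating score"), and take the standard
  deviation of those squared z's across genes.  An ROI whose transcriptome
  deviates strongly and unevenly from the cohort profile scores high.
* the concordance score (C-score) — the Spearman correlation of the
  transcriptome-wide profiles of two ROIs from the same tumor, paired with
  their spatial physical distance (SPD).

The cohort used for z-scoring defaults to all ROIs (a tumor-only cohort has
no normal reference); ``scope="patient"`` restricts it within each tumor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dsp_io import ROIRecord, spd_matrix

__all__ = [
    "HeterogeneityScores",
    "depth_scores",
    "c_score_table",
    "spd_cscore_correlation",
    "spearman",
]


@dataclass
class HeterogeneityScores:
    """Per-ROI DEPTH score plus the per-gene mean/SD used for z-scoring."""

    depth: pd.Series
    gene_mean: pd.Series
    gene_sd: pd.Series


def depth_scores(matrix: pd.DataFrame, scope: str = "cohort",
                 patient_map: pd.Series | None = None) -> HeterogeneityScores:
    """DEPTH-style heterogeneity score for every ROI.

    Parameters
    ----------
    matrix : normalized log-scale gene x ROI matrix.
    scope : "cohort" z-scores each gene against all ROIs; "patient"
        restricts mean/SD to each ROI's own tumor (requires patient_map).
    """
    if matrix.shape[1] < 2:
        raise ValueError("DEPTH needs >=2 ROIs (z-score undefined for one)")
    if scope == "patient":
        if patient_map is None:
            raise ValueError('scope="patient" requires patient_map')
        parts = []
        for _, cols in matrix.T.groupby(patient_map):
            sub = depth_scores(cols.T, scope="cohort")
            parts.append(sub.depth)
        depth = pd.concat(parts).reindex(matrix.columns)
        return HeterogeneityScores(depth=depth, gene_mean=matrix.mean(axis=1),
                                   gene_sd=matrix.std(axis=1, ddof=1))
    if scope != "cohort":
        raise ValueError(f"unknown scope {scope!r}")

    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    z = np.zeros_like(x)
    # an SD at float round-off scale relative to the mean is a constant gene
    ok = sd > np.maximum(np.abs(mean), 1.0) * 1e-12
    z[ok] = (x[ok] - mean[ok, None]) / sd[ok, None]
    d = z**2
    if d.shape[0] < 2:
        depth = np.zeros(d.shape[1])  # SD over a single deviating score
    else:
        depth = d.std(axis=0, ddof=1)
    return HeterogeneityScores(
        depth=pd.Series(depth, index=matrix.columns, name="depth"),
        gene_mean=pd.Series(mean, index=matrix.index, name="mean"),
        gene_sd=pd.Series(sd, index=matrix.index, name="sd"),
    )


def c_score_table(matrix: pd.DataFrame, rois: list[ROIRecord]) -> pd.DataFrame:
    """Spearman concordance for every within-patient ROI pair, with SPD.

    Columns: patient_id, roi_a, roi_b, c_score, spd_um.  A pair involving a
    constant expression vector gets c_score = NaN (undefined; excluded from
    summaries downstream).
    """
    spd = spd_matrix(rois)
    ranks = pd.DataFrame(
        stats.rankdata(matrix.to_numpy(dtype=float), axis=0),
        index=matrix.index, columns=matrix.columns,
    )
    sds = ranks.std(axis=0, ddof=1)
    corr = {}
    for _, row in spd.iterrows():
        a, b = row["roi_a"], row["roi_b"]
        if sds[a] == 0 or sds[b] == 0:
            corr[(a, b)] = np.nan
        else:
            corr[(a, b)] = float(np.corrcoef(ranks[a], ranks[b])[0, 1])
    out = spd.copy()
    out["c_score"] = [corr[(a, b)] for a, b in zip(out["roi_a"], out["roi_b"])]
    return out[["patient_id", "roi_a", "roi_b", "c_score", "spd_um"]]


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(range(len(x)))))
    rx_perm = rx[perms]  # (n!, n)
    ryc = ry - ry.mean()
    rxc = rx_perm - rx_perm.mean(axis=1, keepdims=True)
    num = rxc @ ryc
    den = np.sqrt((rxc**2).sum(axis=1) * (ryc**2).sum())
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(x, y, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rho with a two-sided p: exact permutation below
    ``exact_below`` observations, t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need >=3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: Spearman correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    if n < exact_below:
        p = _exact_spearman_p(x, y, rho)
    else:
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def spd_cscore_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between spatial distance and concordance.

    Tests whether transcriptional concordance of ROI pairs decays with the
    physical distance between them; returns (rho, two-sided p).
    """
    sub = table.dropna(subset=["c_score"])
    if len(sub) < 3:
        raise ValueError("need >=3 ROI pairs with defined c_score")
    return spearman(sub["spd_um"].to_numpy(), sub["c_score"].to_numpy())
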