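"""Patient-level sub-TME classification and outcome statistics.

ROI-level ITH phenotypes aggregate to a per-patient microenvironment
complexity class: high-complex (HCs-TME) or low-complex (LCs-TME).  The
default rule calls a patient HCs-TME when any of their ROIs is h-ITH; two
alternatives ("non-uniform": any phenotype mixture, "majority-h") are
selectable.  The module also wraps the outcome statistics used to compare
the classes: Kaplan-Meier curves with the two-group log-rank test,
Fisher's exact test for contingency tables, and rank-based group
comparisons (Wilcoxon rank-sum / Kruskal-Wallis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "PatientSummary",
    "SurvivalComparison",
    "AssociationResult",
    "TME_RULES",
    "classify_patient_tme",
    "compare_survival",
    "fisher_association",
    "group_compare",
]

TME_RULES = ("any-h", "non-uniform", "majority-h")

_SHORT = {"h-ITH": "h", "m-ITH": "m", "l-ITH": "l"}


@dataclass
class PatientSummary:
    patient_id: str
    roi_phenotype_counts: dict[str, int]
    tme_class: str  # {HCs-TME, LCs-TME}
    median_c_score: float


@dataclass
class SurvivalComparison:
    groups: list[str]
    km_curves: dict[str, pd.DataFrame]  # group -> (time, survival) step function
    logrank_stat: float
    p: float


@dataclass
class AssociationResult:
    table: np.ndarray
    odds_ratio: float | None
    p_exact: float


def classify_patient_tme(
    phenotypes: pd.Series,
    patient_map: pd.Series,
    rule: str = "any-h",
    c_scores: pd.DataFrame | None = None,
) -> list[PatientSummary]:
    """Aggregate ROI phenotypes to an HCs-/LCs-TME class per patient.

    ``phenotypes`` maps roi -> label ("h-ITH"/"m-ITH"/"l-ITH" or the short
    "h"/"m"/"l"); ``c_scores`` (optional) is a concordance table from which
    the per-patient median C-score is summarized.
    """
    if rule not in TME_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {TME_RULES}")
    short = phenotypes.map(lambda v: _SHORT.get(v, v))
    bad = sorted(set(short) - {"h", "m", "l"})
    if bad:
        raise ValueError(f"unknown phenotype label(s): {bad}")
    summaries = []
    for pid, ph in short.groupby(patient_map.loc[short.index]):
        counts = {p: int((ph == p).sum()) for p in ("h", "m", "l")}
        if rule == "any-h":
            hcs = counts["h"] >= 1
        elif rule == "non-uniform":
            hcs = ph.nunique() > 1
        else:  # majority-h
            hcs = counts["h"] / len(ph) > 0.5
        med = np.nan
        if c_scores is not None:
            sub = c_scores[c_scores["patient_id"] == pid]["c_score"].dropna()
            if len(sub):
                med = float(sub.median())
        summaries.append(
            PatientSummary(
                patient_id=str(pid),
                roi_phenotype_counts=counts,
                tme_class="HCs-TME" if hcs else "LCs-TME",
                median_c_score=med,
            )
        )
    return summaries


def compare_survival(survival: pd.DataFrame, groups: pd.Series) -> SurvivalComparison:
    """Kaplan-Meier estimates per group and the two-group log-rank test.

    ``survival`` has columns (patient_id, time, event); ``groups`` maps
    patient_id -> group label.  The log-rank statistic is chi-square with
    1 df.  With no observed events the statistic is 0 (warned).
    """
    df = survival.copy()
    df["group"] = df["patient_id"].map(groups)
    if df["group"].isna().any():
        raise ValueError("every patient needs a group label")
    names = sorted(df["group"].unique())
    if len(names) != 2:
        raise ValueError(f"two groups required, got {names}")
    for g in names:
        if not len(df[df["group"] == g]):
            raise ValueError(f"empty group {g!r}")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    curves = {}
    for g in names:
        sub = df[df["group"] == g]
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=str(g))
        curves[g] = km.survival_function_.reset_index().set_axis(
            ["time", "survival"], axis=1
        )
    if df["event"].sum() == 0:
        warnings.warn("no observed events: log-rank statistic is 0")
        return SurvivalComparison(names, curves, 0.0, 1.0)
    a, b = (df[df["group"] == g] for g in names)
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return SurvivalComparison(names, curves, float(res.test_statistic), float(res.p_value))


def fisher_association(table) -> AssociationResult:
    """Fisher's exact test on a contingency table.

    2x2 tables get the exact two-sided p (sum of hypergeometric
    probabilities <= that of the observed table) and the conditional odds
    ratio.  Larger tables fall back to the chi-square test of independence
    (odds ratio undefined).
    """
    t = np.asarray(table)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be integers")
    t = np.round(t).astype(np.int64)
    if t.sum() == 0:
        raise ValueError("degenerate all-zero table")
    if t.shape == (2, 2):
        res = stats.fisher_exact(t, alternative="two-sided")
        return AssociationResult(table=t, odds_ratio=float(res.statistic), p_exact=float(res.pvalue))
    chi2 = stats.chi2_contingency(t)
    return AssociationResult(table=t, odds_ratio=None, p_exact=float(chi2.pvalue))


def group_compare(values, groups, test: str = "wilcoxon") -> tuple[float, float]:
    """Rank-based comparison of a continuous variable across groups.

    "wilcoxon": two-group Wilcoxon rank-sum (Mann-Whitney; exact when both
    groups are small and tie-free, otherwise the tie-corrected normal
    approximation without continuity correction, which matches the
    Kruskal-Wallis chi-square form at k=2); "kruskal": Kruskal-Wallis for
    >=2 groups.  Returns (statistic, two-sided p).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    samples = [values[groups == g] for g in names]
    if len(samples) < 2:
        raise ValueError("need >=2 groups")
    for g, s in zip(names, samples):
        if len(s) == 0:
            raise ValueError(f"group {g!r} has no observations")
    if test == "wilcoxon":
        if len(samples) != 2:
            raise ValueError("wilcoxon requires exactly 2 groups")
        res = stats.mannwhitneyu(
            samples[0], samples[1], alternative="two-sided",
            method="auto", use_continuity=False,
        )
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal":
        res = stats.kruskal(*samples)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
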