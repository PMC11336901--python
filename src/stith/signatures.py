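"""Phenotype gene signatures: differential expression, co-expression
networks, marker-module scores and over-representation analysis.

Differential expression is one-vs-rest on log2 normalized values with
Welch's t by default (an empirical-Bayes moderated t is available);
a gene passes at |fold change| > 1.5 (i.e. |log2FC| > log2 1.5) and
p <= 0.05, both raw by default.  DEG sets seed a Spearman co-expression
network (edges at |rho| >= 0.6 and p < 0.01).  Module scores are
unweighted means of log2 expression over marker genes (the MCP-counter
marker-averaging principle), and over-representation uses the upper-tail
hypergeometric test against user-supplied GMT gene sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

__all__ = [
    "CoexpressionNetwork",
    "differential_expression",
    "build_coexpression_network",
    "marker_module_score",
    "ora_enrichment",
    "read_gmt",
    "write_gmt",
]

FC_THRESHOLD = 1.5
P_THRESHOLD = 0.05


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph  # nodes = genes; edge attrs rho, p
    edges: pd.DataFrame  # gene_a, gene_b, rho, p
    annotations: dict[str, str]  # gene -> phenotype of origin


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _moderated_t(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes moderated t with a method-of-moments prior.

    Pooled gene variances are shrunk toward a common prior fitted on the
    scaled-F model for log sample variances: with df residual degrees of
    freedom, e_g = log(s_g^2) - digamma(df/2) + log(df/2) has variance
    trigamma(df/2) + trigamma(d0/2), so d0 comes from inverting the
    trigamma (Newton) and s0^2 from the mean of e_g.
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1)) / df
    z = np.log(np.maximum(s2, np.finfo(float).tiny))
    e = z - digamma(df / 2) + math.log(df / 2)
    target = e.var(ddof=1) - polygamma(1, df / 2)
    if target <= 1e-8:  # no excess spread: effectively infinite prior df
        d0, s0_sq = 1e6, math.exp(e.mean())
    else:
        y = 0.5 + 1.0 / target  # starting point, then Newton on trigamma(y)=target
        for _ in range(100):
            delta = (polygamma(1, y) - target) / polygamma(2, y)
            y -= delta
            if abs(delta) < 1e-12:
                break
        d0 = 2 * y
        s0_sq = math.exp(e.mean() - digamma(y) + math.log(y))
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x1.mean(axis=1) - x2.mean(axis=1)) / se
    p = 2 * stats.t.sf(np.abs(t), df=min(df + d0, 1e6))
    return t, p


def differential_expression(
    matrix: pd.DataFrame,
    phenotypes: pd.Series,
    contrast: str,
    method: str = "welch",
    fc_threshold: float = FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One-vs-rest differential expression on a log2 matrix.

    Returns a per-gene table with columns log2fc (in-group mean minus
    rest mean), t, p, direction and passes (|log2fc| > log2(fc_threshold)
    and p <= p_threshold).  Genes with zero variance in both groups but
    unequal means get the smallest representable p and a degenerate flag.
    """
    labels = phenotypes.loc[matrix.columns]
    in_group = matrix.columns[labels == contrast]
    rest = matrix.columns[labels != contrast]
    if len(in_group) < 2 or len(rest) < 2:
        raise ValueError(
            f"both groups need >=2 ROIs (got {len(in_group)} vs {len(rest)})"
        )
    x1 = matrix[in_group].to_numpy(dtype=float)
    x2 = matrix[rest].to_numpy(dtype=float)
    log2fc = x1.mean(axis=1) - x2.mean(axis=1)

    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(x1, x2, axis=1, equal_var=False)
        t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    elif method == "moderated":
        t, p = _moderated_t(x1, x2)
    else:
        raise ValueError(f"unknown method {method!r}")

    degenerate = (x1.var(axis=1) == 0) & (x2.var(axis=1) == 0)
    tiny = np.finfo(float).tiny
    with np.errstate(invalid="ignore"):
        p = np.where(degenerate & (log2fc != 0), tiny, p)
        t = np.where(degenerate & (log2fc != 0), np.sign(log2fc) * np.inf, t)
        p = np.where(degenerate & (log2fc == 0), 1.0, p)
        t = np.where(degenerate & (log2fc == 0), 0.0, t)

    p_use = p
    if bh_correct:
        p_use = stats.false_discovery_control(p, method="bh")
    passes = (np.abs(log2fc) > np.log2(fc_threshold)) & (p_use <= p_threshold)
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "contrast": f"{contrast}_vs_rest",
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "p_adj": p_use if bh_correct else np.nan,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "degenerate": degenerate,
            "passes": passes,
        }
    ).set_index("gene")


# ---------------------------------------------------------------------------
# co-expression network
# ---------------------------------------------------------------------------

def build_coexpression_network(
    matrix: pd.DataFrame,
    deg_sets: dict[str, list[str]],
    rho_min: float = 0.6,
    p_max: float = 0.01,
) -> CoexpressionNetwork:
    """Spearman co-expression network over the union of DEG sets.

    Every unordered pair of DEG genes is tested across ROIs; pairs with
    |rho| >= rho_min and p < p_max become undirected edges.  Genes without
    a qualifying edge are dropped from the node list.  ``annotations``
    records each gene's phenotype of origin (first set that contains it).
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >=3 ROIs for correlation p-values")
    annotations: dict[str, str] = {}
    for phen, genes in deg_sets.items():
        for g in genes:
            annotations.setdefault(g, phen)
    genes = [g for g in annotations if g in matrix.index]
    sub = matrix.loc[genes].to_numpy(dtype=float)
    constant = sub.std(axis=1) == 0
    if constant.any():
        skipped = [g for g, c in zip(genes, constant) if c]
        warnings.warn(f"constant gene vector(s) skipped: {skipped}")
        genes = [g for g, c in zip(genes, constant) if not c]
        sub = matrix.loc[genes].to_numpy(dtype=float)
    rows = []
    if len(genes) >= 2:
        rho, p = stats.spearmanr(sub, axis=1)
        if len(genes) == 2:  # spearmanr returns scalars for a single pair
            rho = np.array([[1.0, rho], [rho, 1.0]])
            p = np.array([[0.0, p], [p, 0.0]])
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if abs(rho[i, j]) >= rho_min and p[i, j] < p_max:
                    rows.append(
                        {
                            "gene_a": genes[i],
                            "gene_b": genes[j],
                            "rho": float(rho[i, j]),
                            "p": float(p[i, j]),
                        }
                    )
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "p"])
    graph = nx.Graph()
    for _, r in edges.iterrows():
        graph.add_edge(r["gene_a"], r["gene_b"], rho=r["rho"], p=r["p"])
    for n in graph.nodes:
        graph.nodes[n]["phenotype"] = annotations.get(n, "")
    return CoexpressionNetwork(graph=graph, edges=edges, annotations=annotations)


# ---------------------------------------------------------------------------
# module scores
# ---------------------------------------------------------------------------

def marker_module_score(matrix: pd.DataFrame, modules: dict[str, list[str]]) -> pd.DataFrame:
    """Mean log2 expression of each module's present genes, per ROI.

    Missing module genes are dropped with a warning; a module with no gene
    present is an error.  Returns a long table (roi_id, module, score).
    """
    rows = []
    for name, genes in modules.items():
        present = [g for g in genes if g in matrix.index]
        if not present:
            raise ValueError(f"module {name!r}: no gene present in the matrix")
        if len(present) < len(genes):
            missing = sorted(set(genes) - set(present))
            warnings.warn(f"module {name!r}: missing gene(s) {missing}")
        scores = matrix.loc[present].mean(axis=0)
        for roi, s in scores.items():
            rows.append({"roi_id": roi, "module": name, "score": float(s)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora_enrichment(
    query: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of query genes.

    Sets are intersected with the universe first; p is P(overlap >=
    observed) drawing |query| genes from the universe.  Benjamini-Hochberg
    adjustment is optional (off by default).
    """
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    uni = set(universe)
    q = set(query) & uni
    if not set(query) <= uni:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, genes in gene_sets.items():
        s = set(genes) & uni
        k = len(q & s)
        # hypergeom.sf(k-1) = P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(s), len(q)))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(s),
                "query_size": len(q),
                "universe_size": len(uni),
                "p_hypergeometric": p,
            }
        )
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        out["p_adj"] = stats.false_discovery_control(
            out["p_hypergeometric"].to_numpy(), method="bh"
        )
    return out


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")
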