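"""Differential expression, co-expression networks, module scores, ORA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stith.signatures import (
    build_coexpression_network,
    differential_expression,
    marker_module_score,
    ora_enrichment,
    read_gmt,
    write_gmt,
)


def _mat(arr, genes=None, rois=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(arr.shape[0])]
    rois = rois or [f"R{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=rois)


def _phen(n_in, n_rest):
    return pd.Series(
        ["h-ITH"] * n_in + ["rest"] * n_rest,
        index=[f"R{j}" for j in range(n_in + n_rest)],
    )


class TestDifferentialExpression:
    def test_identical_gene_is_null(self):
        x = np.vstack([np.full(8, 5.0), np.random.default_rng(0).normal(size=8)])
        out = differential_expression(_mat(x), _phen(4, 4), "h-ITH")
        row = out.loc["G000"]
        assert row["log2fc"] == 0.0
        assert row["p"] == pytest.approx(1.0)
        assert not row["passes"]

    def test_planted_twofold_gene_passes(self):
        """log2fc = 1 with noise SD 0.2 at n = 20/20: Welch power ~ 1."""
        rng = np.random.default_rng(1)
        n = 20
        gene = np.concatenate([rng.normal(6.0, 0.2, n), rng.normal(5.0, 0.2, n)])
        noise = rng.normal(5.0, 0.2, 2 * n)
        m = _mat(np.vstack([gene, noise]), rois=[f"R{j}" for j in range(2 * n)])
        out = differential_expression(m, _phen(n, n), "h-ITH")
        assert bool(out.loc["G000", "passes"])
        assert out.loc["G000", "log2fc"] == pytest.approx(1.0, abs=0.2)
        assert not bool(out.loc["G001", "passes"])

    def test_degenerate_zero_variance_flagged(self):
        x = np.vstack([[1.0, 1, 1, 2, 2, 2]])
        out = differential_expression(_mat(x), _phen(3, 3), "h-ITH")
        row = out.loc["G000"]
        assert bool(row["degenerate"])
        assert row["p"] == np.finfo(float).tiny

    def test_group_swap_negates_log2fc_preserves_p(self):
        rng = np.random.default_rng(2)
        m = _mat(rng.normal(5, 1, size=(10, 12)), rois=[f"R{j}" for j in range(12)])
        phen = _phen(6, 6)
        a = differential_expression(m, phen, "h-ITH")
        b = differential_expression(m, phen, "rest")
        assert b["log2fc"].to_numpy() == pytest.approx(-a["log2fc"].to_numpy())
        assert b["p"].to_numpy() == pytest.approx(a["p"].to_numpy())

    def test_small_group_is_error(self):
        m = _mat(np.zeros((3, 4)), rois=[f"R{j}" for j in range(4)])
        with pytest.raises(ValueError, match=">=2"):
            differential_expression(m, _phen(1, 3), "h-ITH")

    def test_moderated_t_shrinks_extreme_variances(self):
        """Moderated p for a low-variance gene is less extreme than Welch
        (variance shrinks toward the common prior)."""
        rng = np.random.default_rng(3)
        x = rng.normal(5, 1, size=(200, 12))
        x[0] = np.concatenate([np.full(6, 5.02), np.full(6, 5.0)])  # tiny var, tiny fc
        x[0] += rng.normal(0, 1e-4, 12)
        m = _mat(x, rois=[f"R{j}" for j in range(12)])
        welch = differential_expression(m, _phen(6, 6), "h-ITH", method="welch")
        mod = differential_expression(m, _phen(6, 6), "h-ITH", method="moderated")
        assert mod.loc["G000", "p"] > welch.loc["G000", "p"]


class TestModeratedVsLimma:
    def test_moderated_t_tracks_limma_ebayes(self, tmp_path):
        """Independent oracle: limma's eBayes (via Rscript) on the same
        fixture gives identical log-fold-changes and closely matching
        moderated p-values."""
        import subprocess

        rng = np.random.default_rng(0)
        n_genes, n1, n2 = 100, 6, 8
        x = rng.normal(5, 1, size=(n_genes, n1 + n2))
        x[:10, :n1] += 1.0
        m = _mat(x, rois=[f"R{j}" for j in range(n1 + n2)])
        phen = pd.Series(["h"] * n1 + ["rest"] * n2, index=m.columns)
        mine = differential_expression(m, phen, "h", method="moderated")

        m.to_csv(tmp_path / "x.tsv", sep="\t")
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1))
        design <- model.matrix(~ factor(c(rep("h",{n1}), rep("r",{n2})), levels=c("r","h")))
        fit <- eBayes(lmFit(x, design))
        tt <- topTable(fit, coef=2, number=Inf, sort.by="none")
        write.csv(tt, "{tmp_path}/out.csv")
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        limma = pd.read_csv(tmp_path / "out.csv", index_col=0)
        assert mine["log2fc"].to_numpy() == pytest.approx(
            limma["logFC"].to_numpy(), abs=1e-9
        )
        assert np.abs(mine["p"].to_numpy() - limma["P.Value"].to_numpy()).max() < 0.01


class TestCoexpressionNetwork:
    def test_duplicated_genes_form_an_edge(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=12)
        x = np.vstack([base, base, rng.normal(size=12)])
        net = build_coexpression_network(
            _mat(x, rois=[f"R{j}" for j in range(12)]),
            {"h": ["G000", "G001", "G002"]},
        )
        pairs = set(map(tuple, net.edges[["gene_a", "gene_b"]].to_numpy()))
        assert ("G000", "G001") in pairs

    def test_toy_counts_match_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 15))
        x[1] = x[0] + rng.normal(0, 0.1, 15)  # one strongly coupled pair
        m = _mat(x, rois=[f"R{j}" for j in range(15)])
        genes = list(m.index)
        net = build_coexpression_network(m, {"h": genes}, rho_min=0.6, p_max=0.01)
        expected = set()
        for i in range(6):
            for j in range(i + 1, 6):
                rho, p = stats.spearmanr(x[i], x[j])
                if abs(rho) >= 0.6 and p < 0.01:
                    expected.add((genes[i], genes[j]))
        got = set(map(tuple, net.edges[["gene_a", "gene_b"]].to_numpy()))
        assert got == expected
        assert set(net.graph.nodes) == {g for pair in expected for g in pair}

    def test_false_edge_rate_on_independent_noise(self):
        """20 independent genes, 30 ROIs: the p < 0.01 cut caps the
        spurious-edge rate at pairs x 0.01, and the joint |rho| >= 0.6
        requirement can only push it lower; the observed total over 50
        seeds stays below that binomial cap (+3 SDs) but is not zero."""
        n_pairs = 20 * 19 // 2
        total = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            m = _mat(rng.normal(size=(20, 30)), rois=[f"R{j}" for j in range(30)])
            net = build_coexpression_network(m, {"h": list(m.index)})
            total += len(net.edges)
        cap = 50 * n_pairs * 0.01
        sd = math.sqrt(50 * n_pairs * 0.01 * 0.99)
        assert 0 < total <= cap + 3 * sd

    def test_constant_gene_skipped_with_warning(self):
        x = np.vstack([np.full(10, 1.0), np.random.default_rng(6).normal(size=10)])
        m = _mat(x, rois=[f"R{j}" for j in range(10)])
        with pytest.warns(UserWarning, match="constant"):
            net = build_coexpression_network(m, {"h": list(m.index)})
        assert "G000" not in net.graph.nodes

    def test_edge_set_invariant_to_gene_order(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(8, 20))
        x[3] = x[5] + rng.normal(0, 0.05, 20)
        m = _mat(x, rois=[f"R{j}" for j in range(20)])
        a = build_coexpression_network(m, {"h": list(m.index)})
        b = build_coexpression_network(m, {"h": list(m.index[::-1])})
        norm = lambda e: {tuple(sorted(p)) for p in e[["gene_a", "gene_b"]].to_numpy()}
        assert norm(a.edges) == norm(b.edges)


class TestModuleScores:
    def test_single_gene_module_equals_that_gene(self):
        m = _mat([[1.0, 2.0], [5.0, 6.0]])
        out = marker_module_score(m, {"mod": ["G001"]})
        assert out[out["module"] == "mod"]["score"].tolist() == [5.0, 6.0]

    def test_constant_module_scores_constant(self):
        m = _mat(np.full((3, 4), 2.5))
        out = marker_module_score(m, {"mod": ["G000", "G001", "G002"]})
        assert out["score"].tolist() == [2.5] * 4

    def test_half_present_module_averages_present_half(self):
        m = _mat([[1.0, 3.0], [5.0, 7.0]])
        with pytest.warns(UserWarning, match="missing"):
            out = marker_module_score(m, {"mod": ["G000", "G001", "MISSING"]})
        assert out["score"].tolist() == [3.0, 5.0]

    def test_empty_module_is_error(self):
        m = _mat([[1.0, 2.0]])
        with pytest.raises(ValueError, match="ghost"):
            marker_module_score(m, {"ghost": ["NOPE"]})

    def test_linearity_over_roi_averaging(self):
        rng = np.random.default_rng(8)
        m = _mat(rng.normal(size=(6, 2)))
        modules = {"mod": list(m.index[:4])}
        scores = marker_module_score(m, modules)["score"].to_numpy()
        avg_roi = _mat(m.mean(axis=1).to_numpy()[:, None], genes=list(m.index))
        avg_score = marker_module_score(avg_roi, modules)["score"].iloc[0]
        assert avg_score == pytest.approx(scores.mean())


class TestORA:
    def test_full_overlap_matches_closed_form(self):
        universe = [f"G{i}" for i in range(1000)]
        query = universe[:10]
        res = ora_enrichment(query, {"s": universe[:10]}, universe)
        expected = 1 / math.comb(1000, 10)  # only one way to draw all 10
        assert res["p_hypergeometric"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"G{i}" for i in range(100)]
        res = ora_enrichment(universe[:5], {"s": universe[50:60]}, universe)
        assert res["p_hypergeometric"].iloc[0] == pytest.approx(1.0)

    def test_set_outside_universe_is_intersected(self):
        universe = [f"G{i}" for i in range(50)]
        res = ora_enrichment(universe[:5], {"s": universe[:5] + ["ALIEN"]}, universe)
        assert res["set_size"].iloc[0] == 5
        assert res["overlap"].iloc[0] == 5

    def test_p_decreases_with_overlap(self):
        universe = [f"G{i}" for i in range(200)]
        ps = []
        for k in (2, 5, 8):
            res = ora_enrichment(
                universe[:10], {"s": universe[:k] + universe[100 : 110 - k]}, universe
            )
            ps.append(res["p_hypergeometric"].iloc[0])
        assert ps[0] > ps[1] > ps[2]

    def test_empty_query_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            ora_enrichment([], {"s": ["A"]}, ["A"])


class TestGMT:
    def test_roundtrip(self, tmp_path):
        sets = {"alpha": ["A", "B", "C"], "beta": ["D"]}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_malformed_line(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("name_only\tdesc\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(path)
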