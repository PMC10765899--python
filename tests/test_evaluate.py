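import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import notchsig as ns


def auc_all_pairs_oracle(scores, labels):
    """Fraction of concordant (positive, negative) pairs, ties counting half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = ns.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_all_tied_scores(self):
        r = ns.roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_eight_score_toy_matches_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9, 0.5, 0.2]
        labels = [0, 0, 1, 1, 0, 1, 1, 0]
        r = ns.roc_auc(scores, labels)
        assert r.auc == pytest.approx(auc_all_pairs_oracle(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_all_pairs_oracle_on_random_instances(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(6, 30))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        r = ns.roc_auc(scores, labels.astype(bool))
        assert r.auc == pytest.approx(auc_all_pairs_oracle(scores, labels), abs=1e-12)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40).astype(bool)
        a = ns.roc_auc(scores, labels).auc
        b = ns.roc_auc(scores, ~labels).auc
        assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(8)
        r = ns.roc_auc(rng.normal(size=50), rng.integers(0, 2, 50).astype(bool))
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()

    def test_ci_contains_auc_and_is_clipped(self):
        rng = np.random.default_rng(9)
        r = ns.roc_auc(rng.normal(size=30), rng.integers(0, 2, 30).astype(bool))
        assert r.ci[0] <= r.auc <= r.ci[1]
        assert 0.0 <= r.ci[0] and r.ci[1] <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            ns.roc_auc([1, 2, 3], [1, 1, 1])

    def test_bootstrap_ci_close_to_delong(self):
        rng = np.random.default_rng(10)
        scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(1, 1, 60)])
        labels = np.repeat([False, True], 60)
        d = ns.roc_auc(scores, labels, ci_method="delong")
        b = ns.roc_auc(scores, labels, ci_method="bootstrap", seed=1)
        assert d.ci[0] == pytest.approx(b.ci[0], abs=0.03)
        assert d.ci[1] == pytest.approx(b.ci[1], abs=0.03)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_delong_ci_matches_r_proc(self, tmp_path):
        """AUC and DeLong CI agree with the reference R implementation."""
        rng = np.random.default_rng(11)
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(0.8, 1, 40)])
        labels = np.repeat([0, 1], 40)
        pd.DataFrame({"score": scores, "label": labels}).to_csv(
            tmp_path / "roc.tsv", sep="\t", index=False
        )
        script = textwrap.dedent("""
            suppressMessages(library(pROC))
            d <- read.delim(commandArgs(TRUE)[1])
            r <- roc(d$label, d$score, direction="<", quiet=TRUE)
            ci <- ci.auc(r, method="delong")
            cat(sprintf("%.12f\\n%.12f\\n%.12f\\n", ci[1], ci[2], ci[3]))
        """)
        (tmp_path / "roc.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "roc.R"), str(tmp_path / "roc.tsv")],
            capture_output=True, text=True, check=True,
        )
        lo, auc, hi = (float(v) for v in out.stdout.split())
        mine = ns.roc_auc(scores, labels.astype(bool))
        assert mine.auc == pytest.approx(auc, abs=1e-9)
        assert mine.ci[0] == pytest.approx(lo, abs=1e-9)
        assert mine.ci[1] == pytest.approx(hi, abs=1e-9)

    def test_strong_effect_classifies_perturbation(self, cell_cohort):
        """Relative signature scores separate Notch-on from Notch-off."""
        sig = ns.GeneSignature(
            "planted", tuple(cell_cohort.provenance["planted_genes"][:20])
        )
        rel = ns.relative_score(
            ns.signature_score(cell_cohort, sig), cell_cohort.metadata
        )
        cond = cell_cohort.metadata["condition"]
        keep = cond != "ground"
        r = ns.roc_auc(rel.scores.loc[keep, "relative_score"],
                       cond[keep] == "notch_on")
        assert r.auc >= 0.9


class TestRankMetric:
    def _contrast(self, rows):
        table = pd.DataFrame(rows).set_index("gene")
        return ns.ContrastResult(spec=ns.ContrastSpec("on", "off"), table=table)

    def test_logp_lfc_arithmetic(self):
        c = self._contrast([{"gene": "GA", "log2fc": 2.0, "stat": 5.0, "p": 0.01, "padj": 0.02}])
        assert ns.rank_metric(c, "logp_lfc")["GA"] == pytest.approx(4.0)

    def test_zero_fold_change_scores_zero(self):
        c = self._contrast([{"gene": "GA", "log2fc": 0.0, "stat": 0.0, "p": 1e-30, "padj": 1e-29}])
        assert ns.rank_metric(c, "logp_lfc")["GA"] == 0.0

    def test_ties_broken_alphabetically(self):
        rows = [{"gene": g, "log2fc": 1.0, "stat": 2.0, "p": 0.1, "padj": 0.2}
                for g in ["GZ", "GA", "GM"]]
        ranked = ns.rank_metric(self._contrast(rows), "wald")
        assert list(ranked.index) == ["GA", "GM", "GZ"]

    def test_zero_p_floored_with_warning(self):
        c = self._contrast([{"gene": "GA", "log2fc": 1.0, "stat": 9.0, "p": 0.0, "padj": 0.0},
                            {"gene": "GB", "log2fc": 1.0, "stat": 1.0, "p": 0.5, "padj": 0.6}])
        with pytest.warns(UserWarning, match="floored"):
            ranked = ns.rank_metric(c, "logp_lfc")
        assert np.isfinite(ranked["GA"]) and ranked["GA"] > 0

    def test_wald_uses_signed_statistic(self):
        rows = [{"gene": "GA", "log2fc": -1.0, "stat": -4.0, "p": 0.01, "padj": 0.02},
                {"gene": "GB", "log2fc": 1.0, "stat": 3.0, "p": 0.02, "padj": 0.03}]
        ranked = ns.rank_metric(self._contrast(rows), "wald")
        assert list(ranked.index) == ["GB", "GA"]


def gsea_running_sum_oracle(genes, scores, members, weight):
    """Step-by-step running sum, returning the extremal deviation."""
    hits = [abs(s) ** weight if g in members else 0.0 for g, s in zip(genes, scores)]
    total_hit = sum(hits)
    n_miss = sum(1 for g in genes if g not in members)
    run, best = 0.0, 0.0
    for g, s, h in zip(genes, scores, hits):
        if g in members:
            run += h / total_hit
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestGseaEs:
    def _ranked(self, scores, genes=None):
        genes = genes or [f"G{i:02d}" for i in range(len(scores))]
        return pd.Series(scores, index=genes)

    def test_single_gene_at_top_weight_zero(self):
        ranked = self._ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        res = ns.gsea_es(ranked, ns.GeneSignature("s", ("G00",)), weight=0.0,
                         n_permutations=50, seed=1)
        assert res.es == pytest.approx(1.0, abs=1e-12)

    def test_full_list_set_rejected(self):
        ranked = self._ranked([3.0, 2.0, 1.0])
        sig = ns.GeneSignature("s", tuple(ranked.index))
        with pytest.raises(ValueError, match="entire"):
            ns.gsea_es(ranked, sig, n_permutations=10, seed=1)

    def test_empty_intersection_rejected(self):
        ranked = self._ranked([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="intersect"):
            ns.gsea_es(ranked, ns.GeneSignature("s", ("NOPE",)),
                       n_permutations=10, seed=1)

    def test_ten_gene_toy_matches_running_sum_oracle(self):
        scores = [9.0, 7.5, 6.0, 4.0, 2.5, 1.0, -0.5, -2.0, -3.5, -5.0]
        genes = [f"G{i:02d}" for i in range(10)]
        members = {"G01", "G03", "G08"}
        ranked = self._ranked(scores, genes)
        res = ns.gsea_es(ranked, ns.GeneSignature("s", tuple(sorted(members))),
                         weight=1.0, n_permutations=50, seed=2)
        expected = gsea_running_sum_oracle(genes, scores, members, 1.0)
        assert res.es == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_es_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        scores = np.sort(rng.normal(size=n))[::-1]
        genes = [f"G{i:03d}" for i in range(n)]
        k = int(rng.integers(1, n))
        members = tuple(sorted(rng.choice(genes, size=k, replace=False)))
        res = ns.gsea_es(pd.Series(scores, index=genes),
                         ns.GeneSignature("s", members),
                         n_permutations=20, seed=seed)
        assert abs(res.es) <= 1.0 + 1e-12

    def test_top_set_enriched_with_small_p(self):
        rng = np.random.default_rng(3)
        scores = np.sort(rng.normal(size=200))[::-1] + 0.0
        genes = [f"G{i:03d}" for i in range(200)]
        ranked = pd.Series(scores, index=genes)
        res = ns.gsea_es(ranked, ns.GeneSignature("s", tuple(genes[:15])),
                         n_permutations=500, seed=4)
        assert res.es > 0.5
        assert res.p < 0.05
        assert res.nes > 1.0
        assert set(res.leading_edge) <= set(genes[:15])

    def test_reversed_ranking_negates_extremum_side(self):
        scores = np.linspace(5, -5, 60)
        genes = [f"G{i:02d}" for i in range(60)]
        sig = ns.GeneSignature("s", tuple(genes[:8]))
        fwd = ns.gsea_es(pd.Series(scores, index=genes), sig,
                         n_permutations=50, seed=5)
        rev = ns.gsea_es(pd.Series(scores[::-1].copy(), index=genes[::-1]), sig,
                         n_permutations=50, seed=5)
        assert fwd.es > 0 > rev.es


class TestSetSimilarity:
    def test_identical_and_disjoint(self):
        a = ns.GeneSignature("a", ("X1", "X2"))
        b = ns.GeneSignature("b", ("X1", "X2"))
        c = ns.GeneSignature("c", ("Y1", "Y2"))
        sim = ns.set_similarity([a, b, c])
        assert sim.loc["a", "b"] == 1.0
        assert sim.loc["a", "c"] == 0.0
        assert (np.diag(sim) == 1.0).all()

    def test_enumerated_jaccard_and_overlap(self):
        a = ns.GeneSignature("a", ("GA", "GB", "GC"))
        b = ns.GeneSignature("b", ("GB", "GC", "GD", "GE"))
        assert ns.set_similarity([a, b], "jaccard").loc["a", "b"] == pytest.approx(2 / 5)
        assert ns.set_similarity([a, b], "overlap").loc["a", "b"] == pytest.approx(2 / 3)

    def test_jaccard_never_exceeds_overlap(self, rng):
        sigs = []
        pool = [f"G{i:02d}" for i in range(30)]
        for i in range(6):
            k = int(rng.integers(2, 20))
            sigs.append(ns.GeneSignature(f"s{i}", tuple(
                sorted(rng.choice(pool, size=k, replace=False)))))
        jac = ns.set_similarity(sigs, "jaccard")
        ove = ns.set_similarity(sigs, "overlap")
        assert (jac.to_numpy() <= ove.to_numpy() + 1e-12).all()

    def test_single_signature_rejected(self):
        with pytest.raises(ValueError, match="2"):
            ns.set_similarity([ns.GeneSignature("a", ("X1",))])


class TestClustering:
    def test_coincident_pair_merges_first_at_zero(self):
        mat = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]],
                           index=["A", "B", "C"])
        d = ns.cluster_complete_euclidean(mat)
        assert d.merge_heights()[0] == 0.0
        # first merge joins the two coincident leaves (indices 0 and 1)
        assert set(d.linkage[0, :2].astype(int)) == {0, 1}

    def test_four_point_toy_matches_manual_trace(self):
        # points on a line: A=0, B=1, C=10, D=12
        mat = pd.DataFrame([[0.0], [1.0], [10.0], [12.0]],
                           index=["A", "B", "C", "D"])
        d = ns.cluster_complete_euclidean(mat)
        # manual complete linkage: (A,B)@1, (C,D)@2, then all@max=12
        np.testing.assert_allclose(d.merge_heights(), [1.0, 2.0, 12.0])

    def test_single_pair_merges_at_euclidean_distance(self):
        mat = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["A", "B"])
        d = ns.cluster_complete_euclidean(mat)
        assert d.merge_heights()[0] == pytest.approx(5.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(6, 3)),
                           index=["F", "B", "D", "A", "E", "C"])
        d1 = ns.cluster_complete_euclidean(mat)
        d2 = ns.cluster_complete_euclidean(mat.sample(frac=1, random_state=4))
        assert d1.labels == d2.labels
        np.testing.assert_allclose(d1.linkage, d2.linkage)

    def test_newick_round_trips_through_skbio(self):
        import io

        from skbio.tree import TreeNode

        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(5, 3)),
                           index=["A", "B", "C", "D", "E"])
        nwk = ns.cluster_complete_euclidean(mat).to_newick()
        tree = TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"A", "B", "C", "D", "E"}

    def test_nan_rejected(self):
        mat = pd.DataFrame([[0.0], [np.nan]], index=["A", "B"])
        with pytest.raises(ValueError, match="NaN"):
            ns.cluster_complete_euclidean(mat)
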