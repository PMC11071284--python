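"""Clustering input, k-means, DE comparator, ORA, scores, DEG enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from clonadapt.dataset import ExpressionDataset
from clonadapt.downstream import (
    cluster_values,
    de_ttest,
    deg_adaptive_enrichment,
    kmeans_clusters,
    ora,
    read_gmt,
    signature_score,
)
from clonadapt.inference import GeneScanResult

from .conftest import cells_dataset


def make_scan(regime, rows):
    """rows: list of (gene, call, q)."""
    table = pd.DataFrame([
        {"gene": g, "call": c, "q_adaptive": q, "p_adaptive": q}
        for g, c, q in rows
    ])
    return GeneScanResult(regime=regime, table=table, skipped=[])


class TestClusterValues:
    def test_signed_log2_formula(self):
        scans = {
            "r1": make_scan("r1", [("g1", "adaptive-up", 0.25),
                                   ("g2", "adaptive-down", 0.25),
                                   ("g3", "neutral", 0.8)]),
            "r2": make_scan("r2", [("g1", "neutral", 0.9),
                                   ("g2", "neutral", 0.9),
                                   ("g3", "neutral", 0.9)]),
        }
        v = cluster_values(scans)
        assert v.loc["g1", "r1"] == pytest.approx(-2.0)   # log2 0.25
        assert v.loc["g2", "r1"] == pytest.approx(2.0)    # -log2 0.25
        assert v.loc["g1", "r2"] == 0.0
        assert "g3" not in v.index  # adaptive nowhere -> excluded

    def test_flip_sign_display_option(self):
        scans = {"r": make_scan("r", [("g", "adaptive-up", 0.25)])}
        assert cluster_values(scans, flip_sign=True).loc["g", "r"] == pytest.approx(2.0)

    def test_mismatched_universes_rejected(self):
        scans = {
            "a": make_scan("a", [("g1", "adaptive-up", 0.01)]),
            "b": make_scan("b", [("g2", "adaptive-up", 0.01)]),
        }
        with pytest.raises(ValueError):
            cluster_values(scans)


class TestKmeansClusters:
    def test_recovers_three_separated_blobs(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]])
        X = np.vstack([c + 0.2 * rng.normal(size=(30, 3)) for c in centers])
        values = pd.DataFrame(X, index=[f"g{i}" for i in range(90)],
                              columns=list("abc"))
        res = kmeans_clusters(values, k_range=range(2, 6), seed=0)
        assert res.chosen_k == 3
        # silhouette at k=3 beats the alternatives
        assert res.silhouette_by_k[3] == max(res.silhouette_by_k.values())

    def test_min_criterion_flips_choice(self):
        rng = np.random.default_rng(0)
        X = np.vstack([c + 0.2 * rng.normal(size=(30, 3))
                       for c in ([0, 0, 0], [10, 0, 0], [0, 10, 0])])
        values = pd.DataFrame(X, index=[f"g{i}" for i in range(90)], columns=list("abc"))
        res = kmeans_clusters(values, k_range=range(2, 6), seed=0, criterion="min")
        assert res.chosen_k != 3

    def test_identical_points_degenerate(self):
        values = pd.DataFrame(np.ones((10, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            kmeans_clusters(values)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        X = np.vstack([c + 0.3 * rng.normal(size=(20, 3))
                       for c in ([0, 0, 0], [8, 8, 0])])
        values = pd.DataFrame(X, index=[f"g{i}" for i in range(40)], columns=list("abc"))
        res1 = kmeans_clusters(values, k_range=range(2, 4), seed=7)
        perm = rng.permutation(len(values))
        res2 = kmeans_clusters(values.iloc[perm], k_range=range(2, 4), seed=7)
        # same partition up to label names
        def parts(res):
            return {frozenset(res.assignments.index[res.assignments == lab])
                    for lab in res.assignments.unique()}
        assert parts(res1) == parts(res2)

    def test_k_capped_when_few_genes(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.normal(size=(8, 3)))
        res = kmeans_clusters(values, k_range=range(2, 21), seed=0)
        assert res.chosen_k < 8


class TestDeTtest:
    def test_equal_groups_give_large_p(self):
        tree_cells = {f"A_c{i}": "A" for i in range(10)}
        tree_cells.update({f"B_c{i}": "B" for i in range(10)})
        vals = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 4)[None, :]
        ds = ExpressionDataset(genes=["g"], cells=list(tree_cells),
                               values=vals, cell_to_subline=tree_cells)
        p = de_ttest(ds, {"A"})
        assert p["g"] > 0.9

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(0)
        cells = {f"A_c{i}": "A" for i in range(20)}
        cells.update({f"B_c{i}": "B" for i in range(20)})
        vals = np.concatenate([rng.normal(5, 1, 20), rng.normal(0, 1, 20)])[None, :]
        ds = ExpressionDataset(genes=["g"], cells=list(cells), values=vals,
                               cell_to_subline=cells)
        assert de_ttest(ds, {"A"})["g"] < 1e-6

    def test_matches_welch_statistic(self):
        rng = np.random.default_rng(3)
        cells = {f"A_c{i}": "A" for i in range(12)}
        cells.update({f"B_c{i}": "B" for i in range(15)})
        vals = rng.normal(size=(1, 27))
        ds = ExpressionDataset(genes=["g"], cells=list(cells), values=vals,
                               cell_to_subline=cells)
        a, b = vals[0, :12], vals[0, 12:]
        # Welch t and Satterthwaite df computed from the textbook formulas
        va, vb = a.var(ddof=1) / 12, b.var(ddof=1) / 15
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 11 + vb**2 / 14)
        expected = 2 * scipy.stats.t.sf(abs(t), df)
        assert de_ttest(ds, {"A"})["g"] == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_equal_means_p_one(self):
        cells = {f"A_c{i}": "A" for i in range(3)}
        cells.update({f"B_c{i}": "B" for i in range(3)})
        ds = ExpressionDataset(genes=["g"], cells=list(cells),
                               values=np.full((1, 6), 2.0), cell_to_subline=cells)
        assert de_ttest(ds, {"A"})["g"] == 1.0

    def test_iid_noise_calibrated_but_phylogeny_inflates(self, tree23, painting_har):
        """Nominal level on i.i.d. cells; inflated level on tree-correlated cells."""
        from clonadapt.synthetic import SimSpec, make_grid_dataset, FIXTURE_REGIMES
        rng = np.random.default_rng(11)
        n_genes = 1000
        ds_iid = cells_dataset(tree23, 4,
                               values=rng.normal(size=(n_genes, 92)),
                               genes=[f"g{i}" for i in range(n_genes)])
        frac_iid = (de_ttest(ds_iid, set(FIXTURE_REGIMES["HA-R"])) < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_genes)
        assert frac_iid <= 0.05 + 4 * se

        spec = SimSpec(kind="BM", gamma=0.1, replicates=4, n_genes=300, label="neutral")
        lab = make_grid_dataset(tree23, painting_har, [spec], seed=21)
        frac_phylo = (de_ttest(lab.dataset, set(FIXTURE_REGIMES["HA-R"])) < 0.05).mean()
        assert frac_phylo > 2 * frac_iid
        assert frac_phylo > 0.1


def enumerate_hypergeom_tail(M, K, N, k):
    """P(overlap >= k) by direct combinatorial enumeration."""
    total = math.comb(M, N)
    return sum(math.comb(K, j) * math.comb(M - K, N - j)
               for j in range(k, min(K, N) + 1)) / total


class TestOra:
    def test_disjoint_hits_p_one(self):
        table = ora({"a", "b"}, {"s": {"c", "d"}}, {"a", "b", "c", "d", "e"})
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_perfect_overlap_exact_value(self):
        background = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(5)}
        table = ora(gene_set, {"s": gene_set}, background)
        assert table.loc[0, "p"] == pytest.approx(1 / math.comb(20, 5))

    def test_matches_enumeration_on_small_tables(self):
        rng = np.random.default_rng(4)
        background = [f"g{i}" for i in range(20)]
        for _ in range(25):
            K = int(rng.integers(1, 15))
            N = int(rng.integers(1, 15))
            gene_set = set(rng.choice(background, K, replace=False))
            hits = set(rng.choice(background, N, replace=False))
            table = ora(hits, {"s": gene_set}, set(background))
            k = len(gene_set & hits)
            assert table.loc[0, "p"] == pytest.approx(
                enumerate_hypergeom_tail(20, K, N, k), rel=1e-10)

    def test_widening_background_decreases_p(self):
        hits = {"a", "b"}
        gene_set = {"a", "b", "c"}
        small = ora(hits, {"s": gene_set}, {"a", "b", "c", "d", "e"})
        big = ora(hits, {"s": gene_set},
                  {"a", "b", "c", "d", "e"} | {f"x{i}" for i in range(5)})
        assert big.loc[0, "p"] < small.loc[0, "p"]

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError):
            ora({"zz"}, {"s": {"a"}}, {"a", "b"})

    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("s1\tdesc\ta\tb\tc\ns2\tdesc\tb\td\n")
        sets = read_gmt(path)
        assert sets == {"s1": {"a", "b", "c"}, "s2": {"b", "d"}}


class TestSignatureScore:
    def test_mean_of_two_genes(self):
        cells = {"c1": "A", "c2": "A"}
        ds = ExpressionDataset(genes=["Cd8a", "Cd8b"], cells=["c1", "c2"],
                               values=[[2.0, 1.0], [4.0, 5.0]],
                               cell_to_subline=cells)
        score = signature_score(ds, ["Cd8a", "Cd8b"])
        assert score["c1"] == pytest.approx(3.0)
        assert score["c2"] == pytest.approx(3.0)

    def test_single_gene_and_order_invariance(self):
        cells = {"c1": "A"}
        ds = ExpressionDataset(genes=["a", "b"], cells=["c1"],
                               values=[[1.0], [7.0]], cell_to_subline=cells)
        assert signature_score(ds, ["b"])["c1"] == pytest.approx(7.0)
        assert signature_score(ds, ["a", "b"])["c1"] == \
               signature_score(ds, ["b", "a"])["c1"]

    def test_all_genes_missing_rejected(self):
        cells = {"c1": "A"}
        ds = ExpressionDataset(genes=["a"], cells=["c1"], values=[[1.0]],
                               cell_to_subline=cells)
        with pytest.raises(ValueError):
            signature_score(ds, ["nope"])


class TestDegAdaptiveEnrichment:
    def make_inputs(self):
        rows = []
        for i in range(10):
            call = "adaptive-up" if i < 2 else ("adaptive-down" if i == 2 else "neutral")
            rows.append((f"up{i}", call, 0.01 if call != "neutral" else 0.9))
        for i in range(10):
            rows.append((f"dn{i}", "neutral", 0.9))
        scan = make_scan("HA-R", rows)
        deg = pd.DataFrame({
            "gene": [f"up{i}" for i in range(10)] + [f"dn{i}" for i in range(10)],
            "direction": ["responder"] * 10 + ["nonresponder"] * 10,
        })
        return deg, scan

    def test_percentage_arithmetic(self):
        deg, scan = self.make_inputs()
        table, _ = deg_adaptive_enrichment(deg, scan)
        row = table.set_index("deg_class").loc["responder"]
        assert row["pct_adaptive_up"] == pytest.approx(20.0)
        assert row["pct_adaptive_down"] == pytest.approx(10.0)

    def test_no_adaptive_genes_skips_chi2(self):
        rows = [(f"g{i}", "neutral", 0.9) for i in range(10)]
        scan = make_scan("r", rows)
        deg = pd.DataFrame({"gene": [f"g{i}" for i in range(10)],
                            "direction": ["a"] * 5 + ["b"] * 5})
        table, p = deg_adaptive_enrichment(deg, scan)
        assert np.isnan(p)
        assert (table["pct_adaptive_up"] == 0).all()

    def test_chi2_matches_textbook_formula(self):
        rows = []
        counts = {("r", "adaptive-up"): 20, ("r", "adaptive-down"): 5,
                  ("n", "adaptive-up"): 5, ("n", "adaptive-down"): 20}
        deg_rows = []
        i = 0
        for (cls, call), n in counts.items():
            for _ in range(n):
                rows.append((f"g{i}", call, 0.01))
                deg_rows.append({"gene": f"g{i}", "direction": cls})
                i += 1
        scan = make_scan("r", rows)
        _, p = deg_adaptive_enrichment(pd.DataFrame(deg_rows), scan)
        # textbook Pearson chi-square on the 2x2 table (20,5 / 5,20)
        obs = np.array([[20, 5], [5, 20]])
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        stat = ((obs - exp) ** 2 / exp).sum()
        assert p == pytest.approx(scipy.stats.chi2.sf(stat, 1), rel=1e-12)

    def test_empty_deg_class_rejected(self):
        deg, scan = self.make_inputs()
        deg.loc[deg["direction"] == "nonresponder", "gene"] = "absent"
        with pytest.raises(ValueError):
            deg_adaptive_enrichment(deg, scan)
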