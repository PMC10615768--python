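"""Stratification, expression filtering, TMM, NB DE and enrichment."""
import numpy as np
import pandas as pd
import pytest

from splicemr.calibration import simulate_de_counts
from splicemr.expression import (StratifiedGroups, filter_low_expression, gsea,
                                 nb_differential_expression, ora_enrichment,
                                 read_gmt, stratify_by_psihat, tmm_normalize)

# edgeR::calcNormFactors on the same deterministic matrix
# (simulate_de_counts(seed=5, n_genes=150, n_per_group=10, direction='up'))
EDGER_TMM_FACTORS = np.array([
    0.948209, 1.009392, 1.054473, 1.020203, 1.023863, 1.039527, 0.995904,
    0.984258, 1.021569, 0.996246, 1.010756, 0.968429, 0.993006, 0.967826,
    1.035427, 1.007416, 1.012697, 0.971670, 0.986989, 0.959784])


class TestStratification:
    def test_tertiles_of_distinct_values(self):
        psihat = pd.Series(np.linspace(0, 1, 300), index=[f"s{i}" for i in range(300)])
        g = stratify_by_psihat(psihat, min_group=50)
        assert g.n1 == 100 and g.n2 == 100
        assert g.analyzable
        assert set(g.low) | set(g.high) | set(g.unused) == set(psihat.index)
        assert not (set(g.low) & set(g.high))

    def test_central_mass_is_unanalyzable(self):
        """When most samples share one central psi_hat value both tails are
        too small for group analysis."""
        vals = np.concatenate([np.full(270, 0.5), np.linspace(0, 0.2, 15),
                               np.linspace(0.8, 1.0, 15)])
        psihat = pd.Series(vals, index=[f"s{i}" for i in range(300)])
        g = stratify_by_psihat(psihat, min_group=50)
        assert not g.analyzable

    def test_explicit_cutoffs_override_quantiles(self):
        psihat = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
                           index=list("abcdef"))
        g = stratify_by_psihat(psihat, cutoffs=(0.25, 0.45), min_group=1)
        assert set(g.low) == {"a", "b"}
        assert set(g.high) == {"e", "f"}
        assert set(g.unused) == {"c", "d"}


def _counts_with_exact_cpm(values: dict, n1: int, n2: int) -> tuple:
    """Counts where CPM of each test gene equals its count (library 10^6)."""
    samples = [f"L{i}" for i in range(n1)] + [f"H{i}" for i in range(n2)]
    genes = {}
    for name, per_sample in values.items():
        genes[name] = np.asarray(per_sample)
    df = pd.DataFrame(genes, index=samples).T
    filler = 1_000_000 - df.sum(axis=0)
    df.loc["FILLER"] = filler
    groups = StratifiedGroups("E", [s for s in samples if s.startswith("L")],
                              [s for s in samples if s.startswith("H")], [],
                              np.nan, np.nan, min_group=1)
    return df, groups


class TestLowExpressionFilter:
    def test_strictly_more_than_half_min_group(self):
        n1, n2 = 139, 200  # N = 69.5
        low70 = np.r_[np.ones(70), np.full(269, 100.0)]     # <=1 CPM in 70 samples
        low69 = np.r_[np.ones(69), np.full(270, 100.0)]     # <=1 CPM in 69 samples
        high = np.full(339, 100.0)
        counts, groups = _counts_with_exact_cpm(
            {"REMOVED": low70, "KEPT_BOUNDARY": low69, "KEPT": high}, n1, n2)
        kept = filter_low_expression(counts, groups)
        assert "REMOVED" not in kept
        assert "KEPT_BOUNDARY" in kept
        assert "KEPT" in kept

    def test_non_autosomal_removed_first(self):
        counts, groups = _counts_with_exact_cpm(
            {"AUTO": np.full(20, 100.0), "X_GENE": np.full(20, 100.0)}, 10, 10)
        chrom = pd.Series({"AUTO": "chr2", "X_GENE": "chrX", "FILLER": "chr1"})
        kept = filter_low_expression(counts, groups, gene_chrom=chrom)
        assert "AUTO" in kept and "X_GENE" not in kept

    def test_sample_order_invariance(self):
        counts, groups, _up, _down = simulate_de_counts(11, n_genes=100, n_per_group=15)
        kept1 = filter_low_expression(counts, groups)
        shuffled = counts[list(np.random.default_rng(0).permutation(counts.columns))]
        kept2 = filter_low_expression(shuffled, groups)
        assert set(kept1) == set(kept2)


class TestTmm:
    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, size=200)
        counts = pd.DataFrame({"a": col, "b": col})
        assert np.allclose(tmm_normalize(counts), 1.0)

    def test_depth_only_difference_equal_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(200, size=500)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        f = tmm_normalize(counts)
        assert f["a"] == pytest.approx(f["b"], rel=1e-6)

    def test_matches_edger_reference(self):
        counts, _g, _u, _d = simulate_de_counts(5, n_genes=150, n_per_group=10,
                                                direction="up")
        ours = tmm_normalize(counts).to_numpy()
        assert np.max(np.abs(ours - EDGER_TMM_FACTORS) / EDGER_TMM_FACTORS) < 0.01


class TestDifferentialExpression:
    def test_up_regulated_genes_recovered_with_correct_sign(self):
        counts, groups, up, _down = simulate_de_counts(13, n_genes=300,
                                                       n_per_group=50,
                                                       direction="up")
        kept = filter_low_expression(counts, groups)
        res = nb_differential_expression(counts.loc[kept], groups)
        hits = res.index[res["fdr"] < 0.05]
        found = hits.intersection(up)
        assert len(found) / len(up.intersection(kept)) >= 0.8
        assert (res.loc[found, "log2fc"] > 0).all()

    def test_permuted_labels_kill_discoveries(self):
        counts, groups, _u, _d = simulate_de_counts(17, n_genes=300, n_per_group=50)
        rng = np.random.default_rng(0)
        pooled = list(groups.low) + list(groups.high)
        perm = rng.permutation(pooled)
        permuted = StratifiedGroups("E", list(perm[:50]), list(perm[50:]), [],
                                    np.nan, np.nan, min_group=10)
        kept = filter_low_expression(counts, permuted)
        res = nb_differential_expression(counts.loc[kept], permuted)
        assert (res["fdr"] < 0.05).sum() <= 3

    def test_unanalyzable_groups_rejected(self):
        counts, groups, _u, _d = simulate_de_counts(19, n_genes=50, n_per_group=10)
        groups.min_group = 50
        with pytest.raises(ValueError):
            nb_differential_expression(counts, groups)

    def test_covariates_accepted(self):
        counts, groups, _u, _d = simulate_de_counts(23, n_genes=60, n_per_group=20)
        cov = pd.DataFrame({"sex": np.tile([0.0, 1.0], 20)},
                           index=groups.low + groups.high)
        res = nb_differential_expression(counts, groups, covariates=cov)
        assert res["p"].notna().sum() > 50


class TestOra:
    def test_matches_fisher_exact(self):
        from scipy.stats import fisher_exact

        universe = {f"g{i}" for i in range(100)}
        de = {f"g{i}" for i in range(10)}
        sets = {"S": {f"g{i}" for i in range(5)}}  # full overlap of 5
        res = ora_enrichment(de, universe, sets)
        _odds, p = fisher_exact([[5, 5], [0, 90]], alternative="greater")
        assert res.loc["S", "p"] == pytest.approx(p, rel=1e-9)

    def test_all_genes_de_gives_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        res = ora_enrichment(universe, universe, {"S": {"g1", "g2", "g3"}})
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_disjoint_set_not_enriched(self):
        universe = {f"g{i}" for i in range(100)}
        de = {f"g{i}" for i in range(10)}
        res = ora_enrichment(de, universe, {"S": {f"g{i}" for i in range(50, 60)}})
        assert res.loc["S", "p"] >= 0.5

    def test_de_must_be_subset_of_universe(self):
        with pytest.raises(ValueError):
            ora_enrichment({"x"}, {"y"}, {"S": {"y"}})


def _bruteforce_es(metric: pd.Series, members: set, weight=1.0):
    """Full running-sum reference implementation."""
    order = metric.sort_values(ascending=False)
    hit = order.index.isin(list(members))
    w = np.abs(order.to_numpy()) ** weight
    p_hit = np.cumsum(np.where(hit, w, 0.0)) / w[hit].sum()
    p_miss = np.cumsum(~hit) / (len(order) - hit.sum())
    running = p_hit - p_miss
    return running[np.argmax(np.abs(running))]


class TestGsea:
    METRIC = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.4, 0.3, 0.2, 0.1],
                       index=[f"g{i}" for i in range(1, 11)])

    def test_worked_example_matches_bruteforce(self):
        members = {"g2", "g5", "g8"}
        res = gsea(self.METRIC, {"S": members}, n_perm=50, seed=0)
        assert res.loc["S", "es"] == pytest.approx(
            _bruteforce_es(self.METRIC, members), abs=1e-12)

    def test_top_k_set_is_extremal(self):
        rng = np.random.default_rng(0)
        top = {"g1", "g2", "g3"}
        es_top = gsea(self.METRIC, {"S": top}, n_perm=10, seed=0).loc["S", "es"]
        genes = list(self.METRIC.index)
        for _ in range(50):
            other = set(rng.choice(genes, size=3, replace=False))
            es_other = gsea(self.METRIC, {"S": other}, n_perm=10, seed=0).loc["S", "es"]
            assert es_other <= es_top + 1e-12

    def test_es_antisymmetry_under_negation(self):
        members = {"g2", "g5", "g8"}
        pos = gsea(self.METRIC, {"S": members}, n_perm=200, seed=1)
        neg = gsea(-self.METRIC, {"S": members}, n_perm=200, seed=1)
        assert neg.loc["S", "es"] == pytest.approx(-pos.loc["S", "es"], abs=1e-12)
        # permutation p agrees in distribution (the null draws differ)
        assert neg.loc["S", "p"] == pytest.approx(pos.loc["S", "p"], abs=0.12)

    def test_es_bounds_and_reproducibility(self):
        rng = np.random.default_rng(2)
        metric = pd.Series(rng.normal(size=100), index=[f"x{i}" for i in range(100)])
        sets = {f"S{j}": set(rng.choice(metric.index, size=8, replace=False))
                for j in range(5)}
        r1 = gsea(metric, sets, n_perm=100, seed=3)
        r2 = gsea(metric, sets, n_perm=100, seed=3)
        assert ((r1["es"] >= -1) & (r1["es"] <= 1)).all()
        pd.testing.assert_frame_equal(r1, r2)

    def test_leading_edge_members_precede_extremum(self):
        members = {"g1", "g2", "g8"}
        res = gsea(self.METRIC, {"S": members}, n_perm=20, seed=0)
        leading = set(res.loc["S", "leading_edge"].split(","))
        assert leading <= members
        assert "g1" in leading

    def test_es_matches_gseapy_reference(self):
        """Independent cross-check of the running-sum ES against gseapy."""
        import gseapy

        rng = np.random.default_rng(5)
        metric = pd.Series(np.round(rng.normal(size=60), 3),
                           index=[f"y{i}" for i in range(60)])
        metric = metric[~metric.index.duplicated()]
        sets = {f"S{j}": list(rng.choice(metric.index, size=6, replace=False))
                for j in range(3)}
        ours = gsea(metric, {k: set(v) for k, v in sets.items()},
                    n_perm=20, seed=0, min_size=2)
        rnk = metric.reset_index()
        rnk.columns = ["gene", "score"]
        ref = gseapy.prerank(rnk=rnk, gene_sets=sets, min_size=2, max_size=50,
                             permutation_num=10, seed=1, outdir=None,
                             no_plot=True).res2d.set_index("Term")
        for name in sets:
            assert float(ref.loc[name, "ES"]) == pytest.approx(
                ours.loc[name, "es"], abs=1e-6)

    def test_small_sets_skipped(self):
        res = gsea(self.METRIC, {"tiny": {"g1"}}, n_perm=10, seed=0, min_size=3)
        assert len(res) == 0


def test_read_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("SET1\tdesc\tg1\tg2\tg3\nSET2\tdesc\tg4\tg5\n")
    sets = read_gmt(path)
    assert sets == {"SET1": {"g1", "g2", "g3"}, "SET2": {"g4", "g5"}}
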