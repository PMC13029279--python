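import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vigimech.network import build_graph, node_centrality
from vigimech.scoring import (
    adr_composite,
    build_drug_table,
    composite_raw,
    dps,
    dps_table,
    fit_rf_high_burden,
    label_high_burden,
    mvi_diagnostics,
    mvi_percentile,
    mvi_table,
)


@pytest.fixture(scope="module")
def drug_table(cases, pmap, admet, catalog):
    centrality = node_centrality(build_graph(cases))
    return build_drug_table(cases, pmap, centrality, admet, drugs=sorted(catalog))


class TestAdrComposite:
    @pytest.mark.parametrize("tr,nc,expected", [(10, 2, 20), (0, 7, 0), (3, 1, 3)])
    def test_product(self, tr, nc, expected):
        assert adr_composite(tr, nc) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            adr_composite([-1], [2])

    def test_cohort_table_matches_brute_force_recount(self, drug_table, cases, pmap):
        for drug in drug_table.index[:8]:
            sub = [c for c in cases if drug in c.suspect_actives]
            n_clusters = len({pmap(c.raw_cluster) for c in sub})
            expected = len(sub) * n_clusters
            got = adr_composite(
                drug_table.loc[drug, "total_reports"], drug_table.loc[drug, "n_clusters"]
            )
            assert got == expected


class TestHighBurden:
    def test_one_to_eight_labels_top_quarter(self):
        labels = label_high_burden(np.arange(1, 9))
        assert labels.sum() == 2 and labels[-2:].all()

    def test_all_equal_values_all_labelled(self):
        assert label_high_burden([4, 4, 4, 4, 4]).all()

    def test_strictly_increasing_hundred_with_interpolated_quantile(self):
        # Q0.75 of 1..100 by linear interpolation is 75.25, so the 25 values
        # 76..100 sit at or above it
        assert label_high_burden(np.arange(1, 101)).sum() == 25

    def test_fewer_than_four_drugs_rejected(self):
        with pytest.raises(ValueError):
            label_high_burden([1, 2, 3])


class TestCompositeRaw:
    def test_weight_read_off(self):
        assert composite_raw(1, 0, 0, 0) == pytest.approx(0.60)
        assert composite_raw(0, 1, 1, 1) == pytest.approx(0.40)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 20))
        w = np.array([0.6, 0.15, 0.15, 0.10])
        np.testing.assert_allclose(composite_raw(*x), w @ x, rtol=1e-12)

    @pytest.mark.parametrize("w", [(0.5, 0.2, 0.2, 0.2), (-0.1, 0.6, 0.3, 0.2)])
    def test_invalid_weights_rejected(self, w):
        with pytest.raises(ValueError):
            composite_raw(1, 0, 0, 0, weights=w)


class TestMviPercentile:
    def test_twenty_five_distinct_scores_reproduce_printed_grid(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=25)
        pct = mvi_percentile(scores)
        order = np.argsort(scores)[::-1]
        assert round(pct[order[0]], 1) == 100.0
        assert round(pct[order[1]], 1) == 95.8
        assert round(pct[order[2]], 1) == 91.7

    def test_consecutive_ranks_spaced_by_hundred_over_n_minus_one(self):
        pct = np.sort(mvi_percentile(np.arange(25)))
        np.testing.assert_allclose(np.diff(pct), 100 / 24)

    def test_tied_maxima_share_average_rank(self):
        np.testing.assert_allclose(mvi_percentile([5.0, 5.0, 1.0]), [75.0, 75.0, 0.0])

    def test_strictly_monotone_on_tie_free_input(self):
        rng = np.random.default_rng(1)
        s = rng.permutation(17).astype(float)
        pct = mvi_percentile(s)
        assert (np.argsort(pct) == np.argsort(s)).all()

    def test_single_drug_defined_as_hundred(self):
        np.testing.assert_allclose(mvi_percentile([3.2]), [100.0])


class TestRandomForest:
    def test_perfectly_separable_binary_feature_gives_oob_auc_one(self):
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame({"flag": y.astype(float)})
        rf = fit_rf_high_burden(X, y, seed=0, n_trees=300, exclude=())
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, rf.rf_prob) == pytest.approx(1.0)

    def test_permuted_labels_give_chance_level_auc(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
        y = rng.permutation([0] * 40 + [1] * 40)
        rf = fit_rf_high_burden(X, y, seed=0, n_trees=300, exclude=())
        from sklearn.metrics import roc_auc_score

        assert 0.25 <= roc_auc_score(y, rf.rf_prob) <= 0.75

    def test_label_constituents_excluded_by_default(self, drug_table):
        labels = label_high_burden(
            adr_composite(drug_table["total_reports"], drug_table["n_clusters"])
        )
        cols = [c for c in drug_table.columns if drug_table[c].dtype != object]
        rf = fit_rf_high_burden(drug_table[cols], labels, seed=0, n_trees=100)
        assert "total_reports" not in rf.features
        assert "n_clusters" not in rf.features
        rf_incl = fit_rf_high_burden(drug_table[cols], labels, seed=0, n_trees=100, exclude=())
        assert "total_reports" in rf_incl.features

    def test_single_class_labels_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            fit_rf_high_burden(X, [1, 1, 1, 1], seed=0)

    def test_median_imputation_fills_missing_predictors(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0, 4.0], "b": [0.0, 1.0, 0.0, 1.0]})
        rf = fit_rf_high_burden(X, [0, 1, 0, 1], seed=0, n_trees=50)
        assert not rf.X.isna().any().any()
        assert rf.X.loc[1, "a"] == 3.0  # column median


class TestMviTable:
    def test_full_table_invariants(self, drug_table):
        mvi, rf = mvi_table(drug_table, seed=0, n_trees=200)
        assert mvi["rf_prob"].between(0, 1).all()
        assert mvi["mvi_pct"].between(0, 100).all()
        assert (mvi["adr_composite"] == mvi["total_reports"] * mvi["n_clusters"]).all()
        assert mvi["mvi_pct"].iloc[0] == 100.0

    def test_row_order_invariance(self, drug_table):
        mvi1, _ = mvi_table(drug_table, seed=0, n_trees=100)
        shuffled = drug_table.sample(frac=1.0, random_state=4)
        mvi2, _ = mvi_table(shuffled, seed=0, n_trees=100)
        assert (mvi1["high_burden"].sort_index() == mvi2["high_burden"].sort_index()).all()
        assert (
            mvi1["adr_composite"].sort_index() == mvi2["adr_composite"].sort_index()
        ).all()

    def test_percentile_is_monotone_in_composite(self, drug_table):
        mvi, _ = mvi_table(drug_table, seed=0, n_trees=100)
        ranked = mvi.sort_values("composite_raw")
        assert ranked["mvi_pct"].is_monotonic_increasing


@pytest.fixture(scope="module")
def diag(drug_table):
    mvi, rf = mvi_table(drug_table, seed=0, n_trees=100)
    labels = mvi.loc[drug_table.index, "high_burden"]
    return mvi_diagnostics(
        drug_table[rf.features], labels, drug_table, seed=0, n_trees=100, B=40,
        alt_weights=(0.60, 0.15, 0.15, 0.10),
    )


class TestDiagnostics:

    def test_identical_weights_give_perfect_rank_agreement(self, diag):
        assert diag["weight_rank_stability"]["spearman"] == pytest.approx(1.0)
        assert diag["weight_rank_stability"]["kendall"] == pytest.approx(1.0)

    def test_diagnostic_ranges(self, diag):
        assert 0 <= diag["holdout_auc"] <= 1
        assert 0 <= diag["lodo_auc"] <= 1
        assert 0 <= diag["oob_error"] <= 1
        assert 0 <= diag["bootstrap_ci"]["median_width"] <= 1
        assert all(v >= 1 or np.isnan(v) for v in diag["vif"].values())

    def test_lodo_auc_on_separable_toy_set(self):
        y = np.array([0] * 8 + [1] * 8)
        X = pd.DataFrame({"flag": y.astype(float), "noise": np.r_[np.zeros(8), np.ones(8)]})
        table = pd.DataFrame(
            {
                "total_reports": np.arange(16) + 1,
                "n_clusters": 1,
                "mean_polypharmacy": y * 2.0 + 1,
                "mean_degree": np.arange(16.0),
                "mean_betweenness": np.linspace(0, 1, 16),
                "serious_frac": np.linspace(0.2, 0.9, 16),
            },
            index=[f"d{i}" for i in range(16)],
        )
        out = mvi_diagnostics(X, y, table, seed=0, n_trees=100, B=10, exclude=())
        assert out["lodo_auc"] == pytest.approx(1.0)

    def test_b_below_two_rejected(self, drug_table):
        with pytest.raises(ValueError):
            mvi_diagnostics(drug_table[["mean_degree"]], [0, 1] * (len(drug_table) // 2) +
                            [0] * (len(drug_table) % 2), drug_table, B=1)

    def test_rank_stability_under_small_weight_perturbations(self, drug_table):
        """Perturbing the composite weights by <= 0.05 (renormalised) leaves
        the drug ranking nearly unchanged."""
        rng = np.random.default_rng(12)
        base, _ = mvi_table(drug_table, seed=0, n_trees=100)
        passes = 0
        n_seeds = 20
        for _ in range(n_seeds):
            w = np.array([0.60, 0.15, 0.15, 0.10]) + rng.uniform(-0.05, 0.05, 4)
            w = np.clip(w, 0, None)
            w = w / w.sum()
            alt, _ = mvi_table(drug_table, seed=0, weights=tuple(w), n_trees=100)
            rho = stats.spearmanr(
                base["mvi_pct"].sort_index(), alt["mvi_pct"].sort_index()
            ).statistic
            passes += rho >= 0.9
        assert passes / n_seeds >= 0.95


class TestDps:
    FLAGS = pd.DataFrame(
        {
            "BSEP_inhibition": [1, 1, 0, 0],
            "Pgp_inhibition": [1, 1, 1, 0],
            "Pgp_substrate": [0, 0, 0, 0],
            "CYP3A4_inhibition": [0, 1, 0, 0],
        },
        index=["a", "b", "c", "d"],
    )

    def test_floor_regimen_scores_zero_and_low(self):
        rec = dps(
            ["c", "d"], self.FLAGS, degree={"c": 0, "d": 0},
            mvi_pct={"c": 0.0, "d": 0.0}, universe_degree_sums=[0.0, 50.0],
        )
        assert rec.mos == 0.0 and rec.svs == 0.0 and rec.dps == pytest.approx(rec.nas / 3)
        assert rec.tier == "3-low"

    def test_ceiling_regimen_scores_one_and_high(self):
        flags = pd.DataFrame(
            {"x": [1, 1], "y": [1, 1]}, index=["a", "b"]
        )
        rec = dps(
            ["a", "b"], flags, degree={"a": 50, "b": 60},
            mvi_pct={"a": 100.0, "b": 100.0}, universe_degree_sums=[10.0, 110.0],
        )
        assert rec.mos == 1.0 and rec.nas == 1.0 and rec.svs == 1.0
        assert rec.dps == pytest.approx(1.0) and rec.tier == "1-high"

    def test_two_of_four_shared_axes_gives_half_mos(self):
        rec = dps(
            ["a", "b"], self.FLAGS, degree={"a": 1, "b": 1},
            mvi_pct={"a": 50, "b": 50}, universe_degree_sums=[2.0, 2.0],
        )
        assert rec.mos == pytest.approx(0.5)

    def test_singleton_regimen_rejected(self):
        with pytest.raises(ValueError):
            dps(["a"], self.FLAGS, {}, {}, [1.0])

    def test_dps_table_tiers_and_convexity(self, drug_table, cases, admet, catalog):
        from vigimech.scoring import regimens_from_cases

        centrality = node_centrality(build_graph(cases))
        mvi, _ = mvi_table(drug_table, seed=0, n_trees=100)
        flags = admet.set_index("drug")[
            [c for c in admet.columns if c.endswith(("_inhibition", "_substrate"))]
        ]
        regimens = regimens_from_cases(cases, restrict_to=catalog)[:50]
        degree = dict(zip(centrality["drug"], centrality["degree"]))
        out = dps_table(regimens, flags, degree, dict(mvi["mvi_pct"]))
        assert out["dps"].between(0, 1).all()
        assert ((out[["mos", "nas", "svs"]].sum(axis=1) / 3 - out["dps"]).abs() < 1e-12).all()
        assert set(out["tier"]) <= {"1-high", "2-moderate", "3-low"}
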