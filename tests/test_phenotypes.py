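import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vigimech.icsr import CaseReport, expand_cases
from vigimech.phenotypes import (
    admet_signature,
    harmonise_phenotypes,
    icc_one_way,
    kw_panel,
    reaction_class_or,
    seriousness_by_phenotype,
)
from vigimech.synthetic import SynthConfig, generate_admet_table, generate_cohort, make_catalog


def _cases_with_clusters(freqs, n=1000, serious=None, reactions=("r",)):
    out = []
    i = 0
    for label, frac in freqs.items():
        for _ in range(round(frac * n)):
            out.append(
                CaseReport(
                    case_id=f"c{i}",
                    suspect_actives=frozenset({"d"}),
                    concomitant_actives=frozenset(),
                    reactions=tuple(reactions),
                    serious=bool(serious) if serious is not None else False,
                    raw_cluster=label,
                )
            )
            i += 1
    return out


class TestHarmonise:
    def test_labels_below_threshold_collapse_to_other(self):
        cases = _cases_with_clusters({"A": 0.5, "B": 0.3, "C": 0.15, "D": 0.04, "E": 0.01})
        pmap = harmonise_phenotypes(cases)
        assert pmap("E") == "Other"
        for label in "ABCD":
            assert pmap(label) == label

    def test_identity_when_all_labels_frequent(self):
        cases = _cases_with_clusters({"A": 0.6, "B": 0.4})
        pmap = harmonise_phenotypes(cases)
        assert set(pmap.mapping.values()) == {"A", "B"}

    def test_cohort_shaped_data_yields_five_phenotypes(self, cases, pmap):
        assert len(set(pmap.mapping.values())) == 5
        assert "Other" in set(pmap.mapping.values())

    def test_harmonisation_conserves_case_counts(self, cases, pmap):
        raw = pd.Series([c.raw_cluster for c in cases]).value_counts()
        harm = pd.Series([pmap(c.raw_cluster) for c in cases]).value_counts()
        assert raw.sum() == harm.sum() == len(cases)

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_outside_unit_interval_rejected(self, threshold):
        with pytest.raises(ValueError):
            harmonise_phenotypes(_cases_with_clusters({"A": 1.0}), threshold)


class TestSeriousness:
    def test_all_serious_phenotype_is_one(self):
        cases = _cases_with_clusters({"A": 1.0}, n=10, serious=True)
        pmap = harmonise_phenotypes(cases)
        out = seriousness_by_phenotype(cases, pmap)
        assert out.loc[0, "serious_frac"] == 1.0

    def test_three_of_four_serious(self):
        cases = _cases_with_clusters({"A": 1.0}, n=4)
        cases = [
            CaseReport(c.case_id, c.suspect_actives, c.concomitant_actives,
                       c.reactions, serious=(i < 3), raw_cluster="A")
            for i, c in enumerate(cases)
        ]
        pmap = harmonise_phenotypes(cases)
        assert seriousness_by_phenotype(cases, pmap).loc[0, "serious_frac"] == 0.75

    def test_small_phenotypes_flagged_unstable(self):
        cases = _cases_with_clusters({"A": 0.99, "B": 0.01}, n=100)
        pmap = harmonise_phenotypes(cases, threshold_frac=0.005)
        out = seriousness_by_phenotype(cases, pmap).set_index("phenotype")
        assert not out.loc["B", "stability_flag"]
        assert out.loc["A", "stability_flag"]


class TestSignature:
    def test_constant_feature_reported_as_zero_and_flagged(self):
        expanded = pd.DataFrame(
            {"case_id": ["1", "2"], "drug": ["d1", "d2"], "reaction": ["r", "r"],
             "cluster": ["A", "B"], "serious": [False, False]}
        )
        admet = pd.DataFrame({"drug": ["d1", "d2"], "ADMET_Risk": [2.0, 2.0]})
        pmap = harmonise_phenotypes(_cases_with_clusters({"A": 0.5, "B": 0.5}, n=10))
        sig = admet_signature(expanded, admet, pmap, features=["ADMET_Risk"])
        assert (sig.z["ADMET_Risk"] == 0).all()
        assert sig.constant_features == ["ADMET_Risk"]

    def test_two_phenotype_z_scores_use_sample_scaling(self):
        expanded = pd.DataFrame(
            {"case_id": ["1", "2"], "drug": ["d1", "d2"], "reaction": ["r", "r"],
             "cluster": ["A", "B"], "serious": [False, False]}
        )
        admet = pd.DataFrame({"drug": ["d1", "d2"], "ADMET_Risk": [1.0, 3.0]})
        pmap = harmonise_phenotypes(_cases_with_clusters({"A": 0.5, "B": 0.5}, n=10))
        sig = admet_signature(expanded, admet, pmap, features=["ADMET_Risk"])
        np.testing.assert_allclose(
            sorted(sig.z["ADMET_Risk"]), [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12
        )

    def test_planted_two_sigma_shift_attains_extreme_z(self):
        """A +2 sd BSEP IC50 shift planted for one phenotype must surface as
        that phenotype's maximal z in the signature matrix."""
        cfg = SynthConfig(
            n_cases=1200,
            seed=21,
            admet_shift_matrix={"C3": {"BSEP_IC50": 2.0}},
            admet_noise_sd=0.3,
            admet_missing_frac=0.0,
        )
        cases, _ = generate_cohort(cfg)
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[0])
        catalog = make_catalog(cfg, rng)
        admet = generate_admet_table(catalog, cfg.admet_shift_matrix, seed=22,
                                     noise_sd=0.3, missing_frac=0.0)
        pmap = harmonise_phenotypes(cases)
        sig = admet_signature(expand_cases(cases), admet, pmap)
        assert sig.z["BSEP_IC50"].idxmax() == "C3"


class TestKruskalWallis:
    def test_three_groups_match_brute_force_rank_arithmetic(self):
        values = [1.0, 3.0, 2.0, 5.0, 4.0, 9.0, 7.0, 8.0, 6.0]
        groups = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        ranks = stats.rankdata(values)
        n = len(values)
        h_brute = 12 / (n * (n + 1)) * sum(
            len([r for r, g in zip(ranks, groups) if g == k])
            * np.mean([r for r, g in zip(ranks, groups) if g == k]) ** 2
            for k in "abc"
        ) - 3 * (n + 1)
        expanded = pd.DataFrame(
            {"case_id": [str(i) for i in range(n)], "drug": [f"d{i}" for i in range(n)],
             "reaction": ["r"] * n, "cluster": groups, "serious": [False] * n}
        )
        admet = pd.DataFrame({"drug": [f"d{i}" for i in range(n)], "ADMET_Risk": values})
        pmap = harmonise_phenotypes(
            _cases_with_clusters({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}, n=9)
        )
        panel = kw_panel(expanded, admet, pmap, features=["ADMET_Risk"])
        np.testing.assert_allclose(panel.loc[0, "H"], h_brute, rtol=1e-12)

    def test_two_groups_equal_rank_sum_chi_square_form(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(size=15)
        h, _ = stats.kruskal(x, y)
        u = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        nx, ny = len(x), len(y)
        z = (u.statistic - nx * ny / 2) / np.sqrt(nx * ny * (nx + ny + 1) / 12)
        np.testing.assert_allclose(h, z**2, rtol=1e-10)

    def test_null_behaviour_q_at_least_p(self, cases, pmap, admet):
        panel = kw_panel(expand_cases(cases), admet, pmap)
        assert (panel["q"] >= panel["p"] - 1e-15).all()
        assert len(panel) >= 6


class TestICC:
    def test_zero_within_variance_gives_one(self):
        assert icc_one_way([1, 1, 5, 5, 9, 9], ["a", "a", "b", "b", "c", "c"]).icc == 1.0

    def test_equal_group_means_truncated_at_zero(self):
        out = icc_one_way([1, 3, 1, 3, 1, 3], ["a", "a", "b", "b", "c", "c"])
        assert out.icc == 0.0

    def test_balanced_toy_data_matches_hand_anova(self):
        # groups of 3: (1,2,3) and (3,4,5); grand mean 3
        # SSB = 3*(2-3)^2 + 3*(4-3)^2 = 6 -> MSB = 6
        # SSW = 2 + 2 = 4 -> MSW = 1; k0 = 3
        # ICC = (6-1)/(6+2*1) = 0.625
        out = icc_one_way([1, 2, 3, 3, 4, 5], ["a", "a", "a", "b", "b", "b"])
        np.testing.assert_allclose(out.icc, 0.625, rtol=1e-12)
        np.testing.assert_allclose(out.k0, 3.0)

    def test_all_identical_observations_flagged_degenerate(self):
        out = icc_one_way([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert out.icc == 0.0 and out.degenerate

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            icc_one_way([1, 2, 3], ["a", "a", "a"])

    def test_recovers_variance_ratio_on_simulated_groups(self):
        """The ICC(1) estimator is centred on the simulated variance ratio
        (single-draw sampling noise at 50x20 is ~0.04, so the check averages
        over replicate simulations)."""
        rng = np.random.default_rng(42)
        sb2, sw2 = 1.0, 3.0
        k, m = 50, 20
        groups = np.repeat(np.arange(k), m)
        iccs = []
        for _ in range(20):
            means = rng.normal(0, np.sqrt(sb2), size=k)
            values = (means[:, None] + rng.normal(0, np.sqrt(sw2), size=(k, m))).ravel()
            iccs.append(icc_one_way(values, groups).icc)
        assert abs(np.mean(iccs) - sb2 / (sb2 + sw2)) <= 0.05


class TestReactionClassOr:
    def _make(self, a, b, c, d, term="cholestasis"):
        cases = []
        i = 0
        for n, in_ph, has in [(a, True, True), (b, True, False), (c, False, True), (d, False, False)]:
            for _ in range(n):
                cases.append(
                    CaseReport(
                        case_id=f"x{i}",
                        suspect_actives=frozenset({"d"}),
                        concomitant_actives=frozenset(),
                        reactions=(term,) if has else ("nausea",),
                        serious=False,
                        raw_cluster="P" if in_ph else "Q",
                    )
                )
                i += 1
        pmap = harmonise_phenotypes(cases, threshold_frac=0.01)
        return cases, pmap

    def test_balanced_table_gives_unit_odds(self):
        cases, pmap = self._make(10, 10, 10, 10)
        assert reaction_class_or(cases, {"cholestasis"}, "P", pmap)["OR"] == pytest.approx(1.0)

    def test_cross_product_arithmetic(self):
        cases, pmap = self._make(20, 10, 5, 40)
        assert reaction_class_or(cases, {"cholestasis"}, "P", pmap)["OR"] == pytest.approx(16.0)

    def test_zero_cell_correction_keeps_or_finite(self):
        cases, pmap = self._make(5, 0, 5, 5)
        out = reaction_class_or(cases, {"cholestasis"}, "P", pmap)
        assert np.isfinite(out["OR"]) and out["corrected"]

    def test_empty_phenotype_rejected(self):
        cases, pmap = self._make(1, 1, 1, 1)
        with pytest.raises(ValueError):
            reaction_class_or(cases, {"cholestasis"}, "missing", pmap)

    def test_empty_term_set_rejected(self):
        cases, pmap = self._make(1, 1, 1, 1)
        with pytest.raises(ValueError):
            reaction_class_or(cases, set(), "P", pmap)
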