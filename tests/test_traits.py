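"""Trait screen and closed-form assay statistics against independent oracles."""

import itertools

import numpy as np
import pytest

import strigasoil as ss
from strigasoil.traits import DegenerateDesignError, TermStats


def closed_form_balanced_anova(values, soil, striga):
    """Independent oracle: textbook cell-mean SS decomposition, balanced 2x2."""
    values = np.asarray(values, float)
    soil = np.asarray(soil)
    striga = np.asarray(striga)
    soils, strigas = sorted(set(soil)), sorted(set(striga))
    r = len(values) / 4.0
    grand = values.mean()
    mean_a = {a: values[soil == a].mean() for a in soils}
    mean_b = {b: values[striga == b].mean() for b in strigas}
    mean_ab = {
        (a, b): values[(soil == a) & (striga == b)].mean()
        for a in soils for b in strigas
    }
    ss_a = 2 * r * sum((mean_a[a] - grand) ** 2 for a in soils)
    ss_b = 2 * r * sum((mean_b[b] - grand) ** 2 for b in strigas)
    ss_ab = r * sum(
        (mean_ab[a, b] - mean_a[a] - mean_b[b] + grand) ** 2
        for a in soils for b in strigas
    )
    ss_total = ((values - grand) ** 2).sum()
    ss_resid = ss_total - ss_a - ss_b - ss_ab
    df_resid = len(values) - 4
    out = {}
    for name, ss_term in [("soil", ss_a), ("striga", ss_b), ("interaction", ss_ab)]:
        f = (ss_term / 1) / (ss_resid / df_resid)
        import scipy.stats as st

        out[name] = (ss_term, f, st.f.sf(f, 1, df_resid))
    return out, ss_resid, df_resid


BALANCED_DATA = (
    [10.1, 12.3, 11.7, 20.4, 22.1, 19.8, 14.2, 15.9, 13.8, 25.3, 24.1, 26.7],
    ["natural"] * 3 + ["sterilized"] * 3 + ["natural"] * 3 + ["sterilized"] * 3,
    ["control"] * 6 + ["infected"] * 6,
)


class TestTwoWayAnova:
    def test_matches_closed_form_oracle_to_1e10(self):
        values, soil, striga = BALANCED_DATA
        res = ss.two_way_anova(values, soil, striga)
        oracle, ss_resid, df_resid = closed_form_balanced_anova(values, soil, striga)
        for term, (ss_term, f, p) in oracle.items():
            assert res.terms[term].ss == pytest.approx(ss_term, abs=1e-10)
            assert res.terms[term].f == pytest.approx(f, abs=1e-10)
            assert res.terms[term].p == pytest.approx(p, abs=1e-10)
        assert res.residual_ss == pytest.approx(ss_resid, abs=1e-10)
        assert res.residual_df == df_resid
        assert res.ss_type == 1

    def test_location_shift_leaves_f_and_p_unchanged(self):
        values, soil, striga = BALANCED_DATA
        base = ss.two_way_anova(values, soil, striga)
        shifted = ss.two_way_anova([v + 137.5 for v in values], soil, striga)
        for term in base.terms:
            assert shifted.terms[term].f == pytest.approx(base.terms[term].f, rel=1e-9)
            assert shifted.terms[term].p == pytest.approx(base.terms[term].p, rel=1e-9)

    def test_pure_soil_effect_has_zero_striga_and_interaction_f(self):
        # identical values across striga levels within each soil
        values = [10, 12, 20, 22, 10, 12, 20, 22]
        soil = ["natural", "natural", "sterilized", "sterilized"] * 2
        striga = ["control"] * 4 + ["infected"] * 4
        res = ss.two_way_anova(values, soil, striga)
        assert res.terms["striga"].f == pytest.approx(0.0, abs=1e-12)
        assert res.terms["interaction"].f == pytest.approx(0.0, abs=1e-12)
        assert res.terms["soil"].p < 0.01

    def test_ss_decomposition_adds_to_total(self):
        values, soil, striga = BALANCED_DATA
        res = ss.two_way_anova(values, soil, striga)
        total = sum(t.ss for t in res.terms.values()) + res.residual_ss
        assert total == pytest.approx(np.var(values) * len(values), rel=1e-10)

    def test_sample_order_permutation_invariance(self):
        values, soil, striga = BALANCED_DATA
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(values))
        res_a = ss.two_way_anova(values, soil, striga)
        res_b = ss.two_way_anova(
            [values[i] for i in perm], [soil[i] for i in perm], [striga[i] for i in perm]
        )
        for term in res_a.terms:
            assert res_b.terms[term].f == pytest.approx(res_a.terms[term].f, rel=1e-9)

    def test_unbalanced_design_uses_type_two(self):
        values, soil, striga = BALANCED_DATA
        res = ss.two_way_anova(values + [11.0], soil + ["natural"], striga + ["control"])
        assert res.ss_type == 2

    def test_empty_cell_falls_back_to_main_effects(self):
        values = [1.0, 2.0, 3.0, 4.0, 2.5, 3.5, 1.5, 2.9, 3.3]
        soil = ["natural"] * 3 + ["sterilized"] * 6
        striga = ["control"] * 3 + ["control"] * 3 + ["infected"] * 3
        with pytest.warns(UserWarning, match="main-effects-only"):
            res = ss.two_way_anova(values, soil, striga)
        assert res.main_effects_only
        assert "interaction" not in res.terms

    def test_degenerate_designs_raise(self):
        with pytest.raises(DegenerateDesignError, match="cells"):
            ss.two_way_anova([1, 2, 3], ["natural"] * 3, ["control"] * 3)
        constant = [5.0] * 12
        with pytest.raises(DegenerateDesignError, match="degenerate"):
            ss.two_way_anova(constant, BALANCED_DATA[1], BALANCED_DATA[2])


@pytest.mark.parametrize(
    "p_soil, p_striga, p_inter, expected",
    [
        (0.01, 0.8, 0.9, "soil_only"),
        (0.01, 0.2, 0.01, "interaction"),
        (0.9, 0.9, 0.9, "none"),
        (0.2, 0.01, 0.9, "striga_only"),
        (0.01, 0.01, 0.9, "soil_only"),  # soil significant, no interaction
    ],
)
def test_classify_trait_labels(p_soil, p_striga, p_inter, expected):
    res = ss.AnovaResult(
        terms={
            "soil": TermStats(1.0, 1, 1.0, p_soil),
            "striga": TermStats(1.0, 1, 1.0, p_striga),
            "interaction": TermStats(1.0, 1, 1.0, p_inter),
        },
        residual_ss=1.0,
        residual_df=8,
        n=12,
        ss_type=1,
    )
    assert ss.classify_trait(res).label == expected


class TestShannon:
    @pytest.mark.parametrize(
        "counts, expected",
        [([10, 10, 10, 10], np.log(4)), ([42], 0.0), ([5, 3, 2], 1.02965301406457)],
    )
    def test_known_values(self, counts, expected):
        assert ss.shannon_diversity(counts) == pytest.approx(expected, abs=1e-10)

    def test_uniform_maximizes_entropy(self):
        rng = np.random.default_rng(1)
        uniform = ss.shannon_diversity([7] * 8)
        for _ in range(20):
            counts = rng.integers(1, 100, 8)
            assert ss.shannon_diversity(counts) <= uniform + 1e-12

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            ss.shannon_diversity([0, 0])


class TestWelch:
    def test_identical_groups(self):
        t, df, p = ss.welch_t_test([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_example(self):
        t, df, p = ss.welch_t_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(-1.0954451150103321, abs=1e-10)
        assert df == pytest.approx(6.0, abs=1e-10)

    def test_matches_scipy(self):
        import scipy.stats as st

        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 2, 14)
        t, df, p = ss.welch_t_test(x, y)
        ref = st.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_scale_invariance_of_t(self):
        x, y = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0]
        t1, _, _ = ss.welch_t_test(x, y)
        t2, _, _ = ss.welch_t_test([2 * v for v in x], [2 * v for v in y])
        assert t2 == pytest.approx(t1, rel=1e-12)

    def test_zero_variance_unequal_means_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            ss.welch_t_test([1, 1], [2, 2])


class TestHypergeometricEnrichment:
    def brute_force(self, k, big_k, n, big_n):
        universe = range(big_n)
        category = set(range(big_k))
        total = hits = 0
        for draw in itertools.combinations(universe, n):
            total += 1
            hits += len(category.intersection(draw)) >= k
        return hits / total

    def test_textbook_example(self):
        assert ss.hypergeometric_enrichment(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-12)

    @pytest.mark.parametrize(
        "k, big_k, n, big_n", [(2, 4, 5, 11), (0, 3, 4, 9), (3, 3, 3, 3), (1, 6, 2, 12)]
    )
    def test_matches_enumeration(self, k, big_k, n, big_n):
        expected = self.brute_force(k, big_k, n, big_n)
        assert ss.hypergeometric_enrichment(k, big_k, n, big_n) == pytest.approx(
            expected, abs=1e-12
        )

    def test_edge_cases(self):
        assert ss.hypergeometric_enrichment(0, 5, 4, 10) == 1.0
        assert ss.hypergeometric_enrichment(4, 4, 4, 4) == 1.0
        with pytest.raises(ValueError):
            ss.hypergeometric_enrichment(5, 4, 4, 10)


class TestAssayFormulas:
    def test_germination_rate(self):
        assert ss.germination_rate(ss.SeedCounts(100, 50)) == 50.0

    def test_haustorium_rate(self):
        assert ss.haustorium_rate(ss.SeedCounts(20, 10, 7)) == 70.0
        assert ss.haustorium_rate(ss.SeedCounts(20, 10, 0)) == 0.0
        with pytest.warns(UserWarning):
            assert ss.haustorium_rate(ss.SeedCounts(20, 0, 0)) is None

    def test_seed_count_ordering_enforced(self):
        with pytest.raises(ValueError):
            ss.SeedCounts(10, 12, 0)

    def test_porosity_worked_example(self):
        w = ss.PycnometerWeights(
            pycnometer_water=150, with_roots=155, vacuum_infiltrated=157, root_mass=10
        )
        assert ss.root_porosity(w) == pytest.approx(0.40, abs=1e-12)

    def test_porosity_zero_and_negative(self):
        w = ss.PycnometerWeights(150, 155, 155, 10)
        assert ss.root_porosity(w) == 0.0
        with pytest.warns(UserWarning, match="negative"):
            assert ss.root_porosity(ss.PycnometerWeights(150, 155, 154, 10)) < 0

    def test_suberin_odds_ratio(self):
        treated = ss.SuberinCounts(n_fully_suberized=8, n_total=10)
        mock = ss.SuberinCounts(n_fully_suberized=2, n_total=10)
        odds, p = ss.suberin_odds_ratio(treated, mock)
        assert odds == pytest.approx(16.0, abs=1e-12)
        assert 0 < p < 0.05
        same, _ = ss.suberin_odds_ratio(treated, treated)
        assert same == 1.0
        finite, _ = ss.suberin_odds_ratio(
            ss.SuberinCounts(n_fully_suberized=10, n_total=10), mock
        )
        assert np.isfinite(finite)


def test_screen_traits_forwards_soil_only(small_bundle):
    _, _, traits, _ = small_bundle
    screen = ss.screen_traits(traits)
    assert {"trait", "timepoint", "label"}.issubset(screen.columns)
    # the generator plants strong soil effects on aerenchyma at both timepoints
    labels = screen.set_index(["trait", "timepoint"])["label"]
    assert labels[("aerenchyma", "2wpi")] == "soil_only"
    from strigasoil.traits import soil_only_traits

    assert "aerenchyma" in soil_only_traits(screen, "2wpi")
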