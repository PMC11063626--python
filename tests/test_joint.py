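"""Design coding, CLR, taxa filtering, and Gibbs sampler correctness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

import strigasoil as ss
from strigasoil.joint import McmcSettings, Prior, build_design, gibbs_fit


def _metadata(rows):
    frame = pd.DataFrame(rows, columns=["soil", "striga"])
    frame.index = [f"s{i}" for i in range(len(frame))]
    return frame


class TestBuildDesign:
    @pytest.mark.parametrize(
        "soil, striga, expected",
        [
            ("sterilized", "control", [1, 0, 0, 0]),
            ("natural", "control", [1, 1, 0, 0]),
            ("sterilized", "infected", [1, 0, 1, 0]),
            ("natural", "infected", [1, 1, 1, 1]),
        ],
    )
    def test_treatment_coding(self, soil, striga, expected):
        design = build_design(_metadata([(soil, striga)]))
        assert design.x.iloc[0].tolist() == expected

    def test_full_factorial_has_rank_four(self):
        meta = _metadata(
            [(s, t) for s in ("natural", "sterilized") for t in ("infected", "control")]
        )
        assert np.linalg.matrix_rank(build_design(meta).values) == 4

    def test_unknown_level_raises(self):
        with pytest.raises(ValueError, match="unknown factor"):
            build_design(_metadata([("loamy", "control")]))


class TestClr:
    def test_equal_counts_map_to_zero(self):
        out = ss.clr_transform(np.array([7, 7, 7, 7]))
        assert np.allclose(out, 0.0)

    def test_hand_computed_pair(self):
        out = ss.clr_transform(np.array([3, 1]), pseudocount=0.5)
        expected = np.log(3.5 / np.sqrt(3.5 * 1.5))
        assert out[0] == pytest.approx(expected, abs=1e-12)
        assert out[1] == pytest.approx(-expected, abs=1e-12)

    @given(
        hst.lists(hst.integers(min_value=0, max_value=10_000), min_size=2, max_size=30)
    )
    def test_rows_sum_to_zero(self, counts):
        out = ss.clr_transform(np.array(counts, dtype=float))
        assert abs(out.sum()) < 1e-9

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            ss.clr_transform(np.array([1, 2]), pseudocount=0.0)


class TestFilterTaxa:
    def _table(self, counts):
        frame = pd.DataFrame(counts)
        frame.index = [f"s{i}" for i in range(len(frame))]
        meta = pd.DataFrame(
            {
                "soil": "natural",
                "striga": "control",
                "timepoint": "2wpi",
                "sub_category": "bulk_soil",
                "replicate": range(1, len(frame) + 1),
            },
            index=frame.index,
        )
        taxonomy = pd.DataFrame(index=frame.columns)
        return ss.TaxaCountTable(counts=frame, metadata=meta, taxonomy=taxonomy)

    def test_identity_when_thresholds_are_loose(self):
        table = self._table({"t1": [1, 2], "t2": [3, 0]})
        out = ss.filter_taxa(table, min_prevalence=0.0, max_taxa=10)
        assert out.counts.equals(table.counts)

    def test_low_prevalence_taxon_removed(self):
        counts = {"rare": [5] + [0] * 9, "common": [3] * 10}
        out = ss.filter_taxa(self._table(counts), min_prevalence=0.25, max_taxa=10)
        assert out.taxa == ["common"]

    def test_abundance_tie_breaks_lexicographically(self):
        counts = {"b": [5, 5], "a": [5, 5], "c": [50, 50]}
        out = ss.filter_taxa(self._table(counts), min_prevalence=0.0, max_taxa=2)
        assert sorted(out.taxa) == ["a", "c"]

    def test_empty_result_raises(self):
        with pytest.raises(ValueError, match="prevalence"):
            ss.filter_taxa(self._table({"t": [0, 0]}), min_prevalence=0.5)


def _intercept_only_fit(r, n=200, seed=0, mcmc=None):
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, r], [r, 1.0]])
    y = rng.multivariate_normal([0, 0], cov, size=n)
    y = pd.DataFrame(y, columns=["a", "b"])
    x = pd.DataFrame({"intercept": np.ones(n)})
    return y, gibbs_fit(y, x, mcmc=mcmc or McmcSettings(n_iter=3000, burn_in=1000, seed=seed))


class TestGibbsFit:
    def test_recovers_sample_correlation_intercept_only(self, fast_mcmc):
        y, fit = _intercept_only_fit(0.55, seed=4, mcmc=fast_mcmc)
        observed = np.corrcoef(y.to_numpy().T)[0, 1]
        assert fit.resid_corr.loc["a", "b"] == pytest.approx(observed, abs=0.05)

    def test_independent_columns_give_near_zero_residual_corr(self):
        """Sigma = I null, n = 200, 10 seeds: no systematic residual
        association.  The sampling sd of a null correlation at n = 200 is
        ~0.07, so individual entries can stray beyond 0.15 by chance; the
        bulk (95%) must stay within that band and the mean near zero."""
        entries = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
            x = pd.DataFrame({"intercept": np.ones(200)})
            fit = gibbs_fit(
                y, x, mcmc=McmcSettings(n_iter=1200, burn_in=400, thin=2, seed=seed)
            )
            entries.extend(fit.resid_corr.to_numpy()[np.triu_indices(4, 1)])
        entries = np.abs(entries)
        assert np.quantile(entries, 0.95) < 0.15
        assert entries.mean() < 0.07

    def test_vague_prior_posterior_mean_matches_least_squares(self, small_bundle):
        _, taxa, traits, _ = small_bundle
        sub = taxa.subset("rhizosphere", "2wpi")
        clr = ss.clr_transform(sub.counts)
        y = pd.concat(
            [clr.iloc[:, :5], traits.subset("rhizosphere", "2wpi").values[["aerenchyma"]]],
            axis=1,
        )
        x = build_design(sub.metadata)
        fit = gibbs_fit(
            y, x, prior=Prior(tau=1e-8),
            mcmc=McmcSettings(n_iter=4000, burn_in=1000, seed=9),
        )
        lstsq = np.linalg.lstsq(x.values, y.to_numpy(), rcond=None)[0]
        assert np.abs(fit.posterior_mean_b.to_numpy() - lstsq).max() < 0.35

    def test_identical_seed_reproduces_chain(self, fast_mcmc):
        _, fit1 = _intercept_only_fit(0.3, n=60, seed=2, mcmc=fast_mcmc)
        _, fit2 = _intercept_only_fit(0.3, n=60, seed=2, mcmc=fast_mcmc)
        assert np.array_equal(fit1.sigma_draws, fit2.sigma_draws)
        assert np.array_equal(fit1.b_draws, fit2.b_draws)

    def test_every_retained_sigma_draw_is_spd(self, fast_mcmc):
        _, fit = _intercept_only_fit(0.4, n=80, seed=6, mcmc=fast_mcmc)
        for sigma in fit.sigma_draws[::25]:
            assert np.allclose(sigma, sigma.T)
            np.linalg.cholesky(sigma)

    def test_too_few_samples_raises(self):
        y = pd.DataFrame(np.random.default_rng(0).standard_normal((3, 2)), columns=["a", "b"])
        x = pd.DataFrame(np.ones((3, 4)), columns=list("wxyz"))
        with pytest.raises(ValueError, match="filter taxa"):
            gibbs_fit(y, x)


class TestResidualCorrelations:
    def test_unit_diagonal_and_symmetry(self, fast_mcmc):
        _, fit = _intercept_only_fit(0.2, n=80, seed=1, mcmc=fast_mcmc)
        rc = fit.resid_corr
        assert np.allclose(np.diag(rc), 1.0)
        assert rc.equals(rc.T)

    def test_matches_plain_residual_correlation_under_vague_prior(self, small_bundle):
        _, taxa, traits, _ = small_bundle
        sub = taxa.subset("rhizosphere", "3wpi")
        clr = ss.clr_transform(sub.counts).iloc[:, :6]
        y = pd.concat(
            [clr, traits.subset("rhizosphere", "3wpi").values[["suberin"]]], axis=1
        )
        x = build_design(sub.metadata)
        fit = gibbs_fit(
            y, x, prior=Prior(tau=1e-8),
            mcmc=McmcSettings(n_iter=4000, burn_in=1000, seed=3),
        )
        beta = np.linalg.lstsq(x.values, y.to_numpy(), rcond=None)[0]
        resid = y.to_numpy() - x.values @ beta
        oracle = np.corrcoef(resid.T)
        # prior shrinkage at n = 16 loosens agreement slightly beyond MC error
        assert np.abs(fit.resid_corr.to_numpy() - oracle).max() < 0.12

    def test_requires_enough_draws(self):
        _, fit = _intercept_only_fit(
            0.1, n=50, seed=0, mcmc=McmcSettings(n_iter=120, burn_in=40, thin=1, seed=0)
        )
        with pytest.raises(ValueError, match="100"):
            ss.residual_correlations(fit)


class TestContrasts:
    def _planted_fit(self, soil_effect, seed=0, n=200):
        rng = np.random.default_rng(seed)
        half = n // 4
        meta = pd.DataFrame(
            {
                "soil": ["natural"] * (2 * half) + ["sterilized"] * (2 * half),
                "striga": (["infected"] * half + ["control"] * half) * 2,
            },
            index=[f"s{i}" for i in range(4 * half)],
        )
        x = build_design(meta)
        b = np.array([[0.0, 0.0], [soil_effect, 0.0], [1.0, 0.5], [0.0, 0.0]])
        y = pd.DataFrame(
            x.values @ b + rng.standard_normal((4 * half, 2)), columns=["trait", "other"],
            index=meta.index,
        )
        return gibbs_fit(y, x, mcmc=McmcSettings(n_iter=2500, burn_in=500, seed=seed))

    def test_h1_in_sterilized_equals_striga_coefficient_draws(self):
        fit = self._planted_fit(1.0, seed=5, n=80)
        contrasts = ss.contrast_h1_h2(fit)
        h1 = contrasts.query("contrast == 'h1_striga_in_sterilized' and response == 'trait'")
        idx = fit.design_columns.index("striga_infected")
        j = fit.responses.index("trait")
        assert h1["mean"].iloc[0] == pytest.approx(fit.b_draws[:, idx, j].mean(), abs=1e-12)

    def test_recovers_planted_soil_effect(self):
        fit = self._planted_fit(2.0, seed=7)
        contrasts = ss.contrast_h1_h2(fit)
        h2 = contrasts.query("contrast == 'h2_soil_in_control' and response == 'trait'")
        assert h2["mean"].iloc[0] == pytest.approx(2.0, abs=0.3)
        assert h2["ci_lower"].iloc[0] <= h2["mean"].iloc[0] <= h2["ci_upper"].iloc[0]

    def test_null_soil_effect_covered_by_credible_intervals(self):
        covered = total = 0
        for seed in range(5):
            fit = self._planted_fit(0.0, seed=seed, n=120)
            contrasts = ss.contrast_h1_h2(fit)
            h2 = contrasts[contrasts["contrast"].str.startswith("h2")]
            covered += ((h2["ci_lower"] <= 0) & (h2["ci_upper"] >= 0)).sum()
            total += len(h2)
        assert covered / total >= 0.9
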