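"""Transforms, robust regression, FDR, selection and descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uwmc.simulate import CohortConfig, make_cohort
from uwmc.stats import (
    DEFAULT_COVARIATES,
    CognitionAnalysis,
    FdrDecision,
    SelectionConfig,
    bh_fdr,
    conditional_interaction,
    describe_groups,
    huber_regression,
    load_reference_associations,
    log_transform,
    median_split,
    per_percent_effect,
    spearman_validation,
    stability_select,
)


class TestLogTransform:
    def test_reference_points(self):
        assert log_transform(1.0) == 0.0
        assert log_transform(np.e) == pytest.approx(1.0)
        assert log_transform(0.0) == pytest.approx(np.log(0.05))

    def test_vectorised_with_zero_substitution(self):
        out = log_transform(np.array([0.0, 0.05, 1.0]))
        assert out[0] == out[1] == pytest.approx(np.log(0.05))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(-0.1)


class TestPerPercentEffect:
    @pytest.mark.parametrize(
        "beta,expected",
        [(-3.03, -0.030), (0.0, 0.0), (-2.26, -0.023), (-1.84, -0.018)],
    )
    def test_reported_scaling(self, beta, expected):
        assert round(per_percent_effect(beta), 3) == expected

    @given(st.floats(-100, 100, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linear_and_sign_preserving(self, beta):
        assert per_percent_effect(beta) == beta / 100.0
        assert np.sign(per_percent_effect(beta)) == np.sign(beta)


def _brute_force_bh(p, q):
    """Literal step-up definition, independent of statsmodels."""
    m = len(p)
    order = np.argsort(p)
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


class TestBhFdr:
    def test_published_full_sample_families(self):
        # the printed full-sample p-value columns of the amyloid (18 tests)
        # and tau (8 tests) analyses
        ab = load_reference_associations("abeta")
        tau = load_reference_associations("tau")
        dec_ab = bh_fdr(dict(enumerate(ab["p_full"])), q=0.05)
        dec_tau = bh_fdr(dict(enumerate(tau["p_full"])), q=0.05)
        assert len(dec_ab.rejected) == 17
        assert len(dec_tau.rejected) == 5

    def test_all_small_p_all_rejected(self):
        dec = bh_fdr({i: 0.001 for i in range(10)})
        assert len(dec.rejected) == 10

    def test_empty_input(self):
        dec = bh_fdr({})
        assert dec.rejected == set() and dec.adjusted_p == {}

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            q = rng.choice([0.01, 0.05, 0.1])
            dec = bh_fdr(dict(enumerate(p)), q=q)
            expected = _brute_force_bh(p, q)
            assert dec.rejected == set(np.nonzero(expected)[0])

    def test_rejections_monotone_in_q(self):
        rng = np.random.default_rng(1)
        p = dict(enumerate(rng.random(25)))
        sizes = [len(bh_fdr(p, q=q).rejected) for q in (0.01, 0.05, 0.1, 0.2)]
        assert sizes == sorted(sizes)


def _clean_cohort(n=120, beta=2.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age": rng.uniform(50, 89, n),
            "sex": rng.binomial(1, 0.5, n),
            "group": rng.binomial(1, 0.5, n),
            "education": rng.normal(14, 2, n),
            "physical_activity": rng.normal(2, 0.5, n),
            "diabetes": rng.binomial(1, 0.2, n),
            "hypertension": rng.binomial(1, 0.4, n),
            "high_cholesterol": rng.binomial(1, 0.3, n),
            "apoe4": rng.binomial(1, 0.3, n),
            "x": rng.normal(-2, 0.8, n),
        }
    )
    df["moca"] = (
        26.0
        + beta * df["x"]
        - 0.05 * df["age"]
        + 0.2 * df["education"]
        + noise * rng.standard_normal(n)
    )
    return df


class TestHuberRegression:
    def test_noiseless_fit_is_exact(self):
        df = _clean_cohort(noise=0.0)
        res = huber_regression(df, "x", "full")
        assert res.beta == pytest.approx(2.0, abs=1e-8)
        assert res.per_percent == res.beta / 100.0

    def test_gaussian_noise_recovery_within_3_se(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = _clean_cohort(n=200, beta=-1.5, noise=1.0, seed=seed)
            res = huber_regression(df, "x", "full")
            hits += abs(res.beta - (-1.5)) <= 3 * res.se
        assert hits >= 9

    def test_reduces_to_ols_when_no_residual_exceeds_threshold(self):
        # bounded bimodal residuals: MAD-based scale puts the Huber corner
        # at ~2 MAD, every weight is 1, and the fit equals least squares
        n = 60
        df = _clean_cohort(n=n, noise=0.0, seed=2)
        signs = np.tile([1.0, -1.0], n // 2)
        df["moca"] = df["moca"] + 0.5 * signs
        X = np.column_stack(
            [np.ones(n), df["x"]]
            + [df[c].to_numpy(float) for c in DEFAULT_COVARIATES]
        )
        y = df["moca"].to_numpy()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ ols
        scale = np.median(np.abs(r - np.median(r))) / 0.6745
        assert np.abs(r).max() / scale <= 1.345  # precondition of the property
        res = huber_regression(df, "x", "full")
        assert res.beta == pytest.approx(ols[1], abs=1e-8)

    def test_huber_beats_ols_in_bias_under_gross_contamination(self):
        # +15-point contamination on the 10% of participants with the
        # largest predictor value: induces real slope bias in least
        # squares that the bounded psi resists; paired draws
        hub_est, ols_est = [], []
        for seed in range(8):
            df = _clean_cohort(n=200, beta=-1.5, noise=1.0, seed=200 + seed)
            cut = df["x"].quantile(0.9)
            df.loc[df["x"] >= cut, "moca"] += 15.0
            hub_est.append(huber_regression(df, "x", "full").beta)
            X = np.column_stack(
                [np.ones(len(df)), df["x"]]
                + [df[c].to_numpy(float) for c in DEFAULT_COVARIATES]
            )
            ols_est.append(
                np.linalg.lstsq(X, df["moca"].to_numpy(), rcond=None)[0][1]
            )
        hub_bias = abs(np.mean(hub_est) - (-1.5))
        ols_bias = abs(np.mean(ols_est) - (-1.5))
        assert hub_bias < ols_bias

    def test_strata_drop_group_covariate_and_interaction_rules(self):
        df = _clean_cohort(n=150, noise=0.5, seed=5)
        full = huber_regression(df, "x", "full")
        ba = huber_regression(df, "x", "BA")
        nhw = huber_regression(df, "x", "nHW")
        assert ba.n + nhw.n == full.n
        inter = huber_regression(df, "x", "full", with_interaction=True)
        assert inter.stratum == "interaction"
        with pytest.raises(ValueError):
            huber_regression(df, "x", "BA", with_interaction=True)

    def test_tiny_stratum_raises(self):
        df = _clean_cohort(n=30, seed=6)
        df["group"] = 0
        df.loc[df.index[:3], "group"] = 1
        with pytest.raises(ValueError, match="few"):
            huber_regression(df, "x", "BA")


class TestConditionalInteraction:
    def _fdr(self, rejected):
        return FdrDecision(q=0.05, rejected=set(rejected), adjusted_p={})

    def test_fitted_only_when_exactly_one_stratum_significant(self):
        df = _clean_cohort(n=150, noise=0.5, seed=7)
        one = conditional_interaction(df, "x", self._fdr(["x"]), self._fdr([]))
        assert one is not None and one.stratum == "interaction"
        other = conditional_interaction(df, "x", self._fdr([]), self._fdr(["x"]))
        assert other is not None
        assert conditional_interaction(df, "x", self._fdr(["x"]), self._fdr(["x"])) is None
        assert conditional_interaction(df, "x", self._fdr([]), self._fdr([])) is None


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([0.1, 0.2, 0.5, 0.9])
        assert spearman_validation(x, x**2)[0] == pytest.approx(1.0)
        assert spearman_validation(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_validation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_lesioned_phantom_cohort_correlates_uwmc_with_volume(self):
        # cohort of synthetic subjects where lesion burden drives both
        # lobar UWMC and lobar WMH volume
        rng = np.random.default_rng(11)
        n = 40
        burden = rng.gamma(2.0, 1.0, n)
        lobar_uwmc_vals = burden / (burden + 4.0) + rng.normal(0, 0.02, n)
        lobar_wmh = burden * 500 + rng.normal(0, 100, n)
        rho, p = spearman_validation(lobar_uwmc_vals, lobar_wmh)
        assert rho > 0.7
        assert p < 0.001


class TestDescribeGroups:
    def test_identical_groups_exact_p_one(self):
        half = _clean_cohort(n=40, seed=8)
        half["group"] = 0
        mirror = half.copy()
        mirror["group"] = 1
        df = pd.concat([half, mirror], ignore_index=True)
        df["global_uwmc"] = 0.1
        table = describe_groups(df, "racialized_group")
        exact = table[table["test"] == "fisher"]
        assert (exact["p"] == 1.0).all()

    def test_median_value_assigned_high(self):
        assert median_split([1.0, 2.0, 3.0]).tolist() == [False, True, True]

    def test_fisher_and_chisquare_match_enumeration_oracle(self):
        from math import comb

        # 2x2 table (20,5; 5,20)
        a, b, c, d = 20, 5, 5, 20
        from scipy import stats as sps

        fisher_p = sps.fisher_exact([[a, b], [c, d]])[1]
        # exact enumeration of the hypergeometric tail
        row1, row2, col1 = a + b, c + d, a + c
        ntot = row1 + row2

        def prob(x):
            return comb(row1, x) * comb(row2, col1 - x) / comb(ntot, col1)

        p0 = prob(a)
        enum_p = sum(
            prob(x)
            for x in range(max(0, col1 - row2), min(row1, col1) + 1)
            if prob(x) <= p0 * (1 + 1e-9)
        )
        assert fisher_p == pytest.approx(enum_p, abs=1e-6)
        chi_p = sps.chi2_contingency([[a, b], [c, d]], correction=False)[1]
        # textbook chi-square: X2 = n(ad-bc)^2 / (row1 row2 col1 col2)
        x2 = ntot * (a * d - b * c) ** 2 / (row1 * row2 * col1 * (b + d))
        assert chi_p == pytest.approx(1 - sps.chi2.cdf(x2, 1), abs=1e-6)

    def test_split_by_global_uwmc_median(self):
        df = _clean_cohort(n=50, seed=9)
        df["global_uwmc"] = np.linspace(0, 0.4, 50)
        table = describe_groups(df, "global_uwmc_median")
        assert {"high", "low"} <= set(table.columns)


class TestStabilitySelection:
    def _transformed_cohort(self, seed, active):
        cfg = CohortConfig(
            n_participants=300,
            n_features=50,
            active_effects={f: 0.5 for f in active},
            standardize_active=True,
            noise_sd=1.0,
            clip_round=False,
            seed=seed,
        )
        coh = make_cohort(cfg)
        df = coh.table.copy()
        for f in coh.feature_names:
            df[f] = log_transform(df[f].to_numpy())
        df["physical_activity"] = log_transform(df["physical_activity"].to_numpy())
        return df, coh.feature_names

    def test_same_master_seed_reproduces_frequencies(self):
        df, feats = self._transformed_cohort(21, ["uwmc_f0"])
        cfg = SelectionConfig(n_reps=8, master_seed=4)
        a = stability_select(df, feats, cfg)
        b = stability_select(df, feats, cfg)
        assert a.frequency == b.frequency

    def test_frequencies_invariant_to_feature_order(self):
        df, feats = self._transformed_cohort(22, ["uwmc_f0"])
        cfg = SelectionConfig(n_reps=8, master_seed=4)
        a = stability_select(df, feats, cfg)
        b = stability_select(df, list(reversed(feats)), cfg)
        assert a.frequency == b.frequency

    def test_frequencies_are_multiples_of_reps(self):
        df, feats = self._transformed_cohort(23, ["uwmc_f0"])
        res = stability_select(df, feats[:10], SelectionConfig(n_reps=10, master_seed=1))
        assert all(round(f * 10, 9) == int(round(f * 10)) for f in res.frequency.values())

    def test_constant_feature_excluded_with_warning(self):
        df, feats = self._transformed_cohort(24, [])
        df["uwmc_f0"] = -1.0
        with pytest.warns(RuntimeWarning, match="constant"):
            res = stability_select(df, feats, SelectionConfig(n_reps=4, master_seed=2))
        assert "uwmc_f0" not in res.frequency

    def test_recovers_planted_features_single_seed(self):
        # full 20-seed recovery statistics live in the acceptance suite
        df, feats = self._transformed_cohort(25, ["uwmc_f0", "uwmc_f1", "uwmc_f2"])
        res = stability_select(df, feats, SelectionConfig(master_seed=25))
        assert res.selected == ["uwmc_f0", "uwmc_f1", "uwmc_f2"]


class TestCognitionAnalysis:
    def test_model_fit_summary_pipeline(self):
        cfg = CohortConfig(
            n_participants=260,
            n_features=12,
            active_effects={"uwmc_f0": -2.0},
            noise_sd=1.0,
            seed=31,
        )
        coh = make_cohort(cfg)
        model = CognitionAnalysis(
            coh.table,
            coh.feature_names,
            selection=SelectionConfig(n_reps=30, master_seed=3),
        )
        results = model.fit()
        assert "uwmc_f0" in results.selection.selected
        table = results.summary()
        row = table[table["feature"] == "uwmc_f0"].iloc[0]
        assert row["beta_full"] < 0
        assert row["per_percent_full"] == round(row["beta_full"] / 100, 3)
        assert set(table.columns) >= {"beta_BA", "p_nHW", "interaction_p"}
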