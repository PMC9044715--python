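"""The circular MANOVA: design construction, sequential SSCP partition,
Pillai tests and Monte-Carlo calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circmanova import (
    AngleSample,
    DegenerateResponseError,
    DesignError,
    ModelSpec,
    build_design,
    circular_manova,
    embed,
    fit_mlm,
    mc_calibrated_manova,
    results_to_frame,
    sample_vonmises,
    to_radians,
)
from circmanova.manova import batch_term_pvalues, intercept_theory_p_batch

TWO_PI = 2.0 * np.pi


def random_dataset(gen, n):
    """Random angles with one 2-level factor and one covariate."""
    theta = AngleSample(gen.uniform(0, TWO_PI, n))
    data = pd.DataFrame(
        {
            "g": gen.choice(["a", "b"], size=n),
            "x": gen.normal(size=n),
        }
    )
    # guard against a single observed level at tiny n
    data.loc[0, "g"], data.loc[1, "g"] = "a", "b"
    return theta, data


def sequential_pillai_oracle(X, blocks, Y):
    """Brute force: fit every nested model from scratch and difference the
    explained SSCPs; Pillai from the full-model residual SSCP."""
    T = Y.T @ Y
    explained_prev = np.zeros((2, 2))
    H_terms = []
    for _, sl in blocks:
        Xc = X[:, : sl.stop]
        beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
        resid = Y - Xc @ beta
        explained = T - resid.T @ resid
        H_terms.append(explained - explained_prev)
        explained_prev = explained
    E = T - explained_prev
    return [float(np.trace(H @ np.linalg.inv(H + E))) for H in H_terms]


class TestBuildDesign:
    def test_intercept_only(self):
        data = pd.DataFrame(index=range(4))
        X, blocks, labels = build_design(data, ModelSpec(()))
        np.testing.assert_array_equal(X, np.ones((4, 1)))
        assert labels == ["(Intercept)"]

    def test_two_level_factor_treatment_coding(self):
        data = pd.DataFrame({"g": ["b", "a", "b", "a"]})
        spec = ModelSpec.from_term_names(["g"], data)
        X, blocks, labels = build_design(data, spec)
        np.testing.assert_array_equal(
            X, np.array([[1, 1], [1, 0], [1, 1], [1, 0]], dtype=float)
        )
        assert labels == ["(Intercept)", "g[b]"]

    def test_factor_by_covariate_interaction(self):
        data = pd.DataFrame({"g": ["a", "b", "a", "b"], "x": [1.0, 2.0, 3.0, 4.0]})
        spec = ModelSpec.from_term_names(["g", "x", "g:x"], data)
        X, blocks, labels = build_design(data, spec)
        assert X.shape == (4, 4)
        assert labels == ["(Intercept)", "g[b]", "x", "g[b]:x"]
        np.testing.assert_array_equal(X[:, 3], X[:, 1] * X[:, 2])

    def test_unknown_column(self):
        data = pd.DataFrame({"g": ["a", "b"]})
        with pytest.raises(DesignError, match="unknown column"):
            ModelSpec.from_term_names(["missing"], data)

    def test_constant_factor(self):
        data = pd.DataFrame({"g": ["a", "a", "a"]})
        spec = ModelSpec.from_term_names(["g"], data, factors=("g",))
        with pytest.raises(DesignError, match="single observed level"):
            build_design(data, spec)

    def test_rank_deficiency_names_term(self, rng):
        data = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        data["y"] = 2.0 * data["x"]
        spec = ModelSpec.from_term_names(["x", "y"], data)
        X, blocks, labels = build_design(data, spec)
        theta = AngleSample(rng.uniform(0, TWO_PI, 5))
        with pytest.raises(DesignError, match="'y'"):
            fit_mlm(X, embed(theta), blocks, labels)

    def test_interaction_requires_main_effects_first(self):
        data = pd.DataFrame({"g": ["a", "b"], "x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="precedes"):
            ModelSpec(
                (
                    ModelSpec.from_term_names(["g", "x", "g:x"], data).terms[0],
                    ModelSpec.from_term_names(["g", "x", "g:x"], data).terms[3],
                )
            )


class TestFitMlm:
    def test_cardinal_points_intercept_only(self, cardinal_sample):
        X, blocks, labels = build_design(
            pd.DataFrame(index=range(4)), ModelSpec(())
        )
        fit = fit_mlm(X, embed(cardinal_sample), blocks, labels)
        np.testing.assert_allclose(fit.term_H[0], np.zeros((2, 2)), atol=1e-12)
        np.testing.assert_allclose(fit.E, 2.0 * np.eye(2), atol=1e-12)

    def test_identical_angles_degenerate(self):
        sample = AngleSample(np.full(10, 1.0))
        with pytest.raises(DegenerateResponseError):
            circular_manova(sample)

    def test_sscp_conservation_three_level_factor(self, rng):
        theta = AngleSample(rng.uniform(0, TWO_PI, 12))
        data = pd.DataFrame({"g": list("abc") * 4})
        spec = ModelSpec.from_term_names(["g"], data)
        X, blocks, labels = build_design(data, spec)
        fit = fit_mlm(X, embed(theta), blocks, labels)
        total = sum(fit.term_H, np.zeros((2, 2))) + fit.E
        np.testing.assert_allclose(total, embed(theta).Y.T @ embed(theta).Y, atol=1e-8)
        assert fit.df_error + sum(fit.term_df) == theta.n

    def test_insufficient_residual_df(self, rng):
        theta = AngleSample(rng.uniform(0, TWO_PI, 2))
        data = pd.DataFrame({"x": [0.1, 0.7]})
        spec = ModelSpec.from_term_names(["x"], data)
        X, blocks, labels = build_design(data, spec)
        with pytest.raises(DesignError, match="insufficient residual df"):
            fit_mlm(X, embed(theta), blocks, labels)


class TestPillaiOracles:
    def test_sequential_pillai_matches_brute_force(self):
        """20 random small datasets: per-term Pillai equals nested-model
        SSCP differencing to 1e-9."""
        for seed in range(20):
            gen = np.random.default_rng(seed)
            n = int(gen.integers(12, 31))
            theta, data = random_dataset(gen, n)
            spec = ModelSpec.from_term_names(["g", "x"], data)
            X, blocks, labels = build_design(data, spec)
            fit = fit_mlm(X, embed(theta), blocks, labels)
            results = circular_manova(theta, data, spec)
            oracle = sequential_pillai_oracle(X, blocks, embed(theta).Y)
            for res, v in zip(results, oracle):
                assert res.pillai == pytest.approx(v, abs=1e-9)

    def test_intercept_equals_hotelling_t2(self, rng):
        """Intercept-only Pillai F and p coincide with the one-sample
        Hotelling T-squared test of mean (cos, sin) = (0, 0)."""
        theta = AngleSample(rng.uniform(0, TWO_PI, 37))
        res = circular_manova(theta)[0]
        Y = embed(theta).Y
        n = theta.n
        m = Y.mean(axis=0)
        S = np.cov(Y, rowvar=False, ddof=1)
        t2 = n * m @ np.linalg.solve(S, m)
        f_stat = (n - 2) / (2.0 * (n - 1)) * t2
        p = stats.f.sf(f_stat, 2, n - 2)
        assert res.approx_f == pytest.approx(f_stat, abs=1e-9)
        assert res.p_theory == pytest.approx(p, abs=1e-9)

    def test_rotation_invariance_of_intercept_test(self, rng):
        base = rng.uniform(0, TWO_PI, 45)
        r0 = circular_manova(AngleSample(base))[0]
        r1 = circular_manova(to_radians(base + 2.1))[0]
        assert r1.pillai == pytest.approx(r0.pillai, abs=1e-9)
        assert r1.p_theory == pytest.approx(r0.p_theory, abs=1e-9)

    def test_zero_hypothesis_sscp(self, cardinal_sample):
        res = circular_manova(cardinal_sample)[0]
        assert res.pillai == pytest.approx(0.0, abs=1e-12)
        assert res.approx_f == pytest.approx(0.0, abs=1e-12)
        assert res.p_theory == pytest.approx(1.0)


class TestPower:
    def test_concentrated_sample_detected(self, rng):
        theta = sample_vonmises(100, 0.0, 2.0, rng)
        assert circular_manova(theta)[0].p_theory < 0.001

    def test_opposite_groups_detected_by_group_term_not_intercept(self, rng):
        """Two groups 180 deg apart cancel in the pooled mean vector: the
        intercept stays near its level while the group term has power."""
        n_half, reps = 50, 200
        data = pd.DataFrame({"g": ["a"] * n_half + ["b"] * n_half})
        spec = ModelSpec.from_term_names(["g"], data)
        X, blocks, _ = build_design(data, spec)
        Q, _ = np.linalg.qr(X)
        theta = np.concatenate(
            [
                np.mod(rng.vonmises(0.0, 2.0, size=(reps, n_half)), TWO_PI),
                np.mod(rng.vonmises(np.pi, 2.0, size=(reps, n_half)), TWO_PI),
            ],
            axis=1,
        )
        p = batch_term_pvalues(Q, blocks, theta, 2 * n_half - X.shape[1])
        assert np.mean(p[:, 1] < 0.01) > 0.95  # group term
        assert np.mean(p[:, 0] < 0.05) < 0.15  # intercept near level


class TestBatchConsistency:
    def test_batch_matches_scalar_path(self, rng):
        """The vectorised p-value path used by the simulations equals the
        per-sample fit."""
        n = 30
        data = pd.DataFrame({"g": ["a", "b", "c"] * 10, "x": rng.normal(size=n)})
        spec = ModelSpec.from_term_names(["g", "x"], data)
        X, blocks, labels = build_design(data, spec)
        Q, _ = np.linalg.qr(X)
        theta = rng.uniform(0, TWO_PI, size=(8, n))
        batch = batch_term_pvalues(Q, blocks, theta, n - X.shape[1])
        for r, row in enumerate(theta):
            results = circular_manova(AngleSample(row), data, spec)
            for t, res in enumerate(results):
                assert batch[r, t] == pytest.approx(res.p_theory, abs=1e-9)

    def test_intercept_batch_matches_scalar_path(self, rng):
        theta = rng.uniform(0, TWO_PI, size=(6, 21))
        batch = intercept_theory_p_batch(theta)
        for r, row in enumerate(theta):
            assert batch[r] == pytest.approx(
                circular_manova(AngleSample(row))[0].p_theory, abs=1e-9
            )


class TestMcCalibration:
    def test_extreme_observation_attains_minimum(self, rng):
        theta = sample_vonmises(30, 0.0, 10.0, rng)
        res = mc_calibrated_manova(theta, B=99, rng=rng)[0]
        assert res.p_mc == pytest.approx(1 / 100)

    def test_calibrated_p_attached_per_term(self, rng):
        theta, data = random_dataset(rng, 24)
        spec = ModelSpec.from_term_names(["g", "x"], data)
        results = mc_calibrated_manova(theta, data, spec, B=199, rng=rng)
        assert all(r.p_mc is not None for r in results)
        assert all(1 / 200 <= r.p_mc <= 1.0 for r in results)

    def test_b_below_one_rejected(self, rng):
        theta = AngleSample(rng.uniform(0, TWO_PI, 10))
        with pytest.raises(ValueError):
            mc_calibrated_manova(theta, B=0, rng=rng)


def test_results_frame_is_tidy(rng):
    theta, data = random_dataset(rng, 20)
    spec = ModelSpec.from_term_names(["g", "x"], data)
    frame = results_to_frame(circular_manova(theta, data, spec))
    assert list(frame.columns) == [
        "term", "df", "pillai", "approx_f", "df1", "df2", "p_theory", "p_mc",
    ]
    assert list(frame["term"]) == ["(Intercept)", "g", "x"]
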