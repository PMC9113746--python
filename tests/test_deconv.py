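"""Mixture deconvolution: estimator exactness, oracles, and validation fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls

import atlasdecon as ad


def _profile(name, values, genes):
    return ad.ConditionProfile(
        values=pd.Series(values, index=genes, dtype=float), compartment=name
    )


def _exact_mixture(weights=(0.5, 0.3, 0.2)):
    """Three compartments with disjoint exclusive markers and an exact mix."""
    genes = [f"g{i}" for i in range(9)]
    profiles = {
        "a": _profile("a", [200, 0, 0, 50, 80, 10, 30, 20, 10], genes),
        "b": _profile("b", [0, 150, 0, 60, 70, 15, 30, 20, 10], genes),
        "c": _profile("c", [0, 0, 300, 40, 90, 12, 30, 20, 10], genes),
    }
    w = dict(zip(profiles, weights))
    mix = sum(w[c] * profiles[c].values for c in profiles)
    whole = _profile("whole_body", mix.to_numpy(), genes)
    return profiles, whole, w


class TestEstimator:
    def test_identity_mixture(self):
        profiles, _, _ = _exact_mixture()
        whole = _profile("whole_body", profiles["a"].values.to_numpy(),
                         profiles["a"].values.index.tolist())
        census = ad.find_markers(profiles, min_tpm=5, min_fold=50)
        factors = ad.estimate_scaling_factors(census, profiles, whole)
        assert np.isclose(factors.fractions["a"], 1.0)
        assert np.allclose(factors.fractions[["b", "c"]], 0.0)

    def test_recovers_known_weights_and_matches_nnls_oracle(self):
        profiles, whole, w = _exact_mixture()
        census = ad.find_markers(profiles, min_tpm=5, min_fold=50)
        factors = ad.estimate_scaling_factors(census, profiles, whole)
        for comp, weight in w.items():
            assert abs(factors.fractions[comp] - weight) < 1e-9
        # independent oracle: non-negative least squares on the full gene set
        design = np.column_stack([profiles[c].values for c in profiles])
        oracle, _ = nnls(design, whole.values.to_numpy())
        assert np.allclose(factors.fractions[list(profiles)], oracle, atol=1e-6)

    def test_compartment_without_markers_is_an_error(self):
        profiles, whole, _ = _exact_mixture()
        census = ad.find_markers(
            {k: profiles[k] for k in ("a", "b")}, min_tpm=5, min_fold=50
        )
        with pytest.raises(ValueError, match="c"):
            ad.estimate_scaling_factors(census, profiles, whole)


class TestSumCheck:
    @pytest.mark.parametrize(
        ("fractions", "total", "warn"),
        [
            ((0.5, 0.3, 0.2), 100.0, False),
            ((0.4, 0.3, 0.2), 90.0, False),  # boundary passes
            ((0.4, 0.2, 0.2), 80.0, True),
        ],
    )
    def test_total_and_warning(self, fractions, total, warn):
        factors = ad.ScalingFactors(
            fractions=pd.Series(fractions, index=["a", "b", "c"]),
            n_markers=pd.Series([1, 1, 1], index=["a", "b", "c"]),
            sd=pd.Series([np.nan] * 3, index=["a", "b", "c"]),
            per_marker=pd.DataFrame(),
        )
        got_total, got_warn = ad.sum_check(factors)
        assert np.isclose(got_total, total)
        assert got_warn is warn


class TestPrediction:
    def _factors(self, mapping):
        idx = list(mapping)
        return ad.ScalingFactors(
            fractions=pd.Series(mapping),
            n_markers=pd.Series(1, index=idx),
            sd=pd.Series(np.nan, index=idx),
            per_marker=pd.DataFrame(),
        )

    def test_one_hot_returns_that_compartment(self):
        profiles, _, _ = _exact_mixture()
        factors = self._factors({"a": 1.0, "b": 0.0, "c": 0.0})
        pred = ad.predict_whole_body(profiles, factors)
        assert np.allclose(pred.values, profiles["a"].values)

    def test_zero_factors_annihilate(self):
        profiles, _, _ = _exact_mixture()
        factors = self._factors({"a": 0.0, "b": 0.0, "c": 0.0})
        assert (ad.predict_whole_body(profiles, factors).values == 0).all()

    def test_toy_matrix_vector_product(self):
        genes = ["g1", "g2"]
        profiles = {
            "a": _profile("a", [10.0, 20.0], genes),
            "b": _profile("b", [30.0, 40.0], genes),
        }
        factors = self._factors({"a": 0.25, "b": 0.5})
        pred = ad.predict_whole_body(profiles, factors)
        assert np.allclose(pred.values, [0.25 * 10 + 0.5 * 30, 0.25 * 20 + 0.5 * 40])

    def test_missing_factor_is_an_error(self):
        profiles, _, _ = _exact_mixture()
        factors = self._factors({"a": 0.5, "b": 0.5})
        with pytest.raises(ValueError, match="c"):
            ad.predict_whole_body(profiles, factors)

    def test_prediction_conserves_total_tpm(self, noiseless_profiles):
        profiles, whole_body, truth = noiseless_profiles
        census = ad.find_markers(profiles)
        factors = ad.estimate_scaling_factors(census, profiles, whole_body)
        pred = ad.predict_whole_body(profiles, factors)
        assert np.isclose(pred.values.sum(), 1e6 * factors.total, rtol=1e-9)


class TestValidatePrediction:
    def test_identity_fit(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(200)]
        vals = 10.0 ** rng.uniform(0.1, 4, size=200)
        obs = _profile("obs", vals, genes)
        pred = _profile("pred", vals, genes)
        report = ad.validate_prediction(pred, obs)
        assert np.isclose(report.slope, 1.0)
        assert np.isclose(report.intercept, 0.0, atol=1e-12)
        assert np.isclose(report.r_squared, 1.0)
        assert report.removed_outliers == []

    def test_single_inflated_point_is_removed(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(1000)]
        vals = 10.0 ** rng.uniform(0.5, 4, size=1000)
        pred_vals = vals.copy()
        pred_vals[123] *= 100.0  # planted 100x over-prediction
        obs = _profile("obs", vals, genes)
        pred = _profile("pred", pred_vals, genes)
        report = ad.validate_prediction(pred, obs)
        assert report.removed_outliers == ["g123"]
        assert abs(report.slope - 1.0) < 0.01
        # oracle: manual removal then plain OLS reproduces the final fit
        from oracles import ols_fit

        keep = np.ones(1000, dtype=bool)
        keep[123] = False
        slope, _, r2 = ols_fit(
            np.log10(vals[keep] + 1), np.log10(pred_vals[keep] + 1)
        )
        assert np.isclose(report.slope, slope, atol=1e-9)
        assert np.isclose(report.r_squared, r2, atol=1e-9)

    def test_too_few_points_rejected(self):
        genes = [f"g{i}" for i in range(5)]
        prof = _profile("p", [10.0] * 5, genes)
        with pytest.raises(ValueError, match="10 genes"):
            ad.validate_prediction(prof, prof)


class TestNoiseBehaviour:
    def test_unbiased_recovery_under_replicate_noise(self):
        """Mean absolute error of recovered fractions stays small at
        moderate noise (a reduced-seed version of the full bias check)."""
        errors = []
        for seed in range(5):
            matrix, sheet, truth = ad.generate_atlas(
                n_genes=4000, markers_per_compartment=8,
                noise_sd_log=0.2, n_replicates=3, seed=seed,
            )
            grouped = ad.aggregate_replicates(matrix, sheet, ("compartment",))
            profiles = {k[0]: p for k, p in grouped.items()}
            wb = profiles.pop("whole_body")
            census = ad.find_markers(profiles)
            factors = ad.estimate_scaling_factors(census, profiles, wb)
            errors += [
                abs(factors.fractions[c] - truth.true_weights[c]) for c in profiles
            ]
        assert np.mean(errors) < 0.02
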