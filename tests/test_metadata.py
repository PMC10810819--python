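"""Metadata effect estimation: outcomes, cross-validated ridge and flags."""

import numpy as np
import pandas as pd
import pytest

from mirstab.metadata import (
    BIAS_FACTORS,
    VARIANCE_FACTORS,
    ClusterRidgeCV,
    bias_design,
    bias_outcomes,
    flag_large_effects,
    ridge_cv_fit,
    variance_design,
    variance_outcomes,
)


def _normalized_panel(values):
    rows = [("m", pid, v, y) for pid, obs in values.items() for v, y in obs]
    return pd.DataFrame(
        rows, columns=["mirna_id", "participant_id", "visit_index",
                       "normalized_cq"]
    )


class TestBiasOutcomes:
    def test_trend_following_data_gives_zero(self):
        values = {p: [(v, 20.0 + 0.2 * v) for v in range(1, 8)] for p in "AB"}
        out = bias_outcomes(_normalized_panel(values))
        assert out["outcome"].abs().max() < 1e-10

    def test_injected_spike_flips_sign(self):
        """+1 Cq at one visit shows up as ~ -1 log2 expression deviation."""
        values = {p: [(v, 20.0) for v in range(1, 21)] for p in "ABCD"}
        values["A"] = [(v, 20.0 + (1.0 if v == 10 else 0.0))
                       for v in range(1, 21)]
        out = bias_outcomes(_normalized_panel(values))
        spike = out[(out["participant_id"] == "A") & (out["visit_index"] == 10)]
        assert -1.05 < spike["outcome"].iloc[0] < -0.8

    def test_donor_means_near_zero(self, reduced_stages):
        _, _, stages = reduced_stages
        out = bias_outcomes(stages["normalization"].normalized)
        donor_means = out.groupby(["mirna_id", "participant_id"])["outcome"].mean()
        # zero up to the common-slope anchoring correction
        assert donor_means.abs().max() < 0.2
        assert donor_means.abs().median() < 0.05


class TestVarianceOutcomes:
    def test_doubled_noise_donor_scores_one_log2(self):
        rng = np.random.default_rng(0)
        values = {}
        for p in range(10):
            sd = 2.0 if p == 0 else 1.0
            values[f"P{p}"] = [(v, rng.normal(0, sd)) for v in range(1, 120)]
        bias = bias_outcomes(_normalized_panel(values))
        out = variance_outcomes(bias)
        loud = out[out["participant_id"] == "P0"]["outcome"].iloc[0]
        assert loud == pytest.approx(np.log2(2.0) * 0.9, abs=0.25)

    def test_short_series_excluded_with_warning(self):
        values = {"A": [(1, 0.0), (2, 1.0)],
                  "B": [(v, float(v)) for v in range(1, 6)],
                  "C": [(v, -float(v)) for v in range(1, 6)]}
        bias = bias_outcomes(_normalized_panel(values))
        with pytest.warns(UserWarning, match="A"):
            out = variance_outcomes(bias)
        assert "A" not in set(out["participant_id"])

    def test_zero_sd_floored_and_flagged(self):
        values = {"A": [(v, 5.0) for v in range(1, 6)],
                  "B": [(v, 3.0) for v in range(1, 6)]}
        bias = bias_outcomes(_normalized_panel(values))
        out = variance_outcomes(bias)
        row = out[out["participant_id"] == "A"].iloc[0]
        assert bool(row["floored"])
        assert np.isfinite(row["outcome"])


class TestRidge:
    def test_zero_penalty_matches_ols(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = X.to_numpy() @ np.array([1.0, -0.5, 0.2, 0.0]) + rng.normal(0, 0.1, 60)
        weights, alpha = ridge_cv_fit(y, X, alphas=[0.0])
        Z = (X - X.mean()) / X.std(ddof=0)
        Zd = np.column_stack([np.ones(len(Z)), Z])
        ols = np.linalg.lstsq(Zd, y, rcond=None)[0][1:]
        assert np.max(np.abs(weights.to_numpy() - ols)) < 1e-8

    def test_orthogonal_design_closed_form(self):
        """For an orthogonal standardized design the ridge weight is the
        least-squares weight shrunk by 1/(1 + lambda/n)."""
        rng = np.random.default_rng(2)
        n, p = 64, 4
        raw = rng.normal(size=(n, p))
        raw -= raw.mean(axis=0)  # orthogonal to the intercept
        Q, _ = np.linalg.qr(raw)
        X = pd.DataFrame(Q * np.sqrt(n), columns=list("abcd"))  # unit SD, mean 0
        y = rng.normal(size=n)
        lam = 37.0
        weights, _ = ridge_cv_fit(y, X, alphas=[lam])
        ols, _ = ridge_cv_fit(y, X, alphas=[0.0])
        np.testing.assert_allclose(
            weights.to_numpy(), ols.to_numpy() / (1 + lam / n), atol=1e-8
        )

    def test_infinite_penalty_kills_weights(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(0, 0.1, 40)
        weights, _ = ridge_cv_fit(y, X, alphas=[1e12])
        assert np.max(np.abs(weights.to_numpy())) < 1e-6

    def test_weight_norm_shrinks_with_penalty(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        y = X.to_numpy() @ rng.normal(size=5) + rng.normal(0, 0.2, 50)
        norms = []
        for lam in np.logspace(-2, 4, 10):
            w, _ = ridge_cv_fit(y, X, alphas=[lam])
            norms.append(np.linalg.norm(w.to_numpy()))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_constant_predictor_gets_zero_weight(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": rng.normal(size=30), "const": 1.0})
        y = X["x"].to_numpy() + rng.normal(0, 0.1, 30)
        weights, _ = ridge_cv_fit(y, X)
        assert weights["const"] == 0.0

    def test_fewer_observations_than_folds_warned(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x": rng.normal(size=3)})
        y = rng.normal(size=3)
        with pytest.warns(UserWarning, match="folds"):
            ridge_cv_fit(y, X, folds=5)

    def test_group_folds_accepted(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=list("ab"))
        y = rng.normal(size=40)
        groups = np.repeat(np.arange(10), 4)
        model = ClusterRidgeCV().fit(X.to_numpy(), y, groups=groups)
        assert model.alpha_ > 0


class TestDesignSchemas:
    def test_bias_design_time_varying_only(self, reduced_stages):
        study, _, stages = reduced_stages
        design = bias_design(study.samples, stages["hemolysis"])
        assert list(design.columns[2:]) == BIAS_FACTORS
        # first visits carry undefined change predictors and are dropped
        firsts = study.samples.groupby("participant_id")["visit_index"].min()
        merged = design.merge(firsts.rename("first"), on="participant_id")
        assert (merged["visit_index"] > merged["first"]).all()

    def test_variance_design_donor_level_only(self, reduced_stages):
        study, _, stages = reduced_stages
        design = variance_design(
            study.samples, study.participants, stages["hemolysis"]
        )
        assert list(design.columns[1:]) == VARIANCE_FACTORS
        assert len(design) == len(study.participants)


class TestFlags:
    def test_threshold_value(self):
        flags = flag_large_effects(pd.DataFrame({"f": [0.0]}))
        assert flags["threshold"] == pytest.approx(0.585, abs=5e-4)

    def test_counts(self):
        table = pd.DataFrame(
            {"tobacco": [0.6, -0.7, 0.1], "fasting": [0.0, 0.0, 0.0]},
            index=["m1", "m2", "m3"],
        )
        flags = flag_large_effects(table)
        assert flags["tobacco"] == {"increase": 1, "decrease": 1}
        assert flags["fasting"] == {"increase": 0, "decrease": 0}
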