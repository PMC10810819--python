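"""Ridge quantification of metadata effects on miRNA level and noise.

Two families of penalized regressions per miRNA, mirroring the two ways a
factor can perturb a longitudinal biomarker:

* *Measurement bias*: visit-level deviations of log2 expression from the
  donor's own fitted trend, regressed on the five time-varying factors
  (hemolysis score, recent tobacco use, fasting, higher stress than the
  prior visit, sleep-quality change vs the prior visit).
* *Test-retest variance moderation*: the donor-level log2 SD of those
  deviations, centred on the cohort mean, regressed on the seven
  time-invariant or time-averaged factors (average hemolysis, age per
  decade, average sleep quality, average stress, fasting probability, sex,
  regular tobacco use).

Predictors are standardized; each regression selects its own quadratic
penalty by fivefold cross-validation (grouped by donor for the visit-level
regressions so correlated visits never straddle a fold boundary). Weights
are reported on the outcome scale per standardized predictor; effects at or
beyond log2(1.5) ~ 0.58 are counted as large.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge
from sklearn.model_selection import GroupKFold, KFold

BIAS_FACTORS = [
    "hemolysis",
    "recent_tobacco",
    "fasting",
    "stress_higher",
    "sleep_change",
]
VARIANCE_FACTORS = [
    "avg_hemolysis",
    "age_per_decade",
    "avg_sleep_quality",
    "avg_stress",
    "fasting_probability",
    "sex_male",
    "regular_tobacco",
]

_MIN_SD = 1e-3


def bias_outcomes(normalized: pd.DataFrame) -> pd.DataFrame:
    """Visit-level log2-expression deviation from each donor's fitted trend.

    The trend is the within-subjects model of the stability analysis: the
    average (across donors) slope over the visit sequence, anchored at each
    donor's mean level. Using the averaged slope rather than each donor's
    own noisy slope keeps visit-level deviations from leaking into the
    detrending. The outcome is the sign-flipped Cq residual (expression
    deviation = -Cq deviation); donor means of the outcome are zero up to
    the slope-anchoring correction.
    """
    rows = []
    for mirna, grp in normalized.groupby("mirna_id"):
        slopes = []
        for pid, sub in grp.groupby("participant_id"):
            t = sub["visit_index"].to_numpy(dtype=float)
            if len(sub) >= 2 and np.ptp(t) > 0:
                slopes.append(np.polyfit(t, sub["normalized_cq"], 1)[0])
        avg_slope = float(np.mean(slopes)) if slopes else 0.0
        for pid, sub in grp.groupby("participant_id"):
            t = sub["visit_index"].to_numpy(dtype=float)
            y = sub["normalized_cq"].to_numpy(dtype=float)
            resid = y - (y.mean() + avg_slope * (t - t.mean()))
            for v, r in zip(sub["visit_index"], resid):
                rows.append((mirna, pid, int(v), -float(r)))
    return pd.DataFrame(
        rows, columns=["mirna_id", "participant_id", "visit_index", "outcome"]
    )


def variance_outcomes(bias: pd.DataFrame, min_visits: int = 3) -> pd.DataFrame:
    """Donor-level centred log2 SD of the visit-level deviations."""
    rows = []
    for (mirna, pid), grp in bias.groupby(["mirna_id", "participant_id"]):
        if len(grp) < min_visits:
            warnings.warn(
                f"participant {pid} has fewer than {min_visits} visits; "
                "excluded from variance outcomes"
            )
            continue
        sd = float(grp["outcome"].std(ddof=1))
        floored = sd < _MIN_SD
        rows.append((mirna, pid, float(np.log2(max(sd, _MIN_SD))), floored))
    out = pd.DataFrame(
        rows, columns=["mirna_id", "participant_id", "log2_sd", "floored"]
    )
    out["outcome"] = out["log2_sd"] - out.groupby("mirna_id")["log2_sd"].transform(
        "mean"
    )
    return out


def bias_design(samples: pd.DataFrame, hemolysis: pd.DataFrame) -> pd.DataFrame:
    """Visit-level predictor table; change-type predictors are undefined at
    each donor's first visit, so those rows are dropped."""
    s = samples.sort_values(["participant_id", "visit_index"]).copy()
    hem = hemolysis.set_index(["participant_id", "visit_index"])["score"]
    key = pd.MultiIndex.from_frame(s[["participant_id", "visit_index"]])
    s["hemolysis"] = hem.reindex(key).values
    s["hemolysis"] = s["hemolysis"].fillna(s["hemolysis"].median())
    grp = s.groupby("participant_id")
    s["stress_higher"] = (s["stress_level"] > grp["stress_level"].shift(1)).astype(float)
    s["sleep_change"] = s["sleep_quality"] - grp["sleep_quality"].shift(1)
    first = grp["visit_index"].transform("min")
    s = s[s["visit_index"] > first]
    out = s[["participant_id", "visit_index", "hemolysis", "fasting",
             "stress_higher", "sleep_change"]].copy()
    out["recent_tobacco"] = s["recent_tobacco"].astype(float)
    out["fasting"] = out["fasting"].astype(float)
    return out[["participant_id", "visit_index"] + BIAS_FACTORS]


def variance_design(
    samples: pd.DataFrame,
    participants: pd.DataFrame,
    hemolysis: pd.DataFrame,
) -> pd.DataFrame:
    """Donor-level predictor table (time-invariant and time-averaged)."""
    s = samples.copy()
    hem = hemolysis.set_index(["participant_id", "visit_index"])["score"]
    key = pd.MultiIndex.from_frame(s[["participant_id", "visit_index"]])
    s["hemolysis"] = hem.reindex(key).values
    agg = s.groupby("participant_id").agg(
        avg_hemolysis=("hemolysis", "mean"),
        avg_sleep_quality=("sleep_quality", "mean"),
        avg_stress=("stress_level", "mean"),
        fasting_probability=("fasting", "mean"),
    )
    p = participants.set_index("participant_id")
    agg["age_per_decade"] = p["age"] / 10.0
    agg["sex_male"] = (p["sex"] == "M").astype(float)
    agg["regular_tobacco"] = p["regular_tobacco"].astype(float)
    return agg.reset_index()[["participant_id"] + VARIANCE_FACTORS]


class ClusterRidgeCV(BaseEstimator, RegressorMixin):
    """Ridge regression with cross-validated penalty and optional
    cluster-aware folds.

    Predictors are standardized internally (constant columns get weight
    exactly 0); the intercept is unpenalized. The penalty grid defaults to
    50 log-spaced points on [1e-4, 1e4] scaled by the predictor count, and
    the penalty minimizing mean cross-validated squared error is kept.
    """

    def __init__(self, alphas=None, n_folds: int = 5, random_state: int = 0):
        self.alphas = alphas
        self.n_folds = n_folds
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        self.means_ = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        self.constant_ = sds == 0
        self.scales_ = np.where(self.constant_, 1.0, sds)
        Z = (X - self.means_) / self.scales_
        Z[:, self.constant_] = 0.0

        alphas = (
            np.logspace(-4, 4, 50) * p if self.alphas is None else np.asarray(self.alphas)
        )

        if groups is not None:
            groups = np.asarray(groups)
            n_groups = len(np.unique(groups))
            k = min(self.n_folds, n_groups)
            splitter = GroupKFold(n_splits=k)
            splits = list(splitter.split(Z, y, groups))
        else:
            k = min(self.n_folds, n)
            if k < self.n_folds:
                warnings.warn(f"fewer observations than folds; using {k} folds")
            splitter = KFold(n_splits=k, shuffle=True, random_state=self.random_state)
            splits = list(splitter.split(Z, y))

        errors = np.zeros(len(alphas))
        for train, test in splits:
            for i, a in enumerate(alphas):
                model = Ridge(alpha=a, fit_intercept=True)
                model.fit(Z[train], y[train])
                resid = y[test] - model.predict(Z[test])
                errors[i] += float(np.sum(resid**2))
        self.cv_errors_ = errors / n
        self.alpha_ = float(alphas[int(np.argmin(errors))])

        final = Ridge(alpha=self.alpha_, fit_intercept=True)
        final.fit(Z, y)
        coef = final.coef_.copy()
        coef[self.constant_] = 0.0
        self.coef_ = coef
        self.intercept_ = float(final.intercept_)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Z = (X - self.means_) / self.scales_
        Z[:, self.constant_] = 0.0
        return Z @ self.coef_ + self.intercept_


def ridge_cv_fit(
    outcomes,
    predictors: pd.DataFrame,
    folds: int = 5,
    groups=None,
    random_state: int = 0,
    alphas=None,
):
    """Fit one cross-validated ridge; returns (weights Series, penalty)."""
    model = ClusterRidgeCV(alphas=alphas, n_folds=folds, random_state=random_state)
    model.fit(predictors.to_numpy(), np.asarray(outcomes, dtype=float), groups=groups)
    return pd.Series(model.coef_, index=list(predictors.columns)), model.alpha_


def effect_table(
    outcomes: pd.DataFrame,
    design: pd.DataFrame,
    factors: list[str],
    by_participant: bool,
    folds: int = 5,
    random_state: int = 0,
) -> pd.DataFrame:
    """miRNA x factor ridge-weight table.

    ``by_participant`` keys the merge on donor only (variance regressions);
    otherwise on (donor, visit) with donor-grouped CV folds.
    """
    keys = ["participant_id"] if by_participant else ["participant_id", "visit_index"]
    rows = {}
    for mirna, grp in outcomes.groupby("mirna_id"):
        merged = grp.merge(design, on=keys, how="inner").dropna(
            subset=factors + ["outcome"]
        )
        groups = None if by_participant else merged["participant_id"].to_numpy()
        weights, _ = ridge_cv_fit(
            merged["outcome"],
            merged[factors],
            folds=folds,
            groups=groups,
            random_state=random_state,
        )
        rows[mirna] = weights
    table = pd.DataFrame(rows).T
    table.index.name = "mirna_id"
    return table[factors]


def flag_large_effects(table: pd.DataFrame, threshold: float | None = None) -> dict:
    """Per-factor counts of miRNAs with effects beyond +/- log2(1.5)."""
    if threshold is None:
        threshold = float(np.log2(1.5))
    out = {}
    for factor in table.columns:
        col = table[factor]
        out[factor] = {
            "increase": int((col >= threshold).sum()),
            "decrease": int((col <= -threshold).sum()),
        }
    out["threshold"] = threshold
    return out


def analyze_metadata(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    participants: pd.DataFrame,
    hemolysis: pd.DataFrame,
    folds: int = 5,
    random_state: int = 0,
) -> dict:
    """Full metadata analysis: both outcome tables, both effect tables and
    the large-effect counts."""
    bias = bias_outcomes(normalized)
    var = variance_outcomes(bias)
    bdesign = bias_design(samples, hemolysis)
    vdesign = variance_design(samples, participants, hemolysis)
    bias_table = effect_table(
        bias, bdesign, BIAS_FACTORS, by_participant=False,
        folds=folds, random_state=random_state,
    )
    var_table = effect_table(
        var, vdesign, VARIANCE_FACTORS, by_participant=True,
        folds=folds, random_state=random_state,
    )
    return {
        "bias_outcomes": bias,
        "variance_outcomes": var,
        "bias_effects": bias_table,
        "variance_effects": var_table,
        "bias_flags": flag_large_effects(bias_table),
        "variance_flags": flag_large_effects(var_table),
    }
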