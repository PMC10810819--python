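"""Endogenous normalization via per-miRNA censored multilevel regression.

Each retained miRNA is modelled on four per-sample covariates - the mean of
the five miR-16-5p replicates, the median of normalizer set 1 (miR-24-3p,
miR-484), the median of the participant-specific subset of set 2, and the
hemolysis score - with a participant random intercept, using the interval
likelihood: acceptable Cq values enter exactly, censored values as the
interval [calibrated Cq, 40], missing values as (40, inf).

Every visit sample then receives a definite normalized Cq and a standard
error. Exact observations keep their observed (calibrated) value minus the
model-estimated normalizer contribution, with covariates centred at the
cohort medians so the hemolysis effect is adjusted out; censored
observations are imputed by the truncated-normal conditional mean inside
[calibrated Cq, 40] given the participant's posterior random effect, and
missing observations by the conditional linear predictor (the most-likely
level consistent with the normalizers and the donor's other visits; the
right-open interval informs the likelihood only), each minus the same
adjustment. Imputation SEs add the full residual variance, so they exceed
the adjustment-only SEs of exact observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ACCEPTABLE,
    CENSORED,
    MIR16,
    MISSING,
    SET1,
    SET2,
    StudyTable,
)
from .intervalreg import IntervalRegression, truncated_normal_mean

COVARIATES = ["mir16", "set1_median", "set2_median", "hemolysis"]

_SE_FLOOR = 1e-6


@dataclass
class NormalizerSets:
    """Endogenous normalizer definitions.

    ``set2_subsets`` maps each participant to the members of set 2 observed
    acceptably in every one of that donor's visits; the subset may differ by
    donor but must be nonempty.
    """

    primary: str
    set1: tuple[str, ...]
    set2: tuple[str, ...]
    set2_subsets: dict[str, list[str]]


def build_normalizer_sets(study: StudyTable) -> NormalizerSets:
    """Determine the per-participant set-2 subsets from acceptability."""
    wells = study.wells
    ok = wells[(wells["status"] == ACCEPTABLE) & wells["assay_id"].isin(SET2)]
    visits_per = study.samples.groupby("participant_id")["visit_index"].nunique()
    subsets: dict[str, list[str]] = {}
    for pid, n_visits in visits_per.items():
        sub = ok[ok["participant_id"] == pid]
        counts = sub.groupby("assay_id")["visit_index"].nunique()
        members = sorted(counts[counts == n_visits].index)
        if not members:
            raise ValueError(
                f"participant {pid}: no set-2 normalizer observed in every visit"
            )
        subsets[pid] = members
    return NormalizerSets(
        primary=MIR16, set1=SET1, set2=SET2, set2_subsets=subsets
    )


def build_covariates(
    study: StudyTable,
    sets: NormalizerSets,
    hemolysis: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample covariate table from calibrated values.

    Missing hemolysis scores fall back to the cohort median (flagged in the
    ``hemolysis_imputed`` column).
    """
    wells = study.wells
    ok = wells[wells["status"] == ACCEPTABLE]
    per_assay = (
        ok.groupby(["participant_id", "visit_index", "assay_id"])["cq"]
        .mean()
        .rename("cq")
    )

    def sample_stat(assays, agg):
        sub = per_assay[per_assay.index.get_level_values("assay_id").isin(assays)]
        grouped = sub.groupby(["participant_id", "visit_index"])
        return grouped.median() if agg == "median" else grouped.mean()

    out = study.sample_index().set_index(["participant_id", "visit_index"])
    out["mir16"] = sample_stat([sets.primary], "mean")
    out["set1_median"] = sample_stat(list(sets.set1), "median")

    set2_vals = pd.Series(index=out.index, dtype=float)
    for pid, members in sets.set2_subsets.items():
        sub = per_assay[
            (per_assay.index.get_level_values("participant_id") == pid)
            & per_assay.index.get_level_values("assay_id").isin(members)
        ]
        med = sub.groupby(["participant_id", "visit_index"]).median()
        set2_vals.loc[med.index] = med
    out["set2_median"] = set2_vals

    hem = hemolysis.set_index(["participant_id", "visit_index"])["score"]
    out["hemolysis"] = hem.reindex(out.index)
    out["hemolysis_imputed"] = out["hemolysis"].isna()
    out["hemolysis"] = out["hemolysis"].fillna(float(hem.median()))

    for col in ("mir16", "set1_median", "set2_median"):
        if out[col].isna().any():
            bad = out[out[col].isna()].index[:5].tolist()
            raise ValueError(f"covariate {col} undefined for sample(s) {bad}")
    return out.reset_index()


@dataclass
class NormalizationResult:
    """Long normalized matrix + per-miRNA model summaries."""

    normalized: pd.DataFrame  # participant_id, visit_index, mirna_id, normalized_cq, se, kind
    summaries: pd.DataFrame   # per-miRNA coefficients, variances, loglik


def fit_interval_model(
    data: pd.DataFrame,
    covariates: pd.DataFrame,
    max_cq: float = 40.0,
    n_quad: int = 15,
) -> tuple[IntervalRegression, pd.DataFrame]:
    """Fit the censored multilevel model for one miRNA.

    ``data``: wells of the miRNA (participant_id, visit_index, cq, status).
    Covariates are centred at their cohort medians before fitting.
    """
    cov = covariates.set_index(["participant_id", "visit_index"])
    centres = cov[COVARIATES].median()
    key = pd.MultiIndex.from_frame(data[["participant_id", "visit_index"]])
    X = (cov[COVARIATES].reindex(key) - centres).to_numpy()

    status = data["status"].to_numpy()
    cq = data["cq"].to_numpy(dtype=float)
    lower = np.where(status == ACCEPTABLE, cq,
                     np.where(status == CENSORED, cq, max_cq))
    upper = np.where(status == ACCEPTABLE, cq,
                     np.where(status == CENSORED, max_cq, np.inf))

    model = IntervalRegression(n_quad=n_quad)
    model.fit(X, lower, upper, groups=data["participant_id"].to_numpy())

    design = pd.DataFrame(X, columns=COVARIATES)
    design["lower"], design["upper"] = lower, upper
    return model, design


def predict_normalized(
    model: IntervalRegression,
    data: pd.DataFrame,
    covariates: pd.DataFrame,
    max_cq: float = 40.0,
) -> pd.DataFrame:
    """Normalized value + SE per observation of one miRNA (see module doc)."""
    cov = covariates.set_index(["participant_id", "visit_index"])
    centres = cov[COVARIATES].median()
    key = pd.MultiIndex.from_frame(data[["participant_id", "visit_index"]])
    Xc = (cov[COVARIATES].reindex(key) - centres).to_numpy()

    adjustment = Xc @ model.coef_
    adj_var = np.clip(model.adjustment_variance(Xc), 0.0, None)
    mu_cond = model.predict(Xc, groups=data["participant_id"].to_numpy())

    status = data["status"].to_numpy()
    cq = data["cq"].to_numpy(dtype=float)
    value = np.empty(len(data))
    se = np.empty(len(data))
    kind = np.empty(len(data), dtype=object)

    exact = status == ACCEPTABLE
    value[exact] = cq[exact] - adjustment[exact]
    se[exact] = np.sqrt(adj_var[exact])
    kind[exact] = "exact"

    cen = status == CENSORED
    if cen.any():
        ystar = truncated_normal_mean(mu_cond[cen], model.sigma_, cq[cen], max_cq)
        value[cen] = ystar - adjustment[cen]
        se[cen] = np.sqrt(adj_var[cen] + model.sigma_**2)
        kind[cen] = "censored-interval"

    mis = status == MISSING
    if mis.any():
        # the (40, inf) interval informs the likelihood; the imputed value
        # is the model's most-likely level for the donor at that visit
        value[mis] = mu_cond[mis] - adjustment[mis]
        se[mis] = np.sqrt(adj_var[mis] + model.sigma_**2)
        kind[mis] = "missing-interval"

    out = data[["participant_id", "visit_index"]].copy()
    out["normalized_cq"] = value
    out["se"] = np.maximum(se, _SE_FLOOR)
    out["kind"] = kind
    return out


def normalize_study(
    study: StudyTable,
    covariates: pd.DataFrame,
    mirnas: list[str],
    max_cq: float = 40.0,
    n_quad: int = 15,
) -> NormalizationResult:
    """Fit the interval model and produce normalized values for each miRNA."""
    wells = study.wells
    frames = []
    summaries = []
    for mirna in sorted(mirnas):
        data = wells[wells["assay_id"] == mirna]
        model, _ = fit_interval_model(data, covariates, max_cq, n_quad)
        pred = predict_normalized(model, data, covariates, max_cq)
        pred = (
            pred.groupby(["participant_id", "visit_index"], as_index=False)
            .agg(normalized_cq=("normalized_cq", "mean"), se=("se", "mean"),
                 kind=("kind", "first"))
        )
        pred.insert(2, "mirna_id", mirna)
        frames.append(pred)
        summaries.append(
            {
                "mirna_id": mirna,
                "intercept": model.intercept_,
                **{f"beta_{c}": b for c, b in zip(COVARIATES, model.coef_)},
                "sigma": model.sigma_,
                "participant_sd": model.group_sd_,
                "loglik": model.loglik_,
            }
        )
    normalized = pd.concat(frames, ignore_index=True)
    return NormalizationResult(
        normalized=normalized, summaries=pd.DataFrame(summaries)
    )
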