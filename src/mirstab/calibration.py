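"""Technical calibration of Cq values.

Three sequential stages, each applying a per-sample (or per-batch) additive
shift so that within-sample contrasts between assays are untouched and no
reaction status ever changes:

1. *Spike-in median alignment.* A per-sample exogenous calibration factor -
   the average of the mean duplicate cel-miR-39-3p Cq and the median Cq over
   the always-observed miRNAs - is median-aligned across samples, removing
   shared RNA-isolation / qPCR-efficiency shifts.
2. *Sequence detrending.* Values centred per (donor, miRNA) are smoothed
   over the processing sequence with a local-constant Gaussian kernel
   (bandwidth by leave-one-out least-squares cross-validation) and the
   fitted curve is subtracted.
3. *Batch adjustment.* A REML mixed model on the kernel residuals with
   fixed effects for reaction status, a centred quadratic in the hemolysis
   score and technical flags, and a random intercept per RNA-isolation
   batch; the batch BLUPs are subtracted, and the result is recentred to
   the input's global median.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

from .datatypes import ACCEPTABLE, CENSORED, MIR16, SPIKEIN, StudyTable

_VALUED = (ACCEPTABLE, CENSORED)


def _sample_key(df: pd.DataFrame) -> pd.Series:
    return df["participant_id"].astype(str) + "|" + df["visit_index"].astype(str)


def exogenous_calibration_factor(
    study: StudyTable, always_observed: list[str]
) -> pd.DataFrame:
    """Per-sample calibration factor: average of the spike-in duplicate mean
    and the median Cq across the always-observed set."""
    if not always_observed:
        raise ValueError("always-observed set is empty; calibration factor undefined")
    wells = study.wells
    ok = wells[wells["status"] == ACCEPTABLE]

    spike = (
        ok[ok["assay_id"] == SPIKEIN]
        .groupby(["participant_id", "visit_index"])["cq"]
        .mean()
        .rename("spikein_mean")
    )
    med = (
        ok[ok["assay_id"].isin(always_observed)]
        .groupby(["participant_id", "visit_index", "assay_id"])["cq"]
        .mean()
        .groupby(["participant_id", "visit_index"])
        .median()
        .rename("always_observed_median")
    )
    out = study.sample_index().set_index(["participant_id", "visit_index"])
    out = out.join(spike).join(med)
    bad = out[out["spikein_mean"].isna()]
    if len(bad):
        raise ValueError(
            f"spike-in control not acceptable in sample(s) {list(bad.index[:5])}"
        )
    out["factor"] = (out["spikein_mean"] + out["always_observed_median"]) / 2.0
    return out.reset_index()


def median_align(study: StudyTable, factors: pd.DataFrame) -> tuple[StudyTable, dict]:
    """Shift every Cq in sample s by (median factor - factor_s).

    All wells of the sample (targets and controls, acceptable and censored)
    receive the identical shift; missing wells carry no value.
    """
    med = float(factors["factor"].median())
    shifts = factors.set_index(["participant_id", "visit_index"])["factor"].map(
        lambda f: med - f
    )
    wells = study.wells.copy()
    key = pd.MultiIndex.from_frame(wells[["participant_id", "visit_index"]])
    wells["cq"] = wells["cq"] + shifts.reindex(key).values
    audit = {
        "stage": "spikein_aligned",
        "global_median_factor": med,
        "shifts": {
            f"{p}|{v}": float(med - f)
            for (p, v), f in factors.set_index(
                ["participant_id", "visit_index"]
            )["factor"].items()
        },
    }
    return study.copy_with_wells(wells), audit


def control_correlations(
    study: StudyTable, always_observed: list[str]
) -> dict[str, float]:
    """Spearman diagnostics among per-sample control summaries:
    (a) always-observed median vs spike-in mean, (b) miR-16-5p mean vs
    spike-in mean. Apply to the raw study for the pre-calibration values or
    to an aligned study for the residual correlation."""
    wells = study.wells
    ok = wells[wells["status"] == ACCEPTABLE]

    def per_sample(assay_filter, agg="mean"):
        sub = ok[ok["assay_id"].isin(assay_filter)]
        per_assay = sub.groupby(
            ["participant_id", "visit_index", "assay_id"]
        )["cq"].mean()
        grouped = per_assay.groupby(["participant_id", "visit_index"])
        return grouped.median() if agg == "median" else grouped.mean()

    spike = per_sample([SPIKEIN])
    mir16 = per_sample([MIR16])
    med = per_sample(always_observed, agg="median")
    frame = pd.concat(
        {"spike": spike, "mir16": mir16, "median": med}, axis=1
    ).dropna()
    if len(frame) < 3:
        raise ValueError("need at least 3 samples for control correlations")
    r_med = float(spearmanr(frame["median"], frame["spike"]).statistic)
    r_16 = float(spearmanr(frame["mir16"], frame["spike"]).statistic)
    return {
        "always_observed_median_vs_spikein": r_med,
        "mir16_vs_spikein": r_16,
    }


class KernelDetrender(BaseEstimator):
    """Local-constant (Nadaraya-Watson) Gaussian kernel smoother over the
    processing sequence.

    The bandwidth is selected by leave-one-out least-squares
    cross-validation over a log-spaced grid spanning sub-position to
    full-range scales (an explicit grid avoids the local minima that
    derivative-based bandwidth searches fall into on strongly trended
    sequences). sklearn-style: ``fit(order, values)`` then ``predict``.
    """

    def __init__(self, bandwidth: float | None = None, n_grid: int = 30):
        self.bandwidth = bandwidth
        self.n_grid = n_grid

    @staticmethod
    def _weights(train, eval_pts, bw):
        d = (eval_pts[:, None] - train[None, :]) / bw
        return np.exp(-0.5 * d**2)

    def fit(self, order, values):
        order = np.asarray(order, dtype=float)
        values = np.asarray(values, dtype=float)
        if np.ptp(order) == 0:
            raise ValueError("processing order is constant; no sequence information")
        if self.bandwidth is not None:
            self.bandwidth_ = float(self.bandwidth)
        else:
            span = np.ptp(order)
            min_gap = max(np.min(np.diff(np.sort(np.unique(order)))), 1e-6)
            grid = np.geomspace(min_gap / 2.0, 2.0 * span, self.n_grid)
            best_bw, best_err = grid[-1], np.inf
            for bw in grid:
                w = self._weights(order, order, bw)
                np.fill_diagonal(w, 0.0)  # leave-one-out
                denom = w.sum(axis=1)
                ok = denom > 1e-12
                if ok.sum() < len(order) // 2:
                    continue
                pred = (w[ok] @ values) / denom[ok]
                err = float(np.mean((values[ok] - pred) ** 2))
                if err < best_err:
                    best_bw, best_err = float(bw), err
            self.bandwidth_ = best_bw
        self._train = (order, values)
        return self

    def predict(self, order):
        train, values = self._train
        w = self._weights(train, np.asarray(order, dtype=float), self.bandwidth_)
        denom = w.sum(axis=1)
        denom = np.where(denom > 1e-12, denom, np.nan)
        pred = (w @ values) / denom
        return np.where(np.isnan(pred), float(np.mean(values)), pred)


def sequence_detrend(
    study: StudyTable,
    assays: list[str],
    bandwidth: float | None = None,
) -> tuple[StudyTable, dict]:
    """Fit and subtract the processing-sequence trend.

    Values of the given (retained scientific) assays are centred by the
    (donor, miRNA) mean across visits; per-sample means of the centred
    values are smoothed over the processing order and the fitted curve value
    of each sample is subtracted from every well of that sample.
    """
    wells = study.wells
    sub = wells[
        wells["assay_id"].isin(assays) & wells["status"].isin(_VALUED)
    ].copy()
    centred = sub["cq"] - sub.groupby(["participant_id", "assay_id"])["cq"].transform(
        "mean"
    )
    sub = sub.assign(centred=centred)
    per_sample = (
        sub.groupby(["participant_id", "visit_index", "process_order"])["centred"]
        .mean()
        .reset_index()
    )
    if per_sample["process_order"].nunique() <= 1:
        warnings.warn("constant processing order; sequence detrend skipped")
        return study.copy_with_wells(wells.copy()), {
            "stage": "sequence_detrended",
            "skipped": True,
        }

    detr = KernelDetrender(bandwidth=bandwidth).fit(
        per_sample["process_order"], per_sample["centred"]
    )
    curve = detr.predict(per_sample["process_order"])
    per_sample["curve"] = curve

    out = wells.copy()
    curve_by_sample = per_sample.set_index(["participant_id", "visit_index"])["curve"]
    key = pd.MultiIndex.from_frame(out[["participant_id", "visit_index"]])
    out["cq"] = out["cq"] - curve_by_sample.reindex(key).values
    audit = {
        "stage": "sequence_detrended",
        "skipped": False,
        "bandwidth": detr.bandwidth_,
        "curve": per_sample[["process_order", "curve"]]
        .sort_values("process_order")
        .to_dict(orient="list"),
    }
    return study.copy_with_wells(out), audit


def batch_adjust(
    study: StudyTable,
    assays: list[str],
    hemolysis: pd.DataFrame,
    flag_token: str = "BASELINE_DISTANCE_GT8",
) -> tuple[StudyTable, dict]:
    """REML mixed model on the detrended residuals; subtract batch BLUPs and
    recentre to the input's global median.

    Fixed effects: reaction status (censored vs acceptable), centred
    hemolysis score and its square, and the baseline-distance technical
    flag. Random intercept: RNA-isolation batch. Samples without a
    hemolysis score use the cohort median (flagged in the audit).
    """
    wells = study.wells
    valued = wells["status"].isin(_VALUED)
    sub = wells[wells["assay_id"].isin(assays) & valued].copy()
    resid = sub["cq"] - sub.groupby(["participant_id", "assay_id"])["cq"].transform(
        "mean"
    )

    hem = hemolysis.set_index(["participant_id", "visit_index"])["score"]
    hem_med = float(hem.median()) if hem.notna().any() else 0.0
    key = pd.MultiIndex.from_frame(sub[["participant_id", "visit_index"]])
    hem_vals = hem.reindex(key).values
    n_imputed_hem = int(np.isnan(hem_vals).sum())
    hem_vals = np.where(np.isnan(hem_vals), hem_med, hem_vals)
    hem_c = hem_vals - hem_med

    exog = pd.DataFrame(
        {
            "const": 1.0,
            "censored": (sub["status"] == CENSORED).astype(float).values,
            "hemolysis": hem_c,
            "hemolysis_sq": hem_c**2,
            "flag": sub["qualitative_flags"]
            .fillna("")
            .str.contains(flag_token)
            .astype(float)
            .values,
        }
    )
    # drop constant columns (e.g. no censored wells in a tiny study)
    keep = ["const"] + [
        c for c in exog.columns[1:] if np.ptp(exog[c].to_numpy()) > 0
    ]
    exog = exog[keep]

    groups = sub["isolation_batch"].values
    labels = pd.unique(groups)
    input_median = float(wells.loc[valued & wells["assay_id"].isin(assays), "cq"].median())

    if len(labels) < 2:
        warnings.warn("single isolation batch; batch adjustment is a no-op")
        blups = {labels[0]: 0.0} if len(labels) else {}
        out = wells.copy()
    else:
        model = sm.MixedLM(resid.to_numpy(), exog.to_numpy(), groups=groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=True)
        if not np.all(np.isfinite(result.params)):
            raise RuntimeError(
                f"batch mixed model did not converge: params={result.params}"
            )
        try:
            blups = {g: float(re.iloc[0]) for g, re in result.random_effects.items()}
        except ValueError:
            # batch variance estimated at zero: no recoverable batch effects
            blups = {g: 0.0 for g in labels}
        out = wells.copy()
        shift = out["isolation_batch"].map(blups).fillna(0.0)
        out["cq"] = out["cq"] - shift

    out_valued = out["status"].isin(_VALUED) & out["assay_id"].isin(assays)
    recenter = input_median - float(out.loc[out_valued, "cq"].median())
    out["cq"] = out["cq"] + recenter

    audit = {
        "stage": "batch_adjusted",
        "blups": {str(k): v for k, v in blups.items()},
        "recentering_constant": recenter,
        "n_hemolysis_imputed": n_imputed_hem,
        "fixed_effect_columns": keep,
    }
    return study.copy_with_wells(out), audit


def shared_technical_sd(study: StudyTable, assays: list[str]) -> float:
    """SD of the per-sample mean of two-way (miRNA and donor) demeaned
    acceptable Cq residuals: the shared technical component the spike-in
    alignment targets."""
    wells = study.wells
    sub = wells[
        wells["assay_id"].isin(assays) & (wells["status"] == ACCEPTABLE)
    ].copy()
    r = (
        sub["cq"]
        - sub.groupby("assay_id")["cq"].transform("mean")
        - sub.groupby("participant_id")["cq"].transform("mean")
        + sub["cq"].mean()
    )
    per_sample = r.groupby(
        [sub["participant_id"], sub["visit_index"]]
    ).mean()
    return float(per_sample.std(ddof=1))
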