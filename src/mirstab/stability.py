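"""Per-miRNA longitudinal stability indexing.

For each miRNA the normalized Cq values are regressed on the visit sequence
within each donor; the per-donor trends are averaged and the variance of the
average is taken from a cluster-robust (Huber-White) sandwich over donors.
Residual variance around the average trend line is decomposed into a
between-participant component (stable donor differences) and the remaining
test-retest component, the key reliability index; both are reported as SDs
in Cq (log2 expression) units. A miRNA is called stable when both SDs are
strictly below the cutoff (1.0 by default). Average drift is re-expressed as
percentage change in expression per month treating expression as 2^-Cq.

A supremum scan over candidate breakpoints locates the mean-Cq threshold
with the sharpest contrast in measurement dropout rates below vs above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Average month length in days (Julian year / 12).
DAYS_PER_MONTH = 365.25 / 12.0


def drift_percent(slope_cq_per_visit, days_per_visit: float = 14.0):
    """Percent change in expression per month implied by a Cq-per-visit slope.

    Expression is 2**(-Cq), so a positive Cq slope is a negative expression
    drift: drift% = 100 * (2**(-slope_per_month) - 1).
    """
    slope_per_month = np.asarray(slope_cq_per_visit, dtype=float) * (
        DAYS_PER_MONTH / days_per_visit
    )
    return 100.0 * (2.0 ** (-slope_per_month) - 1.0)


def drift_to_cq_slope_per_day(drift_pct_per_month):
    """Inverse of :func:`drift_percent` on a per-day basis (generator use)."""
    d = np.asarray(drift_pct_per_month, dtype=float)
    slope_per_month = -np.log2(1.0 + d / 100.0)
    return slope_per_month / DAYS_PER_MONTH


@dataclass
class TrendFit:
    """Within-subject trend of one miRNA."""

    mirna_id: str
    slope: float                      # average Cq change per visit
    slope_se: float                   # cluster-robust (sandwich) SE
    participant_slopes: pd.Series     # per-donor slopes
    grand_mean: float                 # mean of donor means
    residuals: pd.DataFrame           # participant_id, visit_index, residual
    n_participants: int


@dataclass
class StabilityRecord:
    mirna_id: str
    grand_mean_cq: float
    drift_pct_per_month: float
    drift_se_pct: float
    total_residual_sd: float
    between_participant_sd: float
    test_retest_sd: float
    #: method-of-moments between-participant variance before clipping at
    #: zero; may be negative by sampling noise. Averaging this across
    #: replicate studies before taking the square root avoids the upward
    #: truncation bias of averaging clipped SDs.
    between_variance_unclipped: float
    mean_coverage: float
    stable: bool


@dataclass
class BreakpointResult:
    breakpoint_cq: float | None
    statistics: pd.DataFrame  # candidate, statistic

    @property
    def found(self) -> bool:
        return self.breakpoint_cq is not None


def fit_within_subject_trend(
    data: pd.DataFrame,
    value_col: str = "normalized_cq",
    weight_col: str | None = "weight",
) -> TrendFit:
    """Average of per-donor weighted least-squares slopes over visit sequence.

    ``data`` holds one miRNA: columns participant_id, visit_index, the value
    column and optionally an inverse-variance weight column. Donors with
    fewer than two visits (or no visit spread) are excluded from slope
    estimation with a warning. The sandwich variance of the average slope is
    the empirical variance of donor slopes divided by the donor count.
    """
    mirna = data["mirna_id"].iloc[0] if "mirna_id" in data.columns else ""
    slopes = {}
    fitted_rows = []
    for pid, grp in data.groupby("participant_id"):
        t = grp["visit_index"].to_numpy(dtype=float)
        y = grp[value_col].to_numpy(dtype=float)
        if weight_col and weight_col in grp.columns:
            w = grp[weight_col].to_numpy(dtype=float)
        else:
            w = np.ones_like(y)
        if len(grp) < 2 or np.ptp(t) == 0:
            warnings.warn(
                f"participant {pid} has <2 usable visits; excluded from trend",
                stacklevel=2,
            )
            continue
        tbar = np.average(t, weights=w)
        ybar = np.average(y, weights=w)
        denom = np.sum(w * (t - tbar) ** 2)
        slopes[pid] = float(np.sum(w * (t - tbar) * (y - ybar)) / denom)
        fitted_rows.append((pid, ybar))

    if len(slopes) < 2:
        raise ValueError("need at least two donors with >=2 visits each")

    slope_arr = np.array(list(slopes.values()))
    avg = float(slope_arr.mean())
    n = len(slope_arr)
    sandwich_var = float(np.sum((slope_arr - avg) ** 2) / (n * (n - 1)))

    donor_means = data.groupby("participant_id")[value_col].mean()
    grand_mean = float(donor_means.mean())

    # residuals about the grand line (donor offsets retained)
    tbar_all = float(data["visit_index"].mean())
    resid = data[["participant_id", "visit_index"]].copy()
    resid["residual"] = (
        data[value_col].to_numpy(dtype=float)
        - grand_mean
        - avg * (data["visit_index"].to_numpy(dtype=float) - tbar_all)
    )
    return TrendFit(
        mirna_id=str(mirna),
        slope=avg,
        slope_se=float(np.sqrt(sandwich_var)),
        participant_slopes=pd.Series(slopes),
        grand_mean=grand_mean,
        residuals=resid,
        n_participants=n,
    )


def _variance_components(residuals: pd.DataFrame) -> tuple[float, float, float]:
    """ANOVA (method-of-moments) decomposition of residual variance into
    between-participant and within-participant (test-retest) components.
    Unbalanced visit counts use the standard effective group size
    n0 = (N - sum n_i^2 / N) / (P - 1). Returns (between clipped at zero,
    within, between unclipped)."""
    grp = residuals.groupby("participant_id")["residual"]
    n_i = grp.count().to_numpy(dtype=float)
    means = grp.mean().to_numpy(dtype=float)
    N = float(n_i.sum())
    P = len(n_i)
    grand = float(residuals["residual"].mean())

    ss_within = float(
        ((residuals["residual"] - grp.transform("mean")) ** 2).sum()
    )
    if N - P <= 0:
        return 0.0, 0.0, 0.0
    var_within = ss_within / (N - P)
    if P < 2:
        return 0.0, var_within, 0.0
    ms_between = float(np.sum(n_i * (means - grand) ** 2) / (P - 1))
    n0 = (N - np.sum(n_i**2) / N) / (P - 1)
    raw = (ms_between - var_within) / n0
    return max(0.0, raw), var_within, raw


def stability_statistics(
    fit: TrendFit,
    mean_coverage: float,
    days_per_visit: float = 14.0,
    sd_cutoff: float = 1.0,
) -> StabilityRecord:
    """The five stability statistics for one miRNA.

    Total residual variance is the sum of the between-participant and
    test-retest components (the decomposition identity holds exactly).
    """
    var_between, var_within, var_between_raw = _variance_components(fit.residuals)
    between_sd = float(np.sqrt(var_between))
    within_sd = float(np.sqrt(var_within))
    total_sd = float(np.sqrt(var_between + var_within))
    drift = float(drift_percent(fit.slope, days_per_visit))
    # delta-method SE of the drift percentage
    dslope = DAYS_PER_MONTH / days_per_visit
    deriv = -np.log(2.0) * dslope * 2.0 ** (-fit.slope * dslope) * 100.0
    drift_se = float(abs(deriv) * fit.slope_se)
    record = StabilityRecord(
        mirna_id=fit.mirna_id,
        grand_mean_cq=fit.grand_mean,
        drift_pct_per_month=drift,
        drift_se_pct=drift_se,
        total_residual_sd=total_sd,
        between_participant_sd=between_sd,
        test_retest_sd=within_sd,
        between_variance_unclipped=float(var_between_raw),
        mean_coverage=float(mean_coverage),
        stable=classify_stable(within_sd, between_sd, sd_cutoff),
    )
    return record


def classify_stable(
    test_retest_sd: float, between_participant_sd: float, sd_cutoff: float = 1.0
) -> bool:
    """Stable = both SDs strictly below the cutoff."""
    return bool(test_retest_sd < sd_cutoff and between_participant_sd < sd_cutoff)


def analyze_stability(
    normalized: pd.DataFrame,
    coverage: pd.Series | dict | None = None,
    days_per_visit: float = 14.0,
    sd_cutoff: float = 1.0,
    sigma: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Run the trend + variance-component analysis for every miRNA.

    ``normalized`` is the long normalized matrix (participant_id,
    visit_index, mirna_id, normalized_cq, se). Observation weights are
    inverse total variance 1/(sigma_m^2 + se^2) using each miRNA's model
    residual SD when supplied.
    """
    coverage = coverage or {}
    sigma = sigma or {}
    records = []
    for mirna, grp in normalized.groupby("mirna_id", sort=True):
        grp = grp.copy()
        s2 = float(sigma.get(mirna, 0.0)) ** 2 if hasattr(sigma, "get") else 0.0
        if "se" in grp.columns:
            grp["weight"] = 1.0 / (s2 + grp["se"].to_numpy(dtype=float) ** 2 + 1e-12)
        fit = fit_within_subject_trend(grp)
        cov = coverage.get(mirna, np.nan) if hasattr(coverage, "get") else np.nan
        records.append(
            stability_statistics(fit, cov, days_per_visit, sd_cutoff).__dict__
        )
    return pd.DataFrame(records)


def breakpoint_supremum(
    mean_cq,
    dropout_count,
    total_count,
) -> BreakpointResult:
    """Supremum scan for the mean-Cq breakpoint in dropout rates.

    Every observed per-miRNA mean Cq is a candidate break; for each, the
    pooled dropout proportions of miRNAs at mean Cq <= candidate vs above
    are compared with a two-sample z statistic (difference in proportions
    over the pooled binomial SE). The candidate with the largest |z| wins;
    ties break toward the lower Cq. With no variation in dropout the break
    is undefined.
    """
    mean_cq = np.asarray(mean_cq, dtype=float)
    k = np.asarray(dropout_count, dtype=float)
    n = np.asarray(total_count, dtype=float)
    if len(mean_cq) < 10:
        raise ValueError("need at least 10 miRNAs for the breakpoint scan")
    if np.ptp(k / n) == 0:
        return BreakpointResult(None, pd.DataFrame(columns=["candidate", "statistic"]))

    order = np.argsort(mean_cq, kind="stable")
    cq_s, k_s, n_s = mean_cq[order], k[order], n[order]
    ck, cn = np.cumsum(k_s), np.cumsum(n_s)
    K, Ntot = ck[-1], cn[-1]

    rows = []
    for i in range(len(cq_s) - 1):  # both sides nonempty
        if i + 1 < len(cq_s) and cq_s[i] == cq_s[i + 1]:
            continue
        k1, n1 = ck[i], cn[i]
        k2, n2 = K - k1, Ntot - n1
        p1, p2 = k1 / n1, k2 / n2
        pbar = K / Ntot
        se = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        z = 0.0 if se == 0 else abs(p1 - p2) / se
        rows.append((cq_s[i], z))
    stats = pd.DataFrame(rows, columns=["candidate", "statistic"])
    best = stats["statistic"].to_numpy()
    # argmax with ties toward the lower candidate (rows are Cq-ascending)
    idx = int(np.argmax(best))
    return BreakpointResult(float(stats["candidate"].iloc[idx]), stats)
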