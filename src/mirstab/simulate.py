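"""Seeded synthetic longitudinal qPCR studies with full ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a latent Cq per target reaction

    Cq* = mu_m + a_pm + B_p + tau_pv + g_b + delta_m * h_pv
          + beta_m' x_pv + gamma_m * t_v + eps,   eps ~ N(0, sigma_m * mod_p)

with per-miRNA baseline mu_m, i.i.d. participant offsets a_pm, an optional
shared donor background B_p, a per-sample technical shift tau_pv tracked by
the spike-in, a residual isolation-batch effect g_b (not tracked by the
spike-in), per-miRNA hemolysis sensitivity delta_m, visit-varying metadata
effects, slow drift gamma_m, and heteroscedastic visit noise whose SD can be
moderated by donor-level factors. Reactions drop out ("missing") with
logistic probability in the latent Cq; surviving reactions with Cq* >= 34
are censored with recorded Cq = min(Cq*, 40). All recorded quantities carry
two decimals, as an instrument export would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .config import SimulationConfig, config_to_dict, _from_mapping
from .datatypes import (
    HEMOLYSIS_INSENSITIVE,
    HEMOLYSIS_SENSITIVE,
    MIR16,
    NEGATIVE,
    PARTICIPANT_COLUMNS,
    SAMPLE_COLUMNS,
    SET1,
    SET2,
    SPIKEIN,
    StudyTable,
)
from .ingest import DEFAULT_COLUMN_MAP, classify_wells, default_roster
from .stability import drift_to_cq_slope_per_day

# Fixed low baselines (cycles) for the named assays so that, at default
# noise, the hemolysis proxies and the endogenous normalizer sets are
# abundantly and near-always observed, as on the real card.
NAMED_BASELINES = {
    HEMOLYSIS_INSENSITIVE: 24.0,
    HEMOLYSIS_SENSITIVE: 24.0,
    SET1[0]: 23.0,
    SET1[1]: 23.5,
    SET2[0]: 24.5,
    SET2[1]: 25.0,
    SET2[2]: 25.5,
    SET2[3]: 26.0,
    SET2[4]: 26.5,
}

#: Cq shift added to wells carrying the baseline-distance technical flag.
BASELINE_FLAG_ARTIFACT_CQ = 0.2


@dataclass
class GroundTruth:
    """Latent truths of one simulated study, reproducible from the seed."""

    config: SimulationConfig
    assays: pd.DataFrame          # per-assay latent parameters
    participants: pd.DataFrame    # donor metadata + background
    participant_effects: pd.DataFrame  # a_pm for measurable assays
    samples: pd.DataFrame         # tau, hemolysis, batch, visit covariates
    batches: pd.DataFrame         # batch label -> g_b

    def to_json(self, path) -> None:
        payload = {
            "config": config_to_dict(self.config),
            "assays": self.assays.to_dict(orient="list"),
            "participants": self.participants.to_dict(orient="list"),
            "participant_effects": self.participant_effects.to_dict(orient="list"),
            "samples": self.samples.to_dict(orient="list"),
            "batches": self.batches.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        cfg = _from_mapping(SimulationConfig, payload["config"])
        return cls(
            config=cfg,
            assays=pd.DataFrame(payload["assays"]),
            participants=pd.DataFrame(payload["participants"]),
            participant_effects=pd.DataFrame(payload["participant_effects"]),
            samples=pd.DataFrame(payload["samples"]),
            batches=pd.DataFrame(payload["batches"]),
        )


def _assay_names(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Target assay names and a boolean measurable mask.

    The named proxy/normalizer assays are always part of the measurable set.
    """
    named = list(NAMED_BASELINES)
    if config.n_measurable < len(named):
        raise ValueError(
            f"n_measurable must be >= {len(named)} to accommodate the named "
            "proxy and normalizer assays"
        )
    n_generic = config.n_assays - len(named)
    generic = [f"miR-sim-{i:03d}" for i in range(1, n_generic + 1)]
    names = named + generic
    measurable = np.zeros(config.n_assays, dtype=bool)
    measurable[: config.n_measurable] = True
    return names, measurable


def simulate_study(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[StudyTable, GroundTruth]:
    """Generate one synthetic study and its ground truth.

    ``seed`` overrides ``config.seed``. Regeneration with the same config
    and seed is bit-identical.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_p = config.n_participants
    pids = [f"P{i:02d}" for i in range(1, n_p + 1)]
    visits = list(config.visits_per_participant)

    # ---- donors -------------------------------------------------------
    sex = np.array(["F"] * config.n_female + ["M"] * (n_p - config.n_female))
    rng.shuffle(sex)
    age = np.round(rng.uniform(*config.age_range, size=n_p), 1)
    regular_tobacco = np.zeros(n_p, dtype=bool)
    regular_tobacco[rng.choice(n_p, size=config.n_regular_tobacco, replace=False)] = True
    background = rng.normal(0.0, config.participant_background_sd, size=n_p)

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "sex": sex,
            "age": age,
            "regular_tobacco": regular_tobacco,
            "background": background,
        }
    )

    # ---- samples ------------------------------------------------------
    rows = []
    for i, pid in enumerate(pids):
        for v in range(1, visits[i] + 1):
            rows.append((pid, v, i))
    samples = pd.DataFrame(rows, columns=["participant_id", "visit_index", "p_idx"])
    n_s = len(samples)

    # qPCR run sequence: each donor's time course assayed together
    samples = samples.sort_values(["participant_id", "visit_index"]).reset_index(drop=True)
    samples["process_order"] = np.arange(1, n_s + 1)

    # RNA isolation sessions of batch_size consecutive samples, labelled
    # with synthetic date + half-day. "participant" mode isolates each
    # donor's time course together; "wave" mode isolates by visit round
    # across donors, so batch artifacts vary within a donor.
    if config.batch_mode == "wave":
        iso_order = samples.sort_values(
            ["visit_index", "participant_id"]
        ).index
    else:
        iso_order = samples.sort_values(
            ["participant_id", "visit_index"]
        ).index
    iso_rank = pd.Series(np.arange(n_s), index=iso_order).sort_index()
    if config.batch_mode == "participant":
        # never split a donor across isolation sessions
        batch_idx = np.empty(n_s, dtype=int)
        counter = 0
        for pid, grp in samples.groupby("participant_id", sort=True):
            n_chunks = int(np.ceil(len(grp) / config.batch_size))
            local = np.arange(len(grp)) // config.batch_size
            batch_idx[grp.index] = counter + local
            counter += n_chunks
    else:
        batch_idx = (iso_rank.to_numpy() // config.batch_size).astype(int)
    samples["isolation_batch"] = [
        f"2022-03-{1 + b // 2:02d}-{'AM' if b % 2 == 0 else 'PM'}" for b in batch_idx
    ]

    a, b = config.hemolysis_range
    if config.hemolysis_sd > 0:
        lo = (a - config.hemolysis_mean) / config.hemolysis_sd
        hi = (b - config.hemolysis_mean) / config.hemolysis_sd
        hemolysis = truncnorm.rvs(
            lo, hi, loc=config.hemolysis_mean, scale=config.hemolysis_sd,
            size=n_s, random_state=rng,
        )
    else:
        hemolysis = np.full(n_s, config.hemolysis_mean)
    samples["hemolysis_true"] = np.round(hemolysis, 3)
    samples["tau"] = rng.normal(0.0, config.sample_shift_sd, size=n_s)
    samples["fasting"] = rng.random(n_s) < config.fasting_prob
    samples["stress_level"] = rng.integers(1, 6, size=n_s)
    samples["sleep_quality"] = rng.integers(1, 6, size=n_s)
    reg = regular_tobacco[samples["p_idx"].values]
    samples["recent_tobacco"] = reg & (rng.random(n_s) < config.recent_use_prob)

    batch_labels = sorted(samples["isolation_batch"].unique())
    g = rng.normal(0.0, config.batch_sd, size=len(batch_labels))
    batches = pd.DataFrame({"isolation_batch": batch_labels, "effect": g})
    g_map = dict(zip(batch_labels, g))
    samples["batch_effect"] = samples["isolation_batch"].map(g_map)

    # ---- per-assay latent parameters ---------------------------------
    # Drawn from a dedicated stream when panel_seed is set, so replicate
    # studies (different seeds) can share one latent panel.
    rng_panel = (
        rng if config.panel_seed is None
        else np.random.default_rng(config.panel_seed)
    )
    names, measurable = _assay_names(config)
    n_a = config.n_assays
    mu = rng_panel.uniform(*config.baseline_cq_range, size=n_a)
    mu[~measurable] = rng_panel.uniform(38.0, 46.0, size=(~measurable).sum())
    for assay, value in NAMED_BASELINES.items():
        mu[names.index(assay)] = value

    sigma = rng_panel.uniform(*config.test_retest_sd_range, size=n_a)
    sigma[~measurable] = 0.5
    # the named proxy/normalizer assays are stable by selection (reported
    # normalizer test-retest SDs sit in the 0.24-0.49 range); clipped into
    # the configured range so degenerate zero-noise studies stay exact
    named_idx = [names.index(a) for a in NAMED_BASELINES]
    lo_sd, hi_sd = config.test_retest_sd_range
    sigma[named_idx] = np.clip(
        rng_panel.uniform(0.25, 0.5, size=len(named_idx)), lo_sd, hi_sd
    )
    drift_pct = rng_panel.uniform(*config.drift_pct_per_month_range, size=n_a)
    drift_pct[~measurable] = 0.0

    delta = np.zeros(n_a)
    delta[names.index(HEMOLYSIS_SENSITIVE)] = -1.0
    generic_measurable = np.flatnonzero(measurable)
    generic_measurable = generic_measurable[
        [names[i] not in NAMED_BASELINES for i in generic_measurable]
    ]
    n_sensitive = int(round(config.hemolysis_sensitive_fraction * config.n_measurable))
    n_sensitive = min(n_sensitive, len(generic_measurable))
    sens_idx = rng_panel.choice(generic_measurable, size=n_sensitive, replace=False)
    delta[sens_idx] = rng_panel.normal(
        config.hemolysis_delta_mean, config.hemolysis_delta_sd, size=n_sensitive
    )

    tobacco_bias_cq = np.zeros(n_a)
    n_tb = min(config.n_tobacco_bias_mirnas, len(generic_measurable))
    tb_idx = rng_panel.choice(generic_measurable, size=n_tb, replace=False)
    tobacco_bias_cq[tb_idx] = -config.tobacco_bias_log2  # expression up => Cq down

    tobacco_moderated = np.zeros(n_a, dtype=bool)
    n_tm = min(config.n_tobacco_moderated_mirnas, len(generic_measurable))
    tobacco_moderated[rng_panel.choice(generic_measurable, size=n_tm, replace=False)] = True
    sex_moderated = np.zeros(n_a, dtype=bool)
    n_sm = min(config.n_sex_moderated_mirnas, len(generic_measurable))
    sex_moderated[rng_panel.choice(generic_measurable, size=n_sm, replace=False)] = True

    assays = pd.DataFrame(
        {
            "assay_id": names,
            "measurable": measurable,
            "mu": mu,
            "sigma": sigma,
            "drift_pct_per_month": drift_pct,
            "hemolysis_delta": delta,
            "tobacco_bias_cq": tobacco_bias_cq,
            "tobacco_moderated": tobacco_moderated,
            "sex_moderated": sex_moderated,
        }
    )

    a_pm = rng.normal(0.0, config.participant_sd, size=(n_p, n_a))
    # the hemolysis proxy pair shares most of its donor-level background
    # (the score is a within-sample difference used precisely because it is
    # donor-stable); a small idiosyncratic part remains
    i23 = names.index(HEMOLYSIS_INSENSITIVE)
    i451 = names.index(HEMOLYSIS_SENSITIVE)
    shared = rng.normal(0.0, config.participant_sd, size=n_p)
    idio_sd = 0.15 * config.participant_sd / 0.4 if config.participant_sd > 0 else 0.0
    a_pm[:, i23] = shared + rng.normal(0.0, idio_sd, size=n_p)
    a_pm[:, i451] = shared + rng.normal(0.0, idio_sd, size=n_p)

    # ---- latent target Cq matrix (samples x assays) -------------------
    p_idx = samples["p_idx"].values
    day = (samples["visit_index"].values - 1) * config.days_per_visit
    slope_day = drift_to_cq_slope_per_day(drift_pct)  # cycles per day

    latent = (
        mu[None, :]
        + a_pm[p_idx, :]
        + background[p_idx, None]
        + samples["tau"].values[:, None]
        + samples["batch_effect"].values[:, None]
        + delta[None, :] * samples["hemolysis_true"].values[:, None]
        + tobacco_bias_cq[None, :] * samples["recent_tobacco"].values[:, None]
        - (config.fasting_bias_log2 * samples["fasting"].values[:, None]
           + config.stress_bias_log2 * (samples["stress_level"].values[:, None] - 3)
           + config.sleep_bias_log2 * (samples["sleep_quality"].values[:, None] - 3))
        * np.ones((1, n_a))
        + slope_day[None, :] * day[:, None]
        + config.sequence_trend_slope
        * (samples["process_order"].values[:, None] - (n_s + 1) / 2.0)
    )
    mod = (
        config.tobacco_moderation_factor
        ** (regular_tobacco[p_idx][:, None] & tobacco_moderated[None, :])
        * config.sex_moderation_factor
        ** ((sex[p_idx] == "M")[:, None] & sex_moderated[None, :])
    )
    noise_sd = sigma[None, :] * mod
    latent = latent + rng.standard_normal((n_s, n_a)) * noise_sd

    flagged = rng.random((n_s, n_a)) < config.baseline_flag_prob
    latent = latent + BASELINE_FLAG_ARTIFACT_CQ * flagged

    # ---- observation process -----------------------------------------
    if np.isinf(config.dropout_location):
        p_miss = np.zeros_like(latent)
    else:
        p_miss = expit((latent - config.dropout_location) / config.dropout_scale)
    is_missing = rng.random((n_s, n_a)) < p_miss
    recorded = np.round(np.minimum(latent, config.max_cq), 2)

    amp = np.round(rng.uniform(1.0, 2.0, size=(n_s, n_a)), 3)
    conf = np.round(rng.uniform(0.85, 1.0, size=(n_s, n_a)), 3)
    # failed wells: low AmpScore; half still carry a (meaningless) Cq
    amp[is_missing] = np.round(rng.uniform(0.0, 0.95, size=is_missing.sum()), 3)
    keep_cq = rng.random((n_s, n_a)) < 0.5
    recorded[is_missing & ~keep_cq] = np.nan

    target_wells = pd.DataFrame(
        {
            "participant_id": np.repeat(samples["participant_id"].values, n_a),
            "visit_index": np.repeat(samples["visit_index"].values, n_a),
            "assay_id": np.tile(names, n_s),
            "replicate_index": 1,
            "cq": recorded.ravel(),
            "amp_score": amp.ravel(),
            "cq_conf": conf.ravel(),
            "qualitative_flags": np.where(
                flagged.ravel(), "BASELINE_DISTANCE_GT8", ""
            ),
        }
    )

    # ---- control wells ------------------------------------------------
    def _control_block(assay: str, n_rep: int, visit_cq: np.ndarray, rep_sd: float,
                       acceptable: bool) -> pd.DataFrame:
        reps = np.arange(1, n_rep + 1)
        cq = visit_cq[:, None] + rng.normal(0.0, rep_sd, size=(n_s, n_rep))
        cq = np.round(np.minimum(cq, config.max_cq), 2)
        if acceptable:
            a_ = np.round(rng.uniform(1.2, 2.0, size=(n_s, n_rep)), 3)
            c_ = np.round(rng.uniform(0.9, 1.0, size=(n_s, n_rep)), 3)
        else:
            a_ = np.round(rng.uniform(0.0, 0.5, size=(n_s, n_rep)), 3)
            c_ = np.round(rng.uniform(0.0, 0.5, size=(n_s, n_rep)), 3)
            cq = np.full((n_s, n_rep), np.nan)
        return pd.DataFrame(
            {
                "participant_id": np.repeat(samples["participant_id"].values, n_rep),
                "visit_index": np.repeat(samples["visit_index"].values, n_rep),
                "assay_id": assay,
                "replicate_index": np.tile(reps, n_s),
                "cq": cq.ravel(),
                "amp_score": a_.ravel(),
                "cq_conf": c_.ravel(),
                "qualitative_flags": "",
            }
        )

    spike_visit = config.spikein_true_cq + samples["tau"].values
    if config.spikein_tracks_batch:
        spike_visit = spike_visit + samples["batch_effect"].values
    # miR-16-5p is not among the targets; give it its own donor offset
    mir16_offset = rng.normal(0.0, config.participant_sd, size=n_p)
    mir16_visit = (
        config.mir16_baseline_cq
        + mir16_offset[p_idx]
        + background[p_idx]
        + samples["tau"].values
        + samples["batch_effect"].values
        + rng.normal(0.0, config.control_noise_sd, size=n_s)
    )
    controls = pd.concat(
        [
            _control_block(SPIKEIN, 2, spike_visit, config.spikein_rep_sd, True),
            _control_block(MIR16, 5, mir16_visit, config.mir16_rep_sd, True),
            _control_block(NEGATIVE, 2, np.full(n_s, np.nan), 0.0, False),
        ],
        ignore_index=True,
    )

    wells = pd.concat([target_wells, controls], ignore_index=True)
    order_map = samples.set_index(["participant_id", "visit_index"])
    wells["process_order"] = order_map["process_order"].reindex(
        pd.MultiIndex.from_frame(wells[["participant_id", "visit_index"]])
    ).values
    wells["isolation_batch"] = order_map["isolation_batch"].reindex(
        pd.MultiIndex.from_frame(wells[["participant_id", "visit_index"]])
    ).values
    wells["status"] = classify_wells(wells)
    wells = wells.sort_values(
        ["participant_id", "visit_index", "assay_id", "replicate_index"]
    ).reset_index(drop=True)
    wells["process_order"] = wells["process_order"].astype(int)

    sample_table = samples[
        ["participant_id", "visit_index", "process_order", "isolation_batch",
         "fasting", "stress_level", "sleep_quality", "recent_tobacco"]
    ].copy()
    participant_table = participants[PARTICIPANT_COLUMNS].copy()

    roster = default_roster(wells["assay_id"])
    study = StudyTable(
        wells=wells[
            [
                "participant_id", "visit_index", "assay_id", "replicate_index",
                "cq", "amp_score", "cq_conf", "qualitative_flags",
                "process_order", "isolation_batch", "status",
            ]
        ],
        samples=sample_table,
        participants=participant_table,
        assay_roster=roster,
    )

    truth = GroundTruth(
        config=config,
        assays=assays,
        participants=participants,
        participant_effects=pd.DataFrame(
            {
                "participant_id": np.repeat(pids, int(measurable.sum())),
                "assay_id": np.tile(np.array(names)[measurable], n_p),
                "effect": a_pm[:, measurable].ravel(),
            }
        ),
        samples=samples[
            ["participant_id", "visit_index", "process_order", "isolation_batch",
             "tau", "batch_effect", "hemolysis_true", "fasting", "stress_level",
             "sleep_quality", "recent_tobacco"]
        ].copy(),
        batches=batches,
    )
    return study, truth


def write_study(study: StudyTable, ground_truth: GroundTruth, directory) -> list[Path]:
    """Write per-participant exports (ingest dialect), metadata tables and
    the ground-truth JSON. ``parse_expression_export`` round-trips the
    exports exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if study.n_samples == 0 or len(study.participant_ids) == 0:
        raise ValueError("refusing to write an empty study")

    inverse = {k: v for k, v in DEFAULT_COLUMN_MAP.items()}
    written = []
    for pid in study.participant_ids:
        part = study.wells[study.wells["participant_id"] == pid].copy()
        out = pd.DataFrame()
        for field, col in inverse.items():
            out[col] = part[field]
        out["Cq"] = out["Cq"].map(
            lambda v: "Undetermined" if pd.isna(v) else f"{v:.2f}"
        )
        path = directory / f"{pid}_export.csv"
        out.to_csv(path, index=False)
        written.append(path)

    study.samples.to_csv(directory / "samples.csv", index=False)
    study.participants.to_csv(directory / "participants.csv", index=False)
    ground_truth.to_json(directory / "groundtruth.json")
    return written


def read_metadata(directory) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the samples / participants metadata written by ``write_study``."""
    directory = Path(directory)
    samples = pd.read_csv(directory / "samples.csv")
    participants = pd.read_csv(directory / "participants.csv")
    return samples[SAMPLE_COLUMNS], participants[PARTICIPANT_COLUMNS]
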