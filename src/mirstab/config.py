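"""Configuration objects: QC thresholds, pipeline constants, and the
synthetic-study generator parameters.

Every constant of the analysis (QC acceptance thresholds, the censoring
boundary, the instrument maximum, the coverage cutoff, the hemolysis
threshold, the stability SD cutoff, the large-effect fold threshold, the
visit interval) is surfaced here as a named default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Coverage cutoff 1 - 1/e: the threshold approximating greedy sequential
#: selection of miRNAs by average longitudinal coverage.
COVERAGE_CUTOFF = 1.0 - 1.0 / np.e


@dataclass
class QCConfig:
    """Reaction-level QC acceptance thresholds (all inclusive)."""

    min_amp_score: float = 1.0
    min_cq_conf: float = 0.8
    censor_cq: float = 34.0
    max_cq: float = 40.0


@dataclass
class PipelineConfig:
    """Analysis constants for the full pipeline."""

    qc: QCConfig = field(default_factory=QCConfig)
    coverage_cutoff: float = COVERAGE_CUTOFF
    hemolysis_threshold: float = 7.0
    sd_cutoff: float = 1.0
    effect_flag_log2: float = float(np.log2(1.5))
    days_per_visit: float = 14.0
    baseline_distance_flag: str = "BASELINE_DISTANCE_GT8"


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic longitudinal qPCR study.

    Defaults emulate the study design: 22 donors sampled biweekly (4 with 5
    draws, 10 with 6, 8 with 7 = 136 draws), a 384-well card with 375 target
    assays plus miR-16-5p x5, cel-miR-39-3p x2 and ath-miR159a x2, ~134
    measurable targets, censoring at Cq 34 with instrument maximum 40, a
    shared per-sample technical shift tracked by the spike-in, residual
    isolation-batch effects, hemolysis scores ~1-10 with about a quarter of
    draws above 7, and dropout probability increasing in the latent Cq.
    """

    n_participants: int = 22
    visits_per_participant: tuple[int, ...] = (5,) * 4 + (6,) * 10 + (7,) * 8
    n_assays: int = 375
    n_measurable: int = 134
    baseline_cq_range: tuple[float, float] = (20.0, 36.0)
    participant_sd: float = 0.4
    participant_background_sd: float = 0.0
    test_retest_sd_range: tuple[float, float] = (0.2, 2.0)
    drift_pct_per_month_range: tuple[float, float] = (-0.5, 0.5)
    sample_shift_sd: float = 1.0
    batch_sd: float = 0.3
    batch_size: int = 8
    #: "participant": isolation batches group consecutive samples of one
    #: donor (each time course processed together); "wave": isolation
    #: sessions span donors by visit round, so batch artifacts vary within
    #: a donor's time course.
    batch_mode: str = "participant"
    #: spike-in is added before RNA isolation, so by default its Cq carries
    #: the isolation-batch effect; set False to model batch artifacts that
    #: arise downstream of the spike-in (e.g. qPCR run sessions).
    spikein_tracks_batch: bool = True
    sequence_trend_slope: float = 0.0
    # hemolysis: truncated-normal score distribution, P(score > 7) ~ 0.25
    hemolysis_mean: float = 5.8
    hemolysis_sd: float = 1.8
    hemolysis_range: tuple[float, float] = (0.5, 11.0)
    hemolysis_sensitive_fraction: float = 0.22
    hemolysis_delta_mean: float = -0.4
    hemolysis_delta_sd: float = 0.25
    # visit-varying metadata effects (Cq shift per indicator; expression is -Cq)
    n_tobacco_bias_mirnas: int = 20
    tobacco_bias_log2: float = 0.8
    n_tobacco_moderated_mirnas: int = 25
    tobacco_moderation_factor: float = 1.5
    n_sex_moderated_mirnas: int = 3
    sex_moderation_factor: float = 1.5
    fasting_bias_log2: float = 0.0
    stress_bias_log2: float = 0.0
    sleep_bias_log2: float = 0.0
    # cohort composition
    n_female: int = 15
    age_range: tuple[float, float] = (25.0, 65.0)
    n_regular_tobacco: int = 5
    recent_use_prob: float = 0.7
    fasting_prob: float = 0.8
    # dropout model: P(missing) = logistic((latent_cq - location) / scale)
    dropout_location: float = 34.0
    dropout_scale: float = 1.2
    censor_cq: float = 34.0
    max_cq: float = 40.0
    spikein_true_cq: float = 20.0
    spikein_rep_sd: float = 0.08
    mir16_baseline_cq: float = 20.5
    mir16_rep_sd: float = 0.1
    control_noise_sd: float = 0.1
    baseline_flag_prob: float = 0.02
    days_per_visit: float = 14.0
    seed: int = 0
    #: when set, the assay panel (baselines, noise SDs, drift, hemolysis
    #: sensitivities, affected subsets) is drawn from this seed while the
    #: study realization (donors, shifts, noise, dropout) follows ``seed``,
    #: so replicate studies share one latent panel.
    panel_seed: int | None = None

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if len(self.visits_per_participant) != self.n_participants:
            raise ValueError(
                "visits_per_participant must list one visit count per participant"
            )
        if any(v < 1 for v in self.visits_per_participant):
            raise ValueError("every participant needs at least one visit")
        if not (0 < self.n_measurable <= self.n_assays):
            raise ValueError("need 0 < n_measurable <= n_assays")
        for name in (
            "participant_sd",
            "participant_background_sd",
            "sample_shift_sd",
            "batch_sd",
            "hemolysis_sd",
            "spikein_rep_sd",
            "mir16_rep_sd",
            "control_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.test_retest_sd_range
        if lo < 0 or hi < lo:
            raise ValueError("test_retest_sd_range must be a nonnegative interval")
        for name in ("recent_use_prob", "fasting_prob", "baseline_flag_prob",
                     "hemolysis_sensitive_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_female > self.n_participants:
            raise ValueError("n_female cannot exceed n_participants")
        if self.batch_mode not in ("participant", "wave"):
            raise ValueError("batch_mode must be 'participant' or 'wave'")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.censor_cq > self.max_cq:
            raise ValueError("censor_cq cannot exceed max_cq")

    @property
    def n_samples(self) -> int:
        return int(sum(self.visits_per_participant))


def _from_mapping(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("visits_per_participant", "baseline_cq_range", "test_retest_sd_range",
                "drift_pct_per_month_range", "hemolysis_range", "age_range"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def simulation_config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_mapping(SimulationConfig, data)
    cfg.validate()
    return cfg


def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)
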