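"""Study-design and pipeline configuration.

The defaults encode the study design the pipeline emulates: ~55
participants carrying a phone GPS (10-s epochs) and a hip
accelerometer for 4 days (2 weekdays + 2 weekend days) in each of
three waves — first trimester (T1), third trimester (T3) and 4-6
months postpartum (PP) — inside a 10 km urban region on a 50 m
analysis grid.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

WAVES = ("T1", "T3", "PP")


@dataclass
class EffectTruth:
    """Ground-truth data-generating parameters for daily MVPA.

    Daily MVPA minutes are generated multiplicatively:
    ``exp(mean_log_mvpa + person_intercept + log(effects) + noise)``,
    so recovered mixed-model coefficients are directly comparable to
    these factors after exponentiation.
    """

    within_park_effect: float = 1.25  # multiplicative, on park-exposure days
    within_walkability_effect: float = 1.0  # multiplicative, per unit walkability deviation
    between_sd: float = 0.5  # SD of person intercepts on the log scale
    within_sd: float = 0.6  # SD of day-level log noise
    mean_log_mvpa: float = 3.4  # baseline ~ exp(3.4) = 30 min/day

    def __post_init__(self) -> None:
        if self.within_park_effect <= 0 or self.within_walkability_effect <= 0:
            raise ValueError("multiplicative effects must be positive")
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def icc(self) -> float:
        """Between-person share of log-outcome variance implied by the SDs."""
        b, w = self.between_sd**2, self.within_sd**2
        return b / (b + w)


@dataclass
class SyntheticConfig:
    """Design of one synthetic study."""

    n_participants: int = 55
    waves: tuple[str, ...] = WAVES
    days_per_wave: int = 4  # 2 weekday + 2 weekend
    region_extent: float = 10_000.0  # square side, metres
    cell_size: float = 50.0
    block_size: float = 200.0  # street-lattice block, metres
    tract_size: float = 1_000.0  # walkability patch side, metres
    n_parks: int = 3  # 1-4 rectangular parks
    waking_hours: float = 14.0
    walk_speed: float = 1.2  # m/s
    gps_jitter_sd: float = 10.0  # metres
    park_visit_prob: float = 0.5
    gps_lowcov_frac: float = 0.2  # fraction of days degraded below the 6-h GPS rule
    accel_nonwear_frac: float = 0.3  # fraction of days given a >60-min zero block
    accel_lowwear_frac: float = 0.25  # fraction of days degraded below 10 h wear
    temperature_mean: float = 19.9  # degrees C
    temperature_sd: float = 4.4
    seed: int = 0
    truth: EffectTruth = field(default_factory=EffectTruth)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.days_per_wave < 2:
            raise ValueError("days_per_wave must be >= 2")
        if self.region_extent <= 0 or abs(self.region_extent % self.cell_size) > 1e-9:
            raise ValueError("region_extent must be a positive multiple of cell_size")
        if not (1 <= self.n_parks <= 4):
            raise ValueError("n_parks must be in 1..4 (park distance undefined with no parks)")

    @property
    def n_days(self) -> int:
        return self.n_participants * len(self.waves) * self.days_per_wave


@dataclass
class ImputationParams:
    """Gap-filling rules for 10-s GPS streams.

    A stand-in for the cohort's unpublished imputation: gaps bounded by
    near-stationary fixes are dwell periods and are filled in place;
    short gaps while moving are bridged linearly; anything else is left
    missing.
    """

    stationary_gap_max: float = 240.0  # minutes
    stationary_radius: float = 100.0  # metres
    moving_gap_max: float = 10.0  # minutes

    def __post_init__(self) -> None:
        if min(self.stationary_gap_max, self.stationary_radius, self.moving_gap_max) <= 0:
            raise ValueError("imputation parameters must be positive")


@dataclass
class FreedsonParams:
    """Constants of the Freedson MET prediction equation and MVPA cut point."""

    intercept: float = 1.439008  # METs at zero counts/min
    slope: float = 0.000795  # METs per count/min
    mvpa_threshold: float = 4.0  # METs

    @property
    def mvpa_cpm(self) -> float:
        """Counts-per-minute at which predicted METs reach the MVPA threshold."""
        return (self.mvpa_threshold - self.intercept) / self.slope


@dataclass
class ActivitySpaceParams:
    method: str = "kde"  # kde | daily_path | residential_buffer
    kde_bandwidth: float = 250.0  # metres; sensitivity variant 100
    kde_kernel: str = "quartic"  # quartic | gaussian
    daily_path_radius: float = 250.0
    residential_radius: float = 800.0  # or 1600
    residential_mode: str = "euclidean"  # euclidean | network
    path_gap_break: float = 5.0  # minutes; longer observed gaps split the route


@dataclass
class ModelSpec:
    exposures: tuple[str, ...] = ("green_pct", "park_distance_m", "walkability", "parks_any")
    covariates: tuple[str, ...] = (
        "age",
        "education_college",
        "parity_firstborn",
        "bmi_overweight",
        "bmi_obese",
        "employed",
        "deprivation_index",
        "cohesion_safety",
        "weekend",
        "temperature_c",
        "wave_T3",
        "wave_PP",
        "wear_hours",
    )
    reml: bool = False  # main models by ML; the null ICC model always uses REML
    log_offset: float = 1.0  # outcome is log(minutes + offset)


@dataclass
class RunConfig:
    """Everything one end-to-end pipeline invocation needs."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    imputation: ImputationParams = field(default_factory=ImputationParams)
    activity_space: ActivitySpaceParams = field(default_factory=ActivitySpaceParams)
    freedson: FreedsonParams = field(default_factory=FreedsonParams)
    model: ModelSpec = field(default_factory=ModelSpec)
    seed: int = 0
    log_level: str = "INFO"


def _from_dict(cls, d: dict):
    kwargs = dict(d)
    for key, sub in (("truth", EffectTruth),):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = sub(**kwargs[key])
    for key in ("waves", "exposures", "covariates"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file; missing blocks take defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig(
        synthetic=_from_dict(SyntheticConfig, doc.get("synthetic", {})),
        imputation=_from_dict(ImputationParams, doc.get("gps", {})),
        activity_space=_from_dict(ActivitySpaceParams, doc.get("activity_space", {})),
        freedson=_from_dict(FreedsonParams, doc.get("accelerometry", {})),
        model=_from_dict(ModelSpec, doc.get("model", {})),
        seed=int(doc.get("seed", 0)),
        log_level=str(doc.get("log_level", "INFO")),
    )


def save_config(config: RunConfig, path) -> None:
    doc = {
        "synthetic": asdict(config.synthetic),
        "gps": asdict(config.imputation),
        "activity_space": asdict(config.activity_space),
        "accelerometry": asdict(config.freedson),
        "model": asdict(config.model),
        "seed": config.seed,
        "log_level": config.log_level,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
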