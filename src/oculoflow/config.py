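"""Configuration objects for every pipeline stage.

All defaults reproduce the study settings of the multiplication-with-
distractors paradigm: 250 Hz binocular sampling, 1920x1080 px display at
45 px per degree of visual angle, lambda = 6 velocity threshold, 1.5 deg
microsaccade boundary, 500 ms analysis bins and the two trial-wise
baseline windows. Simulator-only behavioural parameters (rates, noise
levels, amplitude distributions) are literature-plausible choices
documented in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Tuple


class ConfigurationError(ValueError):
    """Raised when a config object violates its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


def _finite(*values: float) -> bool:
    return all(math.isfinite(float(v)) for v in values)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic binocular recording generator.

    Geometry follows the study display (24-inch 1920x1080 screen, 531 mm
    wide, viewed at 70 cm, i.e. ~45 px per degree); everything describing
    oculomotor behaviour is a simulator choice.
    """

    sampling_rate: float = 250.0           # Hz
    px_per_deg: float = 45.0               # pixels per degree visual angle
    screen_size: Tuple[int, int] = (1920, 1080)
    screen_center: Tuple[float, float] = (960.0, 540.0)
    screen_width_mm: float = 531.0         # physical width, for px<->mm
    n_participants: int = 36
    trials_per_condition: int = 18         # multiplication trials per block
    passive_per_block: int = 4
    drift_sd: float = 0.004                # deg per sample, random-walk step
    tremor_sd: float = 0.015               # deg, white noise per eye
    microsaccade_rate: float = 1.2         # Hz, whole trial
    saccade_rate_idc: float = 0.5          # Hz, calculation period only
    blink_rate: float = 0.25               # Hz
    blink_duration_ms: Tuple[float, float] = (100.0, 300.0)
    main_sequence_slope: float = 60.0      # (deg/s) per deg amplitude
    micro_amplitude_lognorm: Tuple[float, float] = (math.log(0.4), 0.45)
    saccade_amplitude_lognorm: Tuple[float, float] = (math.log(3.0), 0.5)
    vergence_sd: float = 0.3               # mm, white fixation-disparity noise
    pupil_baseline: float = 4.0            # mm
    pupil_task_gain: float = 0.3           # mm, dilation amplitude during calculation
    pupil_distractor_gain: float = 0.1     # mm, transient evoked by the distractor
    pupil_noise_sd: float = 0.02           # mm, white per-eye noise
    accuracy: float = 0.85                 # P(correct) per multiplication trial
    forgot_given_error: float = 0.45       # P(forgot | not correct)
    rt_median_s: float = 2.65              # median calculation RT
    rt_log_sd: float = 0.35                # lognormal sigma of RT
    rt_min_s: float = 1.6                  # floor so analysis bins fit
    passive_duration_s: float = 5.0        # target interval in passive trials
    passive_invalid_p: float = 0.01        # P(passive trial response invalid)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(_finite(self.sampling_rate, self.px_per_deg, self.drift_sd,
                         self.tremor_sd, self.microsaccade_rate,
                         self.saccade_rate_idc, self.blink_rate,
                         self.main_sequence_slope, self.vergence_sd,
                         self.pupil_baseline, self.pupil_task_gain,
                         self.pupil_noise_sd),
                 "simulation parameters must be finite")
        _require(self.sampling_rate > 0, "sampling_rate must be > 0")
        _require(self.px_per_deg > 0, "px_per_deg must be > 0")
        _require(self.main_sequence_slope > 0, "main_sequence_slope must be > 0")
        for name in ("microsaccade_rate", "saccade_rate_idc", "blink_rate"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        lo, hi = self.blink_duration_ms
        _require(0 < lo <= hi, "blink_duration_ms range must be positive and ordered")
        _require(0 <= self.accuracy <= 1, "accuracy must be in [0, 1]")
        _require(self.n_participants >= 0 and self.trials_per_condition >= 0
                 and self.passive_per_block >= 0, "counts must be >= 0")

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def mm_per_px(self) -> float:
        return self.screen_width_mm / self.screen_size[0]


@dataclass
class ExclusionConfig:
    """Sample-level artifact rejection settings."""

    blink_pad_samples: int = 2       # extra samples masked on each blink side
    min_blink_run: int = 3           # invalid-pupil run length defining a blink
    pupil_max: float = 15.0          # mm
    pupil_min: float = 1.8           # mm
    disparity_max: float = 60.0      # mm, ~mean inter-pupil distance
    sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        _require(self.blink_pad_samples >= 0, "blink_pad_samples must be >= 0")
        _require(self.min_blink_run >= 1, "min_blink_run must be >= 1")
        _require(self.pupil_min < self.pupil_max, "pupil_min must be < pupil_max")
        _require(self.sd_multiplier > 0, "sd_multiplier must be > 0")


@dataclass
class DetectionConfig:
    """Velocity-threshold (micro)saccade detection settings."""

    lambda_: float = 6.0             # threshold multiplier on the median-based sigma
    min_duration_samples: int = 2    # 8 ms at 250 Hz
    binocular_min_overlap: int = 1   # samples
    micro_amplitude_max: float = 1.5  # deg; <= boundary counts as microsaccade
    velocity_window: int = 5         # samples of the moving-average differentiator

    def __post_init__(self) -> None:
        _require(self.lambda_ > 0, "lambda_ must be > 0")
        _require(self.min_duration_samples >= 1, "min_duration_samples must be >= 1")
        _require(self.binocular_min_overlap >= 1, "binocular_min_overlap must be >= 1")
        _require(self.micro_amplitude_max > 0, "micro_amplitude_max must be > 0")
        _require(self.velocity_window == 5, "only the 5-point differentiator is supported")


#: Analysis bins in ms relative to calculation onset (offset of second operand).
DEFAULT_BINS: Tuple[Tuple[float, float], ...] = (
    (-500.0, 0.0), (0.0, 500.0), (500.0, 1000.0), (1000.0, 1500.0),
)


@dataclass
class BinningConfig:
    """500 ms analysis bins and the gaze-at-center region."""

    bin_width_ms: float = 500.0
    bins: Tuple[Tuple[float, float], ...] = DEFAULT_BINS
    operand_bin_lag_ms: float = 100.0   # operand window starts 100 ms after op1 onset
    center_radius_deg: float = 1.0
    rate_multiplier: float = 2.0        # converts onsets / 500 ms to Hz

    def __post_init__(self) -> None:
        widths = {round(e - s, 9) for s, e in self.bins}
        _require(widths == {round(self.bin_width_ms, 9)},
                 "bins must all have width bin_width_ms")
        for (s0, e0), (s1, e1) in zip(self.bins, self.bins[1:]):
            _require(e0 == s1, "bins must be contiguous")


@dataclass
class BaselineConfig:
    """Trial-wise subtractive baseline windows.

    Pupil diameter and fixation disparity use the median of the 500 ms
    preceding the first operand; event rates and gaze-at-center use the
    whole 2 s presentation of the multiplication sign.
    """

    continuous_window_ms: float = 500.0   # before op1 onset; statistic = median
    rate_window_ms: float = 2000.0        # sign presentation; statistic = mean rate/s

    def __post_init__(self) -> None:
        _require(self.continuous_window_ms > 0 and self.rate_window_ms > 0,
                 "baseline windows must be positive")


@dataclass
class BayesConfig:
    """JZS default Bayes factor settings (Cauchy prior on effect size)."""

    prior_scale: float = 0.707
    rel_tol: float = 1e-6

    def __post_init__(self) -> None:
        _require(self.prior_scale > 0, "prior_scale must be > 0")
        _require(self.rel_tol > 0, "rel_tol must be > 0")


@dataclass
class RunConfig:
    """Top-level pipeline configuration (all stage configs + run options)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    bayes: BayesConfig = field(default_factory=BayesConfig)
    seed: int = 0
    outdir: str = "results"
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build from nested dicts (e.g. parsed YAML); unknown keys rejected."""
        sections = {
            "simulation": SimulationConfig, "exclusion": ExclusionConfig,
            "detection": DetectionConfig, "binning": BinningConfig,
            "baseline": BaselineConfig, "bayes": BayesConfig,
        }
        kwargs: dict = {}
        for key, value in data.items():
            if key in sections:
                klass = sections[key]
                fields_ = {f for f in klass.__dataclass_fields__}
                unknown = set(value) - fields_
                if unknown:
                    raise ConfigurationError(
                        f"unknown keys in section '{key}': {sorted(unknown)}")
                value = {k: (tuple(v) if isinstance(v, list) else v)
                         for k, v in value.items()}
                kwargs[key] = klass(**value)
            elif key in ("seed", "outdir", "verbosity"):
                kwargs[key] = value
            else:
                raise ConfigurationError(f"unknown config section '{key}'")
        return cls(**kwargs)
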