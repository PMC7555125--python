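"""Synthetic breath-record generator.

The study data behind this pipeline — 59 subjects, 36 with confirmed
respiratory-tract malignancies and 23 controls — were never deposited, so
every downstream stage is exercised on synthetic cohorts that reproduce
the *structure* the analysis relies on:

* the thermal-cycling waveform: 3.5 s heating (rising saturation curve)
  followed by 5.5 s cooling (exponential decay toward a per-sensor floor),
  270 samples per period at 30 Hz;
* the meander synchronization channels: a fixed positive level during
  every heating phase, zero during cooling, with the first heat-to-cool
  transition at the 5000 ms mark (sample 150), where the sample valve
  opens;
* a class-dependent multiplicative gas response: from the end of the
  injection cooling phase each sensor's signal is scaled by
  ``exp(w(t) * (gamma_s + beta_s * effect_size * label + eps_s))`` where
  ``w(t)`` ramps linearly from 0 to 1 over one thermal period (the
  chamber equilibrating), ``gamma_s`` is the sensor's label-independent
  response to breath, ``beta_s`` its sensitivity to the disease signature
  and ``eps_s ~ N(0, subject_sd)`` between-subject biological variability;
* additive Gaussian ADC noise and a slow multiplicative per-cycle drift.

The cooling phase of the period containing the injection is therefore a
clean pre-exposure baseline, and from the third complete period onward the
response is fully equilibrated — which is what makes the period-4 /
period-1 cooling-segment ratio an informative response feature.

Only a subset of sensors carries the disease signature (``beta_s``
markedly positive for seven of the fourteen, near zero for the rest),
mimicking volatile-organic-compound markers visible to some sensor
chemistries and not others.  The per-sensor template and response
coefficients are package constants chosen for plausibility; real
per-sensor response magnitudes are unpublished.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional

import numpy as np
import yaml

from .exceptions import ConfigError
from .records import (
    ADC_MAX,
    CHANNEL_NAMES,
    N_SAMPLES,
    N_SENSORS,
    SAMPLE_RATE_HZ,
    Cohort,
    SensorRecord,
)

# Per-sensor waveform template and response coefficients, one row per gas
# sensor in channel order: signal floor and heating amplitude in ADC
# counts, heating rise and cooling decay time constants in seconds,
# disease-response coefficient beta (log-ratio per unit effect size) and
# breath-response coefficient gamma (log response to any breath sample).
_SENSOR_PARAMS = np.array(
    # floor   amp   rise_tau cool_tau  beta   gamma
    [
        [220.0,  900.0, 1.2, 2.0, 0.30, 0.45],   # MP503
        [180.0,  760.0, 0.9, 1.6, 0.24, 0.35],   # WSP2110
        [260.0, 1020.0, 1.5, 2.4, 0.33, 0.50],   # MQ3
        [300.0,  840.0, 1.1, 1.9, 0.21, 0.30],   # MQ2
        [150.0,  680.0, 0.8, 1.4, 0.27, 0.25],   # MQ7
        [340.0,  590.0, 1.3, 2.2, 0.18, 0.20],   # MQ131
        [210.0,  950.0, 1.0, 1.8, 0.35, 0.40],   # MQ135
        [190.0,  720.0, 1.4, 2.1, 0.015, 0.30],  # MQ8
        [280.0,  880.0, 1.2, 2.0, 0.010, 0.45],  # MQ138
        [240.0, 1050.0, 0.9, 1.7, 0.020, 0.55],  # TGS822
        [170.0,  800.0, 1.1, 2.3, 0.005, 0.35],  # TGS2602
        [230.0,  930.0, 1.3, 1.9, 0.012, 0.40],  # TGS2620
        [200.0,  760.0, 1.0, 1.5, 0.000, 0.30],  # TGS2600
        [260.0,  980.0, 1.2, 2.2, 0.018, 0.50],  # TGS2603
    ]
)

SENSOR_FLOOR = _SENSOR_PARAMS[:, 0]
SENSOR_AMPLITUDE = _SENSOR_PARAMS[:, 1]
SENSOR_RISE_TAU_S = _SENSOR_PARAMS[:, 2]
SENSOR_COOL_TAU_S = _SENSOR_PARAMS[:, 3]
SENSOR_BETA = _SENSOR_PARAMS[:, 4]
SENSOR_GAMMA = _SENSOR_PARAMS[:, 5]


@dataclass
class SynthConfig:
    """Generator configuration.

    Defaults reproduce the study conditions: 36 cancer and 23 control
    subjects with the published sex and age-band composition.
    ``demographics`` selects how age/sex relate to the label:

    * ``"study"`` — cancer group 6 F / 30 M (2 subjects aged 20-40, 34
      aged 40-75); control group 16 F / 7 M (14 aged 20-40, 9 aged
      40-50).  Age and sex are then themselves predictive, as in the
      study population.
    * ``"balanced"`` — age and sex drawn identically for both classes,
      so only the sensor signal carries label information (used for
      null-signal and signal-recovery experiments).
    """

    n_cancer: int = 36
    n_control: int = 23
    effect_size: float = 0.5
    noise_sd: float = 8.0
    subject_sd: float = 0.15
    drift_per_cycle: float = 0.005
    injection_time_ms: int = 5000
    heat_ms: int = 3500
    cool_ms: int = 5500
    sync_high: float = 1000.0
    demographics: str = "study"
    smoking_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.heat_ms + self.cool_ms != 9000:
            raise ConfigError(
                f"heat_ms + cool_ms must equal 9000 ms (one thermal period), "
                f"got {self.heat_ms} + {self.cool_ms}"
            )
        if self.n_cancer + self.n_control < 2:
            raise ConfigError("need at least 2 subjects in total")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ConfigError("noise_sd and subject_sd must be >= 0")
        if self.sync_high <= 0 or self.sync_high > ADC_MAX:
            raise ConfigError(f"sync_high must be in (0, {ADC_MAX:g}]")
        if self.demographics not in ("study", "balanced"):
            raise ConfigError(
                f"demographics must be 'study' or 'balanced', got {self.demographics!r}"
            )
        if not 0 <= self.smoking_rate <= 1:
            raise ConfigError("smoking_rate must be in [0, 1]")

    # -- derived acquisition geometry -------------------------------------
    @property
    def heat_samples(self) -> int:
        return self.heat_ms * SAMPLE_RATE_HZ // 1000

    @property
    def cool_samples(self) -> int:
        return self.cool_ms * SAMPLE_RATE_HZ // 1000

    @property
    def period_samples(self) -> int:
        return self.heat_samples + self.cool_samples

    @property
    def injection_sample(self) -> int:
        """Sample index of the heat->cool transition at which the valve opens."""
        return self.injection_time_ms * SAMPLE_RATE_HZ // 1000

    @property
    def first_heat_start(self) -> int:
        """Start of the heating phase that ends at the injection instant."""
        return self.injection_sample - self.heat_samples

    def true_cycle_starts(self) -> List[int]:
        """Ground-truth cooling-phase start indices of all complete cycles."""
        starts = []
        s = self.injection_sample
        while s + self.cool_samples <= N_SAMPLES:
            starts.append(s)
            s += self.period_samples
        return starts

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "SynthConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SynthConfig field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def _phase_template(config: SynthConfig) -> np.ndarray:
    """Per-sensor periodic waveform, shape (14, 2700), before response/noise.

    The waveform is a pure function of heater phase, so cooling segments
    are identical across cycles (drift and gas response are applied on
    top of it).
    """
    t = np.arange(N_SAMPLES)
    phase = (t - config.first_heat_start) % config.period_samples
    heating = phase < config.heat_samples
    th = phase / SAMPLE_RATE_HZ  # seconds into heating phase
    tc = (phase - config.heat_samples) / SAMPLE_RATE_HZ  # seconds into cooling

    floor = SENSOR_FLOOR[:, None]
    amp = SENSOR_AMPLITUDE[:, None]
    peak = SENSOR_FLOOR + SENSOR_AMPLITUDE * (
        1.0 - np.exp(-(config.heat_ms / 1000.0) / SENSOR_RISE_TAU_S)
    )
    heat_curve = floor + amp * (1.0 - np.exp(-th[None, :] / SENSOR_RISE_TAU_S[:, None]))
    cool_curve = floor + (peak[:, None] - floor) * np.exp(
        -tc[None, :] / SENSOR_COOL_TAU_S[:, None]
    )
    return np.where(heating[None, :], heat_curve, cool_curve)


def _response_weight(config: SynthConfig) -> np.ndarray:
    """Ramp w(t): 0 through the injection cooling phase, then linear to 1
    over one thermal period, then 1."""
    t = np.arange(N_SAMPLES)
    onset = config.injection_sample + config.cool_samples
    return np.clip((t - onset) / config.period_samples, 0.0, 1.0)


def generate_record(
    config: SynthConfig,
    label: int,
    age: int,
    sex: str,
    smoking: str,
    rng: np.random.Generator,
    record_id: str = "synthetic-0",
) -> SensorRecord:
    """Generate a single synthetic acquisition for one subject."""
    config.validate()
    if label not in (0, 1):
        raise ConfigError(f"label must be 0 or 1, got {label!r}")

    template = _phase_template(config)
    w = _response_weight(config)

    eps = rng.normal(0.0, config.subject_sd, size=N_SENSORS)
    log_response = SENSOR_GAMMA + SENSOR_BETA * config.effect_size * label + eps
    response = np.exp(log_response[:, None] * w[None, :])

    t = np.arange(N_SAMPLES)
    cycle = np.maximum((t - config.first_heat_start) // config.period_samples, 0)
    drift = (1.0 + config.drift_per_cycle) ** cycle

    signal = template * response * drift[None, :]
    signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    signal = np.clip(signal, 0.0, ADC_MAX)

    phase = (t - config.first_heat_start) % config.period_samples
    sync = np.where(phase < config.heat_samples, config.sync_high, 0.0)

    channels = np.vstack([signal, sync, sync])
    return SensorRecord(
        record_id=record_id,
        channels=channels,
        age=int(age),
        sex=sex,
        smoking=smoking,
        label=int(label),
        channel_names=CHANNEL_NAMES,
    )


def _draw_demographics(config: SynthConfig, rng: np.random.Generator):
    """Return (label, age, sex, smoking) tuples, cancer subjects first."""
    subjects = []
    if config.demographics == "study":
        sexes_ca = rng.permutation(["F"] * 6 + ["M"] * 30)[: config.n_cancer]
        ages_ca = rng.permutation(
            np.concatenate([rng.integers(20, 41, 2), rng.integers(40, 76, 34)])
        )[: config.n_cancer]
        sexes_co = rng.permutation(["F"] * 16 + ["M"] * 7)[: config.n_control]
        ages_co = rng.permutation(
            np.concatenate([rng.integers(20, 41, 14), rng.integers(40, 51, 9)])
        )[: config.n_control]
        # For non-default group sizes, top up by resampling from the bands.
        while len(sexes_ca) < config.n_cancer:
            sexes_ca = np.append(sexes_ca, rng.choice(["F", "M"], p=[6 / 36, 30 / 36]))
            ages_ca = np.append(ages_ca, rng.integers(40, 76))
        while len(sexes_co) < config.n_control:
            sexes_co = np.append(sexes_co, rng.choice(["F", "M"], p=[16 / 23, 7 / 23]))
            ages_co = np.append(ages_co, rng.integers(20, 41))
    else:
        sexes_ca = rng.choice(["F", "M"], size=config.n_cancer)
        ages_ca = rng.integers(20, 76, config.n_cancer)
        sexes_co = rng.choice(["F", "M"], size=config.n_control)
        ages_co = rng.integers(20, 76, config.n_control)

    for i in range(config.n_cancer):
        smoking = "yes" if rng.random() < config.smoking_rate else "no"
        subjects.append((1, int(ages_ca[i]), str(sexes_ca[i]), smoking))
    for i in range(config.n_control):
        smoking = "yes" if rng.random() < config.smoking_rate else "no"
        subjects.append((0, int(ages_co[i]), str(sexes_co[i]), smoking))
    return subjects


def generate_cohort(config: Optional[SynthConfig] = None) -> Cohort:
    """Generate a full synthetic cohort (deterministic given ``config.seed``)."""
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = _draw_demographics(config, rng)
    records = []
    n_ca = n_co = 0
    for label, age, sex, smoking in subjects:
        if label == 1:
            n_ca += 1
            rid = f"case-{n_ca:02d}"
        else:
            n_co += 1
            rid = f"ctrl-{n_co:02d}"
        records.append(
            generate_record(config, label, age, sex, smoking, rng, record_id=rid)
        )
    return Cohort(
        records=records,
        provenance="synthetic",
        generator_config_hash=config.config_hash(),
    )
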