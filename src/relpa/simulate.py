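"""Synthetic cohort, session and multimodal trial-signal generator.

The generator emulates a field protocol in which adult volunteers complete
weekly sessions of five self-paced ambulatory trials (quiet sit/stand,
comfortable walk, brisk walk, jog, fast run) while wearing a chest-strap
heart-rate monitor (HR at 1 Hz plus beat-to-beat RR intervals) and a wrist
device recording electrodermal activity (EDA, uS) and skin temperature
(deg C) at 4 Hz, rating each trial on the Borg 6-20 RPE scale afterwards.

The physiological model is deliberately minimal: first-order exponential HR
kinetics toward an intensity-dependent steady state, a beat-by-beat RR point
process whose variability shrinks with intensity (a vagal-withdrawal
analogue) and carries a respiratory high-frequency oscillation, a tonic EDA
rise with intensity, and a slow skin-temperature drift. These are the
simplest mechanisms that reproduce the qualitative structure the downstream
analysis relies on: heart-derived features track relative strain closely,
EDA less so, temperature least.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import ConfigError, DataError, DomainError

__all__ = [
    "TRIAL_TYPES",
    "ParticipantProfile",
    "SimulationConfig",
    "TrialRecord",
    "Study",
    "hr_max",
    "simulate_cohort",
    "simulate_trial",
    "assign_rpe",
    "simulate_study",
]

#: Trial types in order of intended intensity.
TRIAL_TYPES = ("sit_stand", "comfortable_walk", "brisk_walk", "jog", "run")

#: Protocol trial plan: (trial_type, duration in seconds).
DEFAULT_TRIAL_PLAN = (
    ("sit_stand", 300),
    ("comfortable_walk", 300),
    ("brisk_walk", 300),
    ("jog", 180),
    ("run", 120),
)

#: Target fraction of heart-rate reserve reached at steady state, per trial
#: type, before scaling by the participant's `fitness` (self-selected pace).
DEFAULT_INTENSITY_FRACTIONS = {
    "sit_stand": 0.05,
    "comfortable_walk": 0.35,
    "brisk_walk": 0.55,
    "jog": 0.75,
    "run": 0.90,
}

HR_FS = 1.0  # Hz, chest-strap HR stream
EDA_FS = 4.0  # Hz, wrist EDA and skin-temperature streams


def hr_max(age: float) -> float:
    """Age-predicted maximal heart rate, Tanaka form: 208 - 0.7 * age (bpm)."""
    if age <= 0:
        raise DomainError(f"age must be positive, got {age}")
    return 208.0 - 0.7 * age


@dataclass(frozen=True)
class ParticipantProfile:
    """Anthropometric and fitness attributes of one simulated volunteer."""

    participant_id: str
    age: int  # years
    sex: str  # "male" | "female"
    height: float  # cm
    weight: float  # kg
    bmi: float  # kg/m^2
    pa_status: str  # "sedentary" | "insufficiently_active" | "sufficiently_active"
    hr_rest: float  # bpm
    fitness: float  # (0, 1]; scales self-selected trial intensity

    def __post_init__(self):
        expected_bmi = self.weight / (self.height / 100.0) ** 2
        if abs(expected_bmi - self.bmi) > 1e-6:
            raise ConfigError("bmi", f"bmi {self.bmi} inconsistent with height/weight")
        if not (30.0 <= self.hr_rest < hr_max(self.age)):
            raise ConfigError("hr_rest", f"resting HR {self.hr_rest} outside [30, hr_max)")
        if not (0.0 < self.fitness <= 1.0):
            raise ConfigError("fitness", f"fitness {self.fitness} outside (0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults reproduce the protocol scale of the emulated study: 22
    participants, up to 7 weekly sessions of 5 trials, and per-stage trial
    loss rates matching its exclusion ledger (109 of 770 scheduled trials
    missing/incomplete, 21 of the remaining 661 with missing sensor data,
    25 of the remaining 640 with invalid RPE).
    """

    n_participants: int = 22
    n_sessions: int = 7
    trial_plan: tuple = DEFAULT_TRIAL_PLAN
    intensity_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_FRACTIONS)
    )
    tau_hr: float = 40.0  # s, HR on-kinetics time constant
    tau_eda: float = 60.0  # s
    tau_temp: float = 120.0  # s
    hr_noise: float = 1.5  # bpm, white measurement noise on the 1 Hz stream
    rr_cv: float = 0.05  # resting beat-to-beat coefficient of variation
    rr_hf_amp: float = 30.0  # ms, resting respiratory-oscillation amplitude
    rr_hf_freq: float = 0.25  # Hz, respiratory frequency
    eda_gain: float = 6.0  # uS tonic rise at full intensity
    eda_noise: float = 0.05  # uS
    temp_gain: float = 0.8  # deg C drift at full intensity
    temp_noise: float = 0.05  # deg C
    rpe_sigma: float = 0.7  # Borg points, perceptual noise
    missing_trial_rate: float = 109.0 / 770.0
    missing_sensor_rate: float = 21.0 / 661.0
    invalid_rpe_rate: float = 25.0 / 640.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_participants < 0:
            raise ConfigError("n_participants", "must be >= 0")
        if self.n_sessions < 0:
            raise ConfigError("n_sessions", "must be >= 0")
        for trial_type, duration in self.trial_plan:
            if trial_type not in TRIAL_TYPES:
                raise ConfigError("trial_plan", f"unknown trial type {trial_type!r}")
            if duration <= 20:
                raise ConfigError(
                    "trial_plan",
                    f"duration {duration}s for {trial_type} must exceed 20 s "
                    "(must survive 10 s trimming at each end)",
                )
        for name in ("missing_trial_rate", "missing_sensor_rate", "invalid_rpe_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(name, f"rate {rate} outside [0, 1]")
        for name in ("hr_noise", "rr_cv", "eda_noise", "temp_noise", "rpe_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "noise level must be >= 0")
        if self.tau_hr <= 0:
            raise ConfigError("tau_hr", "time constant must be positive")

    def noiseless(self) -> "SimulationConfig":
        """Copy with all stochastic signal components switched off."""
        return replace(
            self,
            hr_noise=0.0,
            rr_cv=0.0,
            eda_noise=0.0,
            temp_noise=0.0,
            rpe_sigma=0.0,
            missing_trial_rate=0.0,
            missing_sensor_rate=0.0,
            invalid_rpe_rate=0.0,
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "trial_plan" in raw:
            raw["trial_plan"] = tuple((t, d) for t, d in raw["trial_plan"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            k: (list(map(list, v)) if k == "trial_plan" else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class TrialRecord:
    """One activity trial: raw multimodal signals plus its RPE label."""

    participant_id: str
    session_index: int  # 1-based
    trial_type: str
    hr: np.ndarray  # bpm at 1 Hz
    rr: np.ndarray  # RR intervals, ms, beat order
    eda: np.ndarray  # uS at 4 Hz
    temp: np.ndarray  # deg C at 4 Hz
    rpe: int | None  # Borg 6-20, None when missing
    status: str = "complete"  # complete | missing_trial | missing_sensor | invalid_rpe

    @property
    def duration(self) -> float:
        """Trial duration in seconds, from the 1 Hz HR stream."""
        return float(len(self.hr)) / HR_FS


@dataclass
class Study:
    """A full synthetic (or re-loaded) study: cohort plus all trial records."""

    participants: list
    records: list

    def profile(self, participant_id: str) -> ParticipantProfile:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)


def _participant_constants(participant_id: str) -> dict:
    """Stable per-person signal baselines derived from the participant id.

    Using a hash keeps EDA/temperature baselines identical across that
    person's trials without adding device-level fields to the profile.
    """
    seed = zlib.crc32(participant_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    return {
        "eda_base": 0.2 + 0.8 * rng.uniform(),  # uS tonic baseline at rest
        "eda_gain_mult": rng.uniform(0.7, 1.3),
        "temp_base": 32.5 + rng.uniform(),  # deg C wrist skin temperature
    }


def simulate_cohort(config: SimulationConfig) -> list:
    """Draw the participant cohort.

    Ages ~ Normal(29.8, 3.2) rounded and clamped to the 18-40 inclusion
    window; BMI ~ Normal(25.3, 2.6); P(male) = 0.773. Deterministic given
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    profiles = []
    for i in range(config.n_participants):
        age = int(np.clip(np.round(rng.normal(29.8, 3.2)), 18, 40))
        sex = "male" if rng.uniform() < 0.773 else "female"
        height = rng.normal(178.0, 7.0) if sex == "male" else rng.normal(165.0, 6.0)
        height = float(np.clip(height, 150.0, 200.0))
        bmi = float(np.clip(rng.normal(25.3, 2.6), 18.0, 35.0))
        weight = bmi * (height / 100.0) ** 2
        hr_rest = float(np.clip(rng.normal(62.0, 7.0), 45.0, 85.0))
        fitness = float(rng.uniform(0.75, 1.0))
        pa_status = rng.choice(
            ["sedentary", "insufficiently_active", "sufficiently_active"],
            p=[0.2, 0.3, 0.5],
        )
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i + 1:02d}",
                age=age,
                sex=sex,
                height=height,
                weight=weight,
                bmi=weight / (height / 100.0) ** 2,
                pa_status=str(pa_status),
                hr_rest=hr_rest,
                fitness=fitness,
            )
        )
    return profiles


def _steady_state_hr(profile: ParticipantProfile, f: float) -> float:
    return profile.hr_rest + f * (hr_max(profile.age) - profile.hr_rest)


def _hr_curve(profile, f, t, tau):
    hrss = _steady_state_hr(profile, f)
    return hrss - (hrss - profile.hr_rest) * np.exp(-t / tau)


def simulate_trial(
    profile: ParticipantProfile,
    trial_type: str,
    duration: float,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> TrialRecord:
    """Generate one trial's HR, RR, EDA and temperature signals.

    HR rises first-order from rest toward HRss = hr_rest + f*(hr_max -
    hr_rest) with time constant ``tau_hr``, where f is the trial type's
    target fraction of heart-rate reserve scaled by the participant's
    ``fitness``. RR intervals are generated beat by beat around 60000/HR(t)
    with a coefficient of variation and a respiratory (HF) oscillation that
    both shrink as f grows. EDA is a tonic first-order rise with f;
    temperature a slow drift with a small f dependence.
    """
    config = config or SimulationConfig()
    if duration <= 20:
        raise ConfigError("duration", f"trial duration {duration}s must exceed 20 s")
    if trial_type not in TRIAL_TYPES:
        raise ConfigError("trial_type", f"unknown trial type {trial_type!r}")

    f = config.intensity_fractions[trial_type] * profile.fitness
    consts = _participant_constants(profile.participant_id)
    hmax = hr_max(profile.age)

    # --- HR stream, 1 Hz -------------------------------------------------
    t_hr = np.arange(0.0, duration, 1.0 / HR_FS)
    hr = _hr_curve(profile, f, t_hr, config.tau_hr)
    hr = hr + rng.normal(0.0, config.hr_noise, size=hr.shape)
    hr = np.clip(hr, 30.0 + 1e-6, hmax)

    # --- RR point process -------------------------------------------------
    # Generated as a beat sequence (not by inverting the 1 Hz HR trace) so
    # beat-to-beat statistics are well defined. Variability falls with f:
    # the vagal-withdrawal analogue that makes rMSSD/SDSD informative.
    rr_list = []
    t = 0.0
    cv = config.rr_cv * (1.0 - 0.85 * min(f, 1.0))
    hf_amp = config.rr_hf_amp * (1.0 - 0.8 * min(f, 1.0))
    while t < duration:
        inst_hr = float(_hr_curve(profile, f, np.asarray(t), config.tau_hr))
        mean_rr = 60000.0 / inst_hr
        rr_ms = (
            mean_rr
            + hf_amp * np.sin(2.0 * np.pi * config.rr_hf_freq * t)
            + rng.normal(0.0, cv * mean_rr)
        )
        rr_ms = float(np.clip(rr_ms, 301.0, 1999.0))
        rr_list.append(rr_ms)
        t += rr_ms / 1000.0
    rr = np.asarray(rr_list)

    # --- EDA, 4 Hz --------------------------------------------------------
    t4 = np.arange(0.0, duration, 1.0 / EDA_FS)
    eda_base = consts["eda_base"]
    eda_ss = eda_base + config.eda_gain * consts["eda_gain_mult"] * f**1.3
    eda = eda_ss - (eda_ss - eda_base) * np.exp(-t4 / config.tau_eda)
    eda = eda + rng.normal(0.0, config.eda_noise, size=eda.shape)
    eda = np.clip(eda, 0.01, None)

    # --- Skin temperature, 4 Hz ------------------------------------------
    temp_base = consts["temp_base"]
    temp_ss = temp_base + config.temp_gain * f
    temp = temp_ss - (temp_ss - temp_base) * np.exp(-t4 / config.tau_temp)
    temp = temp + rng.normal(0.0, config.temp_noise, size=temp.shape)

    return TrialRecord(
        participant_id=profile.participant_id,
        session_index=0,
        trial_type=trial_type,
        hr=hr,
        rr=rr,
        eda=eda,
        temp=temp,
        rpe=None,
    )


def assign_rpe(
    trial: TrialRecord,
    rng: np.random.Generator,
    sigma: float = 0.7,
) -> int:
    """Borg RPE from the trial's steady-state heart rate.

    Implements Borg's classical HR ~= 10 x RPE correspondence: RPE =
    round(mean steady-state HR / 10 + eps), eps ~ Normal(0, sigma), clamped
    to [6, 20]. Steady state is the last 60 s of the HR stream (the whole
    stream for shorter trials).
    """
    if len(trial.hr) == 0:
        raise DataError("trial has an empty HR series")
    tail = trial.hr[-int(60 * HR_FS):] if len(trial.hr) > 60 else trial.hr
    eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
    return int(np.clip(np.round(float(np.mean(tail)) / 10.0 + eps), 6, 20))


def simulate_study(config: SimulationConfig | None = None) -> Study:
    """Generate the full cohort x session x trial grid.

    Each scheduled trial is independently marked ``missing_trial``,
    ``missing_sensor`` or ``invalid_rpe`` (in that precedence order) at the
    configured rates; an invalid-RPE trial reports a Borg rating below 10.
    Fully reproducible given ``config.rng_seed``.
    """
    config = config or SimulationConfig()
    profiles = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    records = []
    for profile in profiles:
        for session in range(1, config.n_sessions + 1):
            for trial_type, dur in config.trial_plan:
                u_trial, u_sensor, u_rpe = rng.uniform(size=3)
                record = simulate_trial(profile, trial_type, dur, rng, config)
                record.session_index = session
                record.rpe = assign_rpe(record, rng, config.rpe_sigma)
                if u_trial < config.missing_trial_rate:
                    record.status = "missing_trial"
                    # participant opted out / stopped early: no usable signal
                    cut = int(len(record.hr) * rng.uniform(0.0, 0.5))
                    record.hr = record.hr[:cut]
                    record.eda = record.eda[: cut * 4]
                    record.temp = record.temp[: cut * 4]
                    record.rpe = None
                elif u_sensor < config.missing_sensor_rate:
                    record.status = "missing_sensor"
                    lost = rng.choice(["hr", "rr", "eda", "temp"])
                    setattr(record, lost, np.asarray([], dtype=float))
                elif u_rpe < config.invalid_rpe_rate:
                    record.status = "invalid_rpe"
                    record.rpe = int(rng.integers(6, 10))
                records.append(record)
    return Study(participants=profiles, records=records)
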