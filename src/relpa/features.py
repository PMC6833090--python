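"""Per-trial feature extraction for each sensor modality.

Feature groups
--------------
HR (30 features): 10 time-domain statistics of the 1 Hz beats-per-minute
stream, 10 time-domain heart-rate-variability statistics of the RR interval
sequence, and 10 spectral features of the RR tachogram over the standard
VLF (0-0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz) bands.

EDA / Temp (6 each): mean, variance, standard deviation, skewness,
kurtosis, median of the filtered, trimmed stream.

Person (6): height, weight, age, BMI, sex (male=1) and habitual-activity
status coded ordinally (sedentary=0, insufficiently_active=1,
sufficiently_active=2).

Conventions: variance/SD use the sample (n-1) denominator everywhere,
including SDSD; skewness and kurtosis are bias-uncorrected moment
estimators with non-excess kurtosis (normal -> 3); for zero-variance input
both are reported as 0. pNNx uses a strict inequality ("differ by MORE
than x ms"). Spectral features come from the tachogram cubic-interpolated
onto an even 4 Hz grid, mean-removed, with a Welch estimate (64 s Hann
segments, 50% overlap) integrated over each band by the trapezoid rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal, stats

from .dataio import rpe_to_class, smooth_record, trim_trial
from .errors import DataError
from .simulate import EDA_FS, HR_FS, TRIAL_TYPES

__all__ = [
    "FeatureMatrix",
    "hr_time_features",
    "rr_time_features",
    "rr_frequency_features",
    "eda_features",
    "temp_features",
    "person_features",
    "extract_matrix",
    "MODALITY_GROUPS",
]

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

HR_BPM_NAMES = [
    "hr_mean", "hr_var", "hr_sd", "hr_skew", "hr_kurt", "hr_median",
    "hr_on_response", "hr_off_response", "hr_n_increase_norm",
    "hr_n_decrease_norm",
]
RR_TIME_NAMES = [
    "rr_mean", "rr_var", "rr_sd", "rr_skew", "rr_kurt", "rr_median",
    "rr_sdsd", "rr_rmssd", "rr_pnn20", "rr_pnn50",
]
RR_FREQ_NAMES = [
    "rr_avlf", "rr_alf", "rr_ahf", "rr_atotal", "rr_pvlf", "rr_plf",
    "rr_phf", "rr_nlf", "rr_nhf", "rr_lf_hf",
]
EDA_NAMES = ["eda_mean", "eda_var", "eda_sd", "eda_skew", "eda_kurt", "eda_median"]
TEMP_NAMES = ["temp_mean", "temp_var", "temp_sd", "temp_skew", "temp_kurt",
              "temp_median"]
PERSON_NAMES = ["person_height", "person_weight", "person_age", "person_bmi",
                "person_sex_male", "person_pa_status"]

#: Feature names per modality group (person features listed separately).
MODALITY_GROUPS = {
    "hr": HR_BPM_NAMES + RR_TIME_NAMES + RR_FREQ_NAMES,
    "eda": EDA_NAMES,
    "temp": TEMP_NAMES,
    "person": PERSON_NAMES,
}


def _moments(x: np.ndarray, prefix: str) -> dict:
    """mean/var/sd/skew/kurt/median with the package's estimator conventions."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DataError(f"{prefix}: empty series")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, bias=True, fisher=False))
    else:
        skew, kurt = 0.0, 0.0  # degenerate (constant) input
    return {
        f"{prefix}_mean": float(np.mean(x)),
        f"{prefix}_var": sd**2,
        f"{prefix}_sd": sd,
        f"{prefix}_skew": skew,
        f"{prefix}_kurt": kurt,
        f"{prefix}_median": float(np.median(x)),
    }


def _ls_slope(x: np.ndarray, rate: float) -> float:
    """Least-squares slope of a series against time (units/s)."""
    t = np.arange(x.size) / rate
    return float(np.polyfit(t, x, 1)[0]) if x.size > 1 else 0.0


def hr_time_features(hr: np.ndarray, rate: float = HR_FS) -> dict:
    """10 time-domain features of the beats-per-minute stream.

    The on/off responses are least-squares HR slopes (bpm/s) over the first
    and last 30 s of the window; the increase/decrease counts are numbers of
    strictly positive / strictly negative successive differences divided by
    the window length in seconds.
    """
    hr = np.asarray(hr, dtype=float)
    window_s = hr.size / rate
    if window_s < 30:
        raise DataError(f"HR window of {window_s:.0f}s is shorter than 30 s")
    out = _moments(hr, "hr")
    n30 = int(round(30 * rate))
    out["hr_on_response"] = _ls_slope(hr[:n30], rate)
    out["hr_off_response"] = _ls_slope(hr[-n30:], rate)
    d = np.diff(hr)
    out["hr_n_increase_norm"] = float(np.sum(d > 0)) / window_s
    out["hr_n_decrease_norm"] = float(np.sum(d < 0)) / window_s
    return out


def rr_time_features(rr: np.ndarray) -> dict:
    """10 time-domain HRV features of the RR interval sequence (ms)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise DataError(f"need >= 3 RR intervals, got {rr.size}")
    out = _moments(rr, "rr")
    d = np.diff(rr)
    out["rr_sdsd"] = float(np.std(d, ddof=1))
    out["rr_rmssd"] = float(np.sqrt(np.mean(d**2)))
    out["rr_pnn20"] = float(np.mean(np.abs(d) > 20.0))
    out["rr_pnn50"] = float(np.mean(np.abs(d) > 50.0))
    return out


def rr_frequency_features(rr: np.ndarray, fs_interp: float = 4.0) -> dict:
    """10 spectral features of the RR tachogram.

    Band powers are absolute (aVLF/aLF/aHF, ms^2), relative to total
    (pVLF/pLF/pHF) and normalised over LF+HF (nLF/nHF), plus aTotal and
    the LF/HF ratio. Ratios undefined on a flat spectrum (or zero HF
    power) are reported as NaN and imputed downstream at modelling time.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 4:
        raise DataError(f"need >= 4 RR intervals for spectral analysis, got {rr.size}")
    beat_t = np.concatenate(([0.0], np.cumsum(rr)[:-1])) / 1000.0
    span = float(np.sum(rr)) / 1000.0  # time covered by the beats
    if span < 60.0:
        raise DataError(f"tachogram span {span:.1f}s is shorter than 60 s")
    grid = np.arange(0.0, beat_t[-1], 1.0 / fs_interp)
    tachogram = interpolate.interp1d(beat_t, rr, kind="cubic")(grid)
    tachogram = tachogram - tachogram.mean()
    nperseg = min(int(64 * fs_interp), tachogram.size)
    freqs, psd = signal.welch(
        tachogram, fs=fs_interp, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )

    def band_power(lo, hi):
        mask = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[mask], freqs[mask])) if mask.sum() > 1 else 0.0

    avlf = band_power(*VLF_BAND)
    alf = band_power(*LF_BAND)
    ahf = band_power(*HF_BAND)
    atotal = avlf + alf + ahf
    # powers below ~1e-9 ms^2 are numerical residue of a flat spectrum;
    # ratios of such powers are meaningless and flagged NaN for imputation
    eps = 1e-9
    out = {"rr_avlf": avlf, "rr_alf": alf, "rr_ahf": ahf, "rr_atotal": atotal}
    if atotal > eps:
        out.update(rr_pvlf=avlf / atotal, rr_plf=alf / atotal, rr_phf=ahf / atotal)
    else:
        out.update(rr_pvlf=np.nan, rr_plf=np.nan, rr_phf=np.nan)
    if alf + ahf > eps:
        out.update(rr_nlf=alf / (alf + ahf), rr_nhf=ahf / (alf + ahf))
    else:
        out.update(rr_nlf=np.nan, rr_nhf=np.nan)
    out["rr_lf_hf"] = alf / ahf if ahf > eps else np.nan
    return out


def eda_features(eda: np.ndarray) -> dict:
    """Six moment/order statistics of the electrodermal-activity stream."""
    return _moments(eda, "eda")


def temp_features(temp: np.ndarray) -> dict:
    """Six moment/order statistics of the skin-temperature stream."""
    return _moments(temp, "temp")


def person_features(profile) -> dict:
    pa_code = {"sedentary": 0, "insufficiently_active": 1, "sufficiently_active": 2}
    return {
        "person_height": profile.height,
        "person_weight": profile.weight,
        "person_age": float(profile.age),
        "person_bmi": profile.bmi,
        "person_sex_male": 1.0 if profile.sex == "male" else 0.0,
        "person_pa_status": float(pa_code[profile.pa_status]),
    }


@dataclass
class FeatureMatrix:
    """Labelled per-trial feature matrix.

    ``data`` holds one row per analyzable trial; ``meta`` carries, row
    aligned, the participant id, session, trial type, RPE and intensity
    class; ``groups`` maps each modality group to its column names;
    ``dropped`` lists trials whose window was too short for extraction.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    groups: dict
    dropped: list = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return self.meta["intensity"].to_numpy(dtype=int)

    @property
    def participant_ids(self) -> np.ndarray:
        return self.meta["participant_id"].to_numpy()

    def columns_for(self, modalities, include_person: bool = True) -> list:
        """Feature-column names for a set of modality groups (set semantics,
        person columns de-duplicated)."""
        cols: list = []
        seen = set()
        names = list(modalities) + (["person"] if include_person else [])
        for m in names:
            if m not in self.groups:
                from .errors import ConfigError

                raise ConfigError("modalities", f"unknown feature group {m!r}")
            for c in self.groups[m]:
                if c not in seen and c in self.data.columns:
                    seen.add(c)
                    cols.append(c)
        return cols

    def subset_rows(self, mask) -> "FeatureMatrix":
        return FeatureMatrix(
            data=self.data.loc[mask].reset_index(drop=True),
            meta=self.meta.loc[mask].reset_index(drop=True),
            groups=self.groups,
            dropped=self.dropped,
        )

    def to_csv(self, path) -> None:
        """Write rows x features as CSV (metadata columns prefixed
        ``meta_``) with a JSON sidecar listing feature names per group."""
        import json
        from pathlib import Path

        path = Path(path)
        meta = self.meta.add_prefix("meta_")
        pd.concat([meta, self.data], axis=1).to_csv(path, index=False)
        path.with_suffix(path.suffix + ".groups.json").write_text(
            json.dumps(self.groups, indent=2)
        )


def extract_trial_features(record, window_mode: str = "full_trial") -> dict:
    """All sensor-modality features of one preprocessed, trimmed record."""
    if window_mode not in ("full_trial", "last_60s"):
        raise DataError(f"unknown window_mode {window_mode!r}")
    hr, rr, eda, temp = record.hr, record.rr, record.eda, record.temp
    if window_mode == "last_60s":
        hr = hr[-int(60 * HR_FS):]
        eda = eda[-int(60 * EDA_FS):]
        temp = temp[-int(60 * EDA_FS):]
        onsets = np.concatenate(([0.0], np.cumsum(rr)[:-1])) / 1000.0
        total = float(np.sum(rr)) / 1000.0
        # keep every beat overlapping the final 60 s, so the retained
        # tachogram covers the full window
        rr = rr[onsets + rr / 1000.0 > total - 60.0]
    out = {}
    out.update(hr_time_features(hr))
    out.update(rr_time_features(rr))
    out.update(rr_frequency_features(rr))
    out.update(eda_features(eda))
    out.update(temp_features(temp))
    return out


def extract_matrix(
    records,
    profiles,
    window_mode: str = "full_trial",
    include_person: bool = True,
    smooth_span: float = 5.0,
    trim: float = 10.0,
) -> FeatureMatrix:
    """Build the labelled feature matrix from complete trial records.

    Each record is moving-average filtered (HR/EDA/Temp), trimmed by
    ``trim`` seconds at each end, then featurised over either the full
    retained window or its last 60 s. Trials whose window is too short for
    any extractor are dropped and listed in ``FeatureMatrix.dropped``.
    """
    profile_map = {p.participant_id: p for p in profiles}
    rows, meta, dropped = [], [], []
    for record in records:
        try:
            prepped = trim_trial(smooth_record(record, smooth_span), trim)
            feats = extract_trial_features(prepped, window_mode)
            if include_person:
                feats.update(person_features(profile_map[record.participant_id]))
        except DataError as exc:
            dropped.append(
                (record.participant_id, record.session_index, record.trial_type,
                 str(exc))
            )
            continue
        rows.append(feats)
        meta.append(
            {
                "participant_id": record.participant_id,
                "session": record.session_index,
                "trial_type": record.trial_type,
                "rpe": record.rpe,
                "intensity": int(rpe_to_class(record.rpe)),
            }
        )
    groups = {k: list(v) for k, v in MODALITY_GROUPS.items()}
    if not include_person:
        groups.pop("person")
    data = pd.DataFrame(rows)
    meta_df = pd.DataFrame(
        meta, columns=["participant_id", "session", "trial_type", "rpe", "intensity"]
    )
    # canonical row order: by participant, session, protocol trial order
    if len(meta_df):
        order = meta_df.assign(
            _t=meta_df["trial_type"].map({t: i for i, t in enumerate(TRIAL_TYPES)})
        ).sort_values(["participant_id", "session", "_t"]).index
        data = data.loc[order].reset_index(drop=True)
        meta_df = meta_df.loc[order].reset_index(drop=True)
    return FeatureMatrix(data=data, meta=meta_df, groups=groups, dropped=dropped)
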