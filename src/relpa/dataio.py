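"""Dataset I/O, preprocessing and the trial-exclusion ledger.

Preprocessing follows the offline protocol the pipeline assumes: a 5 s
centered moving-average filter on the regularly-sampled streams (HR, EDA,
temperature) to suppress motion artefact, then discarding the first and
last 10 s of every trial so the retained window reflects steady pacing.
The RR beat sequence is deliberately NOT smoothed — a moving average would
destroy the successive-difference statistics (SDSD, rMSSD, pNNx) that carry
the vagal information.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DataError, DomainError, ParseError
from .simulate import EDA_FS, HR_FS, ParticipantProfile, Study, TrialRecord

__all__ = [
    "IntensityClass",
    "ExclusionLedger",
    "moving_average",
    "trim_trial",
    "rpe_to_class",
    "filter_trials",
    "write_study",
    "read_study",
]

_SIGNALS = {"hr": HR_FS, "rr": None, "eda": EDA_FS, "temp": EDA_FS}


class IntensityClass(enum.IntEnum):
    """Relative-intensity category, ordered by severity."""

    LOW = 0
    MODERATE = 1
    HIGH = 2

    @property
    def label(self) -> str:
        return self.name.lower()


def rpe_to_class(rpe: int) -> IntensityClass:
    """Map a Borg RPE rating (6-20) to {low <=11, moderate 12-14, high >=15}."""
    if not (6 <= rpe <= 20):
        raise DomainError(f"RPE {rpe} outside the Borg 6-20 scale")
    if rpe <= 11:
        return IntensityClass.LOW
    if rpe <= 14:
        return IntensityClass.MODERATE
    return IntensityClass.HIGH


@dataclass(frozen=True)
class ExclusionLedger:
    """Counts of trials removed at each filtering stage."""

    scheduled: int
    missing_or_incomplete: int
    missing_sensor: int
    invalid_rpe: int

    @property
    def after_completion_filter(self) -> int:
        return self.scheduled - self.missing_or_incomplete

    @property
    def analyzable(self) -> int:
        return self.after_completion_filter - self.missing_sensor - self.invalid_rpe

    def __post_init__(self):
        counts = (
            self.scheduled,
            self.missing_or_incomplete,
            self.missing_sensor,
            self.invalid_rpe,
        )
        if any(c < 0 for c in counts) or self.analyzable < 0:
            raise DataError(f"inconsistent exclusion ledger: {self}")

    def to_dict(self) -> dict:
        return {
            "scheduled": self.scheduled,
            "missing_or_incomplete": self.missing_or_incomplete,
            "after_completion_filter": self.after_completion_filter,
            "missing_sensor": self.missing_sensor,
            "invalid_rpe": self.invalid_rpe,
            "analyzable": self.analyzable,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def moving_average(series: np.ndarray, span: float, rate: float) -> np.ndarray:
    """Centered moving mean with a window of ``round(span * rate)`` samples.

    The window is truncated symmetrically at the edges, so output length
    equals input length and constants pass through unchanged.
    """
    series = np.asarray(series, dtype=float)
    if span <= 0:
        raise DataError(f"span must be positive, got {span}")
    if series.size == 0:
        raise DataError("cannot filter an empty series")
    w = int(round(span * rate))
    if w <= 1:
        return series.copy()
    left, right = (w - 1) // 2, w // 2
    n = series.size
    csum = np.concatenate(([0.0], np.cumsum(series)))
    out = np.empty(n)
    for i in range(n):
        h_l, h_r = left, right
        edge = min(i, n - 1 - i)
        if edge < max(h_l, h_r):  # symmetric truncation near the edges
            h_l = h_r = edge
        lo, hi = i - h_l, i + h_r + 1
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def smooth_record(record: TrialRecord, span: float = 5.0) -> TrialRecord:
    """Apply the moving-average filter to HR, EDA and temperature (not RR)."""
    return replace(
        record,
        hr=moving_average(record.hr, span, HR_FS) if record.hr.size else record.hr,
        eda=moving_average(record.eda, span, EDA_FS) if record.eda.size else record.eda,
        temp=moving_average(record.temp, span, EDA_FS)
        if record.temp.size
        else record.temp,
    )


def trim_trial(record: TrialRecord, trim: float = 10.0) -> TrialRecord:
    """Discard ``trim`` seconds from each end of every signal.

    RR intervals whose cumulative onset time falls inside a trimmed zone
    are dropped.
    """
    if trim < 0:
        raise DataError(f"trim must be >= 0, got {trim}")
    if trim == 0:
        return record
    duration = record.duration
    if duration <= 2 * trim:
        raise DataError(
            f"trial duration {duration}s does not exceed 2 x trim {trim}s"
        )
    n_hr = int(round(trim * HR_FS))
    n_4 = int(round(trim * EDA_FS))
    onsets = np.concatenate(([0.0], np.cumsum(record.rr)[:-1])) / 1000.0
    total = float(np.sum(record.rr)) / 1000.0
    keep = (onsets >= trim) & (onsets < total - trim)
    return replace(
        record,
        hr=record.hr[n_hr : len(record.hr) - n_hr],
        eda=record.eda[n_4 : len(record.eda) - n_4],
        temp=record.temp[n_4 : len(record.temp) - n_4],
        rr=record.rr[keep],
    )


def filter_trials(records) -> tuple[list, ExclusionLedger]:
    """Remove excluded trials, in order: missing trial, missing sensor,
    invalid RPE. Returns only ``complete`` records plus the ledger."""
    records = list(records)
    n_missing = sum(r.status == "missing_trial" for r in records)
    n_sensor = sum(r.status == "missing_sensor" for r in records)
    n_rpe = sum(r.status == "invalid_rpe" for r in records)
    kept = [r for r in records if r.status == "complete"]
    ledger = ExclusionLedger(
        scheduled=len(records),
        missing_or_incomplete=n_missing,
        missing_sensor=n_sensor,
        invalid_rpe=n_rpe,
    )
    assert ledger.analyzable == len(kept)
    return kept, ledger


# ---------------------------------------------------------------------------
# CSV persistence (participants.csv, signals.csv, labels.csv)
# ---------------------------------------------------------------------------

def write_study(study: Study, directory) -> None:
    """Serialise a study to three CSV files in ``directory``.

    participants.csv: one row per profile. signals.csv: long format
    (participant_id, session, trial_type, signal, sample_index, t_seconds,
    value). labels.csv: (participant_id, session, trial_type, rpe, status).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    part_cols = [
        "participant_id", "age", "sex", "height", "weight", "bmi",
        "pa_status", "hr_rest", "fitness",
    ]
    pd.DataFrame(
        [p.__dict__ for p in study.participants], columns=part_cols
    ).to_csv(directory / "participants.csv", index=False, float_format="%.17g")

    sig_frames = []
    labels = []
    for r in study.records:
        for signal, fs in _SIGNALS.items():
            values = getattr(r, signal)
            if values.size == 0:
                continue
            if signal == "rr":
                t = np.concatenate(([0.0], np.cumsum(values)[:-1])) / 1000.0
            else:
                t = np.arange(values.size) / fs
            sig_frames.append(
                pd.DataFrame(
                    {
                        "participant_id": r.participant_id,
                        "session": r.session_index,
                        "trial_type": r.trial_type,
                        "signal": signal,
                        "sample_index": np.arange(values.size),
                        "t_seconds": t,
                        "value": values,
                    }
                )
            )
        labels.append(
            {
                "participant_id": r.participant_id,
                "session": r.session_index,
                "trial_type": r.trial_type,
                "rpe": r.rpe if r.rpe is not None else "",
                "status": r.status,
            }
        )
    sig_cols = ["participant_id", "session", "trial_type", "signal",
                "sample_index", "t_seconds", "value"]
    if sig_frames:
        sig_df = pd.concat(sig_frames, ignore_index=True)
    else:
        sig_df = pd.DataFrame(columns=sig_cols)
    sig_df.to_csv(directory / "signals.csv", index=False, float_format="%.17g")
    lab_cols = ["participant_id", "session", "trial_type", "rpe", "status"]
    pd.DataFrame(labels, columns=lab_cols).to_csv(
        directory / "labels.csv", index=False
    )


def read_study(directory) -> Study:
    """Reassemble a study from the three CSV files written by write_study."""
    directory = Path(directory)
    try:
        parts = pd.read_csv(directory / "participants.csv",
                            float_precision="round_trip")
        signals = pd.read_csv(directory / "signals.csv",
                              float_precision="round_trip")
        labels = pd.read_csv(directory / "labels.csv")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(str(exc)) from exc

    unknown = set(signals["signal"].unique()) - set(_SIGNALS)
    if unknown:
        raise ConsistencyError(f"unknown signal name(s) in signals.csv: {sorted(unknown)}")

    profiles = [
        ParticipantProfile(
            participant_id=str(row.participant_id),
            age=int(row.age),
            sex=str(row.sex),
            height=float(row.height),
            weight=float(row.weight),
            bmi=float(row.bmi),
            pa_status=str(row.pa_status),
            hr_rest=float(row.hr_rest),
            fitness=float(row.fitness),
        )
        for row in parts.itertuples()
    ]
    known_ids = {p.participant_id for p in profiles}

    sig_ids = set(signals["participant_id"].astype(str).unique()) if len(signals) else set()
    lab_ids = set(labels["participant_id"].astype(str).unique()) if len(labels) else set()
    stray = (sig_ids | lab_ids) - known_ids
    if stray:
        raise ConsistencyError(
            f"participant id(s) {sorted(stray)} appear in signal/label files "
            "but not in participants.csv"
        )

    grouped: dict = {}
    if len(signals):
        signals = signals.sort_values(["participant_id", "session", "trial_type",
                                       "signal", "sample_index"])
        for (pid, session, ttype, signal), grp in signals.groupby(
            ["participant_id", "session", "trial_type", "signal"], sort=False
        ):
            grouped.setdefault((str(pid), int(session), str(ttype)), {})[signal] = (
                grp["value"].to_numpy(dtype=float)
            )

    records = []
    for row in labels.itertuples():
        key = (str(row.participant_id), int(row.session), str(row.trial_type))
        sigs = grouped.get(key, {})
        empty = np.asarray([], dtype=float)
        rpe = None if pd.isna(row.rpe) or row.rpe == "" else int(row.rpe)
        records.append(
            TrialRecord(
                participant_id=key[0],
                session_index=key[1],
                trial_type=key[2],
                hr=sigs.get("hr", empty),
                rr=sigs.get("rr", empty),
                eda=sigs.get("eda", empty),
                temp=sigs.get("temp", empty),
                rpe=rpe,
                status=str(row.status),
            )
        )
    return Study(participants=profiles, records=records)
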