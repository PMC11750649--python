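"""Trial, annotation and cohort-table file formats.

All on-disk formats are plain text:

* **Trial CSV** — long format, one row per sample and channel:
  ``time_s, sensor, channel, value``.  Sensors are ``shin_L`` / ``shin_R``
  (tri-axial accelerometer, channels AP/ML/V, units of g) and ``lumbar``
  (tri-axial gyroscope, channels yaw/pitch/roll, units of deg/s).
* **Annotation TSV** — ELAN-export-like interval file with columns
  ``begin_s, end_s, label`` where label is ``trembling`` or ``akinetic``.
* **Cohort CSV** — one row per subject with self-report and phenotype columns.

Times are seconds from trial start; intervals are half-open ``[start, end)``
so duration arithmetic for percent-time-frozen is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ACCEL_CHANNELS = ("AP", "ML", "V")
GYRO_CHANNELS = ("yaw", "pitch", "roll")
EPISODE_TYPES = ("trembling", "akinetic")

#: maximum run of missing samples repaired by linear interpolation on load
MAX_GAP_SAMPLES = 3


class TrialFormatError(ValueError):
    """A trial file violates the expected schema or an invariant."""


class AnnotationFormatError(ValueError):
    """An annotation file violates interval invariants."""


@dataclass
class IMUTrial:
    """One subject's one-minute multi-sensor recording.

    Attributes
    ----------
    subject_id : str
    sample_rate_hz : float
        Must exceed 16 Hz (Nyquist for the 8 Hz freeze-band edge).
    duration_s : float
    shin_left, shin_right : dict[str, np.ndarray]
        Channel map ``{"AP", "ML", "V"}`` -> acceleration in g.
    lumbar_gyro : dict[str, np.ndarray]
        Channel map ``{"yaw", "pitch", "roll"}`` -> angular velocity in deg/s.
    """

    subject_id: str
    sample_rate_hz: float
    duration_s: float
    shin_left: dict[str, np.ndarray]
    shin_right: dict[str, np.ndarray]
    lumbar_gyro: dict[str, np.ndarray]

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def validate(self) -> "IMUTrial":
        if self.sample_rate_hz <= 16:
            raise TrialFormatError(
                f"sample_rate_hz={self.sample_rate_hz} must exceed 16 Hz "
                "(Nyquist for the 3-8 Hz freeze band)"
            )
        if self.duration_s <= 0:
            raise TrialFormatError("duration_s must be positive")
        n = self.n_samples
        for sensor_name, chan_map, channels in (
            ("shin_L", self.shin_left, ACCEL_CHANNELS),
            ("shin_R", self.shin_right, ACCEL_CHANNELS),
            ("lumbar", self.lumbar_gyro, GYRO_CHANNELS),
        ):
            for ch in channels:
                if ch not in chan_map:
                    raise TrialFormatError(f"missing channel {sensor_name}/{ch}")
                series = np.asarray(chan_map[ch], dtype=float)
                if series.size != n:
                    raise TrialFormatError(
                        f"{sensor_name}/{ch} has {series.size} samples, "
                        f"expected {n} (= {self.duration_s} s x {self.sample_rate_hz} Hz)"
                    )
                if np.isnan(series).any():
                    raise TrialFormatError(f"{sensor_name}/{ch} contains NaNs")
                chan_map[ch] = series
        return self


@dataclass(frozen=True)
class Episode:
    """One freezing episode, half-open interval [start_s, end_s)."""

    start_s: float
    end_s: float
    type: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class FogAnnotation:
    """Rater-style list of FOG episodes for one trial."""

    rater_id: str
    episodes: list[Episode]
    trial_duration_s: float
    disagreements: list[str] = field(default_factory=list)

    def validate(self) -> "FogAnnotation":
        if self.trial_duration_s <= 0:
            raise AnnotationFormatError("trial_duration_s must be positive")
        eps = sorted(self.episodes, key=lambda e: e.start_s)
        prev_end = -np.inf
        for ep in eps:
            if ep.type not in EPISODE_TYPES:
                raise AnnotationFormatError(
                    f"unknown episode label {ep.type!r}; expected one of {EPISODE_TYPES}"
                )
            if not (0 <= ep.start_s < ep.end_s <= self.trial_duration_s):
                raise AnnotationFormatError(
                    f"episode ({ep.start_s}, {ep.end_s}) outside "
                    f"[0, {self.trial_duration_s}] or end <= start"
                )
            if ep.start_s < prev_end:
                raise AnnotationFormatError(
                    f"episode starting at {ep.start_s} s overlaps the previous "
                    f"episode ending at {prev_end} s"
                )
            prev_end = ep.end_s
        self.episodes = eps
        return self


def _interpolate_gaps(series: np.ndarray, name: str) -> np.ndarray:
    """Linearly repair NaN runs of <= MAX_GAP_SAMPLES; longer runs are errors."""
    isnan = np.isnan(series)
    if not isnan.any():
        return series
    if isnan.all():
        raise TrialFormatError(f"{name} is entirely missing")
    # locate NaN runs
    idx = np.flatnonzero(isnan)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if run.size > MAX_GAP_SAMPLES:
            raise TrialFormatError(
                f"{name} has a gap of {run.size} samples (> {MAX_GAP_SAMPLES}); refusing to interpolate"
            )
    valid = ~isnan
    out = series.copy()
    out[isnan] = np.interp(
        np.flatnonzero(isnan), np.flatnonzero(valid), series[valid]
    )
    return out


DEFAULT_SCHEMA = {
    "time": "time_s",
    "sensor": "sensor",
    "channel": "channel",
    "value": "value",
}


def write_trial(trial: IMUTrial, path) -> None:
    """Write a trial as long-format CSV (time_s, sensor, channel, value)."""
    trial.validate()
    t = trial.time_s
    frames = []
    for sensor_name, chan_map in (
        ("shin_L", trial.shin_left),
        ("shin_R", trial.shin_right),
        ("lumbar", trial.lumbar_gyro),
    ):
        for ch, series in chan_map.items():
            frames.append(
                pd.DataFrame(
                    {"time_s": t, "sensor": sensor_name, "channel": ch, "value": series}
                )
            )
    long = pd.concat(frames, ignore_index=True)
    long.to_csv(path, index=False, float_format="%.9g")


def read_trial(path, schema_config: dict | None = None, subject_id: str | None = None) -> IMUTrial:
    """Load and validate a long-format trial CSV.

    Parameters
    ----------
    path : path-like
    schema_config : dict, optional
        Maps roles ``time``/``sensor``/``channel``/``value`` to the actual
        column names, so differently exported files can be adapted.
    subject_id : str, optional
        Defaults to the file stem.

    Gaps of up to three consecutive missing samples per channel are linearly
    interpolated; longer gaps raise :class:`TrialFormatError`.
    """
    schema = dict(DEFAULT_SCHEMA)
    if schema_config:
        schema.update(schema_config)
    df = pd.read_csv(path)
    missing_cols = [c for c in schema.values() if c not in df.columns]
    if missing_cols:
        raise TrialFormatError(f"missing columns {missing_cols} in {path}")
    df = df.rename(columns={v: k for k, v in schema.items()})

    t_all = np.unique(df["time"].to_numpy(dtype=float))
    if t_all.size < 2:
        raise TrialFormatError("trial has fewer than two time samples")
    dt = np.diff(t_all)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise TrialFormatError("inconsistent sampling interval in time column")
    fs = 1.0 / dt[0]
    duration = t_all.size / fs

    sensors: dict[str, dict[str, np.ndarray]] = {}
    for (sensor_name, ch), grp in df.groupby(["sensor", "channel"], sort=False):
        series = (
            grp.set_index("time")["value"].reindex(t_all).to_numpy(dtype=float)
        )
        sensors.setdefault(str(sensor_name), {})[str(ch)] = _interpolate_gaps(
            series, f"{sensor_name}/{ch}"
        )

    for sensor_name, channels in (
        ("shin_L", ACCEL_CHANNELS),
        ("shin_R", ACCEL_CHANNELS),
        ("lumbar", GYRO_CHANNELS),
    ):
        got = sensors.get(sensor_name, {})
        for ch in channels:
            if ch not in got:
                raise TrialFormatError(f"file {path} is missing channel {sensor_name}/{ch}")

    if subject_id is None:
        from pathlib import Path

        subject_id = Path(path).stem
    trial = IMUTrial(
        subject_id=subject_id,
        sample_rate_hz=fs,
        duration_s=duration,
        shin_left=sensors["shin_L"],
        shin_right=sensors["shin_R"],
        lumbar_gyro=sensors["lumbar"],
    )
    return trial.validate()


def write_annotations(annotation: FogAnnotation, path) -> None:
    """Write an annotation as tab-separated begin_s/end_s/label rows."""
    annotation.validate()
    rows = [
        {"begin_s": ep.start_s, "end_s": ep.end_s, "label": ep.type}
        for ep in annotation.episodes
    ]
    pd.DataFrame(rows, columns=["begin_s", "end_s", "label"]).to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )


def read_annotations(path, trial_duration_s: float = 60.0, rater_id: str = "rater") -> FogAnnotation:
    """Read a tab-separated interval file into a sorted, validated annotation.

    An empty file (header only, or zero bytes) yields zero episodes.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["begin_s", "end_s", "label"])
    for col in ("begin_s", "end_s", "label"):
        if col not in df.columns:
            raise AnnotationFormatError(f"missing column {col!r} in {path}")
    episodes = [
        Episode(float(r.begin_s), float(r.end_s), str(r.label))
        for r in df.itertuples()
    ]
    return FogAnnotation(
        rater_id=rater_id, episodes=episodes, trial_duration_s=trial_duration_s
    ).validate()


def write_cohort_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.9g")


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "subject_id" not in df.columns:
        raise TrialFormatError(f"cohort table {path} lacks a subject_id column")
    return df


def copy_annotation(annotation: FogAnnotation, **changes) -> FogAnnotation:
    return replace(annotation, **changes)
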