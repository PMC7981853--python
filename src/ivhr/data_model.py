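"""Survival-data containers, counting-process views, and delimited-file I/O.

The observed data are i.i.d. subject records (T_i, Δ_i, X_i, W_i): follow-up
time (minimum of event and censoring time), event indicator, exposure, and
instrument.  Time origin is 0 for every subject; there is no delayed entry.
:class:`RiskSetIndex` materialises the at-risk sets R_i(v) = 1{T_i >= v} and
the event groups dN(v) that every estimating-equation sum runs over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, InputDataError

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "time": "time",
    "event": "event",
    "exposure": "exposure",
    "instrument": "instrument",
}


@dataclass(frozen=True)
class SurvivalSample:
    """One row per subject: follow-up time, event indicator, exposure, instrument.

    Parameters
    ----------
    time : ndarray
        Non-negative follow-up times T_i (min of event and censoring time).
    event : ndarray
        Event indicators Δ_i in {0, 1}; 1 means the event was observed.
    exposure : ndarray
        Exposure X_i.  Binary 0/1 in the motivating applications, but any
        real coding is accepted.
    instrument : ndarray
        Instrument W_i (continuous, ordinal or binary).
    """

    time: np.ndarray
    event: np.ndarray
    exposure: np.ndarray
    instrument: np.ndarray

    def __post_init__(self) -> None:
        for name in ("time", "event", "exposure", "instrument"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = self.time.shape[0]
        if n < 1:
            raise InputDataError("a sample requires at least one subject")
        for name in ("event", "exposure", "instrument"):
            if getattr(self, name).shape != (n,):
                raise InputDataError(
                    f"column '{name}' has length {getattr(self, name).shape}, expected ({n},)"
                )
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            bad = int(np.flatnonzero(~np.isfinite(self.time) | (self.time < 0))[0])
            raise InputDataError(f"negative or non-finite time in row {bad}, column 'time'")
        if not np.all(np.isin(self.event, (0.0, 1.0))):
            bad = int(np.flatnonzero(~np.isin(self.event, (0.0, 1.0)))[0])
            raise InputDataError(f"event not in {{0,1}} in row {bad}, column 'event'")
        for name in ("exposure", "instrument"):
            if not np.all(np.isfinite(getattr(self, name))):
                bad = int(np.flatnonzero(~np.isfinite(getattr(self, name)))[0])
                raise InputDataError(f"non-finite value in row {bad}, column '{name}'")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def require_events(self) -> None:
        """Raise :class:`DegenerateDataError` unless at least one event occurred."""
        if self.n_events == 0:
            raise DegenerateDataError("sample contains no events; estimation is impossible")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "event": self.event.astype(int),
                "exposure": self.exposure,
                "instrument": self.instrument,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RiskSetIndex:
    """Risk sets and event groups at the distinct event times.

    ``at_risk_ids[k]`` holds the subjects with T_i >= event_times[k] (subjects
    censored exactly at an event time are still at risk there, and tied events
    share one risk set — the Breslow tie convention).  ``event_ids[k]`` holds
    the subjects whose event occurs at event_times[k].
    """

    event_times: np.ndarray
    at_risk_ids: list = field(repr=False)
    event_ids: list = field(repr=False)

    @property
    def n_event_times(self) -> int:
        return self.event_times.shape[0]


def load_sample(path, column_map: dict | None = None) -> SurvivalSample:
    """Read a delimited text file with header into a :class:`SurvivalSample`.

    ``column_map`` maps the canonical names (time, event, exposure,
    instrument) to the file's column names; unmapped names are used as-is.
    Rows with missing values in any mapped column are dropped, and the count
    of dropped rows is logged.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise InputDataError(f"unknown canonical column names in column_map: {sorted(unknown)}")
        cols.update(column_map)

    df = pd.read_csv(path)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise InputDataError(f"missing column(s) {missing} in {path}")

    sub = df[[cols[k] for k in ("time", "event", "exposure", "instrument")]].copy()
    sub.columns = ["time", "event", "exposure", "instrument"]
    complete = sub.dropna().copy()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.warning("dropped %d row(s) with missing values from %s", n_dropped, path)
    if complete.empty:
        raise InputDataError(f"no complete rows in {path}")

    for name in ("time", "event", "exposure", "instrument"):
        try:
            complete[name] = pd.to_numeric(complete[name])
        except (ValueError, TypeError):
            coerced = pd.to_numeric(complete[name], errors="coerce")
            row = int(complete.index[coerced.isna()][0])
            raise InputDataError(
                f"non-numeric value in row {row}, column '{cols[name]}'"
            ) from None

    # Re-check invariants with the file's own row labels for error messages.
    time = complete["time"].to_numpy(float)
    event = complete["event"].to_numpy(float)
    if np.any(time < 0):
        row = int(complete.index[time < 0][0])
        raise InputDataError(f"negative time in row {row}, column '{cols['time']}'")
    if not np.all(np.isin(event, (0.0, 1.0))):
        row = int(complete.index[~np.isin(event, (0.0, 1.0))][0])
        raise InputDataError(f"event not in {{0,1}} in row {row}, column '{cols['event']}'")

    return SurvivalSample(
        time=time,
        event=event,
        exposure=complete["exposure"].to_numpy(float),
        instrument=complete["instrument"].to_numpy(float),
    )


def build_risk_sets(sample: SurvivalSample) -> RiskSetIndex:
    """Index the distinct event times, their risk sets, and their event groups.

    Ties are grouped: all events at the same time form one entry and share one
    risk set.  Requires at least one event.
    """
    sample.require_events()
    is_event = sample.event == 1
    event_times = np.unique(sample.time[is_event])
    at_risk = [np.flatnonzero(sample.time >= v) for v in event_times]
    events = [np.flatnonzero(is_event & (sample.time == v)) for v in event_times]
    return RiskSetIndex(event_times=event_times, at_risk_ids=at_risk, event_ids=events)
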