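"""Uniformly sampled differential-power traces and their plain-text storage.

A trace is stored as a two-column CSV (``time_s``, ``power_uJ_per_s``) with a
JSON sidecar (same path, ``.json`` extension) carrying the injection
schedule, so a written experiment round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from .errors import InvalidInputError, TraceParseError
from .forward import InjectionSchedule

__all__ = ["PowerTrace", "write_trace", "read_trace", "injection_slots"]

logger = logging.getLogger(__name__)


@dataclass
class PowerTrace:
    """Uniformly sampled differential power ΔP(t).

    times are strictly increasing and uniformly spaced (relative tolerance
    1e-9); values are in μJ/s.  ``meta`` carries optional annotations such as
    the schedule or detected peak bounds.
    """

    times: np.ndarray
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidInputError("times and values must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise InvalidInputError("a trace needs at least two samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            i = int(np.argmax(steps <= 0))
            raise InvalidInputError(f"times must be strictly increasing (violated at sample {i + 1})")
        dt = steps[0]
        if not np.allclose(steps, dt, rtol=1e-9, atol=1e-9 * max(dt, 1.0)):
            raise InvalidInputError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)

    @property
    def schedule(self) -> Optional[InjectionSchedule]:
        return self.meta.get("schedule")

    def window(self, i0: int, i1: int, **extra_meta) -> "PowerTrace":
        """Sub-trace of samples [i0, i1); meta is copied and updated."""
        meta = dict(self.meta)
        meta.update(extra_meta)
        return PowerTrace(self.times[i0:i1], self.values[i0:i1], meta)


def injection_slots(trace: PowerTrace, schedule: InjectionSchedule) -> tuple[list[tuple[int, int]], list[bool]]:
    """Index ranges of the per-injection spacing slots, including the null slot.

    Returns (slots, is_null) where each slot is a half-open sample range
    [i0, i1) starting at an injection onset and ending at the next onset (or
    the trace end for the last slot).
    """
    onsets = schedule.onset_times(include_null=True)
    t0, t1 = trace.times[0], trace.times[-1]
    if onsets[0] < t0 - trace.dt / 2 or onsets[-1] > t1:
        raise InvalidInputError(
            f"trace [{t0}, {t1}] s does not span the schedule onsets "
            f"[{onsets[0]}, {onsets[-1]}] s"
        )
    idx = np.searchsorted(trace.times, onsets - trace.dt / 2)
    bounds = list(idx) + [len(trace)]
    slots = [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(onsets))]
    is_null = [schedule.has_null and i == 0 for i in range(len(onsets))]
    return slots, is_null


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _schedule_to_dict(schedule: InjectionSchedule) -> dict:
    d = dataclasses.asdict(schedule)
    if d["null_injection"] is not None:
        d["null_injection"] = list(d["null_injection"])
    return d


def _schedule_from_dict(d: dict) -> InjectionSchedule:
    if d.get("null_injection") is not None:
        d = dict(d, null_injection=tuple(d["null_injection"]))
    return InjectionSchedule(**d)


def write_trace(path, trace: PowerTrace, schedule: Optional[InjectionSchedule] = None) -> None:
    """Write a trace as CSV plus a JSON sidecar with the schedule."""
    path = Path(path)
    # pandas' default float repr is shortest-round-trip, so read(write(x)) == x
    pd.DataFrame({"time_s": trace.times, "power_uJ_per_s": trace.values}).to_csv(path, index=False)
    schedule = schedule or trace.schedule
    sidecar: dict[str, Any] = {"format": "itcdissolve-trace/1"}
    if schedule is not None:
        sidecar["schedule"] = _schedule_to_dict(schedule)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_trace(path) -> PowerTrace:
    """Read a trace CSV written by :func:`write_trace`.

    A missing sidecar is tolerated (schedule absent, warning logged); a
    malformed CSV raises :class:`TraceParseError` naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap any pandas parse failure
        raise TraceParseError(f"{path}: could not parse CSV ({exc})") from exc
    for col in ("time_s", "power_uJ_per_s"):
        if col not in df.columns:
            raise TraceParseError(f"{path}: missing required column {col!r} (line 1)")
    for col in ("time_s", "power_uJ_per_s"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: 1-based lines and the header row
            line = int(np.argmax(bad.to_numpy())) + 2
            raise TraceParseError(f"{path}: non-numeric or missing {col} at line {line}")
        df[col] = coerced
    times = df["time_s"].to_numpy()
    steps = np.diff(times)
    if np.any(steps <= 0):
        line = int(np.argmax(steps <= 0)) + 3
        raise TraceParseError(f"{path}: time column not strictly increasing at line {line}")

    meta: dict[str, Any] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        if "schedule" in payload:
            meta["schedule"] = _schedule_from_dict(payload["schedule"])
    else:
        logger.warning("no sidecar %s found; schedule unavailable", sidecar)
    return PowerTrace(times, df["power_uJ_per_s"].to_numpy(), meta)
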