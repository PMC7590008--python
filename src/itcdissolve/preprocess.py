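"""Trace preprocessing: peak-bound detection, baseline correction, segmentation.

Peak boundaries within each injection window are the first and last times
the (moving-average smoothed) derivative |dΔP/dt| exceeds a threshold
(default 2×10⁻³ μJ s⁻¹ per s).  Baseline drift is then removed in two
regimes: a single third-degree polynomial fitted to all non-peak samples,
and a first-degree polynomial across each peak interval.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import BaselineError, InvalidInputError
from .forward import InjectionSchedule
from .trace import PowerTrace, injection_slots

__all__ = [
    "detect_peak_bounds",
    "correct_baseline",
    "segment_injections",
    "write_peak_bounds",
]

logger = logging.getLogger(__name__)

#: Derivative threshold used to delimit peaks (μJ·s⁻¹ per s).
DERIVATIVE_THRESHOLD = 2e-3


def _smoothed_derivative(trace: PowerTrace, smooth_window: int) -> np.ndarray:
    if smooth_window < 1:
        raise InvalidInputError("smooth_window must be >= 1")
    w = int(smooth_window)
    if w % 2 == 0:
        w += 1
    if w > 1:
        kernel = np.ones(w) / w
        padded = np.pad(trace.values, w // 2, mode="edge")
        smooth = np.convolve(padded, kernel, mode="valid")
    else:
        smooth = trace.values
    return np.gradient(smooth, trace.times)


def detect_peak_bounds(
    trace: PowerTrace,
    threshold: float = DERIVATIVE_THRESHOLD,
    smooth_window: int = 5,
    windows: Optional[Sequence[tuple[int, int]]] = None,
    noise_floor_factor: float = 5.0,
) -> list[tuple[int, int]]:
    """Detect one peak interval per injection window by derivative threshold.

    Within each window [i0, i1) the peak runs from the first to the last
    sample where |dΔP/dt| of the smoothed trace exceeds the threshold.  The
    effective threshold is floored at ``noise_floor_factor`` times the
    robust (MAD) noise level of the derivative, so detection does not
    degenerate when instrument noise exceeds the nominal threshold.
    Windows with no crossing contribute no pair (logged).
    """
    if threshold <= 0:
        raise InvalidInputError("threshold must be positive")
    if windows is None:
        schedule = trace.schedule
        if schedule is not None:
            slots, _ = injection_slots(trace, schedule)
            windows = slots
        else:
            windows = [(0, len(trace))]
    deriv = _smoothed_derivative(trace, smooth_window)
    mad = float(np.median(np.abs(deriv - np.median(deriv))))
    sigma = 1.4826 * mad
    eff_threshold = max(threshold, noise_floor_factor * sigma)

    # keep the search away from window edges: smoothing and the central
    # difference smear the next injection's onset step a few samples back
    # across the boundary, which would otherwise pin every peak end there
    guard = (max(1, int(smooth_window)) // 2 + 2) if len(windows) > 1 else 0
    bounds: list[tuple[int, int]] = []
    for i0, i1 in windows:
        j1 = max(i0 + 1, i1 - guard)
        hits = np.flatnonzero(np.abs(deriv[i0:j1]) > eff_threshold)
        if len(hits) == 0:
            logger.info("no peak found in window [%d, %d)", i0, i1)
            continue
        bounds.append((i0 + int(hits[0]), i0 + int(hits[-1])))
    return bounds


def correct_baseline(
    trace: PowerTrace,
    bounds: Sequence[tuple[int, int]],
    poly_degree: int = 3,
    peak_endpoint: str = "baseline",
    tail_margin: float = 1.0,
    slot_skip_fraction: float = 2.0 / 3.0,
) -> PowerTrace:
    """Remove baseline drift in two regimes.

    Outside all peaks a single polynomial of ``poly_degree`` (default 3) is
    fitted to baseline samples and subtracted.  Inside each peak interval a
    first-degree polynomial (straight line across the interval) is
    subtracted instead.  With ``peak_endpoint="baseline"`` (default) the
    line joins the fitted polynomial evaluated at the peak bounds, which
    keeps slow dissolution tails — still slightly above baseline at the
    detected peak end — from leaking into the correction;
    ``peak_endpoint="signal"`` anchors the line on the raw signal values.

    Two exclusions keep slow tails out of the polynomial fit support (they
    are still corrected by it): samples within ``tail_margin`` peak-widths
    after each detected peak, and — when the trace carries a schedule — the
    first ``slot_skip_fraction`` of every injection slot, because
    near-solubility dissolution is slow enough that its signal never
    crosses the detection threshold yet decays for a large part of the
    slot.
    """
    if peak_endpoint not in ("baseline", "signal"):
        raise InvalidInputError("peak_endpoint must be 'baseline' or 'signal'")
    if not 0 <= slot_skip_fraction < 1:
        raise InvalidInputError("slot_skip_fraction must lie in [0, 1)")
    n = len(trace)
    fit_excluded = np.zeros(n, dtype=bool)
    for s, e in bounds:
        if not 0 <= s <= e < n:
            raise InvalidInputError(f"peak bounds ({s}, {e}) outside trace of length {n}")
        width = e - s
        fit_excluded[s : min(n, e + 1 + int(round(tail_margin * width)))] = True
    schedule = trace.schedule
    if schedule is not None and slot_skip_fraction > 0:
        try:
            slots, _ = injection_slots(trace, schedule)
        except InvalidInputError:
            slots = []
        for i0, i1 in slots:
            fit_excluded[i0 : i0 + int(round(slot_skip_fraction * (i1 - i0)))] = True

    support = ~fit_excluded
    if support.sum() < poly_degree + 1:
        raise BaselineError("peaks cover the whole trace; no baseline support left")
    poly = np.polynomial.Polynomial.fit(trace.times[support], trace.values[support], poly_degree)
    corrected = trace.values - poly(trace.times)
    # re-correct peak interiors with the first-degree (chord) baseline
    for s, e in bounds:
        if peak_endpoint == "signal":
            y0, y1 = trace.values[s], trace.values[e]
        else:
            y0, y1 = poly(trace.times[s]), poly(trace.times[e])
        chord = np.interp(trace.times[s : e + 1], [trace.times[s], trace.times[e]], [y0, y1])
        corrected[s : e + 1] = trace.values[s : e + 1] - chord
    meta = dict(trace.meta)
    meta["peak_bounds"] = [tuple(b) for b in bounds]
    meta["baseline_poly"] = poly
    return PowerTrace(trace.times.copy(), corrected, meta)


def segment_injections(trace: PowerTrace, schedule: Optional[InjectionSchedule] = None) -> list[PowerTrace]:
    """Split a trace into one window per regular injection.

    Each window starts at its injection onset and ends at the next onset
    (or the trace end); the null injection's slot is excluded.  Windows
    carry ``injection_index`` (1-based) and ``onset_s`` in their meta.
    """
    schedule = schedule or trace.schedule
    if schedule is None:
        raise InvalidInputError("segmentation requires an injection schedule")
    slots, is_null = injection_slots(trace, schedule)
    windows = []
    index = 0
    for (i0, i1), null in zip(slots, is_null):
        if null:
            continue
        index += 1
        windows.append(trace.window(i0, i1, injection_index=index, onset_s=float(trace.times[i0])))
    if len(windows) != schedule.n_injections:
        raise InvalidInputError(
            f"trace yields {len(windows)} windows for {schedule.n_injections} scheduled injections"
        )
    return windows


def write_peak_bounds(path, trace: PowerTrace, bounds: Sequence[tuple[int, int]]) -> None:
    """Write detected peak bounds as a 3-column text file (index, start_s, end_s)."""
    lines = [
        f"{i}\t{trace.times[s]:.6g}\t{trace.times[e]:.6g}"
        for i, (s, e) in enumerate(bounds)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
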