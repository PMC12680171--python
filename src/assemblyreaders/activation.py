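"""Assembly activation strength and activation events.

The instantaneous activation strength of an assembly with weight vector C
is the quadratic form A(t) = z(t)' P z(t), where P = outer(C, C) with the
diagonal zeroed (so a single unit firing alone contributes nothing) and
z(t) is the standardized member spike count in a sliding window (15 ms
width, 1 ms step by default). Only member activity enters z, which keeps
the strength trace specific to member coactivity rather than global rate
fluctuations. An assembly is considered active while A(t) exceeds the 95th
percentile of the values above baseline (the median, which corresponds to
empty bins); the midpoint of each supra-threshold run is the activation
peak.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .spikes import (
    MS,
    IntervalSet,
    SpikeData,
    _count_in_windows,
    _grid_window_counts,
    bin_and_zscore,
)
from .detect import AssemblyModel

logger = logging.getLogger("assemblyreaders")


@dataclass
class ActivationSeries:
    """Activation-strength timeline plus extracted events."""

    times: np.ndarray  # window centers, seconds
    strength: np.ndarray
    window_ms: float
    step_ms: float
    assembly_id: int = 0
    baseline: float = np.nan
    threshold: float = np.nan
    starts: np.ndarray = field(default_factory=lambda: np.empty(0))
    stops: np.ndarray = field(default_factory=lambda: np.empty(0))
    peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_active: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    recruited: List[np.ndarray] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return self.peaks.size

    def incidence_hz(self, duration_s: float) -> float:
        return self.n_events / duration_s

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "assembly_id": self.assembly_id,
                "start_s": self.starts,
                "stop_s": self.stops,
                "peak_s": self.peaks,
                "n_active": self.n_active,
            }
        )

    def save_events(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.events_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(
                json.dumps([r.tolist() for r in self.recruited])
            )


def _strength_from_z(z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Quadratic form z' P z with P = outer(w, w), zero diagonal, for every
    column of z (computed without materializing P)."""
    s = w @ z
    return s * s - (w * w) @ (z * z)


def activation_strength(
    spikes: SpikeData,
    assembly: AssemblyModel,
    window_ms: float = 15.0,
    step_ms: float = 1.0,
    epochs: IntervalSet | None = None,
    use_all_units: bool = False,
) -> ActivationSeries:
    """Member-only activation strength A(t) on a sliding-window grid.

    With ``use_all_units`` the full weight vector and all units' activity
    are used instead (the control variant; normally inferior because
    nonmember bursts can mimic activations).
    """
    units = [int(u) for u in (assembly.unit_index if use_all_units else assembly.members)]
    if len(units) < 2:
        raise ValueError("activation strength needs at least two units")
    w = np.array([assembly.weight_of(u) for u in units])
    if epochs is None:
        tmax = max((spikes.trains[u][-1] for u in units if spikes.trains[u].size),
                   default=0.0)
        epochs = IntervalSet(np.array([[0.0, tmax + window_ms * MS]]))

    width, step = window_ms * MS, step_ms * MS
    starts = []
    for a, b in epochs.intervals:
        n = int(np.floor((b - a - width) / step + 1e-9)) + 1
        if n > 0:
            starts.append(a + step * np.arange(n))
    if not starts:
        raise ValueError("epochs shorter than one window")
    starts = np.concatenate(starts)
    times = starts + 0.5 * width

    # accumulate s = w'z and q = (w*w)'(z*z) one unit at a time, so the full
    # units x steps sliding matrix is never materialized (the all-units
    # variant at a 1-ms step would otherwise reach GB scale); standardization
    # reuses the fixed-bin statistics at the matching width, as in
    # sliding_counts
    stats = bin_and_zscore(spikes.subset(units), epochs,
                           bin_width_ms=window_ms, zscore=False)
    grid_exact = abs(window_ms / step_ms - round(window_ms / step_ms)) < 1e-9
    s = np.zeros(starts.size)
    q = np.zeros(starts.size)
    for wi, u in zip(w, units):
        if grid_exact:
            c = _grid_window_counts(spikes.trains[u], epochs, width, step)
        else:
            c = _count_in_windows(spikes.trains[u], starts, width)
        try:
            r = stats.row_of(u)
            z = (c - stats.row_mean[r]) / stats.row_std[r]
        except KeyError:  # silent unit: leave raw (all-zero) row
            z = c
        s += wi * z
        q += (wi * wi) * (z * z)
    strength = s * s - q
    return ActivationSeries(
        times=times,
        strength=strength,
        window_ms=window_ms,
        step_ms=step_ms,
        assembly_id=assembly.id,
    )


def extract_activation_events(
    series: ActivationSeries,
    spikes: SpikeData | None = None,
    assembly: AssemblyModel | None = None,
    percentile: float = 95.0,
) -> ActivationSeries:
    """Fill baseline, threshold and events on an ActivationSeries.

    Baseline is the median strength; the threshold is the ``percentile``-th
    percentile of the values strictly above baseline; events are maximal
    contiguous supra-threshold runs (runs never bridge gaps in the sampling
    grid). If spikes and the assembly are given, each event records which
    members fired within half a window of its peak.
    """
    a = series.strength
    baseline = float(np.median(a))
    above = a[a > baseline]
    if above.size == 0:
        logger.warning("constant strength trace: no activation events")
        series.baseline = baseline
        series.threshold = baseline
        return series
    threshold = float(np.percentile(above, percentile))
    series.baseline = baseline
    series.threshold = max(threshold, baseline)

    supra = a > series.threshold
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return series
    step = series.step_ms * MS
    # break runs at index gaps or time-grid gaps (epoch boundaries)
    gap = (np.diff(idx) > 1) | (np.diff(series.times[idx]) > 1.5 * step)
    run_starts = np.concatenate([[0], np.flatnonzero(gap) + 1])
    run_stops = np.concatenate([np.flatnonzero(gap), [idx.size - 1]])
    i0 = idx[run_starts]
    i1 = idx[run_stops]
    series.starts = series.times[i0]
    series.stops = series.times[i1]
    series.peaks = 0.5 * (series.starts + series.stops)

    if spikes is not None and assembly is not None:
        half = 0.5 * series.window_ms * MS
        members = np.asarray(assembly.members, int)
        active = np.zeros((series.peaks.size, members.size), bool)
        for j, m in enumerate(members):
            t = spikes.trains[m]
            lo = np.searchsorted(t, series.peaks - half)
            hi = np.searchsorted(t, series.peaks + half)
            active[:, j] = hi > lo
        series.n_active = active.sum(axis=1).astype(int)
        series.recruited = [members[row] for row in active]
    else:
        series.n_active = np.zeros(series.peaks.size, int)
        series.recruited = [np.empty(0, int) for _ in range(series.peaks.size)]
    return series


def activation_events(
    spikes: SpikeData,
    assembly: AssemblyModel,
    epochs: IntervalSet | None = None,
    window_ms: float | None = None,
    step_ms: float = 1.0,
    percentile: float = 95.0,
) -> ActivationSeries:
    """Strength plus events in one call (window defaults to the assembly's
    detection timescale)."""
    if window_ms is None:
        window_ms = assembly.timescale_ms
    series = activation_strength(spikes, assembly, window_ms, step_ms, epochs)
    return extract_activation_events(series, spikes, assembly, percentile)


def compare_member_vs_all_strength(
    spikes: SpikeData,
    assembly: AssemblyModel,
    epochs: IntervalSet | None = None,
    window_ms: float = 15.0,
    step_ms: float = 1.0,
) -> dict:
    """Fraction of members coactive around event peaks, for the member-only
    strength versus the all-units variant."""
    if len(assembly.members) < 2 or len(assembly.unit_index) <= len(assembly.members):
        raise ValueError("need >=2 members and >=1 nonmember")
    out = {}
    for label, use_all in (("member_only", False), ("all_units", True)):
        series = activation_strength(
            spikes, assembly, window_ms, step_ms, epochs, use_all_units=use_all
        )
        series = extract_activation_events(series, spikes, assembly)
        frac = (
            series.n_active / len(assembly.members)
            if series.n_events
            else np.empty(0)
        )
        out[label] = {
            "n_events": series.n_events,
            "coactive_fraction": float(np.mean(frac)) if frac.size else np.nan,
        }
    return out
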