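"""Spike-train containers, epoch restriction, and binning.

All internal times are seconds; user-facing bin widths, windows and delays
are milliseconds and converted at the API boundary. Bins are half-open
``[t, t + w)`` and left-aligned to each analysis epoch, with epochs binned
independently so that no bin straddles a gap between non-contiguous sleep
periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("assemblyreaders")

MS = 1e-3


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SpikeData:
    """Per-unit spike trains with structure/session/animal labels.

    Parameters
    ----------
    trains
        Mapping from integer unit id to a sorted array of spike times (s).
    structure
        Mapping from unit id to a structure label (e.g. ``"A"`` / ``"B"``
        for the two interconnected regions).
    session_id, animal_id
        Session and animal labels, used by the hierarchical bootstrap.
    """

    trains: Dict[int, np.ndarray]
    structure: Dict[int, str]
    session_id: str = "s0"
    animal_id: str = "a0"

    def __post_init__(self) -> None:
        clean: Dict[int, np.ndarray] = {}
        for unit, times in self.trains.items():
            t = np.asarray(times, dtype=float).ravel()
            if t.size and not np.all(np.isfinite(t)):
                raise ValueError(f"unit {unit}: non-finite spike times")
            if t.size and np.any(np.diff(t) < 0):
                t = np.sort(t)
            clean[int(unit)] = t
        self.trains = clean
        for unit in self.trains:
            if unit not in self.structure:
                raise ValueError(f"unit {unit} has no structure label")

    @property
    def units(self) -> np.ndarray:
        return np.array(sorted(self.trains), dtype=int)

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def units_in(self, structure: str) -> np.ndarray:
        return np.array(
            [u for u in sorted(self.trains) if self.structure[u] == structure],
            dtype=int,
        )

    def n_spikes(self, unit: int | None = None) -> int:
        if unit is not None:
            return int(self.trains[unit].size)
        return int(sum(t.size for t in self.trains.values()))

    def subset(self, units: Iterable[int]) -> "SpikeData":
        units = [int(u) for u in units]
        return SpikeData(
            trains={u: self.trains[u] for u in units},
            structure={u: self.structure[u] for u in units},
            session_id=self.session_id,
            animal_id=self.animal_id,
        )

    def pooled(self, units: Iterable[int] | None = None) -> np.ndarray:
        """All spike times of the given units (default: all), sorted."""
        units = list(units) if units is not None else list(self.trains)
        if not units:
            return np.empty(0)
        return np.sort(np.concatenate([self.trains[u] for u in units]))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame({"unit_id": u, "time_s": t})
            for u, t in sorted(self.trains.items())
        ]
        if not rows:
            return pd.DataFrame(columns=["unit_id", "time_s"])
        return pd.concat(rows, ignore_index=True)


@dataclass
class IntervalSet:
    """Sorted, non-overlapping ``[start, stop)`` analysis epochs (seconds)."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size == 0:
            raise ValueError("no analysis epochs")
        if np.any(iv[:, 0] >= iv[:, 1]):
            raise ValueError("interval start must precede stop")
        iv = iv[np.argsort(iv[:, 0])]
        if np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError("intervals overlap")
        self.intervals = iv

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def stops(self) -> np.ndarray:
        return self.intervals[:, 1]

    @property
    def total_duration(self) -> float:
        return float(np.sum(self.stops - self.starts))

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside some [start, stop)."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.starts, times, side="right") - 1
        ok = idx >= 0
        ok[ok] &= times[ok] < self.stops[idx[ok]]
        return ok


@dataclass
class BinnedMatrix:
    """Units x bins count (or z-scored) matrix on an epoch-aligned grid."""

    values: np.ndarray
    bin_width: float  # seconds
    bin_starts: np.ndarray  # seconds, one per column
    zscored: bool
    unit_index: np.ndarray  # unit id per row
    row_mean: np.ndarray = field(default=None)  # pre-z-score stats per row
    row_std: np.ndarray = field(default=None)

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row_of(self, unit: int) -> int:
        pos = np.flatnonzero(self.unit_index == unit)
        if pos.size == 0:
            raise KeyError(f"unit {unit} not in matrix")
        return int(pos[0])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def restrict_to_intervals(spikes: SpikeData, epochs: IntervalSet) -> SpikeData:
    """Keep only spikes inside the epochs; the unit set is preserved."""
    trains = {u: t[epochs.contains(t)] for u, t in spikes.trains.items()}
    return SpikeData(
        trains=trains,
        structure=dict(spikes.structure),
        session_id=spikes.session_id,
        animal_id=spikes.animal_id,
    )


def _epoch_bin_starts(epochs: IntervalSet, width: float) -> np.ndarray:
    """Left edges of half-open bins tiling each epoch independently."""
    starts = []
    for a, b in epochs.intervals:
        n = int(np.floor((b - a) / width + 1e-9))
        if n > 0:
            starts.append(a + width * np.arange(n))
    if not starts:
        return np.empty(0)
    return np.concatenate(starts)


def _count_in_windows(times: np.ndarray, starts: np.ndarray,
                      width: float) -> np.ndarray:
    """Spike count per half-open window [s, s + width) (windows may overlap)."""
    lo = np.searchsorted(times, starts, side="left")
    hi = np.searchsorted(times, starts + width, side="left")
    return (hi - lo).astype(np.float64)


def _grid_window_counts(times: np.ndarray, epochs: "IntervalSet",
                        width: float, step: float) -> np.ndarray:
    """Counts in windows [a + k*step, a + k*step + width) tiling each epoch,
    for width an integer multiple of step: bin spikes on the fine step grid
    and take a rolling sum (exact, O(n_steps) instead of O(n_windows log n))."""
    ratio = int(round(width / step))
    out = []
    for a, b in epochs.intervals:
        n_win = int(np.floor((b - a - width) / step + 1e-9)) + 1
        if n_win <= 0:
            continue
        n_fine = n_win + ratio - 1
        t = times[(times >= a) & (times < a + n_fine * step)]
        fine = np.bincount(
            np.minimum((np.floor((t - a) / step)).astype(np.int64), n_fine - 1),
            minlength=n_fine,
        )
        cs = np.concatenate([[0], np.cumsum(fine)])
        out.append((cs[ratio:] - cs[:-ratio]).astype(np.float64))
    return np.concatenate(out) if out else np.empty(0)


def bin_and_zscore(
    spikes: SpikeData,
    epochs: IntervalSet,
    bin_width_ms: float = 15.0,
    zscore: bool = True,
) -> BinnedMatrix:
    """Bin in-epoch spike counts and z-score each unit's row.

    Units whose binned counts have zero variance (e.g. silent units) cannot
    be z-scored; they are dropped from the matrix with a logged warning.
    The pre-z-scoring mean and standard deviation of every retained row are
    kept on the result so that sliding-window traces can be standardized
    with the same statistics used at detection time.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be positive")
    width = bin_width_ms * MS
    bin_starts = _epoch_bin_starts(epochs, width)
    if bin_starts.size == 0:
        raise ValueError("epochs shorter than one bin")

    units = spikes.units
    counts = np.empty((units.size, bin_starts.size))
    for i, u in enumerate(units):
        counts[i] = _grid_window_counts(spikes.trains[u], epochs, width, width)

    mean = counts.mean(axis=1)
    std = counts.std(axis=1)
    keep = std > 0
    if not np.all(keep):
        dropped = units[~keep].tolist()
        logger.warning(
            "excluding %d constant-rate/silent unit(s) from binned matrix: %s",
            len(dropped), dropped,
        )
    counts = counts[keep]
    units = units[keep]
    mean = mean[keep]
    std = std[keep]

    values = (counts - mean[:, None]) / std[:, None] if zscore else counts
    return BinnedMatrix(
        values=values,
        bin_width=width,
        bin_starts=bin_starts,
        zscored=zscore,
        unit_index=units,
        row_mean=mean,
        row_std=std,
    )


def sliding_counts(
    spikes: SpikeData,
    members: Sequence[int],
    window_ms: float = 15.0,
    step_ms: float = 1.0,
    epochs: IntervalSet | None = None,
) -> BinnedMatrix:
    """Member-only spike counts in overlapping windows, standardized with
    the fixed-bin statistics at the matching window width.

    Windows of ``window_ms`` advance by ``step_ms`` within each epoch.
    Rows are standardized with the mean/std of the non-overlapping binned
    counts at the same width, so the resulting trace is on the same scale
    as the z-scored matrix used for assembly detection.
    """
    members = [int(u) for u in members]
    if not members:
        raise ValueError("empty member set")
    if step_ms > window_ms:
        raise ValueError("step_ms must not exceed window_ms")
    if epochs is None:
        tmax = max(
            (spikes.trains[u][-1] for u in members if spikes.trains[u].size),
            default=0.0,
        )
        epochs = IntervalSet(np.array([[0.0, tmax + window_ms * MS]]))

    width = window_ms * MS
    step = step_ms * MS
    starts = []
    for a, b in epochs.intervals:
        n = int(np.floor((b - a - width) / step + 1e-9)) + 1
        if n > 0:
            starts.append(a + step * np.arange(n))
    if not starts:
        raise ValueError("epochs shorter than one window")
    starts = np.concatenate(starts)

    base = bin_and_zscore(
        spikes.subset(members), epochs, bin_width_ms=window_ms, zscore=False
    )
    grid_exact = abs(width / step - round(width / step)) < 1e-9
    values = np.empty((len(members), starts.size))
    mean = np.zeros(len(members))
    std = np.ones(len(members))
    for i, u in enumerate(members):
        if grid_exact:
            values[i] = _grid_window_counts(spikes.trains[u], epochs, width, step)
        else:
            values[i] = _count_in_windows(spikes.trains[u], starts, width)
        try:
            r = base.row_of(u)
            mean[i], std[i] = base.row_mean[r], base.row_std[r]
        except KeyError:  # silent unit: leave raw (all-zero) row
            mean[i], std[i] = 0.0, 1.0
    values = (values - mean[:, None]) / std[:, None]
    return BinnedMatrix(
        values=values,
        bin_width=width,
        bin_starts=starts,
        zscored=True,
        unit_index=np.array(members, dtype=int),
        row_mean=mean,
        row_std=std,
    )


# ---------------------------------------------------------------------------
# text-format I/O
# ---------------------------------------------------------------------------

def load_spikes(
    spike_path: str | Path,
    metadata_path: str | Path | None = None,
    sep: str = "\t",
) -> SpikeData:
    """Read a delimited spike table (columns unit_id, time_s) plus optional
    unit metadata (unit_id, structure, session_id, animal_id)."""
    df = pd.read_csv(spike_path, sep=sep)
    for col in ("unit_id", "time_s"):
        if col not in df.columns:
            raise ValueError(f"spike table missing column '{col}'")
    trains = {
        int(u): np.sort(g["time_s"].to_numpy(float))
        for u, g in df.groupby("unit_id")
    }
    structure = {u: "A" for u in trains}
    session_id, animal_id = "s0", "a0"
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep=sep)
        for col in ("unit_id", "structure"):
            if col not in meta.columns:
                raise ValueError(f"unit metadata missing column '{col}'")
        structure = dict(
            zip(meta["unit_id"].astype(int), meta["structure"].astype(str))
        )
        for u in trains:
            if u not in structure:
                raise ValueError(f"unit {u} missing from metadata")
        if "session_id" in meta.columns:
            session_id = str(meta["session_id"].iloc[0])
        if "animal_id" in meta.columns:
            animal_id = str(meta["animal_id"].iloc[0])
    return SpikeData(trains, structure, session_id, animal_id)


def save_spikes(
    spikes: SpikeData,
    spike_path: str | Path,
    metadata_path: str | Path | None = None,
    sep: str = "\t",
) -> None:
    spikes.to_dataframe().to_csv(spike_path, sep=sep, index=False)
    if metadata_path is not None:
        meta = pd.DataFrame(
            {
                "unit_id": sorted(spikes.trains),
                "structure": [spikes.structure[u] for u in sorted(spikes.trains)],
                "session_id": spikes.session_id,
                "animal_id": spikes.animal_id,
            }
        )
        meta.to_csv(metadata_path, sep=sep, index=False)


def load_intervals(path: str | Path, sep: str = "\t") -> IntervalSet:
    df = pd.read_csv(path, sep=sep)
    for col in ("start_s", "stop_s"):
        if col not in df.columns:
            raise ValueError(f"interval table missing column '{col}'")
    return IntervalSet(df[["start_s", "stop_s"]].to_numpy(float))


def save_intervals(epochs: IntervalSet, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(epochs.intervals, columns=["start_s", "stop_s"]).to_csv(
        path, sep=sep, index=False
    )


def load_neurosuite(
    res_path: str | Path,
    clu_path: str | Path,
    sampling_rate: float = 20000.0,
    structure: str = "A",
) -> SpikeData:
    """Read paired neurosuite-style .res (sample index) / .clu (cluster id)
    files; the first line of the .clu file is the cluster count. Clusters 0
    and 1 (noise / multi-unit by convention) are dropped."""
    samples = np.loadtxt(res_path, dtype=np.int64, ndmin=1)
    clu = np.loadtxt(clu_path, dtype=np.int64, ndmin=1)[1:]
    if samples.size != clu.size:
        raise ValueError(".res and .clu files have mismatched lengths")
    times = samples / sampling_rate
    trains = {
        int(c): np.sort(times[clu == c]) for c in np.unique(clu) if c >= 2
    }
    return SpikeData(trains, {u: structure for u in trains})
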