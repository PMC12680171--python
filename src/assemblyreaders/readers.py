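"""Downstream (reader) responses to assembly activation peaks.

For each candidate assembly-reader pair, reader spikes are collected in a
2-s window (10-ms bins) centered on activation peaks, giving a trials x
bins response matrix M. Significance is assessed against a Monte-Carlo
null built by independently permuting the time bins within each trial row
(200 repeats), which preserves every trial's spike count while destroying
temporal alignment. A pair is significant when the summed PETH exceeds the
per-bin 95th-percentile (pointwise) band in at least one bin of the
10-30 ms response window, its maximum exceeds the 95th percentile of the
per-shuffle maxima (the global band, which controls for multiple bins),
and the PETH mode sits at a positive delay. PETHs with fewer than 30
spikes are not testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from numba import njit
from scipy import stats

from .spikes import MS, IntervalSet, SpikeData
from .activation import ActivationSeries
from .detect import random_balanced_halves

logger = logging.getLogger("assemblyreaders")

MIN_PETH_SPIKES = 30


@dataclass
class PethResult:
    """Trial x bin response matrix with Monte-Carlo significance bands."""

    M: np.ndarray  # trials x bins spike counts
    bin_ms: float
    half_window_s: float
    m: np.ndarray = field(default=None)  # summed PETH per bin
    shuffle_mean: np.ndarray = field(default=None)
    shuffle_sd: np.ndarray = field(default=None)
    pointwise_band: np.ndarray = field(default=None)
    global_band: float = np.nan
    response_score: np.ndarray = field(default=None)
    excluded: bool = False
    n_spikes_total: int = 0

    def __post_init__(self) -> None:
        if self.m is None:
            self.m = self.M.sum(axis=0).astype(np.int64)
        self.n_spikes_total = int(self.m.sum())
        if self.n_spikes_total < MIN_PETH_SPIKES:
            self.excluded = True

    @property
    def n_trials(self) -> int:
        return self.M.shape[0]

    @property
    def n_bins(self) -> int:
        return self.M.shape[1]

    @property
    def bin_starts_ms(self) -> np.ndarray:
        return -self.half_window_s / MS + self.bin_ms * np.arange(self.n_bins)

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return self.bin_starts_ms + self.bin_ms / 2


def window_counts(
    times: np.ndarray, refs: np.ndarray, lo_ms: float, hi_ms: float
) -> np.ndarray:
    """Spike count per reference in [ref + lo_ms, ref + hi_ms) (ms)."""
    refs = np.asarray(refs, float)
    lo = np.searchsorted(times, refs + lo_ms * MS)
    hi = np.searchsorted(times, refs + hi_ms * MS)
    return (hi - lo).astype(np.int64)


def compute_peth(
    reader_times: np.ndarray,
    peaks: np.ndarray,
    half_window_s: float = 1.0,
    bin_ms: float = 10.0,
) -> PethResult:
    """Fill the trials x bins response matrix around activation peaks."""
    peaks = np.asarray(peaks, float)
    if peaks.size == 0:
        raise ValueError("no activation peaks")
    q = int(round(2 * half_window_s / (bin_ms * MS)))
    rel_edges = -half_window_s + bin_ms * MS * np.arange(q + 1)
    M = np.empty((peaks.size, q), dtype=np.int64)
    for i, p in enumerate(peaks):
        pos = np.searchsorted(reader_times, p + rel_edges)
        M[i] = np.diff(pos)
    return PethResult(M=M, bin_ms=bin_ms, half_window_s=half_window_s)


@njit(cache=True)
def _null_peth_sums(nnz, vals, q, n_shuffles, seed):  # pragma: no cover
    """Summed null PETHs under independent within-trial bin permutation.

    Permuting a trial's q bins uniformly is equivalent to assigning its
    nonzero counts to a uniform ordered subset of distinct bins; a partial
    Fisher-Yates draw per trial gives exactly that at O(nnz) per shuffle.
    """
    np.random.seed(seed)
    idxs = np.arange(q)
    out = np.zeros((n_shuffles, q), np.int64)
    for s in range(n_shuffles):
        off = 0
        for t in range(nnz.size):
            k = nnz[t]
            for j in range(k):
                r = j + np.random.randint(0, q - j)
                tmp = idxs[j]
                idxs[j] = idxs[r]
                idxs[r] = tmp
                out[s, idxs[j]] += vals[off + j]
            off += k
    return out


def shuffle_bands(
    peth: PethResult, n_shuffles: int = 200, seed: int = 0
) -> PethResult:
    """Fill pointwise/global bands and the response score from the
    within-trial bin-permutation null."""
    if peth.excluded:
        raise ValueError("PETH excluded (fewer than 30 spikes)")
    trial_idx, bin_idx = np.nonzero(peth.M)
    vals = peth.M[trial_idx, bin_idx]
    nnz = np.bincount(trial_idx, minlength=peth.n_trials).astype(np.int64)
    null = _null_peth_sums(
        nnz, vals.astype(np.int64), peth.n_bins, n_shuffles, int(seed) % (2**31 - 1)
    )
    peth.pointwise_band = np.percentile(null, 95, axis=0)
    peth.global_band = float(np.percentile(null.max(axis=1), 95))
    peth.shuffle_mean = null.mean(axis=0)
    peth.shuffle_sd = null.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        peth.response_score = np.where(
            peth.shuffle_sd > 0,
            (peth.m - peth.shuffle_mean) / peth.shuffle_sd,
            np.nan,
        )
    return peth


def classify_reader_pair(
    peth: PethResult,
    response_window_ms: Tuple[float, float] = (10.0, 30.0),
) -> dict:
    """Verdict for one assembly-reader pair (see module docstring for the
    three criteria). The PETH mode must be a unique positive-delay argmax."""
    if peth.excluded:
        return {"testable": False, "significant": False}
    if peth.pointwise_band is None:
        raise ValueError("bands not computed; call shuffle_bands first")
    starts = peth.bin_starts_ms
    lo, hi = response_window_ms
    in_window = (starts >= lo - 1e-9) & (starts + peth.bin_ms <= hi + 1e-9)
    exceeds_pointwise = peth.m > peth.pointwise_band
    peak = peth.m.max()
    mode_positions = np.flatnonzero(peth.m == peak)
    mode_ok = mode_positions.size == 1 and peth.bin_centers_ms[mode_positions[0]] > 0
    crit_window = bool(np.any(exceeds_pointwise & in_window))
    crit_global = bool(peak > peth.global_band)
    sig_bins = np.flatnonzero(exceeds_pointwise & (peth.m > peth.global_band))
    first_sig = (
        float(peth.bin_centers_ms[sig_bins[0]]) if sig_bins.size else np.nan
    )
    return {
        "testable": True,
        "significant": bool(crit_window and crit_global and mode_ok),
        "crit_window": crit_window,
        "crit_global": crit_global,
        "crit_mode": bool(mode_ok),
        "mode_delay_ms": float(peth.bin_centers_ms[mode_positions[0]]),
        "first_sig_delay_ms": first_sig,
        "peak_score": float(np.nanmax(peth.response_score)),
        "n_events": peth.n_trials,
        "n_spikes": peth.n_spikes_total,
    }


def test_pair(
    reader_times: np.ndarray,
    peaks: np.ndarray,
    n_shuffles: int = 200,
    seed: int = 0,
    half_window_s: float = 1.0,
    bin_ms: float = 10.0,
    response_window_ms: Tuple[float, float] = (10.0, 30.0),
) -> Tuple[PethResult, dict]:
    """PETH + bands + verdict in one call."""
    peth = compute_peth(reader_times, peaks, half_window_s, bin_ms)
    if peth.excluded:
        return peth, {"testable": False, "significant": False}
    shuffle_bands(peth, n_shuffles=n_shuffles, seed=seed)
    return peth, classify_reader_pair(peth, response_window_ms)


def delay_profile(verdicts: Sequence[dict], bin_ms: float = 10.0) -> dict:
    """Percentage of testable pairs whose first significant delay falls in
    each 10-ms delay bin across the +-1 s window."""
    testable = [v for v in verdicts if v.get("testable")]
    if not testable:
        raise ValueError("no testable pairs")
    edges = np.arange(-1000.0, 1000.0 + bin_ms / 2, bin_ms)
    delays = np.array(
        [
            v["first_sig_delay_ms"]
            for v in testable
            if np.isfinite(v.get("first_sig_delay_ms", np.nan))
        ]
    )
    counts, _ = np.histogram(delays, edges)
    return {
        "delay_ms": 0.5 * (edges[:-1] + edges[1:]),
        "percent": 100.0 * counts / len(testable),
        "n_pairs": len(testable),
    }


def split_half_response_score(
    reader_times: np.ndarray,
    peaks: np.ndarray,
    seed: int = 0,
    n_shuffles: int = 200,
    chunk_s: float = 10.0,
) -> dict:
    """Response-score stability across two balanced random halves.

    Peaks are partitioned by two balanced sets of random time intervals;
    the per-bin response score is computed independently per half and the
    Pearson correlation between the two curves reported.
    """
    peaks = np.asarray(peaks, float)
    span = IntervalSet(np.array([[peaks.min() - 1.0, peaks.max() + 1.0]]))
    half_a, half_b = random_balanced_halves(span, seed=seed, chunk_s=chunk_s)
    scores = []
    for half in (half_a, half_b):
        sel = peaks[half.contains(peaks)]
        if sel.size == 0:
            return {"testable": False}
        peth = compute_peth(reader_times, sel)
        if peth.excluded:
            return {"testable": False}
        shuffle_bands(peth, n_shuffles=n_shuffles, seed=seed)
        scores.append(peth.response_score)
    ok = np.isfinite(scores[0]) & np.isfinite(scores[1])
    r = float(np.corrcoef(scores[0][ok], scores[1][ok])[0, 1])
    return {"testable": True, "correlation": r}


def member_count_response_curve(
    reader_times: np.ndarray,
    events: ActivationSeries,
    response_window_ms: Tuple[float, float] = (10.0, 30.0),
    min_events: int = 20,
) -> dict:
    """Reader response in the 10-30 ms window stratified by the number of
    coactive members, with a Spearman monotone-trend statistic computed
    across events. Strata with fewer than ``min_events`` events are omitted
    from the stratum means."""
    if events.n_events == 0:
        raise ValueError("no events")
    lo, hi = response_window_ms
    win_s = (hi - lo) * MS
    resp = window_counts(reader_times, events.peaks, lo, hi) / win_s  # Hz
    n_active = events.n_active
    strata = [int(v) for v in np.unique(n_active) if v >= 1]
    means, counts, kept = [], [], []
    for v in strata:
        mask = n_active == v
        if mask.sum() >= min_events:
            kept.append(v)
            means.append(float(resp[mask].mean()))
            counts.append(int(mask.sum()))
    out = {
        "n_active": kept,
        "mean_response_hz": means,
        "n_events": counts,
    }
    if len(kept) < 2:
        out.update({"testable": False, "spearman_rho": np.nan, "p": np.nan})
        return out
    rho, p = stats.spearmanr(n_active, resp)
    out.update({"testable": True, "spearman_rho": float(rho), "p": float(p)})
    return out


def member_influence(
    reader_times: np.ndarray,
    spikes: SpikeData,
    members: Sequence[int],
    events: ActivationSeries,
    response_window_ms: Tuple[float, float] = (10.0, 30.0),
) -> dict:
    """Per-member influence: mean reader response (10-30 ms) following that
    member's spikes emitted outside activation epochs."""
    lo, hi = response_window_ms
    out = {}
    for m in members:
        t = spikes.trains[int(m)]
        if events.n_events:
            inside = np.zeros(t.size, bool)
            idx = np.searchsorted(events.starts, t, side="right") - 1
            ok = idx >= 0
            inside[ok] = t[ok] <= events.stops[idx[ok]]
            t = t[~inside]
        out[int(m)] = (
            float(window_counts(reader_times, t, lo, hi).mean()) if t.size else 0.0
        )
    return out


def leave_k_out_response(
    reader_times: np.ndarray,
    spikes: SpikeData,
    members: Sequence[int],
    events: ActivationSeries,
    k: int = 1,
    duration_s: float | None = None,
    response_window_ms: Tuple[float, float] = (10.0, 30.0),
    min_events: int = 20,
) -> dict:
    """Mean reader response using only activations in which the top-k most
    influential members were not recruited, compared with the reader's
    baseline rate."""
    members = [int(m) for m in members]
    if k >= len(members):
        raise ValueError("k must be smaller than the member count")
    infl = member_influence(reader_times, spikes, members, events, response_window_ms)
    top = sorted(infl, key=infl.get, reverse=True)[:k]
    keep = np.array(
        [not any(m in rec for m in top) for rec in events.recruited]
    )
    if keep.sum() < min_events:
        return {"testable": False, "top_members": top, "n_events": int(keep.sum())}
    lo, hi = response_window_ms
    win_s = (hi - lo) * MS
    resp = window_counts(reader_times, events.peaks[keep], lo, hi) / win_s
    if duration_s is None:
        duration_s = float(reader_times.max() - reader_times.min()) or 1.0
    baseline = reader_times.size / duration_s
    return {
        "testable": True,
        "top_members": top,
        "n_events": int(keep.sum()),
        "response_hz": float(resp.mean()),
        "baseline_hz": float(baseline),
    }
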