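"""Collective nature of reader responses: supralinearity and identity
selectivity.

The linear benchmark is a least-squares readout (identity link) trained to
predict reader spike counts around member spikes emitted *outside* assembly
activations, from the member spike-count vector in 15-ms bins. Applied to
member spikes emitted *during* activations it yields the response eta that
a reader summing its inputs linearly would show; the supralinearity index

    S(dt) = (mean R_in(dt) - mean eta(dt)) / mean eta(20 ms)

is positive when the observed in-assembly response exceeds linear
summation. Two surrogate readers bracket the measure: a "perfect" reader
spiking 20 ms after every activation that recruits at least half the
(observed) members, and an "independent" reader that copies every member
spike with a 20-ms shift.

Identity selectivity (AB/AA): reader PETHs around pairs of spikes from two
different members (AB) are compared with pairs from one member (AA) at the
same total spike count, jointly z-scored; a coincidence detector responds
more to AB than AA only at brief inter-spike delays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .spikes import MS, IntervalSet, SpikeData
from .activation import ActivationSeries, activation_events
from .detect import AssemblyModel, detect, match_assemblies
from .readers import window_counts

logger = logging.getLogger("assemblyreaders")


# ---------------------------------------------------------------------------
# linear readout and supralinearity
# ---------------------------------------------------------------------------

@dataclass
class LinearReadout:
    """Least-squares readout trained outside activations, evaluated inside."""

    delays_ms: np.ndarray
    W: np.ndarray  # n_delays x (m + 1), constant term first
    eta: np.ndarray  # mean linear prediction per delay, in-assembly triggers
    r_in: np.ndarray  # mean observed reader count per delay, in-assembly
    r_out: np.ndarray  # same, out-of-assembly triggers
    n_in: int
    n_out: int
    bin_ms: float

    @property
    def eta_20ms(self) -> float:
        return float(np.interp(20.0, self.delays_ms, self.eta))

    def at(self, curve: np.ndarray, delay_ms: float) -> float:
        return float(np.interp(delay_ms, self.delays_ms, curve))


def split_member_triggers(
    spikes: SpikeData,
    members: Sequence[int],
    events: ActivationSeries | Sequence[ActivationSeries],
) -> Tuple[np.ndarray, np.ndarray]:
    """Pool member spikes and split them into in-assembly triggers (inside
    any supra-threshold run of the given event series) and out-of-assembly
    triggers (outside all of them)."""
    if isinstance(events, ActivationSeries):
        events = [events]
    t = spikes.pooled(members)
    inside = np.zeros(t.size, bool)
    for ev in events:
        if ev.n_events == 0:
            continue
        idx = np.searchsorted(ev.starts, t, side="right") - 1
        ok = idx >= 0
        upd = np.zeros(t.size, bool)
        upd[ok] = t[ok] <= ev.stops[idx[ok]]
        inside |= upd
    return t[inside], t[~inside]


def _design(
    spikes: SpikeData, members: Sequence[int], triggers: np.ndarray, bin_ms: float
) -> np.ndarray:
    """(n_triggers x (m+1)) member counts in one bin centered on each trigger,
    constant term first."""
    half = bin_ms / 2
    cols = [np.ones(triggers.size)]
    for m in members:
        cols.append(window_counts(spikes.trains[int(m)], triggers, -half, half))
    return np.column_stack(cols)


def fit_linear_readout(
    reader_times: np.ndarray,
    spikes: SpikeData,
    members: Sequence[int],
    in_triggers: np.ndarray,
    out_triggers: np.ndarray,
    bin_ms: float = 15.0,
    delay_step_ms: float = 5.0,
    delay_range_ms: Tuple[float, float] = (-1000.0, 1000.0),
    min_out: int = 200,
    max_triggers: int = 4000,
    seed: int = 0,
) -> LinearReadout:
    """Fit W per delay on out-of-assembly triggers and evaluate eta on
    in-assembly triggers.

    All delays share one design matrix, so the fit is a single multi-RHS
    least-squares solve; rank deficiency falls back to the pseudo-inverse
    (minimum-norm) solution with a log entry. Trigger sets larger than
    ``max_triggers`` are subsampled for tractability.
    """
    if out_triggers.size < min_out:
        raise ValueError(
            f"need at least {min_out} out-of-assembly triggers, got {out_triggers.size}"
        )
    rng = np.random.default_rng(seed)
    if out_triggers.size > max_triggers:
        out_triggers = np.sort(rng.choice(out_triggers, max_triggers, replace=False))
    if in_triggers.size > max_triggers:
        in_triggers = np.sort(rng.choice(in_triggers, max_triggers, replace=False))

    delays = np.arange(delay_range_ms[0], delay_range_ms[1] + delay_step_ms / 2,
                       delay_step_ms)
    half = bin_ms / 2
    X_out = _design(spikes, members, out_triggers, bin_ms)
    R_out = np.column_stack(
        [window_counts(reader_times, out_triggers, d - half, d + half)
         for d in delays]
    ).astype(float)
    W, _, rank, _ = np.linalg.lstsq(X_out, R_out, rcond=None)
    if rank < X_out.shape[1]:
        logger.warning(
            "rank-deficient linear-readout design (rank %d < %d); "
            "minimum-norm solution used", rank, X_out.shape[1]
        )
    X_in = _design(spikes, members, in_triggers, bin_ms)
    eta = (X_in @ W).mean(axis=0) if in_triggers.size else np.full(delays.size, np.nan)
    r_in = (
        np.array(
            [window_counts(reader_times, in_triggers, d - half, d + half).mean()
             for d in delays]
        )
        if in_triggers.size
        else np.full(delays.size, np.nan)
    )
    return LinearReadout(
        delays_ms=delays,
        W=W.T,
        eta=eta,
        r_in=r_in,
        r_out=R_out.mean(axis=0),
        n_in=int(in_triggers.size),
        n_out=int(out_triggers.size),
        bin_ms=bin_ms,
    )


def supralinearity_index(readout: LinearReadout) -> np.ndarray:
    """S per delay; raises if the 20-ms linear prediction is non-positive
    (the normalization is then undefined)."""
    norm = readout.eta_20ms
    if not norm > 0:
        raise ValueError("not testable: eta at 20 ms is not positive")
    return (readout.r_in - readout.eta) / norm


def supralinearity_zdiff(readout: LinearReadout, delay_ms: float = 20.0) -> float:
    """Observed-minus-linear response at one delay after jointly z-scoring
    the R_in and eta curves (concatenated into a single vector); the scale-
    free statistic used in the timescale scan."""
    both = np.concatenate([readout.r_in, readout.eta])
    mu, sd = both.mean(), both.std()
    if sd == 0:
        return np.nan
    z_in = (readout.r_in - mu) / sd
    z_eta = (readout.eta - mu) / sd
    return readout.at(z_in - z_eta, delay_ms)


# ---------------------------------------------------------------------------
# simulated readers
# ---------------------------------------------------------------------------

def simulate_perfect_reader(
    events: ActivationSeries, n_members: int, delay_ms: float = 20.0
) -> np.ndarray:
    """Surrogate spike train responding exclusively to collective activity:
    one spike ``delay_ms`` after each activation peak recruiting at least
    half the members. For assemblies whose largest observed coactive subset
    n is smaller than the full size, the half-rule uses n/2."""
    if events.n_events == 0:
        return np.empty(0)
    n_ref = int(events.n_active.max())
    if n_ref >= n_members:
        n_ref = n_members
    need = n_ref / 2.0
    sel = events.peaks[events.n_active >= need]
    return np.sort(sel + delay_ms * MS)


def simulate_independent_reader(
    spikes: SpikeData, members: Sequence[int], delay_ms: float = 20.0
) -> np.ndarray:
    """Surrogate that copies every member spike with a +20 ms shift."""
    return spikes.pooled(members) + delay_ms * MS


# ---------------------------------------------------------------------------
# AB / AA identity selectivity
# ---------------------------------------------------------------------------

def find_ab_aa_events(
    times_a: np.ndarray,
    times_b: np.ndarray,
    timescale_ms: float = 15.0,
    delay_window_ms: Tuple[float, float] | None = None,
    other_times: np.ndarray | None = None,
) -> dict:
    """Find AB events (one A and one B spike within the timescale, no
    intervening A or B spike) and AA events (two consecutive A spikes under
    the same rule). Reference time is the midpoint of the two spikes.

    With ``delay_window_ms`` the inter-spike delay must instead fall inside
    the given window (the 5-ms-precision delay-scan variant).

    ``other_times`` (pooled spikes of the remaining assembly members) lets
    the caller enforce the comparison's premise — a constant total count of
    assembly spikes — exactly: pairs with any other-member spike within
    half a timescale of either defining spike are rejected, so AB and AA
    events differ only in which of the two neurons fired.
    """
    lo, hi = (
        (0.0, timescale_ms) if delay_window_ms is None else delay_window_ms
    )
    t = np.concatenate([times_a, times_b])
    lab = np.concatenate(
        [np.zeros(times_a.size, int), np.ones(times_b.size, int)]
    )
    order = np.argsort(t, kind="stable")
    t, lab = t[order], lab[order]
    if t.size < 2:
        return {"ab_mid": np.empty(0), "ab_delay_ms": np.empty(0),
                "aa_mid": np.empty(0), "aa_delay_ms": np.empty(0)}
    dt = np.diff(t) / MS
    ok = (dt > lo) & (dt <= hi)  # consecutive => no intervening A/B spike
    if other_times is not None and len(other_times):
        guard = 0.5 * timescale_ms * MS
        other_times = np.asarray(other_times, float)
        nearby = (
            np.searchsorted(other_times, t[1:] + guard)
            - np.searchsorted(other_times, t[:-1] - guard)
        ) > 0
        ok &= ~nearby
    is_ab = ok & (lab[1:] != lab[:-1])
    is_aa = ok & (lab[1:] == 0) & (lab[:-1] == 0)
    mid = 0.5 * (t[1:] + t[:-1])
    return {
        "ab_mid": mid[is_ab],
        "ab_delay_ms": dt[is_ab],
        "aa_mid": mid[is_aa],
        "aa_delay_ms": dt[is_aa],
    }


@dataclass
class AbAaResult:
    """Jointly z-scored reader PETHs around AB and AA event midpoints."""

    bin_centers_ms: np.ndarray
    peth_aa: np.ndarray  # z-scored
    peth_ab: np.ndarray
    difference: np.ndarray  # AB - AA per bin
    n_aa: int
    n_ab: int
    degenerate: bool = False

    def difference_at(self, delay_ms: float = 20.0) -> float:
        return float(
            np.interp(delay_ms, self.bin_centers_ms, self.difference)
        )


def ab_aa_response(
    reader_times: np.ndarray,
    ab_mid: np.ndarray,
    aa_mid: np.ndarray,
    half_window_s: float = 0.5,
    bin_ms: float = 10.0,
    min_events: int = 20,
) -> AbAaResult:
    """Reader PETHs around AB and AA midpoints, normalized conjointly:
    the two mean-rate curves are concatenated to compute one mean and sd,
    then each curve is z-scored with them."""
    if ab_mid.size < min_events or aa_mid.size < min_events:
        raise ValueError(f"need at least {min_events} AB and AA events")
    edges = np.arange(-half_window_s, half_window_s + bin_ms * MS / 2, bin_ms * MS)
    centers = 0.5 * (edges[:-1] + edges[1:]) / MS

    def mean_rate(refs: np.ndarray) -> np.ndarray:
        counts = np.zeros(centers.size)
        for lo_idx, e in enumerate(edges[:-1]):
            counts[lo_idx] = window_counts(
                reader_times, refs, e / MS, edges[lo_idx + 1] / MS
            ).sum()
        return counts / (refs.size * bin_ms * MS)

    m_ab = mean_rate(ab_mid)
    m_aa = mean_rate(aa_mid)
    both = np.concatenate([m_ab, m_aa])
    mu, sd = both.mean(), both.std()
    if sd == 0:
        return AbAaResult(centers, m_aa * 0, m_ab * 0, m_ab * 0,
                          aa_mid.size, ab_mid.size, degenerate=True)
    z_ab = (m_ab - mu) / sd
    z_aa = (m_aa - mu) / sd
    return AbAaResult(
        bin_centers_ms=centers,
        peth_aa=z_aa,
        peth_ab=z_ab,
        difference=z_ab - z_aa,
        n_aa=int(aa_mid.size),
        n_ab=int(ab_mid.size),
    )


def ab_aa_delay_scan(
    reader_times: np.ndarray,
    times_a: np.ndarray,
    times_b: np.ndarray,
    delays_ms: Sequence[float] = tuple(np.arange(5.0, 105.0, 5.0)),
    precision_ms: float = 5.0,
    min_events: int = 20,
    response_delay_ms: float = 20.0,
    other_times: np.ndarray | None = None,
) -> dict:
    """AB-AA difference at the response delay, for inter-spike delays taken
    in 5-ms strata; strata lacking events are reported as NaN."""
    out_delays, out_diff, out_n = [], [], []
    for d in delays_ms:
        win = (d - precision_ms / 2, d + precision_ms / 2)
        ev = find_ab_aa_events(times_a, times_b, delay_window_ms=win,
                               other_times=other_times)
        out_delays.append(float(d))
        if ev["ab_mid"].size < min_events or ev["aa_mid"].size < min_events:
            out_diff.append(np.nan)
            out_n.append(0)
            continue
        res = ab_aa_response(reader_times, ev["ab_mid"], ev["aa_mid"],
                             min_events=min_events)
        out_diff.append(
            np.nan if res.degenerate else res.difference_at(response_delay_ms)
        )
        out_n.append(min(res.n_ab, res.n_aa))
    return {
        "delay_ms": np.array(out_delays),
        "ab_minus_aa": np.array(out_diff),
        "n_events": np.array(out_n),
    }


# ---------------------------------------------------------------------------
# timescale scan
# ---------------------------------------------------------------------------

DEFAULT_SCALES_MS = (1.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 75.0, 100.0)


def timescale_scan(
    spikes: SpikeData,
    epochs: IntervalSet,
    reader_times: np.ndarray,
    scales_ms: Sequence[float] = DEFAULT_SCALES_MS,
    seed: int = 0,
    match_threshold: float = 0.7,
    min_out: int = 200,
) -> dict:
    """Supralinearity versus detection timescale.

    Assemblies are re-detected at each scale; the "same" assembly is
    tracked across scales by greedy |cosine| matching against the coarsest
    already-seen detection. At each scale, activation runs that contain an
    activation of the same assembly at a briefer scale are excluded, so
    the statistic reflects structure specific to that scale. The reported
    statistic is the jointly z-scored observed-minus-linear response at
    20 ms.
    """
    scales = sorted(scales_ms)
    per_scale: Dict[float, dict] = {}
    reference: List[AssemblyModel] = []
    briefer_events: Dict[int, List[ActivationSeries]] = {}

    for scale in scales:
        models = detect(spikes, epochs, bin_width_ms=scale, seed=seed)
        if not models:
            logger.info("no assemblies at %.0f ms scale", scale)
            per_scale[scale] = {"testable": False, "reason": "no assemblies"}
            continue
        if not reference:
            chain = list(range(len(models)))
            ref_ids = chain
            reference = models
            matched = [(i, i, 1.0) for i in range(len(models))]
        else:
            matched = match_assemblies(reference, models, threshold=match_threshold)
        if not matched:
            per_scale[scale] = {"testable": False, "reason": "no matched assembly"}
            continue
        stats_here = []
        for ref_idx, cur_idx, _cos in matched:
            model = models[cur_idx]
            ev = activation_events(spikes, model, epochs, window_ms=scale)
            if ev.n_events == 0:
                continue
            prior = briefer_events.get(ref_idx, [])
            keep = np.ones(ev.n_events, bool)
            for pe in prior:
                if pe.n_events == 0:
                    continue
                # drop runs overlapping any briefer-scale activation run
                lo = np.searchsorted(pe.stops, ev.starts[keep], side="left")
                overlap = (lo < pe.n_events) & (
                    pe.starts[np.minimum(lo, pe.n_events - 1)] <= ev.stops[keep]
                )
                idx = np.flatnonzero(keep)
                keep[idx[overlap]] = False
            briefer_events.setdefault(ref_idx, []).append(ev)
            if not np.any(keep):
                continue
            kept = ActivationSeries(
                times=ev.times, strength=ev.strength,
                window_ms=ev.window_ms, step_ms=ev.step_ms,
                assembly_id=ev.assembly_id,
                baseline=ev.baseline, threshold=ev.threshold,
                starts=ev.starts[keep], stops=ev.stops[keep],
                peaks=ev.peaks[keep],
                n_active=ev.n_active[keep],
                recruited=[r for r, k in zip(ev.recruited, keep) if k],
            )
            # in-triggers: inside the surviving runs at this scale;
            # out-triggers: outside the runs of every scale seen so far
            t_in, _ = split_member_triggers(spikes, model.members, kept)
            _, t_out = split_member_triggers(
                spikes, model.members, briefer_events[ref_idx]
            )
            if t_in.size == 0 or t_out.size < min_out:
                continue
            ro = fit_linear_readout(
                reader_times, spikes, model.members, t_in, t_out,
                bin_ms=scale, min_out=min_out, seed=seed,
            )
            stats_here.append(supralinearity_zdiff(ro))
        if not stats_here:
            per_scale[scale] = {"testable": False, "reason": "all epochs excluded"}
        else:
            per_scale[scale] = {
                "testable": True,
                "zdiff_20ms": float(np.nanmean(stats_here)),
                "n_assemblies": len(stats_here),
            }
    return per_scale
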