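"""Pattern completion and pattern separation statistics.

Completion: reader responses to every observed combination of recruited
members, as a function of the active fraction x = n_active / n_members,
normalized by the response to the complete assembly. A reader that
completes patterns responds near-fully to partial activations, so the
response curve is sigmoid rather than proportional; both models are fit
and compared by R^2, and the boost r - x (excess over proportionality) is
summarized per tertile of x.

Separation: the Hoyer sparsity of a neuron's response vector across the
simultaneously recorded assemblies (1 = responds to exactly one assembly,
0 = uniform), referenced to identity-shuffled surrogates, and a
discrimination index d = (r1 - r2) / (r1 + r2) between a paired assembly
and an overlapping assembly, tested against pooled-label shuffles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .spikes import MS
from .activation import ActivationSeries
from .detect import AssemblyModel
from .readers import window_counts

logger = logging.getLogger("assemblyreaders")


# ---------------------------------------------------------------------------
# pattern completion
# ---------------------------------------------------------------------------

def coactivation_events(
    spikes,
    members: Sequence[int],
    timescale_ms: float = 15.0,
) -> ActivationSeries:
    """Enumerate member co-activation events directly from the spike trains:
    each event is a maximal group of member spikes opened by its first spike
    and spanning one timescale window; the recruited subset is the set of
    distinct members firing in it and the reference time is the mean spike
    time. Unlike supra-threshold activation events, this includes partial
    and even single-member activations, as needed to probe completion."""
    members = [int(m) for m in members]
    t = np.concatenate([spikes.trains[m] for m in members])
    lab = np.concatenate(
        [np.full(spikes.trains[m].size, m, int) for m in members]
    )
    order = np.argsort(t, kind="stable")
    t, lab = t[order], lab[order]
    ts = timescale_ms * MS
    peaks, n_active, recruited, starts, stops = [], [], [], [], []
    i = 0
    while i < t.size:
        j = np.searchsorted(t, t[i] + ts, side="left")
        group = slice(i, j)
        units = np.unique(lab[group])
        peaks.append(float(t[group].mean()))
        starts.append(float(t[i]))
        stops.append(float(t[j - 1]))
        n_active.append(units.size)
        recruited.append(units)
        i = j
    return ActivationSeries(
        times=np.empty(0),
        strength=np.empty(0),
        window_ms=timescale_ms,
        step_ms=np.nan,
        starts=np.asarray(starts),
        stops=np.asarray(stops),
        peaks=np.asarray(peaks),
        n_active=np.asarray(n_active, int),
        recruited=recruited,
    )


def subset_responses(
    reader_times: np.ndarray,
    events: ActivationSeries,
    n_members: int,
    baseline_rate_hz: float,
    response_window_ms: Tuple[float, float] = (10.0, 30.0),
    min_events: int = 20,
) -> dict:
    """Mean reader response per distinct recruited member subset, relative
    to the reader's baseline rate; subsets with fewer than ``min_events``
    activations are omitted. Each activation counts toward exactly one
    subset (the set of members recruited at its peak)."""
    if baseline_rate_hz <= 0:
        raise ValueError("baseline rate must be positive")
    lo, hi = response_window_ms
    win_s = (hi - lo) * MS
    resp = window_counts(reader_times, events.peaks, lo, hi) / win_s
    groups: Dict[tuple, List[float]] = {}
    for r, rec in zip(resp, events.recruited):
        if len(rec) == 0:
            continue
        groups.setdefault(tuple(sorted(int(m) for m in rec)), []).append(float(r))
    subsets, x, rel, n = [], [], [], []
    for key, vals in sorted(groups.items(), key=lambda kv: (len(kv[0]), kv[0])):
        if len(vals) < min_events:
            continue
        subsets.append(key)
        x.append(len(key) / n_members)
        rel.append(float(np.mean(vals)) / baseline_rate_hz)
        n.append(len(vals))
    if not subsets:
        return {"testable": False}
    return {
        "testable": True,
        "subsets": subsets,
        "x": np.array(x),
        "response_rel": np.array(rel),
        "n_events": np.array(n, int),
    }


def _sigmoid(x: np.ndarray, k: float, x0: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-k * (x - x0)))


@dataclass
class CompletionFit:
    """Sigmoid-vs-proportional comparison for one assembly-reader pair."""

    x: np.ndarray
    y: np.ndarray  # responses normalized by the complete-assembly response
    k: float
    x0: float
    r2_sigmoid: float
    r2_proportional: float
    boost: np.ndarray  # y - x per observation
    tertile_boost: np.ndarray  # mean boost for x in (0,1/3], (1/3,2/3], (2/3,1]
    converged: bool = True


def fit_sigmoid_vs_proportional(
    x: np.ndarray,
    response_rel: np.ndarray,
    r_complete: float | None = None,
) -> CompletionFit:
    """Fit the normalized response curve with a bounded sigmoid
    F(x) = 1 / (1 + exp(-k (x - x0))) (multistart nonlinear least squares,
    k in (0, 100], x0 in [0, 1]) and compare against the parameter-free
    proportional model F(x) = x; R^2 uses the usual residual/total
    sum-of-squares ratio for both."""
    x = np.asarray(x, float)
    r = np.asarray(response_rel, float)
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct active fractions")
    if r_complete is None:
        r_complete = float(r[np.argmax(x)])
    if r_complete <= 0:
        raise ValueError("complete-assembly response must be positive")
    y = r / r_complete

    best = None
    for k0 in (2.0, 5.0, 10.0, 20.0, 50.0):
        for x0_0 in (0.25, 0.5, 0.75):
            try:
                popt, _ = curve_fit(
                    _sigmoid, x, y, p0=(k0, x0_0),
                    bounds=((1e-6, 0.0), (100.0, 1.0)), maxfev=2000,
                )
            except RuntimeError:
                continue
            sse = float(np.sum((y - _sigmoid(x, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
    sst = float(np.sum((y - y.mean()) ** 2))
    if best is None:
        logger.warning("sigmoid fit did not converge")
        k, x0, r2_sig, converged = np.nan, np.nan, np.nan, False
    else:
        k, x0 = (float(v) for v in best[1])
        r2_sig = 1.0 - best[0] / sst if sst > 0 else np.nan
        converged = True
    r2_prop = 1.0 - float(np.sum((y - x) ** 2)) / sst if sst > 0 else np.nan
    boost = y - x
    tert = np.full(3, np.nan)
    for i, (lo, hi) in enumerate(((0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1))):
        mask = (x > lo) & (x <= hi + 1e-12)
        if np.any(mask):
            tert[i] = float(boost[mask].mean())
    return CompletionFit(
        x=x, y=y, k=k, x0=x0,
        r2_sigmoid=r2_sig, r2_proportional=r2_prop,
        boost=boost, tertile_boost=tert, converged=converged,
    )


# ---------------------------------------------------------------------------
# pattern separation
# ---------------------------------------------------------------------------

def hoyer_sparsity(r: np.ndarray) -> float:
    """Hoyer sparsity H = (sqrt(n) - sum(r)/sqrt(sum(r^2))) / (sqrt(n) - 1);
    1 for a one-hot vector, 0 for a uniform positive vector."""
    r = np.asarray(r, float)
    n = r.size
    if n < 2:
        raise ValueError("not testable: need at least two assemblies")
    if np.any(r < 0):
        raise ValueError("Hoyer sparsity requires nonnegative responses")
    ssq = float(np.sum(r * r))
    if ssq == 0:
        raise ValueError("not testable: all responses zero")
    return float((np.sqrt(n) - np.sum(r) / np.sqrt(ssq)) / (np.sqrt(n) - 1.0))


def _event_responses(
    neuron_times: np.ndarray,
    events_by_assembly: Sequence[ActivationSeries],
    response_window_ms: Tuple[float, float],
) -> List[np.ndarray]:
    lo, hi = response_window_ms
    win_s = (hi - lo) * MS
    return [
        window_counts(neuron_times, ev.peaks, lo, hi) / win_s
        for ev in events_by_assembly
    ]


def _rectified_means(
    pooled: np.ndarray, sizes: np.ndarray, baseline_hz: float
) -> np.ndarray:
    """Per-assembly mean response minus baseline, floored at 0."""
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    means = np.array(
        [pooled[a:b].mean() if b > a else 0.0
         for a, b in zip(bounds[:-1], bounds[1:])]
    )
    return np.maximum(means - baseline_hz, 0.0)


def sparsity_increase(
    neuron_times: np.ndarray,
    events_by_assembly: Sequence[ActivationSeries],
    baseline_rate_hz: float,
    n_shuffles: int = 1000,
    seed: int = 0,
    response_window_ms: Tuple[float, float] = (10.0, 30.0),
) -> dict:
    """Hoyer sparsity of one neuron's per-assembly response vector,
    relative to surrogates where assembly identities are shuffled across
    all pooled activations: increase = (H - H0) / H0.

    Responses are baseline-subtracted and floored at zero so the sparsity
    stays in its documented range."""
    if len(events_by_assembly) < 2:
        raise ValueError("need at least two simultaneously recorded assemblies")
    per_assembly = _event_responses(neuron_times, events_by_assembly,
                                    response_window_ms)
    sizes = np.array([len(v) for v in per_assembly])
    pooled = np.concatenate(per_assembly)
    r = _rectified_means(pooled, sizes, baseline_rate_hz)
    try:
        H = hoyer_sparsity(r)
    except ValueError:
        return {"testable": False}
    rng = np.random.default_rng(seed)
    H0_samples = []
    for _ in range(n_shuffles):
        perm = rng.permutation(pooled)
        r0 = _rectified_means(perm, sizes, baseline_rate_hz)
        try:
            H0_samples.append(hoyer_sparsity(r0))
        except ValueError:
            continue
    if not H0_samples:
        return {"testable": False}
    H0 = float(np.mean(H0_samples))
    if H0 == 0:
        return {"testable": False}
    return {
        "testable": True,
        "H": H,
        "H0": H0,
        "increase": (H - H0) / H0,
        "n_shuffles": len(H0_samples),
    }


def assembly_overlap(a: AssemblyModel, b: AssemblyModel) -> int:
    return int(np.intersect1d(a.members, b.members).size)


def overlapping_pairs(
    assemblies: Sequence[AssemblyModel],
    min_overlap_frac: float = 0.25,
    min_members: int = 3,
) -> List[Tuple[int, int]]:
    """Pairs (i, j) sharing at least ``min_overlap_frac`` of each assembly's
    members, both assemblies having more than two members."""
    out = []
    for i, a in enumerate(assemblies):
        for j, b in enumerate(assemblies):
            if i == j:
                continue
            if len(a.members) < min_members or len(b.members) < min_members:
                continue
            ov = assembly_overlap(a, b)
            if ov >= min_overlap_frac * len(a.members) and (
                ov >= min_overlap_frac * len(b.members)
            ):
                out.append((i, j))
    return out


def discrimination_index(
    reader_times: np.ndarray,
    paired_events: ActivationSeries,
    overlapping_events: ActivationSeries,
    baseline_rate_hz: float = 0.0,
    n_shuffles: int = 1000,
    seed: int = 0,
    response_window_ms: Tuple[float, float] = (10.0, 30.0),
    min_events: int = 20,
) -> dict:
    """d = (r1 - r2) / (r1 + r2) between the paired and the overlapping
    assembly, with a null built by shuffling assembly labels over the
    pooled activations; significant when d exceeds the null's 95th
    percentile."""
    if paired_events.n_events < min_events or overlapping_events.n_events < min_events:
        return {"testable": False}
    resp = _event_responses(
        reader_times, [paired_events, overlapping_events], response_window_ms
    )
    sizes = np.array([len(v) for v in resp])
    pooled = np.concatenate(resp)
    r1, r2 = _rectified_means(pooled, sizes, baseline_rate_hz)
    if r1 + r2 == 0:
        return {"testable": False}
    d = (r1 - r2) / (r1 + r2)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_shuffles):
        perm = rng.permutation(pooled)
        s1, s2 = _rectified_means(perm, sizes, baseline_rate_hz)
        if s1 + s2 > 0:
            null.append((s1 - s2) / (s1 + s2))
    null = np.asarray(null)
    return {
        "testable": True,
        "d": float(d),
        "null_median": float(np.median(null)) if null.size else np.nan,
        "significant": bool(null.size and d > np.percentile(null, 95)),
        "n_shuffles": int(null.size),
    }
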