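"""Learning-related changes in assembly-reader responses across epochs.

Assemblies are detected on the concatenated pre+post sleep (so the "same"
assembly is compared by construction) and their activation events are
extracted per epoch. For each pair, the change statistic is the difference
in mean 10-30 ms response between post and pre activations; its null
distribution is built by permuting the epoch labels over the pooled
activations (the minimal exchangeability null for a pre/post difference).
A pair changes direction "increase"/"decrease" when the observed delta
falls outside the central 95% of the null. Change rates between conditions
(e.g. conditioning vs control) are contrasted with a 2x2 chi-squared test
without continuity correction, falling back to Fisher's exact test when an
expected cell count drops below 5.
"""

from __future__ import annotations

import logging
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .spikes import MS, IntervalSet, SpikeData
from .activation import ActivationSeries, activation_events
from .detect import detect
from .readers import window_counts

logger = logging.getLogger("assemblyreaders")


def response_change(
    reader_times: np.ndarray,
    pre_events: ActivationSeries | np.ndarray,
    post_events: ActivationSeries | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    response_window_ms: Tuple[float, float] = (10.0, 30.0),
    min_spikes: int = 30,
) -> dict:
    """Per-pair pre/post change verdict (see module docstring)."""
    peaks_pre = (
        pre_events.peaks if isinstance(pre_events, ActivationSeries) else
        np.asarray(pre_events, float)
    )
    peaks_post = (
        post_events.peaks if isinstance(post_events, ActivationSeries) else
        np.asarray(post_events, float)
    )
    if peaks_pre.size == 0 or peaks_post.size == 0:
        return {"testable": False, "direction": "none"}
    # enough reader spikes around the peaks of each epoch to form a PETH
    for peaks in (peaks_pre, peaks_post):
        n = int(window_counts(reader_times, peaks, -1000.0, 1000.0).sum())
        if n < min_spikes:
            return {"testable": False, "direction": "none"}
    lo, hi = response_window_ms
    win_s = (hi - lo) * MS
    r_pre = window_counts(reader_times, peaks_pre, lo, hi) / win_s
    r_post = window_counts(reader_times, peaks_post, lo, hi) / win_s
    delta = float(r_post.mean() - r_pre.mean())

    pooled = np.concatenate([r_pre, r_post])
    n_pre = r_pre.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    total = pooled.sum()
    for b in range(n_boot):
        idx = rng.permutation(pooled.size)
        s_pre = pooled[idx[:n_pre]].sum()
        null[b] = (total - s_pre) / (pooled.size - n_pre) - s_pre / n_pre
    lo_q, hi_q = np.percentile(null, [2.5, 97.5])
    if delta > hi_q:
        direction = "increase"
    elif delta < lo_q:
        direction = "decrease"
    else:
        direction = "none"
    p = 2.0 * min(
        (np.sum(null >= delta) + 1) / (n_boot + 1),
        (np.sum(null <= delta) + 1) / (n_boot + 1),
    )
    return {
        "testable": True,
        "response_pre": float(r_pre.mean()),
        "response_post": float(r_post.mean()),
        "delta": delta,
        "direction": direction,
        "significant": direction != "none",
        "p": float(min(p, 1.0)),
        "null_sd": float(null.std()),
        "n_pre": int(n_pre),
        "n_post": int(r_post.size),
    }


def pre_post_pipeline(
    spikes: SpikeData,
    pre_epochs: IntervalSet,
    post_epochs: IntervalSet,
    reader_units: Sequence[int] | None = None,
    upstream: str = "A",
    n_boot: int = 1000,
    seed: int = 0,
    bin_width_ms: float = 15.0,
) -> dict:
    """Detect upstream-structure assemblies on the pooled epochs, extract
    per-epoch activation events, and test every (assembly, reader) pair for
    a response change. Readers default to all units of the other structure."""
    both = IntervalSet(
        np.vstack([pre_epochs.intervals, post_epochs.intervals])
    )
    upstream_units = spikes.units_in(upstream)
    if reader_units is None:
        reader_units = [
            u for u in sorted(spikes.trains) if spikes.structure[u] != upstream
        ]
    models = detect(
        spikes.subset(upstream_units), both, bin_width_ms=bin_width_ms, seed=seed
    )
    verdicts = []
    for model in models:
        ev_pre = activation_events(spikes, model, pre_epochs)
        ev_post = activation_events(spikes, model, post_epochs)
        for u in reader_units:
            v = response_change(
                spikes.trains[int(u)], ev_pre, ev_post,
                n_boot=n_boot, seed=seed + 31 * model.id + int(u),
            )
            v.update({"assembly_id": model.id, "reader_unit": int(u)})
            verdicts.append(v)
    tested = [v for v in verdicts if v["testable"]]
    changed = [v for v in tested if v["significant"]]
    return {
        "n_assemblies": len(models),
        "verdicts": verdicts,
        "n_tested": len(tested),
        "n_changed": len(changed),
        "change_rate": len(changed) / len(tested) if tested else np.nan,
    }


def compare_change_rates(
    n_changed_a: int, n_tested_a: int, n_changed_b: int, n_tested_b: int
) -> dict:
    """2x2 chi-squared contrast of change rates between two conditions,
    without continuity correction; exact-test fallback when an expected
    count is below 5."""
    if n_tested_a < 1 or n_tested_b < 1:
        raise ValueError("need at least one tested pair per condition")
    table = np.array(
        [
            [n_changed_a, n_tested_a - n_changed_a],
            [n_changed_b, n_tested_b - n_changed_b],
        ]
    )
    expected = stats.contingency.expected_freq(table)
    if np.any(expected < 5):
        logger.info("expected cell count < 5: using Fisher's exact test")
        _, p = stats.fisher_exact(table)
        return {
            "test": "fisher",
            "statistic": np.nan,
            "p": float(p),
            "rate_a": n_changed_a / n_tested_a,
            "rate_b": n_changed_b / n_tested_b,
        }
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "test": "chi2",
        "statistic": float(chi2),
        "p": float(p),
        "rate_a": n_changed_a / n_tested_a,
        "rate_b": n_changed_b / n_tested_b,
    }
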