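"""Hierarchical bootstrap for nested (animal -> session -> observation) data.

Each bootstrap repeat resamples with replacement following the hierarchy:
animals first, then sessions within each drawn animal, then observations
within each drawn session, with the number of draws at every level equal
to the observed count at that level. The statistic (mean or median) is
computed per repeat and percentile confidence intervals are taken from the
resampled distribution, so the interval honours the dependence structure
of nested recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("assemblyreaders")

_STATS: dict = {"mean": np.mean, "median": np.median}


@dataclass
class BootstrapEstimate:
    point: float
    samples: np.ndarray
    ci_low: float
    ci_high: float
    repeats: int
    n_redrawn: int = 0


def hierarchical_bootstrap(
    values: np.ndarray,
    animals: Sequence,
    sessions: Sequence,
    statistic: str | Callable = "mean",
    repeats: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> BootstrapEstimate:
    """Percentile bootstrap CI respecting the animal/session nesting.

    Parameters
    ----------
    values
        Observations (one scalar each).
    animals, sessions
        Labels of the same length as ``values``.
    statistic
        ``"mean"``, ``"median"`` or a callable mapping an array to a scalar.
    """
    if repeats < 100:
        raise ValueError("use at least 100 bootstrap repeats")
    values = np.asarray(values, float)
    animals = np.asarray(animals)
    sessions = np.asarray(sessions)
    if not (values.size == animals.size == sessions.size):
        raise ValueError("values, animals and sessions must align")
    if values.size == 0:
        raise ValueError("no observations")
    stat = _STATS[statistic] if isinstance(statistic, str) else statistic
    rng = np.random.default_rng(seed)

    tree = {}
    for a in np.unique(animals):
        mask_a = animals == a
        tree[a] = {
            s: values[mask_a & (sessions == s)]
            for s in np.unique(sessions[mask_a])
        }
    animal_keys = list(tree)
    n_a = len(animal_keys)

    # balanced fast path: same session count per animal, same obs count per
    # session -> all index draws can be vectorized across repeats
    sess_counts = {a: len(tree[a]) for a in animal_keys}
    obs_counts = {
        (a, s): tree[a][s].size for a in animal_keys for s in tree[a]
    }
    balanced = (
        len(set(sess_counts.values())) == 1
        and len(set(obs_counts.values())) == 1
    )
    if balanced:
        n_s = next(iter(sess_counts.values()))
        n_o = next(iter(obs_counts.values()))
        data = np.array(
            [[tree[a][s] for s in tree[a]] for a in animal_keys]
        )  # n_a x n_s x n_o
        ai = rng.integers(0, n_a, (repeats, n_a))
        si = rng.integers(0, n_s, (repeats, n_a, n_s))
        oi = rng.integers(0, n_o, (repeats, n_a, n_s, n_o))
        drawn = data[
            ai[:, :, None, None], si[:, :, :, None], oi
        ].reshape(repeats, -1)
        samples = np.array([stat(row) for row in drawn])
        n_redrawn = 0
    else:
        samples = np.empty(repeats)
        n_redrawn = 0
        for b in range(repeats):
            while True:
                obs = []
                for ai_ in rng.integers(0, n_a, n_a):
                    a = animal_keys[ai_]
                    sess_keys = list(tree[a])
                    for si_ in rng.integers(0, len(sess_keys), len(sess_keys)):
                        v = tree[a][sess_keys[si_]]
                        if v.size:
                            obs.append(v[rng.integers(0, v.size, v.size)])
                if obs:
                    pooled = np.concatenate(obs)
                    val = stat(pooled)
                    if np.isfinite(val):
                        samples[b] = val
                        break
                n_redrawn += 1
        if n_redrawn:
            logger.info("redrew %d degenerate bootstrap resamples", n_redrawn)

    alpha = (100.0 - ci) / 2.0
    return BootstrapEstimate(
        point=float(stat(values)),
        samples=samples,
        ci_low=float(np.percentile(samples, alpha)),
        ci_high=float(np.percentile(samples, 100.0 - alpha)),
        repeats=repeats,
        n_redrawn=n_redrawn,
    )
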