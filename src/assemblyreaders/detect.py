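"""Candidate cell-assembly detection (PCA/ICA) and validation.

Detection follows the classical unsupervised recipe: spike trains are
binned (15 ms default) and z-scored; eigenvalues of the correlation matrix
exceeding the upper Marchenko-Pastur bound mark significant co-activation
subspaces; a fixed-point ICA on the projection onto that subspace extracts
one weight vector per significant dimension. Weight vectors are scaled to
unit norm with the sign convention that the largest absolute weight is
positive; members are the high-|weight| group under Otsu's threshold, and
assemblies whose members carry both signs are discarded (they reflect ICA
limitations rather than coincident firing).

Validation utilities: spike-identity shuffling (preserves global rate
fluctuations while destroying coactivity), split-half cross-validation,
peer prediction gain, and member-pair cross-correlograms.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.decomposition import FastICA

from .spikes import (
    MS,
    BinnedMatrix,
    IntervalSet,
    SpikeData,
    bin_and_zscore,
)

logger = logging.getLogger("assemblyreaders")


@dataclass
class AssemblyModel:
    """A detected ensemble: unit-norm weights plus Otsu membership."""

    weights: np.ndarray  # unit-norm, over unit_index
    unit_index: np.ndarray  # unit id per weight entry
    members: np.ndarray  # unit ids above the Otsu threshold
    otsu_threshold: float
    effectiveness: float  # inter-class / total variance of |weights|
    timescale_ms: float
    sign_valid: bool  # all member weights share one sign
    id: int = 0

    def member_weights(self) -> np.ndarray:
        pos = np.isin(self.unit_index, self.members)
        return self.weights[pos]

    def weight_of(self, unit: int) -> float:
        pos = np.flatnonzero(self.unit_index == unit)
        return float(self.weights[pos[0]]) if pos.size else 0.0

    def to_dict(self) -> dict:
        return {
            "id": int(self.id),
            "weights": self.weights.tolist(),
            "unit_index": self.unit_index.tolist(),
            "members": self.members.tolist(),
            "otsu_threshold": float(self.otsu_threshold),
            "effectiveness": float(self.effectiveness),
            "timescale_ms": float(self.timescale_ms),
            "sign_valid": bool(self.sign_valid),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssemblyModel":
        return cls(
            weights=np.asarray(d["weights"], float),
            unit_index=np.asarray(d["unit_index"], int),
            members=np.asarray(d["members"], int),
            otsu_threshold=d["otsu_threshold"],
            effectiveness=d["effectiveness"],
            timescale_ms=d["timescale_ms"],
            sign_valid=d["sign_valid"],
            id=d.get("id", 0),
        )


def save_assemblies(assemblies: Sequence[AssemblyModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([a.to_dict() for a in assemblies]))


def load_assemblies(path: str | Path) -> List[AssemblyModel]:
    return [AssemblyModel.from_dict(d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# eigenvalue significance and membership
# ---------------------------------------------------------------------------

def marcenko_pastur_bound(n_units: int, n_bins: int) -> float:
    """Upper edge (1 + sqrt(n_units/n_bins))^2 of the Marchenko-Pastur
    eigenvalue distribution for an n_units x n_bins white-noise matrix."""
    if n_bins <= n_units:
        raise ValueError("need more bins than units for the Marchenko-Pastur bound")
    if n_units < 1:
        raise ValueError("need at least one unit")
    return float((1.0 + np.sqrt(n_units / n_bins)) ** 2)


def otsu_members(weights: np.ndarray) -> Tuple[float, np.ndarray, float]:
    """Split |weights| into two groups by exhaustively maximizing the
    inter-class variance; returns (threshold, member indices, effectiveness).

    The threshold is the midpoint between the two groups; members are the
    high-|weight| group; effectiveness is inter-class over total variance.
    """
    w = np.abs(np.asarray(weights, float))
    order = np.argsort(w)
    ws = w[order]
    n = ws.size
    if np.ptp(ws) == 0:
        raise ValueError("no separation: all |weights| equal")
    # candidate split after position k: low = ws[:k+1], high = ws[k+1:]
    csum = np.cumsum(ws)
    total = csum[-1]
    k = np.arange(1, n)  # size of the low group
    mu_lo = csum[:-1] / k
    mu_hi = (total - csum[:-1]) / (n - k)
    p_lo = k / n
    inter = p_lo * (1 - p_lo) * (mu_lo - mu_hi) ** 2
    # splits between equal values are not real thresholds
    valid = ws[1:] > ws[:-1]
    inter[~valid] = -np.inf
    best = int(np.argmax(inter))
    threshold = 0.5 * (ws[best] + ws[best + 1])
    members = np.flatnonzero(w > threshold)
    effectiveness = float(inter[best] / np.var(w))
    return float(threshold), members, effectiveness


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _normalize_pattern(w: np.ndarray) -> np.ndarray:
    w = w / np.linalg.norm(w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


def detect_assemblies(
    Z: BinnedMatrix,
    seed: int = 0,
    dedup_cosine: float = 0.95,
) -> List[AssemblyModel]:
    """Detect candidate assemblies from a z-scored binned matrix.

    The number of ICA components equals the number of eigenvalues above the
    Marchenko-Pastur bound; ICA is initialized deterministically from
    ``seed``. Components with |cosine| above ``dedup_cosine`` are treated
    as duplicates and only the one with higher Otsu effectiveness is kept.
    Returns an empty list when no eigenvalue is significant.
    """
    if not Z.zscored:
        raise ValueError("detection requires a z-scored matrix")
    n_units, n_bins = Z.values.shape
    if n_units < 2:
        raise ValueError("need at least two units")
    if n_bins < 10 * n_units:
        logger.warning(
            "only %d bins for %d units; detection may be unstable", n_bins, n_units
        )
    corr = np.corrcoef(Z.values)
    eigval, eigvec = np.linalg.eigh(corr)
    bound = marcenko_pastur_bound(n_units, n_bins)
    sig = eigval > bound
    k = int(np.sum(sig))
    if k == 0:
        return []
    V = eigvec[:, sig]  # n_units x k
    if k == 1:
        patterns = [V[:, 0]]
    else:
        proj = V.T @ Z.values  # k x bins
        ica = FastICA(
            n_components=k,
            random_state=seed,
            whiten="unit-variance",
            max_iter=1000,
            tol=1e-4,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica.fit(proj.T)
        patterns = [V @ ica.components_[i] for i in range(k)]

    models: List[AssemblyModel] = []
    for w in patterns:
        w = _normalize_pattern(w)
        try:
            thr, member_rows, eff = otsu_members(w)
        except ValueError:
            continue
        member_signs = np.sign(w[member_rows])
        models.append(
            AssemblyModel(
                weights=w,
                unit_index=Z.unit_index.copy(),
                members=Z.unit_index[member_rows],
                otsu_threshold=thr,
                effectiveness=eff,
                timescale_ms=Z.bin_width / MS,
                sign_valid=bool(np.all(member_signs == member_signs[0])),
            )
        )

    # deduplicate near-identical components (ICA rotation ambiguity)
    kept: List[AssemblyModel] = []
    for m in sorted(models, key=lambda a: -a.effectiveness):
        if all(
            abs(float(m.weights @ other.weights)) <= dedup_cosine
            for other in kept
        ):
            kept.append(m)
    kept.sort(key=lambda a: -abs(a.weights).max())
    for i, m in enumerate(kept):
        m.id = i
    return kept


def filter_mixed_sign(
    assemblies: Sequence[AssemblyModel],
) -> Tuple[List[AssemblyModel], List[AssemblyModel]]:
    """Split assemblies into (kept same-sign, discarded mixed-sign)."""
    kept = [a for a in assemblies if a.sign_valid]
    discarded = [a for a in assemblies if not a.sign_valid]
    return kept, discarded


def detect(
    spikes: SpikeData,
    epochs: IntervalSet,
    bin_width_ms: float = 15.0,
    min_rate_hz: float = 0.05,
    seed: int = 0,
    keep_mixed_sign: bool = False,
) -> List[AssemblyModel]:
    """Convenience wrapper: rate-filter units, bin+z-score, detect, and
    drop mixed-sign assemblies."""
    dur = epochs.total_duration
    units = [
        u for u in spikes.trains
        if epochs.contains(spikes.trains[u]).sum() / dur >= min_rate_hz
    ]
    if len(units) < 2:
        return []
    Z = bin_and_zscore(spikes.subset(units), epochs, bin_width_ms)
    models = detect_assemblies(Z, seed=seed)
    if keep_mixed_sign:
        return models
    kept, _ = filter_mixed_sign(models)
    for i, m in enumerate(kept):
        m.id = i
    return kept


# ---------------------------------------------------------------------------
# controls and cross-validation
# ---------------------------------------------------------------------------

def shuffle_spike_identities(spikes: SpikeData, seed: int = 0) -> SpikeData:
    """Randomly permute which unit emitted each spike, preserving every
    spike time, every unit's total spike count, and hence the pooled
    population rate (the global-fluctuation control)."""
    units = sorted(spikes.trains)
    if len(units) < 2:
        raise ValueError("need at least two units to shuffle identities")
    rng = np.random.default_rng(seed)
    times = np.concatenate([spikes.trains[u] for u in units])
    labels = np.concatenate(
        [np.full(spikes.trains[u].size, u, dtype=int) for u in units]
    )
    labels = rng.permutation(labels)
    order = np.argsort(times, kind="stable")
    times, labels = times[order], labels[order]
    trains = {u: times[labels == u] for u in units}
    return SpikeData(
        trains,
        dict(spikes.structure),
        session_id=spikes.session_id,
        animal_id=spikes.animal_id,
    )


def random_balanced_halves(
    epochs: IntervalSet, seed: int = 0, chunk_s: float = 10.0
) -> Tuple[IntervalSet, IntervalSet]:
    """Partition the epochs into two balanced sets of random time intervals."""
    chunks = []
    for a, b in epochs.intervals:
        n = int(np.ceil((b - a) / chunk_s - 1e-9))
        edges = a + chunk_s * np.arange(n + 1)  # no accumulation drift
        edges[-1] = b
        for lo, hi in zip(edges[:-1], edges[1:]):
            chunks.append((lo, hi))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chunks))
    half_a, half_b = [], []
    dur_a = dur_b = 0.0
    for i in order:
        a, b = chunks[i]
        if dur_a <= dur_b:
            half_a.append((a, b))
            dur_a += b - a
        else:
            half_b.append((a, b))
            dur_b += b - a
    return IntervalSet(np.array(half_a)), IntervalSet(np.array(half_b))


def match_assemblies(
    set_a: Sequence[AssemblyModel],
    set_b: Sequence[AssemblyModel],
    threshold: float = 0.7,
) -> List[Tuple[int, int, float]]:
    """Greedy maximal-|cosine| matching; returns (idx_a, idx_b, |cosine|)
    pairs with |cosine| above the threshold."""
    if not set_a or not set_b:
        return []
    units = np.union1d(
        np.unique(np.concatenate([a.unit_index for a in set_a])),
        np.unique(np.concatenate([b.unit_index for b in set_b])),
    )

    def expand(m: AssemblyModel) -> np.ndarray:
        w = np.zeros(units.size)
        pos = np.searchsorted(units, m.unit_index)
        w[pos] = m.weights
        return w

    wa = np.array([expand(a) for a in set_a])
    wb = np.array([expand(b) for b in set_b])
    cos = np.abs(wa @ wb.T)
    na = np.linalg.norm(wa, axis=1)
    nb = np.linalg.norm(wb, axis=1)
    cos = cos / np.outer(na, nb)
    pairs = []
    cos = cos.copy()
    while True:
        i, j = np.unravel_index(np.argmax(cos), cos.shape)
        if cos[i, j] < threshold:
            break
        pairs.append((int(i), int(j), float(cos[i, j])))
        cos[i, :] = -1
        cos[:, j] = -1
    return pairs


def split_half_crossvalidate(
    spikes: SpikeData,
    epochs: IntervalSet,
    seed: int = 0,
    bin_width_ms: float = 15.0,
    n_null: int = 200,
) -> dict:
    """Detect assemblies independently in two balanced random halves of the
    epochs, match them by |cosine|, and test each matched pair against a
    weight-shuffled null (95th percentile of |cosine| with one vector's
    entries permuted)."""
    half_a, half_b = random_balanced_halves(epochs, seed=seed)
    det_a = detect(spikes, half_a, bin_width_ms=bin_width_ms, seed=seed)
    det_b = detect(spikes, half_b, bin_width_ms=bin_width_ms, seed=seed + 1)
    pairs = match_assemblies(det_a, det_b)
    rng = np.random.default_rng(seed + 2)
    results = []
    for i, j, c in pairs:
        wa, wb = det_a[i].weights, det_b[j].weights
        if wa.size != wb.size:  # different retained units: align on overlap
            common, ia, ib = np.intersect1d(
                det_a[i].unit_index, det_b[j].unit_index, return_indices=True
            )
            wa, wb = wa[ia], wb[ib]
        r = float(np.corrcoef(wa, wb)[0, 1])
        null = np.array(
            [
                abs(np.dot(rng.permutation(wa), wb))
                / (np.linalg.norm(wa) * np.linalg.norm(wb))
                for _ in range(n_null)
            ]
        )
        results.append(
            {
                "idx_a": i,
                "idx_b": j,
                "cosine": c,
                "weight_corr": r,
                "significant": bool(c > np.percentile(null, 95)),
            }
        )
    n_min = min(len(det_a), len(det_b))
    return {
        "n_half_a": len(det_a),
        "n_half_b": len(det_b),
        "n_matched": len(pairs),
        "frac_matched": len(pairs) / n_min if n_min else 0.0,
        "pairs": results,
    }


def peer_prediction_gain(
    Z: BinnedMatrix,
    assembly: AssemblyModel,
    n_shuffles: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Prediction gain g = e_shuffled / e - 1 per assembly member.

    Each member's binned activity is predicted from its co-members with a
    2-fold cross-validated linear model (contiguous halves as folds); e is
    the median absolute held-out error and e_shuffled the median error
    after shuffling predictions relative to observations.
    """
    members = [u for u in assembly.members if u in Z.unit_index]
    if len(members) < 2:
        raise ValueError("peer prediction needs at least two members")
    rng = np.random.default_rng(seed)
    rows = {u: Z.values[Z.row_of(u)] for u in members}
    T = Z.n_bins
    half = T // 2
    folds = [(slice(0, half), slice(half, T)), (slice(half, T), slice(0, half))]
    gains = np.empty(len(members))
    for gi, u in enumerate(members):
        y = rows[u]
        X = np.column_stack([rows[v] for v in members if v != u])
        X = np.column_stack([np.ones(T), X])
        pred = np.empty(T)
        for train, test in folds:
            beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
            pred[test] = X[test] @ beta
        err = np.abs(y - pred)
        e = float(np.median(err))
        e_shuf = float(
            np.median(
                [
                    np.median(np.abs(y - rng.permutation(pred)))
                    for _ in range(n_shuffles)
                ]
            )
        )
        if e == 0:
            logger.warning("zero prediction error for unit %d", u)
            gains[gi] = np.inf
        else:
            gains[gi] = e_shuf / e - 1.0
    return gains


def member_synchrony_ccg(
    spikes: SpikeData,
    assembly: AssemblyModel,
    control_pairs: Sequence[Tuple[int, int]] = (),
    window_ms: float = 100.0,
    bin_ms: float = 5.0,
    min_count: int = 100,
) -> dict:
    """Z-scored cross-correlograms between member pairs (and control pairs),
    each z-scored against its own mean/sd across lags; the mode (lag of the
    maximum) is recorded per pair. Pairs whose correlogram holds fewer than
    ``min_count`` joint spikes are skipped."""
    window = window_ms * MS
    edges = np.arange(-window, window + bin_ms * MS / 2, bin_ms * MS)
    centers = 0.5 * (edges[:-1] + edges[1:]) / MS  # ms

    def ccg(u: int, v: int):
        tu, tv = spikes.trains[u], spikes.trains[v]
        if tu.size == 0 or tv.size == 0:
            return None
        lo = np.searchsorted(tv, tu - window)
        hi = np.searchsorted(tv, tu + window)
        total = int(np.sum(hi - lo))
        if total < min_count:
            return None
        diffs = np.concatenate(
            [tv[a:b] - t for t, a, b in zip(tu, lo, hi) if b > a]
        )
        counts, _ = np.histogram(diffs, edges)
        sd = counts.std()
        if sd == 0:
            return None
        z = (counts - counts.mean()) / sd
        return z, float(centers[int(np.argmax(z))])

    member_pairs = [
        (int(a), int(b))
        for ai, a in enumerate(assembly.members)
        for b in assembly.members[ai + 1:]
    ]
    out = {"lags_ms": centers, "members": {}, "controls": {}}
    for group, pairs in (("members", member_pairs), ("controls", control_pairs)):
        for u, v in pairs:
            res = ccg(u, v)
            if res is not None:
                out[group][(u, v)] = {"z": res[0], "mode_ms": res[1]}
    return out
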