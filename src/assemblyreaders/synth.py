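"""Synthetic two-structure spike recordings with planted assemblies and readers.

The generator emulates the statistical structure the downstream analyses
assume: Poisson-like background firing with a shared slow rate modulation
(standing in for sleep rhythms), planted member ensembles in structure "A"
that co-activate within a brief (~15 ms) timescale at ~1-2 Hz with partial
member recruitment, and downstream units in structure "B" that respond
10-30 ms later. Reader variants:

``collective``
    responds to observed member co-activations: member spikes are grouped
    into timescale-wide co-activation windows, and the reader fires once
    per group with a probability that is a sigmoid of the fraction of
    distinct members in it (a genuinely collective, completion-capable
    response; planted activations recruit many members and so drive it
    strongly, background coincidences only weakly).
``independent``
    fires after every individual member spike with a fixed probability (a
    rate-driven response, the linear-summation control).
``coincidence``
    fires whenever >=2 distinct members spike within the assembly timescale,
    wherever that happens in the recording (the identity-selective control).

Reader spikes are added on top of the reader's own background train, so
peri-event histograms ride on a baseline as in real recordings. Everything
is reproducible from the config seed; a ground-truth manifest records the
planted structure for recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .spikes import MS, IntervalSet, SpikeData

logger = logging.getLogger("assemblyreaders")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AssemblySpec:
    """One planted ensemble: which units co-activate, how often, how tightly."""

    members: List[int]
    timescale_ms: float = 15.0
    incidence_hz: float = 1.8
    recruitment_p: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.recruitment_p <= 1.0:
            raise ValueError("recruitment_p must be in [0, 1]")
        if self.timescale_ms <= 0 or self.incidence_hz < 0:
            raise ValueError("timescale and incidence must be positive")


@dataclass
class ReaderSpec:
    """One planted downstream coupling."""

    unit: int
    assembly: int  # index into SynthConfig.assemblies
    mode: str = "collective"  # collective | independent | coincidence
    delay_ms: float = 20.0
    delay_sd_ms: float = 3.0
    # half-response at 40% of members recruited: a collective reader that
    # responds near-fully to sufficient partial activations (completion)
    sigmoid_midpoint: float = 0.4
    sigmoid_steepness: float = 10.0
    response_p: float = 0.5  # fixed probability for independent/coincidence

    def __post_init__(self) -> None:
        if self.mode not in ("collective", "independent", "coincidence"):
            raise ValueError(f"unknown reader mode '{self.mode}'")
        if self.delay_ms <= 0:
            raise ValueError("delay must be positive")
        if not 0.0 <= self.response_p <= 1.0:
            raise ValueError("response_p must be in [0, 1]")

    def response_prob(self, active_fraction: float) -> float:
        if self.mode == "collective":
            return float(
                1.0
                / (1.0 + np.exp(-self.sigmoid_steepness
                                * (active_fraction - self.sigmoid_midpoint)))
            )
        return self.response_p


@dataclass
class SynthConfig:
    """Full description of one synthetic session.

    Background rates are log-normal across units (median ``exp(rate_log_mean)``
    Hz); the shared slow modulation multiplies every unit's rate by
    ``1 + amplitude * sin(2 pi f t)``.
    """

    n_units_a: int = 60
    n_units_b: int = 20
    duration_s: float = 1800.0
    rate_log_mean: float = 0.0  # median 1 Hz background (sparse SWS firing)
    rate_log_sd: float = 0.5
    modulation_amplitude: float = 0.1
    modulation_freq_hz: float = 1.0  # slow-oscillation scale
    assemblies: List[AssemblySpec] = field(default_factory=list)
    readers: List[ReaderSpec] = field(default_factory=list)
    plasticity: Dict[int, float] = field(default_factory=dict)  # reader idx -> multiplier
    animal_rate_sd: float = 0.2  # log-rate sd of per-animal random effect
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_amplitude <= 1.0:
            raise ValueError("modulation amplitude must be in [0, 1]")
        a_units = set(range(self.n_units_a))
        b_units = set(range(self.n_units_a, self.n_units_a + self.n_units_b))
        member_units = set()
        homes = []  # structure holding each assembly's members
        for spec in self.assemblies:
            mem = set(spec.members)
            if mem <= a_units:
                homes.append("A")
            elif mem <= b_units:
                homes.append("B")
            else:
                raise ValueError(
                    "assembly members must all belong to one structure"
                )
            member_units |= mem
        for spec in self.readers:
            if not 0 <= spec.assembly < len(self.assemblies):
                raise ValueError("reader references unknown assembly")
            target = b_units if homes[spec.assembly] == "A" else a_units
            if spec.unit not in target:
                raise ValueError(
                    "readers must sit in the structure opposite their assembly"
                )
            if spec.unit in member_units:
                raise ValueError("a unit cannot be both member and reader")


def default_config(
    seed: int = 0,
    n_assemblies: int = 5,
    members_per_assembly: int = 8,
    reader_modes: Sequence[str] = ("collective",),
    **overrides,
) -> SynthConfig:
    """Study-conditions config: 60+20 units, 30 min, five 5-member
    assemblies at 1.8 Hz / 15 ms, one reader per assembly and mode."""
    # 8-member assemblies: realistic PCA-ICA assembly size, and large enough
    # that supra-threshold activation events are plentiful in a 30-min session
    cfg = SynthConfig(seed=seed, **{k: v for k, v in overrides.items()
                                    if k not in ("assemblies", "readers")})
    members = np.arange(n_assemblies * members_per_assembly).reshape(
        n_assemblies, members_per_assembly
    )
    if members.size > cfg.n_units_a:
        raise ValueError("not enough structure-A units for requested assemblies")
    cfg.assemblies = [AssemblySpec(members=row.tolist()) for row in members]
    readers = []
    b0 = cfg.n_units_a
    k = 0
    for mode in reader_modes:
        for a in range(n_assemblies):
            if b0 + k >= cfg.n_units_a + cfg.n_units_b:
                raise ValueError("not enough structure-B units for readers")
            readers.append(ReaderSpec(unit=b0 + k, assembly=a, mode=mode))
            k += 1
    cfg.readers = readers
    cfg.__post_init__()
    return cfg


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Manifest of what was planted, for recovery tests."""

    members: List[List[int]]  # per assembly
    timescales_ms: List[float]
    event_times: List[np.ndarray]  # per assembly, seconds
    event_recruited: List[List[List[int]]]  # per assembly, per event
    readers: List[dict]  # unit, assembly, mode, delay_ms, multiplier
    epoch: str = "pre"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "members": self.members,
            "timescales_ms": self.timescales_ms,
            "event_times": [t.tolist() for t in self.event_times],
            "event_recruited": self.event_recruited,
            "readers": self.readers,
            "epoch": self.epoch,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            members=payload["members"],
            timescales_ms=payload["timescales_ms"],
            event_times=[np.asarray(t, float) for t in payload["event_times"]],
            event_recruited=payload["event_recruited"],
            readers=payload["readers"],
            epoch=payload.get("epoch", "pre"),
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _modulated_poisson(
    rate: float,
    t0: float,
    t1: float,
    amplitude: float,
    freq: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous Poisson train with rate*(1 + A sin(2 pi f t)), by thinning."""
    peak = rate * (1.0 + amplitude)
    n = rng.poisson(peak * (t1 - t0))
    t = np.sort(rng.uniform(t0, t1, n))
    if amplitude > 0 and n:
        accept = rng.random(n) < (
            (1.0 + amplitude * np.sin(2 * np.pi * freq * t)) / (1.0 + amplitude)
        )
        t = t[accept]
    return t


def _simulate_epoch(
    config: SynthConfig,
    base_rates: np.ndarray,
    t0: float,
    t1: float,
    rng: np.random.Generator,
    response_scale: Dict[int, float] | None = None,
    epoch_label: str = "pre",
) -> Tuple[Dict[int, np.ndarray], GroundTruth]:
    """Simulate one epoch [t0, t1); returns per-unit trains and ground truth."""
    response_scale = response_scale or {}
    n_total = config.n_units_a + config.n_units_b
    trains: Dict[int, List[np.ndarray]] = {
        u: [
            _modulated_poisson(
                base_rates[u], t0, t1,
                config.modulation_amplitude, config.modulation_freq_hz, rng,
            )
        ]
        for u in range(n_total)
    }

    # planted assembly activations
    event_times: List[np.ndarray] = []
    event_recruited: List[List[List[int]]] = []
    member_spikes_per_event: List[List[np.ndarray]] = []
    for spec in config.assemblies:
        ts = spec.timescale_ms * MS
        n_ev = rng.poisson(spec.incidence_hz * (t1 - t0))
        times = np.sort(rng.uniform(t0, t1 - ts - 0.05, n_ev))
        kept_times, recruited_lists, spikes_lists = [], [], []
        for t in times:
            mask = rng.random(len(spec.members)) < spec.recruitment_p
            recruited = [m for m, keep in zip(spec.members, mask) if keep]
            if not recruited:
                continue  # nothing emitted: not a manifest event
            offs = rng.uniform(0.0, ts, len(recruited))
            sp = t + offs
            for m, s in zip(recruited, sp):
                trains[m].append(np.array([s]))
            kept_times.append(t)
            recruited_lists.append(recruited)
            spikes_lists.append(sp)
        event_times.append(np.asarray(kept_times))
        event_recruited.append(recruited_lists)
        member_spikes_per_event.append(spikes_lists)

    # planted readers
    reader_manifest = []
    for idx, spec in enumerate(config.readers):
        scale = response_scale.get(idx, 1.0)
        a = spec.assembly
        n_members = len(config.assemblies[a].members)
        ts = config.assemblies[a].timescale_ms * MS
        out = []
        if spec.mode == "collective":
            merged_t = []
            merged_lab = []
            for m in config.assemblies[a].members:
                t = np.concatenate(trains[m])
                merged_t.append(t)
                merged_lab.append(np.full(t.size, m, int))
            t_all = np.concatenate(merged_t)
            lab = np.concatenate(merged_lab)
            order = np.argsort(t_all, kind="stable")
            t_all, lab = t_all[order], lab[order]
            i = 0
            clipped = False
            while i < t_all.size:
                j = int(np.searchsorted(t_all, t_all[i] + ts, side="left"))
                n_distinct = np.unique(lab[i:j]).size
                p = spec.response_prob(n_distinct / n_members) * scale
                if p > 1.0:
                    clipped = True
                    p = 1.0
                if rng.random() < p:
                    out.append(
                        float(t_all[i:j].mean())
                        + rng.normal(spec.delay_ms, spec.delay_sd_ms) * MS
                    )
                i = j
            if clipped:
                logger.warning("response probability clipped to 1")
        elif spec.mode == "independent":
            p = min(spec.response_p * scale, 1.0)
            if spec.response_p * scale > 1.0:
                logger.warning("response probability clipped to 1")
            pooled = np.sort(
                np.concatenate(
                    [np.concatenate(trains[m]) for m in config.assemblies[a].members]
                )
            )
            hits = pooled[rng.random(pooled.size) < p]
            out = (
                hits + rng.normal(spec.delay_ms, spec.delay_sd_ms, hits.size) * MS
            ).tolist()
        else:  # coincidence: any two distinct members within the timescale
            p = min(spec.response_p * scale, 1.0)
            if spec.response_p * scale > 1.0:
                logger.warning("response probability clipped to 1")
            merged = []
            for m in config.assemblies[a].members:
                t = np.concatenate(trains[m])
                merged.append(np.stack([t, np.full(t.size, m, float)]))
            merged = np.concatenate(merged, axis=1)
            order = np.argsort(merged[0])
            t_all, lab = merged[0][order], merged[1][order]
            last_trigger = -np.inf
            for i in range(1, t_all.size):
                if (
                    t_all[i] - t_all[i - 1] <= ts
                    and lab[i] != lab[i - 1]
                    and t_all[i] - last_trigger > ts
                ):
                    last_trigger = t_all[i]
                    if rng.random() < p:
                        mid = 0.5 * (t_all[i] + t_all[i - 1])
                        out.append(
                            mid + rng.normal(spec.delay_ms, spec.delay_sd_ms) * MS
                        )
        out = np.asarray(out, float)
        out = out[(out >= t0) & (out < t1)]
        trains[spec.unit].append(out)
        reader_manifest.append(
            {
                "unit": spec.unit,
                "assembly": a,
                "mode": spec.mode,
                "delay_ms": spec.delay_ms,
                "multiplier": scale,
            }
        )

    merged_trains = {
        u: np.sort(np.concatenate(parts)) for u, parts in trains.items()
    }
    truth = GroundTruth(
        members=[list(s.members) for s in config.assemblies],
        timescales_ms=[s.timescale_ms for s in config.assemblies],
        event_times=event_times,
        event_recruited=event_recruited,
        readers=reader_manifest,
        epoch=epoch_label,
    )
    return merged_trains, truth


def _structure_labels(config: SynthConfig) -> Dict[int, str]:
    labels = {u: "A" for u in range(config.n_units_a)}
    labels.update(
        {u: "B" for u in range(config.n_units_a, config.n_units_a + config.n_units_b)}
    )
    return labels


def generate_session(
    config: SynthConfig,
    rate_multiplier: float = 1.0,
    session_id: str = "s0",
    animal_id: str = "a0",
) -> Tuple[SpikeData, IntervalSet, GroundTruth]:
    """Simulate one session; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_total = config.n_units_a + config.n_units_b
    base = rate_multiplier * rng.lognormal(
        config.rate_log_mean, config.rate_log_sd, n_total
    )
    trains, truth = _simulate_epoch(config, base, 0.0, config.duration_s, rng)
    spikes = SpikeData(
        trains, _structure_labels(config), session_id=session_id, animal_id=animal_id
    )
    epochs = IntervalSet(np.array([[0.0, config.duration_s]]))
    return spikes, epochs, truth


def generate_cohort(
    config: SynthConfig,
    n_animals: int = 4,
    n_sessions: int = 5,
) -> List[Tuple[SpikeData, IntervalSet, GroundTruth]]:
    """Nested cohort: per-animal log-normal rate offsets induce the
    between-animal correlation the hierarchical bootstrap must respect.
    Session seeds are derived deterministically from (seed, animal, session)."""
    if n_animals < 1 or n_sessions < 1:
        raise ValueError("need at least one animal and one session")
    out = []
    for a in range(n_animals):
        eff_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7919, a])
        )
        mult = float(np.exp(eff_rng.normal(0.0, config.animal_rate_sd)))
        for s in range(n_sessions):
            child = int(
                np.random.SeedSequence([config.seed, a, s]).generate_state(1)[0]
                % (2**31 - 1)
            )
            cfg = replace(config, seed=child)
            out.append(
                generate_session(
                    cfg,
                    rate_multiplier=mult,
                    session_id=f"a{a}s{s}",
                    animal_id=f"a{a}",
                )
            )
    return out


def generate_pre_post(
    config: SynthConfig,
    gap_s: float = 60.0,
) -> Tuple[SpikeData, IntervalSet, IntervalSet, GroundTruth, GroundTruth]:
    """Two epochs with an identical generative process except that selected
    reader couplings' response probabilities are scaled in "post".

    Returns one SpikeData spanning both epochs (post offset by the epoch
    duration plus a gap), the pre/post IntervalSets, and per-epoch truths.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_units_a + config.n_units_b
    base = rng.lognormal(config.rate_log_mean, config.rate_log_sd, n_total)
    t_post = config.duration_s + gap_s
    trains_pre, truth_pre = _simulate_epoch(
        config, base, 0.0, config.duration_s, rng, epoch_label="pre"
    )
    trains_post, truth_post = _simulate_epoch(
        config, base, t_post, t_post + config.duration_s, rng,
        response_scale=dict(config.plasticity), epoch_label="post",
    )
    trains = {
        u: np.sort(np.concatenate([trains_pre[u], trains_post[u]]))
        for u in trains_pre
    }
    spikes = SpikeData(trains, _structure_labels(config))
    pre = IntervalSet(np.array([[0.0, config.duration_s]]))
    post = IntervalSet(np.array([[t_post, t_post + config.duration_s]]))
    return spikes, pre, post, truth_pre, truth_post
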