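"""Simulation studies validating the pipeline against planted ground truth.

Each study generates synthetic sessions (the generator's defaults are the
study conditions), runs the corresponding pipeline stage end to end, and
returns summary statistics: recovery of planted assemblies and readers,
null calibration of the Monte-Carlo significance machinery, the
collective-coding dissociations (supralinearity, AB/AA, timescales),
pattern completion/separation, learning-related plasticity, and
hierarchical-bootstrap CI coverage. The acceptance script and the
acceptance test suite both run these studies.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence

import numpy as np

from . import synth as synth_mod
from .synth import AssemblySpec, ReaderSpec, SynthConfig, default_config
from .detect import detect, shuffle_spike_identities
from .activation import activation_events
from .readers import compute_peth, shuffle_bands, classify_reader_pair, test_pair
from .collective import (
    ab_aa_delay_scan,
    fit_linear_readout,
    simulate_independent_reader,
    simulate_perfect_reader,
    split_member_triggers,
    supralinearity_index,
    timescale_scan,
)
from .patterns import (
    coactivation_events,
    discrimination_index,
    fit_sigmoid_vs_proportional,
    sparsity_increase,
    subset_responses,
)
from .plasticity import compare_change_rates, pre_post_pipeline, response_change
from .bootstrap import hierarchical_bootstrap

logger = logging.getLogger("assemblyreaders")


def _child_seed(seed: int, *keys: int) -> int:
    return int(
        np.random.SeedSequence([int(seed)] + [int(k) for k in keys])
        .generate_state(1)[0] % (2**31 - 1)
    )


def _planted_vector(members: Sequence[int], unit_index: np.ndarray) -> np.ndarray:
    v = np.zeros(unit_index.size)
    v[np.isin(unit_index, list(members))] = 1.0
    return v / np.linalg.norm(v)


def _match_planted(models, planted_members, cos_threshold=0.8):
    """Greedy match of detected models to planted member sets by |cosine|
    against the idealized (uniform-weight) planted vector."""
    matches: Dict[int, int] = {}
    used = set()
    for pi, members in enumerate(planted_members):
        best, best_cos = None, cos_threshold
        for mi, m in enumerate(models):
            if mi in used:
                continue
            cos = abs(float(_planted_vector(members, m.unit_index) @ m.weights))
            if cos > best_cos:
                best, best_cos = mi, cos
        if best is not None:
            matches[pi] = best
            used.add(best)
    return matches


# ---------------------------------------------------------------------------
# recovery (assemblies and readers)
# ---------------------------------------------------------------------------

def recovery_study(
    n_sessions: int = 20,
    seed: int = 0,
    duration_s: float = 1800.0,
    n_assemblies: int = 5,
) -> dict:
    """Detection and reader recovery over seeded synthetic sessions
    (60 structure-A units, 5 planted assemblies, 30 min by default)."""
    n_planted = n_matched = n_exact = 0
    n_readers = n_reader_sig = n_delay_ok = 0
    delays = []
    event_counts = []
    for s in range(n_sessions):
        cfg = default_config(
            seed=_child_seed(seed, 1, s),
            duration_s=duration_s,
            n_assemblies=n_assemblies,
            reader_modes=("collective",),
        )
        spikes, epochs, truth = synth_mod.generate_session(cfg)
        A = spikes.subset(spikes.units_in("A"))
        models = detect(A, epochs, seed=_child_seed(seed, 2, s))
        matches = _match_planted(models, truth.members)
        n_planted += len(truth.members)
        n_matched += len(matches)
        for pi, mi in matches.items():
            if set(int(u) for u in models[mi].members) == set(truth.members[pi]):
                n_exact += 1
        for reader in truth.readers:
            pi = reader["assembly"]
            if pi not in matches:
                continue
            n_readers += 1
            ev = activation_events(spikes, models[matches[pi]], epochs)
            event_counts.append(ev.n_events)
            _, verdict = test_pair(
                spikes.trains[reader["unit"]], ev.peaks,
                seed=_child_seed(seed, 3, s, reader["unit"]),
            )
            if verdict.get("significant"):
                n_reader_sig += 1
                d = verdict["first_sig_delay_ms"]
                delays.append(d)
                if 10.0 <= d <= 30.0:
                    n_delay_ok += 1
    return {
        "n_planted": n_planted,
        "assembly_recovery_rate": n_matched / n_planted,
        "exact_member_set_rate": n_exact / n_planted,
        "n_readers": n_readers,
        "reader_detection_rate": n_reader_sig / max(n_readers, 1),
        "reader_delay_in_window_rate": n_delay_ok / max(n_readers, 1),
        "median_first_sig_delay_ms": float(np.median(delays)) if delays else np.nan,
        "mean_events_per_assembly": float(np.mean(event_counts)) if event_counts else 0,
    }


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def peth_null_study(
    n_pairs: int = 500,
    seed: int = 0,
    reader_rate_hz: float = 3.0,
    n_peaks: int = 150,
    duration_s: float = 600.0,
) -> dict:
    """Uncoupled assembly-reader pairs: per-bin pointwise exceedance of the
    95% band (should sit near 5%) and the pair-level significance rate with
    the joint pointwise+global+mode criterion (should be well below 5%)."""
    exceed = []
    n_sig = n_testable = 0
    for i in range(n_pairs):
        rng = np.random.default_rng(_child_seed(seed, 10, i))
        reader = np.sort(
            rng.uniform(0, duration_s, rng.poisson(reader_rate_hz * duration_s))
        )
        peaks = np.sort(rng.uniform(1, duration_s - 1, n_peaks))
        peth = compute_peth(reader, peaks)
        if peth.excluded:
            continue
        n_testable += 1
        shuffle_bands(peth, seed=_child_seed(seed, 11, i))
        exceed.append(float(np.mean(peth.m > peth.pointwise_band)))
        if classify_reader_pair(peth)["significant"]:
            n_sig += 1
    return {
        "n_pairs": n_testable,
        "pointwise_exceedance": float(np.mean(exceed)),
        "pair_significance_rate": n_sig / max(n_testable, 1),
    }


def identity_shuffle_study(n_sessions: int = 3, seed: int = 0,
                           duration_s: float = 1800.0) -> dict:
    """Spike-identity shuffling destroys planted coactivity: shuffled
    sessions retain at most a global-rate component, never a planted
    member set."""
    orig_counts, shuf_counts = [], []
    planted_recovered_after_shuffle = 0
    for s in range(n_sessions):
        cfg = default_config(seed=_child_seed(seed, 20, s),
                             duration_s=duration_s, reader_modes=())
        spikes, epochs, truth = synth_mod.generate_session(cfg)
        A = spikes.subset(spikes.units_in("A"))
        models = detect(A, epochs, seed=_child_seed(seed, 21, s))
        shuffled = shuffle_spike_identities(A, seed=_child_seed(seed, 22, s))
        models_sh = detect(shuffled, epochs, seed=_child_seed(seed, 21, s))
        orig_counts.append(len(models))
        shuf_counts.append(len(models_sh))
        planted = [set(m) for m in truth.members]
        for m in models_sh:
            if set(int(u) for u in m.members) in planted:
                planted_recovered_after_shuffle += 1
    return {
        "original_counts": orig_counts,
        "shuffled_counts": shuf_counts,
        "mean_shuffled_count": float(np.mean(shuf_counts)),
        "planted_sets_after_shuffle": planted_recovered_after_shuffle,
    }


def prepost_null_study(
    n_pairs: int = 500,
    seed: int = 0,
    n_events: int = 150,
    duration_s: float = 600.0,
) -> dict:
    """Exchangeable pre/post data for coupled pairs (responses present but
    unchanged): the per-pair change test should reject ~5% of the time."""
    n_changed = n_tested = 0
    for i in range(n_pairs):
        rng = np.random.default_rng(_child_seed(seed, 30, i))
        pre = np.sort(rng.uniform(1, duration_s - 1, n_events))
        post = np.sort(rng.uniform(1, duration_s - 1, n_events))
        background = rng.uniform(0, duration_s, rng.poisson(2.0 * duration_s))
        responses = []
        for peaks in (pre, post):
            hit = peaks[rng.random(peaks.size) < 0.7]
            responses.append(hit + rng.normal(0.020, 0.003, hit.size))
        reader = np.sort(np.concatenate([background] + responses))
        v = response_change(reader, pre, post, n_boot=1000,
                            seed=_child_seed(seed, 31, i))
        if v["testable"]:
            n_tested += 1
            n_changed += v["significant"]
    return {
        "n_pairs": n_tested,
        "null_change_rate": n_changed / max(n_tested, 1),
    }


# ---------------------------------------------------------------------------
# collective coding
# ---------------------------------------------------------------------------

def supralinearity_study(
    n_sessions: int = 8,
    seed: int = 0,
    duration_s: float = 1800.0,
) -> dict:
    """Simulated perfect vs independent readers run through the linear-
    readout supralinearity analysis on detected assemblies."""
    perfect_s20, perfect_base, indep_s20 = [], [], []
    for s in range(n_sessions):
        cfg = default_config(seed=_child_seed(seed, 40, s),
                             duration_s=duration_s, n_assemblies=3,
                             reader_modes=())
        spikes, epochs, truth = synth_mod.generate_session(cfg)
        A = spikes.subset(spikes.units_in("A"))
        models = detect(A, epochs, seed=_child_seed(seed, 41, s))
        matches = _match_planted(models, truth.members)
        for pi, mi in matches.items():
            model = models[mi]
            ev = activation_events(spikes, model, epochs)
            if ev.n_events == 0:
                continue
            t_in, t_out = split_member_triggers(spikes, model.members, ev)
            if t_in.size == 0 or t_out.size < 200:
                continue
            fit_seed = _child_seed(seed, 42, s, pi)
            for name, reader in (
                ("perfect", simulate_perfect_reader(ev, len(model.members))),
                ("independent", simulate_independent_reader(spikes, model.members)),
            ):
                ro = fit_linear_readout(
                    reader, spikes, model.members, t_in, t_out, seed=fit_seed
                )
                S = supralinearity_index(ro)
                s20 = ro.at(S, 20.0)
                if name == "perfect":
                    perfect_s20.append(s20)
                    perfect_base.append(ro.at(S, -500.0))
                else:
                    indep_s20.append(s20)
    perfect_s20 = np.asarray(perfect_s20)
    perfect_base = np.asarray(perfect_base)
    indep_s20 = np.asarray(indep_s20)
    lo, hi = (
        np.percentile(indep_s20, [2.5, 97.5]) if indep_s20.size else (np.nan, np.nan)
    )
    return {
        "n_assemblies": int(perfect_s20.size),
        "perfect_s20_mean": float(perfect_s20.mean()),
        "perfect_above_baseline_rate": float(
            np.mean(perfect_s20 > perfect_base)
        ),
        "independent_s20_mean": float(indep_s20.mean()),
        "independent_ci": (float(lo), float(hi)),
        "independent_ci_covers_zero": bool(lo <= 0.0 <= hi),
    }


def ab_aa_study(
    n_sessions: int = 6,
    seed: int = 0,
    duration_s: float = 1800.0,
    brief_delays_ms: Sequence[float] = (10.0, 15.0, 20.0),
    long_delays_ms: Sequence[float] = (40.0, 50.0, 60.0),
) -> dict:
    """AB vs AA reader responses for coincidence-detector vs rate
    (independent) planted readers, per inter-spike delay stratum."""
    out = {"coincidence": {"brief": [], "long": []},
           "rate": {"brief": [], "long": []}}
    delays = list(brief_delays_ms) + list(long_delays_ms)
    for s in range(n_sessions):
        cfg = default_config(seed=_child_seed(seed, 50, s),
                             duration_s=duration_s, n_assemblies=2,
                             reader_modes=("coincidence", "independent"))
        spikes, epochs, truth = synth_mod.generate_session(cfg)
        for reader in truth.readers:
            label = "coincidence" if reader["mode"] == "coincidence" else "rate"
            members = truth.members[reader["assembly"]]
            rt = spikes.trains[reader["unit"]]
            # pool AB/AA strata over distinct member pairs
            for a_i in range(min(len(members), 4)):
                for b_i in range(min(len(members), 4)):
                    if a_i == b_i:
                        continue
                    others = spikes.pooled(
                        [m for k, m in enumerate(members)
                         if k not in (a_i, b_i)]
                    )
                    scan = ab_aa_delay_scan(
                        rt, spikes.trains[members[a_i]],
                        spikes.trains[members[b_i]], delays_ms=delays,
                        other_times=others,
                    )
                    for d, v in zip(scan["delay_ms"], scan["ab_minus_aa"]):
                        if not np.isfinite(v):
                            continue
                        key = "brief" if d in brief_delays_ms else "long"
                        out[label][key].append(float(v))
    return {
        f"{label}_{key}_mean": float(np.mean(vals)) if vals else np.nan
        for label, groups in out.items()
        for key, vals in groups.items()
    } | {
        f"{label}_{key}_n": len(vals)
        for label, groups in out.items()
        for key, vals in groups.items()
    }


def timescale_study(
    n_sessions: int = 2,
    seed: int = 0,
    duration_s: float = 1800.0,
    scales_ms: Sequence[float] = (15.0, 50.0, 75.0),
) -> dict:
    """Supralinearity of a perfect collective reader versus detection
    timescale: elevated at the planted 15-ms scale, vanishing at >=50 ms."""
    per_scale: Dict[float, List[float]] = {s: [] for s in scales_ms}
    for s in range(n_sessions):
        cfg = default_config(seed=_child_seed(seed, 60, s),
                             duration_s=duration_s, n_assemblies=2,
                             reader_modes=())
        spikes, epochs, truth = synth_mod.generate_session(cfg)
        A = spikes.subset(spikes.units_in("A"))
        models = detect(A, epochs, seed=_child_seed(seed, 61, s))
        matches = _match_planted(models, truth.members)
        if not matches:
            continue
        model = models[matches[min(matches)]]
        ev = activation_events(spikes, model, epochs)
        reader = simulate_perfect_reader(ev, len(model.members))
        scan = timescale_scan(
            spikes, epochs, reader, scales_ms=scales_ms,
            seed=_child_seed(seed, 62, s),
        )
        for scale, res in scan.items():
            if res.get("testable"):
                per_scale[scale].append(res["zdiff_20ms"])
    return {
        f"zdiff_{int(scale)}ms": float(np.mean(v)) if v else np.nan
        for scale, v in per_scale.items()
    }


# ---------------------------------------------------------------------------
# completion / separation
# ---------------------------------------------------------------------------

def completion_study(
    n_sessions: int = 6,
    seed: int = 0,
    duration_s: float = 1800.0,
) -> dict:
    """Sigmoid-recruitment planted readers: sigmoid vs proportional fits of
    subset responses and the per-tertile boost."""
    n_pairs = n_sig_wins = 0
    mid_boosts, top_boosts = [], []
    for s in range(n_sessions):
        cfg = default_config(seed=_child_seed(seed, 70, s),
                             duration_s=duration_s, n_assemblies=3,
                             reader_modes=("collective",))
        spikes, epochs, truth = synth_mod.generate_session(cfg)
        for reader in truth.readers:
            members = truth.members[reader["assembly"]]
            rt = spikes.trains[reader["unit"]]
            ev = coactivation_events(spikes, members, 15.0)
            baseline = rt.size / duration_s
            sr = subset_responses(rt, ev, len(members), baseline)
            if not sr["testable"] or np.unique(sr["x"]).size < 4:
                continue
            fit = fit_sigmoid_vs_proportional(sr["x"], sr["response_rel"])
            if not fit.converged:
                continue
            n_pairs += 1
            n_sig_wins += fit.r2_sigmoid > fit.r2_proportional
            if np.isfinite(fit.tertile_boost[1]):
                mid_boosts.append(fit.tertile_boost[1])
            if np.isfinite(fit.tertile_boost[2]):
                top_boosts.append(fit.tertile_boost[2])
    return {
        "n_pairs": n_pairs,
        "sigmoid_beats_proportional_rate": n_sig_wins / max(n_pairs, 1),
        "mid_tertile_boost_median": float(np.median(mid_boosts)) if mid_boosts else np.nan,
        "top_tertile_boost_median": float(np.median(top_boosts)) if top_boosts else np.nan,
    }


def _overlap_config(seed: int, duration_s: float) -> SynthConfig:
    """Three 8-member assemblies, the first two sharing 3 members (37.5%),
    each with a collective reader."""
    return SynthConfig(
        seed=seed,
        duration_s=duration_s,
        assemblies=[
            AssemblySpec(members=list(range(0, 8))),
            AssemblySpec(members=list(range(5, 13))),
            AssemblySpec(members=list(range(15, 23))),
        ],
        readers=[
            ReaderSpec(unit=60, assembly=0, mode="collective"),
            ReaderSpec(unit=61, assembly=1, mode="collective"),
            ReaderSpec(unit=62, assembly=2, mode="collective"),
        ],
    )


def separation_study(
    n_sessions: int = 6,
    seed: int = 0,
    duration_s: float = 1800.0,
    n_shuffles: int = 1000,
) -> dict:
    """Sparsity increase for readers vs nonreaders, and discrimination
    between 37.5%-overlapping assemblies for coupled vs uncoupled units."""
    reader_increase, nonreader_increase = [], []
    disc_coupled = disc_coupled_sig = 0
    disc_uncoupled = disc_uncoupled_sig = 0
    for s in range(n_sessions):
        cfg = _overlap_config(_child_seed(seed, 80, s), duration_s)
        spikes, epochs, truth = synth_mod.generate_session(cfg)
        A = spikes.subset(spikes.units_in("A"))
        models = detect(A, epochs, seed=_child_seed(seed, 81, s))
        matches = _match_planted(models, truth.members)
        if len(matches) < 3:
            continue
        evs = {pi: activation_events(spikes, models[mi], epochs)
               for pi, mi in matches.items()}
        ev_list = [evs[pi] for pi in sorted(evs)]
        reader_units = {r["unit"] for r in truth.readers}
        for u in spikes.units_in("B"):
            u = int(u)
            rt = spikes.trains[u]
            res = sparsity_increase(
                rt, ev_list, rt.size / duration_s,
                n_shuffles=n_shuffles, seed=_child_seed(seed, 82, s, u),
            )
            if not res["testable"]:
                continue
            (reader_increase if u in reader_units else nonreader_increase).append(
                res["increase"]
            )
        # discrimination between the two overlapping assemblies
        for u, paired, other in ((60, 0, 1), (61, 1, 0)):
            rt = spikes.trains[u]
            d = discrimination_index(
                rt, evs[paired], evs[other], rt.size / duration_s,
                n_shuffles=n_shuffles, seed=_child_seed(seed, 83, s, u),
            )
            if d.get("testable"):
                disc_coupled += 1
                disc_coupled_sig += d["significant"]
        for u in spikes.units_in("B"):
            u = int(u)
            if u in reader_units:
                continue
            rt = spikes.trains[u]
            d = discrimination_index(
                rt, evs[0], evs[1], rt.size / duration_s,
                n_shuffles=n_shuffles, seed=_child_seed(seed, 84, s, u),
            )
            if d.get("testable"):
                disc_uncoupled += 1
                disc_uncoupled_sig += d["significant"]
    return {
        "reader_sparsity_increase_median": float(np.median(reader_increase)),
        "nonreader_sparsity_increase_median": float(np.median(nonreader_increase)),
        "n_readers": len(reader_increase),
        "n_nonreaders": len(nonreader_increase),
        "discrimination_coupled_rate": disc_coupled_sig / max(disc_coupled, 1),
        "n_coupled": disc_coupled,
        "discrimination_uncoupled_rate": disc_uncoupled_sig / max(disc_uncoupled, 1),
        "n_uncoupled": disc_uncoupled,
    }


# ---------------------------------------------------------------------------
# plasticity
# ---------------------------------------------------------------------------

def _two_direction_config(seed: int, duration_s: float,
                          multipliers: Dict[int, float]) -> SynthConfig:
    """Assemblies in both structures with readers in the opposite one.
    Reader couplings 0-1 are A->B, couplings 2-3 are B->A."""
    return SynthConfig(
        seed=seed,
        duration_s=duration_s,
        n_units_a=30,
        n_units_b=30,
        assemblies=[
            AssemblySpec(members=list(range(0, 8))),     # A
            AssemblySpec(members=list(range(10, 18))),   # A
            AssemblySpec(members=list(range(30, 38))),   # B
            AssemblySpec(members=list(range(40, 48))),   # B
        ],
        # fixed-probability couplings (p = 0.3) leave multiplicative
        # headroom for the post-epoch scaling, unlike a saturated sigmoid
        readers=[
            ReaderSpec(unit=50, assembly=0, mode="coincidence", response_p=0.3),
            ReaderSpec(unit=51, assembly=1, mode="coincidence", response_p=0.3),
            ReaderSpec(unit=20, assembly=2, mode="coincidence", response_p=0.3),
            ReaderSpec(unit=21, assembly=3, mode="coincidence", response_p=0.3),
        ],
        plasticity=dict(multipliers),
    )


def plasticity_study(
    n_sessions: int = 4,
    seed: int = 0,
    duration_s: float = 900.0,
    multiplier: float = 2.5,
    n_boot: int = 1000,
) -> dict:
    """Double dissociation: one condition scales the A->B couplings in the
    post epoch, another scales B->A, a control scales nothing. Change rates
    are counted per direction and contrasted with the control by
    chi-squared."""
    conditions = {
        "scale_ab": {0: multiplier, 1: multiplier},
        "scale_ba": {2: multiplier, 3: multiplier},
        "control": {},
    }
    counts = {
        c: {"AB": [0, 0], "BA": [0, 0]} for c in conditions
    }  # direction -> [changed, tested]
    for ci, (cond, mult) in enumerate(conditions.items()):
        for s in range(n_sessions):
            cfg = _two_direction_config(
                _child_seed(seed, 90, ci, s), duration_s, mult
            )
            spikes, pre, post, *_ = synth_mod.generate_pre_post(cfg)
            for direction, upstream, readers in (
                ("AB", "A", [50, 51]), ("BA", "B", [20, 21]),
            ):
                res = pre_post_pipeline(
                    spikes, pre, post, reader_units=readers, upstream=upstream,
                    n_boot=n_boot, seed=_child_seed(seed, 91, ci, s),
                )
                counts[cond][direction][0] += res["n_changed"]
                counts[cond][direction][1] += res["n_tested"]

    def contrast(cond: str, direction: str) -> dict:
        ch, n = counts[cond][direction]
        ch0, n0 = counts["control"][direction]
        return compare_change_rates(ch, max(n, 1), ch0, max(n0, 1))

    return {
        "counts": counts,
        "ab_change_rate_when_ab_scaled": counts["scale_ab"]["AB"][0]
        / max(counts["scale_ab"]["AB"][1], 1),
        "ba_change_rate_when_ab_scaled": counts["scale_ab"]["BA"][0]
        / max(counts["scale_ab"]["BA"][1], 1),
        "ab_change_rate_when_ba_scaled": counts["scale_ba"]["AB"][0]
        / max(counts["scale_ba"]["AB"][1], 1),
        "ba_change_rate_when_ba_scaled": counts["scale_ba"]["BA"][0]
        / max(counts["scale_ba"]["BA"][1], 1),
        "ab_control_rate": counts["control"]["AB"][0]
        / max(counts["control"]["AB"][1], 1),
        "ba_control_rate": counts["control"]["BA"][0]
        / max(counts["control"]["BA"][1], 1),
        "ab_vs_control_when_ab_scaled": contrast("scale_ab", "AB"),
        "ba_vs_control_when_ba_scaled": contrast("scale_ba", "BA"),
        "ba_vs_control_when_ab_scaled": contrast("scale_ab", "BA"),
        "ab_vs_control_when_ba_scaled": contrast("scale_ba", "AB"),
    }


# ---------------------------------------------------------------------------
# hierarchical bootstrap coverage
# ---------------------------------------------------------------------------

def bootstrap_coverage_study(
    n_experiments: int = 500,
    seed: int = 0,
    n_animals: int = 4,
    n_sessions: int = 5,
    n_obs: int = 20,
    animal_sd: float = 0.2,
    session_sd: float = 0.2,
    obs_sd: float = 1.0,
    repeats: int = 1000,
) -> dict:
    """CI coverage of the hierarchical bootstrap on nested Gaussian data
    with animal and session random effects (the cohort generator's shape
    and random-effect scale)."""
    covered = 0
    for e in range(n_experiments):
        rng = np.random.default_rng(_child_seed(seed, 95, e))
        vals, animals, sessions = [], [], []
        a_eff = rng.normal(0.0, animal_sd, n_animals)
        for a in range(n_animals):
            for s in range(n_sessions):
                obs = a_eff[a] + rng.normal(0.0, session_sd) + rng.normal(
                    0.0, obs_sd, n_obs
                )
                vals.append(obs)
                animals += [a] * n_obs
                sessions += [f"{a}_{s}"] * n_obs
        est = hierarchical_bootstrap(
            np.concatenate(vals), animals, sessions,
            repeats=repeats, seed=_child_seed(seed, 96, e),
        )
        covered += est.ci_low <= 0.0 <= est.ci_high
    return {
        "n_experiments": n_experiments,
        "coverage": covered / n_experiments,
    }
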