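"""End-to-end pipeline: synth -> detect -> activations -> readers ->
collective -> patterns -> report.

Each stage reads/writes plain-text artifacts (TSV/JSON) in the output
directory; detection resumes from cached assemblies when present, and the
configuration, its hash and the seed are recorded alongside every run.
Pre/post (learning) comparisons take two epoch sets and run through
``plasticity.pre_post_pipeline`` instead of this single-session driver.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml

from . import synth as synth_mod
from .spikes import (
    IntervalSet,
    SpikeData,
    load_intervals,
    load_spikes,
    save_intervals,
    save_spikes,
)
from .detect import AssemblyModel, detect, load_assemblies, save_assemblies
from .activation import ActivationSeries, activation_events
from .readers import test_pair
from .collective import (
    fit_linear_readout,
    simulate_independent_reader,
    simulate_perfect_reader,
    split_member_triggers,
    supralinearity_index,
)
from .patterns import (
    coactivation_events,
    fit_sigmoid_vs_proportional,
    sparsity_increase,
    subset_responses,
)

logger = logging.getLogger("assemblyreaders")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the analysis conventions
    (15-ms detection bins, 1-ms activation step, 10-ms PETH bins in a
    +-1 s window, 200 PETH shuffles, 1000 pattern/bootstrap shuffles,
    10-30 ms response window, 30-spike PETH minimum, 20-event minimum)."""

    spikes_path: str = ""
    intervals_path: str = ""
    metadata_path: str = ""
    output_dir: str = "results"
    synth: bool = False
    bin_width_ms: float = 15.0
    step_ms: float = 1.0
    peth_bin_ms: float = 10.0
    peth_half_window_s: float = 1.0
    n_peth_shuffles: int = 200
    n_pattern_shuffles: int = 1000
    n_boot: int = 1000
    response_window_ms: Tuple[float, float] = (10.0, 30.0)
    min_peth_spikes: int = 30
    min_events: int = 20
    min_rate_hz: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_peth_shuffles", "n_pattern_shuffles", "n_boot",
            "min_peth_spikes", "min_events",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "response_window_ms" in data:
            data["response_window_ms"] = tuple(data["response_window_ms"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["response_window_ms"] = list(data["response_window_ms"])
        data["config_hash"] = self.hash()
        Path(path).write_text(yaml.safe_dump(data))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_synth(config: PipelineConfig, out: Path) -> None:
    """Write a synthetic session (and its ground truth) in the text formats
    the rest of the pipeline reads."""
    cfg = synth_mod.default_config(seed=config.seed)
    spikes, epochs, truth = synth_mod.generate_session(cfg)
    save_spikes(spikes, out / "spikes.tsv", out / "units.tsv")
    save_intervals(epochs, out / "intervals.tsv")
    truth.to_json(out / "ground_truth.json")


def _load_inputs(config: PipelineConfig, out: Path) -> Tuple[SpikeData, IntervalSet]:
    if config.synth:
        spikes = load_spikes(out / "spikes.tsv", out / "units.tsv")
        epochs = load_intervals(out / "intervals.tsv")
    else:
        spikes = load_spikes(config.spikes_path, config.metadata_path or None)
        epochs = load_intervals(config.intervals_path)
    return spikes, epochs


def stage_detect(
    config: PipelineConfig, spikes: SpikeData, epochs: IntervalSet, out: Path
) -> Dict[str, List[AssemblyModel]]:
    models: Dict[str, List[AssemblyModel]] = {}
    for structure in sorted(set(spikes.structure.values())):
        units = spikes.units_in(structure)
        if units.size < 2:
            models[structure] = []
            continue
        path = out / f"assemblies_{structure}.json"
        if path.exists():
            models[structure] = load_assemblies(path)
            continue
        found = detect(
            spikes.subset(units), epochs,
            bin_width_ms=config.bin_width_ms,
            min_rate_hz=config.min_rate_hz,
            seed=config.seed,
        )
        save_assemblies(found, path)
        models[structure] = found
    return models


def stage_activations(
    config: PipelineConfig,
    spikes: SpikeData,
    epochs: IntervalSet,
    models: Dict[str, List[AssemblyModel]],
    out: Path,
) -> Dict[str, List[ActivationSeries]]:
    events: Dict[str, List[ActivationSeries]] = {}
    for structure, assemblies in models.items():
        events[structure] = []
        frames = []
        for model in assemblies:
            ev = activation_events(
                spikes, model, epochs, step_ms=config.step_ms
            )
            events[structure].append(ev)
            frames.append(ev.events_frame())
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / f"events_{structure}.tsv", sep="\t", index=False
            )
    return events


def stage_readers(
    config: PipelineConfig,
    spikes: SpikeData,
    events: Dict[str, List[ActivationSeries]],
    out: Path,
) -> pd.DataFrame:
    """Test every (assembly, downstream-unit) pair across structures."""
    structures = sorted(events)
    rows = []
    for upstream in structures:
        downstream_units = [
            u for s in structures if s != upstream for u in
            [u for u in sorted(spikes.trains) if spikes.structure[u] == s]
        ]
        for ev in events[upstream]:
            if ev.n_events == 0:
                continue
            for u in downstream_units:
                _, verdict = test_pair(
                    spikes.trains[u], ev.peaks,
                    n_shuffles=config.n_peth_shuffles,
                    seed=config.seed + 131 * ev.assembly_id + u,
                    half_window_s=config.peth_half_window_s,
                    bin_ms=config.peth_bin_ms,
                    response_window_ms=config.response_window_ms,
                )
                rows.append(
                    {
                        "upstream": upstream,
                        "assembly_id": ev.assembly_id,
                        "reader_unit": u,
                        "testable": verdict.get("testable", False),
                        "significant": verdict.get("significant", False),
                        "first_sig_delay_ms": verdict.get("first_sig_delay_ms", np.nan),
                        "peak_score": verdict.get("peak_score", np.nan),
                        "n_events": verdict.get("n_events", 0),
                        "n_spikes": verdict.get("n_spikes", 0),
                    }
                )
    table = pd.DataFrame(rows)
    table.to_csv(out / "pairs.tsv", sep="\t", index=False)
    return table


def stage_collective(
    config: PipelineConfig,
    spikes: SpikeData,
    events: Dict[str, List[ActivationSeries]],
    models: Dict[str, List[AssemblyModel]],
    pairs: pd.DataFrame,
    out: Path,
) -> pd.DataFrame:
    """Supralinearity of each significant pair, bracketed by the simulated
    perfect and independent readers of its assembly."""
    rows = []
    sig = pairs[pairs["significant"]] if len(pairs) else pairs
    for _, row in sig.iterrows():
        upstream = row["upstream"]
        model = models[upstream][int(row["assembly_id"])]
        ev = events[upstream][int(row["assembly_id"])]
        t_in, t_out = split_member_triggers(spikes, model.members, ev)
        if t_in.size == 0 or t_out.size < 200:
            continue
        entry = {"upstream": upstream, "assembly_id": model.id,
                 "reader_unit": int(row["reader_unit"])}
        for label, rt in (
            ("observed", spikes.trains[int(row["reader_unit"])]),
            ("perfect", simulate_perfect_reader(ev, len(model.members))),
            ("independent", simulate_independent_reader(spikes, model.members)),
        ):
            try:
                ro = fit_linear_readout(rt, spikes, model.members, t_in,
                                        t_out, seed=config.seed)
                S = supralinearity_index(ro)
                entry[f"s20_{label}"] = ro.at(S, 20.0)
            except ValueError:
                entry[f"s20_{label}"] = np.nan
        rows.append(entry)
    table = pd.DataFrame(rows)
    table.to_csv(out / "collective.tsv", sep="\t", index=False)
    return table


def stage_patterns(
    config: PipelineConfig,
    spikes: SpikeData,
    events: Dict[str, List[ActivationSeries]],
    models: Dict[str, List[AssemblyModel]],
    pairs: pd.DataFrame,
    out: Path,
) -> pd.DataFrame:
    """Completion fits for significant pairs and sparsity increases for all
    downstream units (per upstream structure with >= 2 assemblies)."""
    duration = max(
        (t[-1] for t in spikes.trains.values() if t.size), default=1.0
    )
    rows = []
    sig = pairs[pairs["significant"]] if len(pairs) else pairs
    for _, row in sig.iterrows():
        upstream = row["upstream"]
        model = models[upstream][int(row["assembly_id"])]
        rt = spikes.trains[int(row["reader_unit"])]
        ev = coactivation_events(spikes, model.members, model.timescale_ms)
        sr = subset_responses(rt, ev, len(model.members),
                              max(rt.size / duration, 1e-9),
                              min_events=config.min_events)
        if not sr["testable"] or np.unique(sr["x"]).size < 4:
            continue
        fit = fit_sigmoid_vs_proportional(sr["x"], sr["response_rel"])
        rows.append({
            "upstream": upstream, "assembly_id": model.id,
            "reader_unit": int(row["reader_unit"]),
            "kind": "completion",
            "r2_sigmoid": fit.r2_sigmoid,
            "r2_proportional": fit.r2_proportional,
            "mid_tertile_boost": fit.tertile_boost[1],
        })
    for upstream, ev_list in events.items():
        if len(ev_list) < 2:
            continue
        downstream = [u for u in sorted(spikes.trains)
                      if spikes.structure[u] != upstream]
        for u in downstream:
            rt = spikes.trains[u]
            res = sparsity_increase(
                rt, ev_list, max(rt.size / duration, 1e-9),
                n_shuffles=config.n_pattern_shuffles,
                seed=config.seed + 977 + u,
            )
            if res.get("testable"):
                rows.append({
                    "upstream": upstream, "assembly_id": -1,
                    "reader_unit": u, "kind": "sparsity",
                    "sparsity_increase": res["increase"],
                })
    table = pd.DataFrame(rows)
    table.to_csv(out / "patterns.tsv", sep="\t", index=False)
    return table


def stage_report(
    config: PipelineConfig,
    out: Path,
    models: Dict[str, List[AssemblyModel]],
    pairs: pd.DataFrame,
) -> Path:
    lines = [
        "# Assembly-reader pipeline report",
        "",
        f"- config hash: `{config.hash()}`",
        f"- seed: {config.seed}",
        "",
    ]
    for structure, assemblies in sorted(models.items()):
        lines.append(
            f"- structure {structure}: {len(assemblies)} candidate assemblies"
        )
    if len(pairs):
        sig = pairs[pairs["significant"]]
        lines += [
            f"- tested pairs: {int(pairs['testable'].sum())}",
            f"- significant assembly-reader pairs: {len(sig)}",
        ]
    truth_path = out / "ground_truth.json"
    if truth_path.exists():
        truth = synth_mod.GroundTruth.from_json(truth_path)
        planted = {tuple(sorted(m)) for m in truth.members}
        recovered = {
            tuple(sorted(int(u) for u in a.members))
            for assemblies in models.values()
            for a in assemblies
        }
        lines += [
            "",
            f"- planted assemblies: {len(planted)}",
            f"- planted member sets recovered exactly: "
            f"{len(planted & recovered)}",
        ]
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns a result bundle of summaries."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "pipeline.log")
    logger.addHandler(handler)
    try:
        if config.synth and not (out / "spikes.tsv").exists():
            stage_synth(config, out)
        spikes, epochs = _load_inputs(config, out)
        models = stage_detect(config, spikes, epochs, out)
        events = stage_activations(config, spikes, epochs, models, out)
        pairs = stage_readers(config, spikes, events, out)
        collective = stage_collective(config, spikes, events, models, pairs, out)
        patterns = stage_patterns(config, spikes, events, models, pairs, out)
        report = stage_report(config, out, models, pairs)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {
        "output_dir": str(out),
        "n_assemblies": {s: len(m) for s, m in models.items()},
        "n_pairs_tested": int(pairs["testable"].sum()) if len(pairs) else 0,
        "n_pairs_significant": int(pairs["significant"].sum()) if len(pairs) else 0,
        "n_collective_rows": len(collective),
        "n_pattern_rows": len(patterns),
        "report": str(report),
    }
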