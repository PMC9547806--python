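"""Orchestration: seeds, configs, fixture suites and end-to-end runs.

A single global seed expands to independent per-stage seeds through a
documented scheme — ``stage_seed(global_seed, name)`` hashes the stage name
(CRC-32) into the spawn key of a ``numpy.random.SeedSequence`` — so any stage
can be re-run in isolation and still reproduce its in-pipeline behaviour.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crosslink, synth
from .clusters import QuantConfig, quantify_stack
from .errors import InvalidArgumentError
from .io import save_image_stack, sha256_of, write_manifest

log = logging.getLogger("clusterlab")


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(key, index))
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> dict:
    """Read a TOML or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        return tomllib.loads(text)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    raise InvalidArgumentError(f"unknown config format {path.suffix!r}")


def _default_panel() -> list[crosslink.AntibodySpecies]:
    return [
        crosslink.AntibodySpecies(id=f"anti-{s}", target_subunit=s, molecule_count=0)
        for s in ("alpha", "beta", "delta", "epsilon")
    ]


def generate_fixture_suite(outdir: str | Path, seed: int = 0) -> dict:
    """Write the documented set of synthetic datasets with ground truth.

    Contents: cluster time-lapses at three SNR levels, junction images at
    fragment counts {1, 2, 4, 8}, flow event tables at planted ratios
    {1, 2, 5, 10}, a calcium trace set, and a simulator combination sweep.
    Deterministic: the same seed reproduces byte-identical files.  Returns the
    inventory (relative path -> sha256).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, str] = {}

    def record(path: Path) -> None:
        inventory[str(path.relative_to(outdir))] = sha256_of(path)

    # cluster time-lapses at three SNR levels (photon_scale sets the SNR)
    for tag, photons in (("low", 40.0), ("mid", 200.0), ("high", 600.0)):
        optics = synth.OpticsParams(photon_scale=photons)
        stack, truth = synth.synth_cluster_timelapse(
            n_pre=5, n_post=10, shape=(192, 192), optics=optics,
            seed=stage_seed(seed, f"timelapse_{tag}"),
        )
        p = save_image_stack(stack, outdir / f"timelapse_snr_{tag}.ome.tif")
        record(p)
        tp = outdir / f"timelapse_snr_{tag}.truth.json"
        tp.write_text(json.dumps({
            "addition_time": truth.addition_time,
            "counts": truth.counts.tolist(),
            "count_slope_per_second": truth.count_slope_per_second,
            "snr": optics.snr,
        }))
        record(tp)

    # junction images over fragment counts
    for nfrag in (1, 2, 4, 8):
        stack, truth = synth.synth_nmj_image(
            n_fragments=nfrag, achr_retention=0.7, c3_level=120.0,
            seed=stage_seed(seed, "nmj", nfrag),
        )
        p = save_image_stack(stack, outdir / f"nmj_frag{nfrag}.ome.tif")
        record(p)
        tp = outdir / f"nmj_frag{nfrag}.truth.json"
        tp.write_text(json.dumps({
            "n_fragments": truth.n_fragments,
            "retention": truth.retention,
            "c3_level": truth.c3_level,
            "area_um2": truth.area_um2,
        }))
        record(tp)

    # flow event tables at planted GMFI ratios
    for ratio in (1, 2, 5, 10):
        events = synth.synth_flow_events(
            n_events=5000, binding_ratio=float(ratio),
            seed=stage_seed(seed, "flow", ratio),
        )
        p = outdir / f"flow_ratio{ratio}.csv"
        events.to_csv(p, index=False)
        record(p)

    # calcium traces
    traces = synth.synth_calcium_traces(seed=stage_seed(seed, "traces"))
    p = outdir / "calcium_traces.csv"
    traces.to_dataframe().to_csv(p, index=False)
    record(p)

    # simulator sweep: component sizes per seed and the synergy table
    panel = _default_panel()
    seeds = [stage_seed(seed, "sim", i) for i in range(10)]
    sweep = crosslink.sweep_combinations(n_receptors=100, panel=panel, seeds=seeds,
                                         total_count=200)
    p = outdir / "simulator_sweep.csv"
    sweep.to_csv(p, index=False)
    record(p)

    sizes_rows = []
    pool = crosslink.make_receptor_pool(100)
    for sd in seeds:
        sp = crosslink.AntibodySpecies(id="anti-alpha", target_subunit="alpha",
                                       molecule_count=200)
        stats = crosslink.component_stats(
            crosslink.simulate_binding(pool, [sp], seed=sd)
        )
        for size in stats.component_sizes:
            sizes_rows.append({"seed": sd, "component_size": size})
    p = outdir / "component_sizes.csv"
    pd.DataFrame(sizes_rows).to_csv(p, index=False)
    record(p)

    write_manifest(outdir / "manifest.json",
                   config={"seed": seed, "generator": "generate_fixture_suite"},
                   outputs=[outdir / k for k in inventory], seed=seed)
    return inventory


@dataclass
class EndToEndConfig:
    """Configuration of the simulate -> render -> quantify -> compare run."""

    n_receptors: int = 150
    density_per_um2: float = 8000.0
    capture_radius_nm: float = 15.0
    total_antibody: int = 300
    panel_subunits: tuple[str, ...] = ("alpha", "beta")
    include_pairs: bool = True
    n_pre_frames: int = 4
    n_post_frames: int = 8
    frame_interval: float = 20.0
    k_on: float = 1.0
    k_cross: float = 5.0
    seed: int = 0
    outdir: str = "clusterlab_run"


def _snapshot_graphs(pool, species, params, seed, checkpoints):
    """Graphs after increasing numbers of events along one trajectory.

    Re-running the attachment loop with the same seed replays the identical
    event sequence, so truncating at each checkpoint yields consistent
    snapshots of a single stochastic trajectory.
    """
    graphs = []
    for m in checkpoints:
        from dataclasses import replace as _replace

        p = _replace(params, max_events=int(m))
        graphs.append(crosslink.simulate_binding(pool, species, p, seed=seed))
    return graphs


def run_end_to_end(config: EndToEndConfig) -> Path:
    """Simulate each antibody condition, render, quantify, and compare.

    For every condition (each single, and each pair at half counts) the
    crosslinking simulation is snapshotted along its trajectory, every
    snapshot is rendered as a fluorescence frame, and the resulting synthetic
    time-lapse is quantified by the cluster pipeline.  Emits a
    condition-by-growth-rate table, a well-mixed synergy sweep, and a run
    manifest; returns the manifest path.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = crosslink.BindingParams(
        k_on=config.k_on, k_cross=config.k_cross,
        mode="geometric", capture_radius=config.capture_radius_nm,
    )
    by_sub = {
        s: crosslink.AntibodySpecies(id=f"anti-{s}", target_subunit=s, molecule_count=0)
        for s in config.panel_subunits
    }
    conditions: list[tuple[str, list[crosslink.AntibodySpecies]]] = []
    from dataclasses import replace as _replace

    for s, sp in by_sub.items():
        conditions.append((sp.id, [_replace(sp, molecule_count=config.total_antibody)]))
    if config.include_pairs:
        import itertools

        for a, b in itertools.combinations(by_sub.values(), 2):
            conditions.append(
                (f"{a.id}+{b.id}",
                 [_replace(a, molecule_count=config.total_antibody // 2),
                  _replace(b, molecule_count=config.total_antibody // 2)])
            )

    optics = synth.OpticsParams(pixel_size=0.16, psf_sigma=0.2,
                                background_level=10.0, photon_scale=50.0)
    rows = []
    outputs: list[Path] = []
    n_frames = config.n_pre_frames + config.n_post_frames
    for ci, (label, species) in enumerate(conditions):
        log.info("condition %s: simulating %d receptors, %s",
                 label, config.n_receptors, [ (sp.id, sp.molecule_count) for sp in species])
        cond_seed = stage_seed(config.seed, "simulate", ci)
        pool = crosslink.place_receptors(
            crosslink.make_receptor_pool(config.n_receptors),
            config.density_per_um2, seed=stage_seed(config.seed, "place", ci),
        )
        # exhaust once to learn the trajectory length, then snapshot post frames
        full = crosslink.simulate_binding(pool, species, params, seed=cond_seed)
        total_events = sum(len(ab.attachments) for ab in full.antibodies)
        checkpoints = [0] * config.n_pre_frames + list(
            np.linspace(1, max(total_events, 1), config.n_post_frames).astype(int)
        )
        graphs = _snapshot_graphs(pool, species, params, cond_seed, checkpoints)
        frames = []
        for fi, g in enumerate(graphs):
            frame_stack, _ = synth.render_simulated_field(
                g, optics=optics, seed=stage_seed(config.seed, "render", ci * 1000 + fi),
            )
            frames.append(frame_stack.data[0, 0])
        # jitter can change the auto-sized field by a pixel; crop to common shape
        shape = (min(f.shape[0] for f in frames), min(f.shape[1] for f in frames))
        frames = [f[: shape[0], : shape[1]] for f in frames]
        times = np.arange(n_frames) * config.frame_interval
        stack = synth.ImageStack(
            data=np.stack(frames)[:, None], frame_times=times,
            channel_names=["BTX"], pixel_size=optics.pixel_size,
        )
        tif = save_image_stack(stack, outdir / f"condition_{label}.ome.tif")
        outputs.append(tif)
        addition_time = 0.5 * (times[config.n_pre_frames - 1] + times[config.n_pre_frames])
        result = quantify_stack(stack, addition_time,
                                QuantConfig(background_radius=None, area_min=0.1,
                                            area_max=50.0))
        stats = crosslink.component_stats(full)
        rows.append({
            "condition": label,
            "n_species": len(species),
            "count_slope": result.rates.post["n_clusters"].slope,
            "total_area_slope": result.rates.post["total_area_um2"].slope,
            "mean_size_final": stats.mean_size,
            "proxy_ge4_final": crosslink.complement_proxy(stats, 4),
        })

    growth = pd.DataFrame(rows)
    growth_path = outdir / "condition_growth_rates.csv"
    growth.to_csv(growth_path, index=False)
    outputs.append(growth_path)

    sweep = crosslink.sweep_combinations(
        n_receptors=config.n_receptors,
        panel=[_replace(sp, molecule_count=0) for sp in by_sub.values()],
        seeds=[stage_seed(config.seed, "sweep", i) for i in range(10)],
        params=crosslink.BindingParams(k_on=config.k_on, k_cross=config.k_cross),
        total_count=config.total_antibody if config.total_antibody % 2 == 0
        else config.total_antibody + 1,
        pairs=None if config.include_pairs else [],
    )
    sweep_path = outdir / "synergy_sweep.csv"
    sweep.to_csv(sweep_path, index=False)
    outputs.append(sweep_path)

    manifest = write_manifest(outdir / "manifest.json", config=vars(config),
                              outputs=outputs, seed=config.seed)
    return manifest
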