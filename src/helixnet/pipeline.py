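"""Pipeline driver: configuration, stage orchestration, fixtures, and reports.

Stages run in order geometry → energy → network → report; each stage is
skippable and any stage can consume pre-computed inputs (e.g. externally
produced decomposition tables). Tabular outputs are deterministic byte-for-byte
for a fixed config and seed; every figure has a sibling CSV holding exactly
the plotted numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energetics import (
    AveragedMatrix,
    apply_exclusion,
    average_matrices,
    export_decomposition,
    import_decomposition,
    pairwise_interaction_energy,
)
from .errors import ConfigError, HelixnetError
from .geometry import align_to_reference, angle_rmsd_means, angle_rmsd_series, rmsf
from .network import (
    ContactCriteria,
    contacts_frame,
    detect_hbonds,
    detect_salt_bridges,
    diff_network,
    group_matrix,
    residue_wise,
    significant_residues,
)
from .params import ParamTable, default_params
from .plots import network_edges, render_group_chord, render_structure_network
from .structure import (
    SegmentDefinition,
    Structure,
    Trajectory,
    read_structure,
    read_trajectory,
    write_structure,
    write_trajectory,
)
from .synthetic import (
    HelixSpec,
    PlantedEnergySpec,
    SegmentMotion,
    make_bundle,
    make_noisy_trajectory,
    make_planted_energy_system,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"
ALL_STAGES = ("geometry", "energy", "network", "report")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml`` for the file schema)."""

    output_dir: Path
    structure: Path | None = None
    trajectory: Path | None = None
    segments: Path | None = None
    params: Path | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    exclusion_window: int = 4
    energy_frames: str = "reference"     # "reference" or "trajectory"
    energy_stride: int = 1
    wt_decomposition: tuple[Path, ...] = ()
    mut_decomposition: tuple[Path, ...] = ()
    mutated_residues: tuple[int, ...] = ()
    significance_threshold: float = 1.0
    network_edge_threshold: float = 0.5
    detect_hbond_contacts: bool = True
    detect_saltbridge_contacts: bool = True
    contact_criteria: ContactCriteria = field(default_factory=ContactCriteria)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config: no such file: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _path(key, raw_value, required=False):
            if raw_value is None:
                if required:
                    raise ConfigError(f"{key}: required path missing")
                return None
            p = Path(raw_value)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise ConfigError(f"{key}: no such file: {p}")
            return p

        energy = raw.get("energy") or {}
        net = raw.get("network") or {}
        contacts = raw.get("contacts") or {}
        stages = tuple(raw.get("stages") or ALL_STAGES)
        for s in stages:
            if s not in ALL_STAGES:
                raise ConfigError(f"stages: unknown stage {s!r}")
        window = int(energy.get("exclusion_window", 4))
        if window < 0:
            raise ConfigError("energy.exclusion_window: must be ≥ 0")
        threshold = float(net.get("significance_threshold", 1.0))
        if threshold < 0:
            raise ConfigError("network.significance_threshold: must be ≥ 0")
        out_dir = Path(raw.get("output_dir", "helixnet_out"))
        if not out_dir.is_absolute():
            out_dir = base / out_dir
        return cls(
            output_dir=out_dir,
            structure=_path("structure", raw.get("structure")),
            trajectory=_path("trajectory", raw.get("trajectory")),
            segments=_path("segments", raw.get("segments")),
            params=_path("params", raw.get("params")),
            stages=stages,
            seed=int(raw.get("seed", 0)),
            exclusion_window=window,
            energy_frames=str(energy.get("frames", "reference")),
            energy_stride=max(1, int(energy.get("stride", 1))),
            wt_decomposition=tuple(
                _path(f"network.wt_decomposition[{i}]", p, required=True)
                for i, p in enumerate(net.get("wt_decomposition") or [])),
            mut_decomposition=tuple(
                _path(f"network.mut_decomposition[{i}]", p, required=True)
                for i, p in enumerate(net.get("mut_decomposition") or [])),
            mutated_residues=tuple(int(r) for r in net.get("mutated_residues") or []),
            significance_threshold=threshold,
            network_edge_threshold=float(net.get("edge_threshold", 0.5)),
            detect_hbond_contacts=bool(contacts.get("hbonds", True)),
            detect_saltbridge_contacts=bool(contacts.get("salt_bridges", True)),
            contact_criteria=ContactCriteria(
                hbond_distance_max=float(contacts.get("hbond_distance_max", 3.5)),
                hbond_angle_min=float(contacts.get("hbond_angle_min", 120.0)),
                saltbridge_distance_max=float(
                    contacts.get("saltbridge_distance_max", 4.0))),
        )

    def digest(self) -> str:
        doc = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


@dataclass
class ReportBundle:
    """Stage outputs plus the manifest that reproduces them."""

    output_dir: Path
    outputs: dict[str, Path]
    manifest: dict


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def _averaged_from_tables(paths, window: int) -> AveragedMatrix:
    mats = [apply_exclusion(import_decomposition(p), window) for p in paths]
    return average_matrices(mats)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the configured stages and write the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    structure = read_structure(config.structure) if config.structure else None
    definition = SegmentDefinition.from_yaml(config.segments) if config.segments else None
    table = ParamTable.from_csv(config.params) if config.params else default_params()
    trajectory = None
    if config.trajectory is not None:
        if structure is None:
            raise ConfigError("trajectory: requires a structure (topology)")
        trajectory = read_trajectory(structure, config.trajectory)

    wt_avg: AveragedMatrix | None = None
    mut_avg: AveragedMatrix | None = None

    try:
        if "geometry" in config.stages:
            t0 = time.perf_counter()
            if structure is None or trajectory is None or definition is None:
                raise ConfigError(
                    "geometry: needs structure, trajectory and segments")
            aligned = align_to_reference(trajectory, structure,
                                         definition=definition)
            samples = angle_rmsd_series(aligned, structure, definition)
            outputs["angle_rmsd"] = _write_csv(samples, out / "angle_rmsd.csv")
            outputs["angle_rmsd_means"] = _write_csv(
                angle_rmsd_means(samples), out / "angle_rmsd_means.csv")
            fluct = rmsf(aligned).reset_index()
            outputs["rmsf"] = _write_csv(fluct, out / "rmsf.csv")
            counts["geometry_samples"] = len(samples)
            timings["geometry"] = time.perf_counter() - t0
            logger.info("geometry: %d samples in %.2fs",
                        len(samples), timings["geometry"])

        if "energy" in config.stages:
            t0 = time.perf_counter()
            if structure is None:
                raise ConfigError("energy: needs a structure")
            if config.energy_frames == "trajectory" and trajectory is not None:
                mats = []
                for k in range(0, trajectory.n_frames, config.energy_stride):
                    frame_struct = trajectory.frame_structure(k)
                    mats.append(apply_exclusion(
                        pairwise_interaction_energy(frame_struct, table),
                        config.exclusion_window))
                wt_avg = average_matrices(mats)
                export_mat = mats[0]
            else:
                mat = apply_exclusion(
                    pairwise_interaction_energy(structure, table),
                    config.exclusion_window)
                wt_avg = average_matrices([mat])
                export_mat = mat
            outputs["energy_decomposition"] = out / "energy_decomposition.csv"
            export_decomposition(export_mat, outputs["energy_decomposition"])
            counts["energy_residues"] = len(wt_avg.residues)
            timings["energy"] = time.perf_counter() - t0
            logger.info("energy: %d residues in %.2fs",
                        counts["energy_residues"], timings["energy"])

        if "network" in config.stages:
            t0 = time.perf_counter()
            if config.wt_decomposition:
                wt_avg = _averaged_from_tables(config.wt_decomposition,
                                               config.exclusion_window)
            if wt_avg is None:
                raise ConfigError(
                    "network: needs the energy stage or network.wt_decomposition")
            if config.mut_decomposition:
                mut_avg = _averaged_from_tables(config.mut_decomposition,
                                                config.exclusion_window)
            wt_profile = residue_wise(wt_avg)
            outputs["residue_profile_wt"] = _write_csv(
                wt_profile.as_series().reset_index(), out / "residue_profile_wt.csv")
            if definition is not None:
                gm = group_matrix(wt_avg, definition)
                outputs["group_matrix_wt"] = _write_csv(
                    gm.as_frame().reset_index(names="group"),
                    out / "group_matrix_wt.csv")
            if mut_avg is not None:
                mut_profile = residue_wise(mut_avg)
                outputs["residue_profile_mut"] = _write_csv(
                    mut_profile.as_series().reset_index(),
                    out / "residue_profile_mut.csv")
                mutated = [("A", r) for r in config.mutated_residues]
                dn = diff_network(wt_avg, mut_avg, mutated)
                diff_pairs = dn.pairs(config.network_edge_threshold)
                outputs["diff_network"] = _write_csv(
                    diff_pairs, out / "diff_network.csv")
                sig = significant_residues(wt_profile, mut_profile,
                                           config.significance_threshold)
                sig.insert(0, "threshold_kcal_mol", config.significance_threshold)
                outputs["significant_residues"] = _write_csv(
                    sig, out / "significant_residues.csv")
                if definition is not None:
                    gmm = group_matrix(mut_avg, definition)
                    outputs["group_matrix_mut"] = _write_csv(
                        gmm.as_frame().reset_index(names="group"),
                        out / "group_matrix_mut.csv")
                counts["diff_pairs"] = len(diff_pairs)
            source = trajectory if trajectory is not None else structure
            if source is not None:
                records = []
                if config.detect_hbond_contacts:
                    try:
                        records += detect_hbonds(source,
                                                 criteria=config.contact_criteria)
                    except HelixnetError as exc:
                        logger.info("hbond detection skipped: %s", exc)
                if config.detect_saltbridge_contacts:
                    try:
                        records += detect_salt_bridges(
                            source, criteria=config.contact_criteria)
                    except HelixnetError as exc:
                        logger.info("salt-bridge detection skipped: %s", exc)
                outputs["contacts"] = _write_csv(contacts_frame(records),
                                                 out / "contacts.csv")
                counts["contacts"] = len(records)
            timings["network"] = time.perf_counter() - t0
            logger.info("network: done in %.2fs", timings["network"])

        if "report" in config.stages:
            t0 = time.perf_counter()
            if wt_avg is not None and definition is not None:
                gm = group_matrix(wt_avg, definition)
                try:
                    outputs["chord_wt"] = Path(render_group_chord(
                        gm, str(out / "chord_wt.svg")))
                except HelixnetError as exc:
                    logger.info("chord diagram skipped: %s", exc)
            net_source = mut_avg is not None and wt_avg is not None
            if structure is not None and wt_avg is not None:
                target = diff_network(wt_avg, mut_avg) if net_source else wt_avg
                edges = network_edges(target, config.network_edge_threshold)
                edge_df = pd.DataFrame(
                    [{"chain_i": a[0], "res_i": a[1], "chain_j": b[0],
                      "res_j": b[1], "energy_kcal_mol": e, "class": c}
                     for a, b, e, c in edges],
                    columns=["chain_i", "res_i", "chain_j", "res_j",
                             "energy_kcal_mol", "class"])
                outputs["network_edges"] = _write_csv(
                    edge_df, out / "network_edges.csv")
                if edges:
                    outputs["network_figure"] = Path(render_structure_network(
                        structure, target, str(out / "network.svg"),
                        threshold=config.network_edge_threshold))
            timings["report"] = time.perf_counter() - t0
    except Exception:
        failed_marker.write_text("pipeline failed; partial outputs retained\n")
        raise

    manifest = {
        "package": "helixnet",
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_sha256": config.digest(),
        "seed": config.seed,
        "stages": list(config.stages),
        "exclusion_window": config.exclusion_window,
        "significance_threshold": config.significance_threshold,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "record_counts": counts,
        "outputs": {k: p.name for k, p in outputs.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    return ReportBundle(out, outputs, manifest)


# ---------------------------------------------------------------------------
# The generated 7TM study fixture
# ---------------------------------------------------------------------------

def generate_preset_7tm(outdir: str | Path, seed: int = 1,
                        n_frames: int = 12, sigma: float = 0.06
                        ) -> dict[str, Path]:
    """Write a complete synthetic 7TM study to a directory.

    Contents: the bundle structure (PDB) and segment definition, a noisy
    trajectory (multi-model PDB) with a +10° tilt of the TM6-2 compartment
    planted mid-trajectory, the synthetic parameter table, wildtype/mutant
    replicate decomposition tables with planted pairwise differences, a ready
    pipeline config, and the ground truth as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed) % (2**31 - 1)

    bundle, definition, tilts = make_bundle()
    paths: dict[str, Path] = {}
    paths["structure"] = outdir / "bundle.pdb"
    write_structure(bundle, paths["structure"])
    paths["segments"] = outdir / "segments.yaml"
    definition.to_yaml(paths["segments"])
    paths["params"] = outdir / "params.csv"
    default_params().to_csv(paths["params"])

    motion = SegmentMotion("TM6-2", start_frame=n_frames // 2, tilt_deg=10.0)
    traj = make_noisy_trajectory(bundle, sigma=sigma, n_frames=n_frames,
                                 seed=rng_seed, rigid_motions=[motion],
                                 definition=definition)
    paths["trajectory"] = outdir / "trajectory.pdb"
    write_trajectory(traj, paths["trajectory"])

    # planted energy system over the bundle's residue universe
    ordered = sorted(definition.segments.items(), key=lambda kv: kv[1][0])
    groups = tuple((name, last - first + 1) for name, (first, last) in ordered)
    tm2 = definition.segments["TM2"]
    tm3 = definition.segments["TM3"]
    tm7 = definition.segments["TM7"]
    ecl2 = definition.segments["ECL2"]
    baseline = (
        (tm2[0] + 5, tm7[0] + 5, -6.0),
        (tm2[0] + 8, tm3[0] + 3, -4.0),
        (ecl2[0] + 1, tm7[1] - 2, -3.5),
        (tm3[0] + 10, tm7[0] + 10, -2.5),
        (tm2[0] + 2, tm3[0] + 12, 1.5),
    )
    deltas = (
        (tm2[0] + 5, tm7[0] + 5, 3.0),
        (tm2[0] + 8, tm3[0] + 3, 2.0),
        (ecl2[0] + 1, tm7[1] - 2, 3.5),
        (tm3[0] + 10, tm7[0] + 10, -1.5),
        (tm2[0] + 2, tm3[0] + 12, 1.0),
    )
    spec = PlantedEnergySpec(groups=groups, baseline_pairs=baseline,
                             mutant_deltas=deltas, replicate_noise_sd=0.1,
                             n_replicates=3, seed=rng_seed)
    wt, mut, truth = make_planted_energy_system(spec)
    for k, m in enumerate(wt, 1):
        paths[f"wt_rep{k}"] = outdir / f"wt_rep{k}.csv"
        export_decomposition(m, paths[f"wt_rep{k}"])
    for k, m in enumerate(mut, 1):
        paths[f"mut_rep{k}"] = outdir / f"mut_rep{k}.csv"
        export_decomposition(m, paths[f"mut_rep{k}"])

    truth_doc = {
        "seed": rng_seed,
        "planted_tilts_deg": tilts,
        "trajectory": {"sigma_A": sigma, "n_frames": n_frames,
                       "motion": {"segment": motion.segment,
                                  "start_frame": motion.start_frame,
                                  "tilt_deg": motion.tilt_deg}},
        "planted_baseline_pairs": [list(p) for p in baseline],
        "planted_mutant_deltas": [list(p) for p in deltas],
        "replicate_noise_sd": spec.replicate_noise_sd,
        "n_replicates": spec.n_replicates,
    }
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth_doc, indent=2, sort_keys=True) + "\n")

    config_doc = {
        "seed": rng_seed,
        "output_dir": "out",
        "structure": "bundle.pdb",
        "trajectory": "trajectory.pdb",
        "segments": "segments.yaml",
        "params": "params.csv",
        "energy": {"exclusion_window": 4, "frames": "reference"},
        "network": {
            "wt_decomposition": [f"wt_rep{k}.csv" for k in (1, 2, 3)],
            "mut_decomposition": [f"mut_rep{k}.csv" for k in (1, 2, 3)],
            "significance_threshold": 1.0,
            "edge_threshold": 0.5,
        },
        "contacts": {"hbonds": False, "salt_bridges": False},
    }
    paths["config"] = outdir / "run.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config_doc, fh, sort_keys=True)
    return paths
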