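"""End-to-end pipeline: inputs -> restraints -> simulation -> ensemble -> report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
from Bio import SeqIO

from . import __version__
from .analysis import (
    pair_distance_distribution,
    radius_of_gyration,
    scaling_exponent,
)
from .cg_model import Conditions, build_topology, make_potential
from .config import RunConfig, save_config
from .distogram import read_distogram
from .ensemble import WeightedEnsemble, read_ensemble_pdb, write_ensemble_pdb
from .md_engine import (
    initialize_replicas,
    minimize,
    run_replicas,
    self_avoiding_walk,
)
from .metadynamics import CVSpec, PBMetaDHook, recompute_final_bias
from .metainference import MetainferenceHook, RMSDWallHook, WallSpec
from .restraints import (
    ResidueAnnotations,
    read_pae_json,
    read_plddt_table,
    select_restraints,
    write_restraints,
)
from .reweighting import (
    convergence_profiles,
    effective_sample_size,
    resample_ensemble,
    torrie_valleau_weights,
)

__all__ = ["run_pipeline", "prepare_restraints"]

log = logging.getLogger("afmi")


def _require(path: str, label: str) -> Path:
    if not path:
        raise FileNotFoundError(f"missing required input: {label}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing required input: {label} ({path})")
    return p


def _load_inputs(config: RunConfig):
    fasta = _require(config.paths.fasta, "fasta")
    record = next(SeqIO.parse(str(fasta), "fasta"))
    sequence = str(record.seq)
    disto = read_distogram(_require(config.paths.distogram, "distogram"))
    pae = read_pae_json(_require(config.paths.pae, "pae"))
    plddt_path = _require(config.paths.plddt, "plddt")
    if plddt_path.suffix.lower() == ".pdb":
        _, _, plddt = read_ensemble_pdb(plddt_path)
        if plddt is None:
            raise ValueError("pLDDT PDB carries no B-factor column")
    else:
        plddt = read_plddt_table(plddt_path)
    if disto.sequence != sequence:
        raise ValueError("distogram sequence differs from FASTA sequence")
    ann = ResidueAnnotations.from_sequence(sequence, plddt, pae)
    start = None
    if config.paths.start_structure:
        ens, _, _ = read_ensemble_pdb(_require(config.paths.start_structure, "start structure"))
        start = ens.frames[0]
    return sequence, disto, ann, start


def prepare_restraints(config: RunConfig, out_dir: Path | None = None):
    """Selection stage: distogram + annotations -> restraint set on disk."""
    sequence, disto, ann, start = _load_inputs(config)
    sel = config.selection
    rs = select_restraints(
        disto,
        ann,
        tail_threshold=sel.tail_threshold,
        min_separation=sel.min_separation,
        kd_threshold=sel.kd_threshold,
        stretch_len=sel.stretch_len,
        stretch_cutoff=sel.stretch_cutoff,
        segment_cutoff=sel.segment_cutoff,
        segment_min_len=sel.segment_min_len,
    )
    if out_dir is not None:
        write_restraints(out_dir / "restraints", rs)
    return sequence, rs, start


def _default_cv_specs(n_beads: int, start_rg: float, start_ree: float, width_fraction: float):
    return [
        CVSpec(
            kind="radius_of_gyration",
            grid_min=0.1,
            grid_max=max(4.0, 3.0 * start_rg),
            grid_spacing=0.01,
            gaussian_width=max(0.02, width_fraction * start_rg),
        ),
        CVSpec(
            kind="inter_bead_distance",
            grid_min=0.0,
            grid_max=max(12.0, 4.0 * max(start_ree, 1.0)),
            grid_spacing=0.02,
            gaussian_width=max(0.05, width_fraction * max(start_ree, 0.5)),
            parameters={"i": 0, "j": n_beads - 1},
        ),
    ]


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the run directory.

    Deterministic per seed in serial mode.  The manifest records the config
    hash, package version and per-stage timings; on a stage failure the
    partial outputs written so far are retained.
    """
    out = Path(config.output.directory)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {"version": __version__, "config_sha256": cfg_hash, "timings_s": {}}
    timings = manifest["timings_s"]

    def stage(name):
        log.info("stage: %s", name)
        return time.perf_counter()

    t0 = stage("prepare")
    sequence, rs, start = prepare_restraints(config, out_dir=out)
    timings["prepare"] = time.perf_counter() - t0

    eng = config.engine
    conditions = Conditions(
        temperature=eng.temperature, pH=eng.pH, ionic_strength=eng.ionic_strength
    )
    top = build_topology(
        sequence, conditions, charged_termini=eng.charged_termini
    )
    potential = make_potential(top, overlap_floor=None)

    t0 = stage("minimize")
    if start is None:
        start = self_avoiding_walk(top.n_beads, bond_length=top.bond_r0, seed=eng.seed)
    start = minimize(start, potential, max_steps=eng.minimize_steps)
    timings["minimize"] = time.perf_counter() - t0

    t0 = stage("run")
    ens = initialize_replicas(
        start, eng.n_replicas, top.mass, eng.temperature, seed=eng.seed, jitter=0.01
    )
    rg0 = float(np.sqrt(((start - start.mean(0)) ** 2).sum(1).mean()))
    ree0 = float(np.linalg.norm(start[-1] - start[0]))
    metad = PBMetaDHook(
        _default_cv_specs(top.n_beads, rg0, ree0, config.metad.width_fraction),
        eng.temperature,
        height=config.metad.height,
        bias_factor=config.metad.bias_factor,
        pace=config.metad.pace,
    )
    hooks: list = [metad]
    mi = config.metainference
    if len(rs):
        hooks.append(
            MetainferenceHook(
                rs,
                eng.n_replicas,
                eng.temperature,
                forward_model=mi.forward_model,
                sigma_prior=mi.sigma_prior,
                sem_window=mi.sem_window,
                bounds=tuple(mi.sigma_bounds),
                move_width=mi.move_width,
                seed=eng.seed,
            )
        )
    else:
        log.warning("empty restraint set; ensemble governed by prior (and wall)")
    if rs.structured_segments:
        wall = WallSpec(
            segments=[s for s in rs.structured_segments if s[1] - s[0] >= 3],
            reference=np.array(start),
            threshold=mi.wall_threshold,
            kappa=mi.wall_kappa,
        )
        if wall.segments:
            hooks.append(RMSDWallHook(wall))
    run_replicas(
        ens,
        potential,
        top.mass,
        eng.n_steps,
        hooks=hooks,
        save_every=eng.save_every,
        dt=eng.dt,
        friction=eng.friction,
        temperature=eng.temperature,
    )
    timings["run"] = time.perf_counter() - t0

    t0 = stage("reweight")
    traj = ens.trajectory
    start_f = int(np.ceil(config.output.equilibration_fraction * traj.n_frames))
    frames = np.concatenate([traj.coords[start_f:, r] for r in range(eng.n_replicas)])
    cvs = np.concatenate(
        [traj.cvs["PBMetaDHook"][start_f:, r] for r in range(eng.n_replicas)]
    )
    final_bias = recompute_final_bias(cvs, metad.bias, eng.temperature)
    weights = torrie_valleau_weights(final_bias, eng.temperature)
    np.savetxt(
        out / "weights.tsv",
        np.column_stack([np.arange(len(weights)), weights]),
        fmt=("%d", "%.10e"),
        header="frame_index weight",
    )
    final = resample_ensemble(frames, weights, config.output.n_resampled, seed=eng.seed)
    write_ensemble_pdb(out / "final_ensemble.pdb", final, sequence)
    timings["reweight"] = time.perf_counter() - t0

    t0 = stage("analyze")
    weighted = WeightedEnsemble(frames=frames, weights=weights)
    pr = pair_distance_distribution(weighted)
    rg_mean, rg_sem, _ = radius_of_gyration(weighted.frames, weighted.weights)
    report = {
        "n_restraints": int(len(rs)),
        "selection_provenance": rs.provenance,
        "pae_cutoff_A": rs.selection_mode,
        "effective_sample_size": effective_sample_size(weights),
        "rg_mean_A": rg_mean,
        "rg_sem_A": rg_sem,
        "p_of_r": {
            "r_A": pr.r_grid.tolist(),
            "density": pr.density.tolist(),
        },
    }
    if top.n_beads >= 10:
        fit = scaling_exponent(weighted)
        report["scaling_exponent_nu"] = fit.nu
        report["scaling_prefactor_A"] = fit.prefactor
    # convergence diagnostic: free-energy profiles along the first biased CV
    # over blocks of increasing coverage, per the production protocol
    try:
        cv_all = traj.cvs["PBMetaDHook"]  # (F, R, K)
        per_replica_cv = [cv_all[:, r, 0] for r in range(eng.n_replicas)]
        per_replica_w = []
        for r in range(eng.n_replicas):
            fb = recompute_final_bias(cv_all[:, r], metad.bias, eng.temperature)
            per_replica_w.append(torrie_valleau_weights(fb, eng.temperature))
        centers, profiles = convergence_profiles(
            per_replica_cv,
            per_replica_w,
            eng.temperature,
            n_blocks=config.output.n_convergence_blocks,
            equilibration_fraction=config.output.equilibration_fraction,
        )
        report["convergence"] = {
            "cv_nm": centers.tolist(),
            "free_energy_kj_mol": [
                [None if not np.isfinite(v) else v for v in row]
                for row in profiles
            ],
        }
    except ValueError as exc:
        log.warning("convergence diagnostic skipped: %s", exc)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    timings["analyze"] = time.perf_counter() - t0

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
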