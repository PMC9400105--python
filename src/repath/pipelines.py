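"""The two desk-scale pipelines: a toy reaction study and a dynamics contrast.

``reaction``: minimize reactant → drive the forming-bond restraint (RESD) →
release and minimize into the product basin → seed 16 replicas by linear
interpolation → optimize the chain → optionally refine around the barrier →
energy profile and monitored reaction distances.

``dynamics``: generate a synthetic two-domain trajectory (or load one) →
align → RMSD/RMSF → PCA → DCCM → bin classification, with the holo-like vs
apo-like scenario contrast summarized.

Everything is reproducible from config + seed; artifacts (XYZ, CSV, JSON) are
written under the configured output directory with a failure manifest if a
stage dies.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import path as rp
from . import resd, surfaces, synth, trajectory
from .geometry import minimize
from .io import RunConfig, write_trajectory_xyz, write_xyz

log = logging.getLogger("repath")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def run_reaction(config: RunConfig, outdir: Path) -> dict:
    surf_params = dict(config.surface.params)
    bs_params = surfaces.BondSwapParams(**surf_params) if surf_params else surfaces.BondSwapParams()
    cart = surfaces.cartesian_bond_swap(bs_params)
    reactant0, product_guess = surfaces.bond_swap_frames(bs_params)
    log.info("reaction: surface=%s k_rms=%s k_angle=%s cosmax=%s n_replicas=%s",
             config.surface.name, config.path.k_rms, config.path.k_angle,
             config.path.cosmax, config.path.n_replicas)

    # stage 1: relax the reactant; build basin references
    xr, _ = minimize(cart, reactant0.coords.ravel(), grad_tol=1e-6)
    reactant = reactant0.with_coords(xr.reshape(-1, 3))
    xp, _ = minimize(cart, product_guess.coords.ravel(), grad_tol=1e-6)
    basins = {"reactant": xr, "product": xp}

    # stage 2: RESD drive + release into the product basin
    restraints = [resd.DistanceRestraint(tuple(r.pair), r.k_force, r.d_eq)
                  for r in config.resd.restraints]
    if not restraints:
        restraints = [resd.DistanceRestraint(("Pg", "Ow"), 500.0, bs_params.r2_eq)]
    product, resd_report = resd.make_product_state(
        reactant, cart, restraints, n_steps=config.resd.n_steps,
        schedule=config.resd.schedule, grad_tol=config.resd.release_grad_tol,
        basins=basins)
    log.info("reaction: release landed in %s basin (rms grad %.2e)",
             resd_report["release"].basin, resd_report["release"].rms_gradient)

    # stage 3: interpolate + optimize the replica chain
    chain = rp.interpolate_endpoints(
        reactant, product, n_replicas=config.path.n_replicas,
        k_rms=config.path.k_rms, k_angle=config.path.k_angle,
        cosmax=config.path.cosmax, fit=config.path.fit)
    opt, report = rp.optimize_path(
        chain, cart, max_steps=config.path.max_steps,
        grad_tol=config.path.grad_tol, energy_tol=config.path.energy_tol,
        patience=config.path.patience)
    profile = rp.energy_profile(opt, cart)

    refined_profile = None
    if config.path.refine and 0 < profile.ts_index < opt.n_replicas - 1:
        refined = rp.refine_endpoints(opt, cart, window=config.path.refine_window,
                                      n_replicas=config.path.n_replicas)
        refined_opt, _ = rp.optimize_path(
            refined, cart, max_steps=config.path.max_steps,
            grad_tol=config.path.grad_tol, energy_tol=config.path.energy_tol,
            patience=config.path.patience)
        refined_profile = rp.energy_profile(refined_opt, cart)
        write_xyz(outdir / "path_refined.xyz", refined_opt.replicas)

    # stage 4: monitored reaction distances
    pairs = dict(config.monitor.pairs) or {"R1": ("Pg", "Os"), "R2": ("Pg", "Ow")}
    monitor = rp.monitor_distances(opt, pairs)

    write_xyz(outdir / "reactant.xyz", reactant)
    write_xyz(outdir / "product.xyz", product)
    write_xyz(outdir / "path_optimized.xyz", opt.replicas)
    monitor.to_csv(outdir / "monitor.csv", index=False)
    np.savetxt(outdir / "profile.csv",
               np.column_stack([np.arange(1, opt.n_replicas + 1),
                                profile.per_replica_energy]),
               delimiter=",", header="replica,energy", comments="")

    summary = {
        "pipeline": "reaction",
        "release_basin": resd_report["release"].basin,
        "release_rms_gradient": resd_report["release"].rms_gradient,
        "driven_distances": resd_report["driven_distances"],
        "converged": report.converged,
        "steps_taken": report.steps_taken,
        "activation_energy": profile.activation_energy,
        "ts_index": profile.ts_index,
        "per_replica_energy": profile.per_replica_energy.tolist(),
        "monitor_pairs": {k: list(v) for k, v in pairs.items()},
    }
    if refined_profile is not None:
        # barrier referenced to the original reactant, with the refined chain's
        # sharper sampling of the barrier top
        summary["refined_ts_energy"] = float(refined_profile.per_replica_energy.max())
        summary["refined_activation_energy"] = float(
            refined_profile.per_replica_energy.max() - profile.per_replica_energy[0])
    return summary


def run_dynamics(config: RunConfig, outdir: Path) -> dict:
    summary: dict = {"pipeline": "dynamics", "scenarios": {}}
    for name in ("coherent_holo_like", "incoherent_apo_like"):
        spec = synth.scenario(name, seed=config.seed, n_frames=config.synth.n_frames)
        traj, truth = synth.generate(spec)
        aligned = trajectory.align_trajectory(
            traj, selection=config.analysis.selection,
            reference=config.analysis.align_reference)
        series = trajectory.rmsd_series(aligned)
        fluct = trajectory.rmsf(aligned)
        pc = trajectory.pca(aligned, n_modes=config.analysis.n_modes)
        cc = trajectory.dccm(aligned, low=config.analysis.dccm_low,
                             high=config.analysis.dccm_high)
        core = traj.selections["core"]
        mobile = traj.selections["mobile"]
        inter = cc.matrix[np.ix_(core, mobile)]
        scen = {
            "rmsd_mean": float(series.mean()),
            "rmsf_core_mean": float(fluct[core].mean()),
            "rmsf_mobile_mean": float(fluct[mobile].mean()),
            "pc1_pc2_variance_fraction": float(pc.cumulative_variance[1]),
            "interdomain_mean_abs_corr": float(np.abs(inter).mean()),
            "interdomain_strong_fraction": float(np.mean(np.abs(inter) > 0.25)),
            "anticorrelated_bin_fraction": float(np.mean(cc.bins == -1)),
        }
        summary["scenarios"][name] = scen
        sdir = outdir / name
        sdir.mkdir(parents=True, exist_ok=True)
        write_trajectory_xyz(sdir / "trajectory.xyz", aligned, precision=4)
        np.savetxt(sdir / "dccm.csv", cc.matrix, delimiter=",")
        np.savetxt(sdir / "rmsf.csv", fluct, delimiter=",")
        np.savetxt(sdir / "rmsd.csv", series, delimiter=",")
        np.savetxt(sdir / "pca_cumvar.csv", pc.cumulative_variance, delimiter=",")
        cc.top_anticorrelated.to_csv(sdir / "anticorrelated_edges.csv", index=False)
        log.info("dynamics[%s]: PC1+PC2 %.3f, inter-domain mean|C| %.3f",
                 name, scen["pc1_pc2_variance_fraction"],
                 scen["interdomain_mean_abs_corr"])

    holo = summary["scenarios"]["coherent_holo_like"]
    apo = summary["scenarios"]["incoherent_apo_like"]
    summary["contrast"] = {
        "pc1_pc2_fraction_difference": holo["pc1_pc2_variance_fraction"]
        - apo["pc1_pc2_variance_fraction"],
        "interdomain_mean_abs_corr_difference": holo["interdomain_mean_abs_corr"]
        - apo["interdomain_mean_abs_corr"],
    }
    return summary


def run_pipeline(config: RunConfig, which: str) -> dict:
    """Run one named pipeline; always writes a summary (or failure manifest)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    try:
        if which == "reaction":
            summary = run_reaction(config, outdir)
        elif which == "dynamics":
            summary = run_dynamics(config, outdir)
        else:
            raise ValueError(f"unknown pipeline {which!r}; options: reaction, dynamics")
    except Exception as exc:  # failure manifest with partial artifacts
        manifest = {"pipeline": which, "failed": True, "error": str(exc),
                    "error_type": type(exc).__name__}
        _write_json(outdir / "failure_manifest.json", manifest)
        raise
    summary["seed"] = config.seed
    _write_json(outdir / "summary.json", summary)
    return summary
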