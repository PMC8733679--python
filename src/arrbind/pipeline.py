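"""Configuration-driven orchestration of the analysis battery.

Each ``run_*`` function takes a :class:`~arrbind.config.RunConfig`, executes
one analysis over all configured replica trajectories, writes tidy TSV/JSON
outputs into the configured output directory and returns a ReplicaReport.
Replicas pool by contributing windows: the cross-replica SEM is the standard
error over all per-window means (e.g. three replicas with two analysed
intervals each pool into six intervals).

All outputs are stamped with the configuration hash and package version; a
log line records every resolved default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import contacts as contacts_mod
from . import energetics as energetics_mod
from . import geometry as geometry_mod
from . import secondary as secondary_mod
from . import synth as synth_mod
from .config import ConfigError, RunConfig
from .core import (AnalysisWindows, Structure, Trajectory, load_structure,
                   load_trajectory, make_windows)

logger = logging.getLogger("arrbind")

__all__ = [
    "ReplicaReport",
    "run_contacts",
    "run_geometry",
    "run_energetics",
    "run_helicity",
    "run_structure_metrics",
    "simulate",
]


@dataclass
class ReplicaReport:
    analysis: str
    config_hash: str
    outputs: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "analysis": self.analysis,
            "arrbind_version": __version__,
            "config_hash": self.config_hash,
            "outputs": self.outputs,
            "summary": self.summary,
        }
        pathlib.Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True, default=float))


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------


def _out_dir(config: RunConfig) -> pathlib.Path:
    out = config.resolve_path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _load_topology(config: RunConfig) -> Structure:
    return load_structure(config.require_file("topology"))


def _load_replicas(config: RunConfig, topology: Structure) -> list[Trajectory]:
    paths = config.require_files("trajectories")
    fmt = config.get("trajectory_format")
    dt = config["dt_ns"]
    replicas = []
    for p in paths:
        try:
            replicas.append(load_trajectory(p, topology, format=fmt, dt=dt))
        except (ValueError, OSError) as exc:
            raise DataError(f"failed to read trajectory {p}: {exc}") from exc
    return replicas


class DataError(RuntimeError):
    """Raised when inputs exist but cannot be analysed."""


def _selection(config: RunConfig, structure: Structure, name: str):
    table = dict(synth_mod.SELECTIONS)
    table.update(config["selections"] or {})
    if name in table:
        expr = table[name]
    else:
        expr = name   # allow literal expressions in config slots
    try:
        return structure.select(expr, label=name)
    except Exception as exc:
        raise ConfigError(f"selection {name!r} ({expr!r}) failed: {exc}")


def _windows(config: RunConfig, traj: Trajectory) -> AnalysisWindows:
    w = config["windows"]
    if w.get("intervals"):
        return make_windows(traj, intervals=[tuple(i) for i in w["intervals"]])
    return make_windows(traj, length=float(w["length_ns"]),
                        burn_in=float(w.get("burn_in_ns", 0.0)))


def _log_resolved(analysis: str, config: RunConfig, **extra) -> None:
    logger.info("%s: config_hash=%s version=%s", analysis, config.config_hash,
                __version__)
    for key in ("windows", "contacts", "geometry", "energetics", "helicity"):
        logger.info("%s: resolved %s = %s", analysis, key, config[key])
    for k, v in extra.items():
        logger.info("%s: %s = %s", analysis, k, v)


def _edges(spec) -> np.ndarray:
    lo, hi, width = spec
    return np.arange(lo, hi + width / 2, width)


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------


def run_contacts(config: RunConfig) -> ReplicaReport:
    """Per-residue contact-probability profiles, pooled across replicas."""
    topo = _load_topology(config)
    replicas = _load_replicas(config, topo)
    ccfg = config["contacts"]
    residues = _selection(config, topo, ccfg["residues"]).split_by_residue()
    target = _selection(config, topo, ccfg["target"])
    out = _out_dir(config)
    _log_resolved("contacts", config, n_replicas=len(replicas))
    profiles = []
    all_window_means = []
    weights = []
    for i, traj in enumerate(replicas):
        w = _windows(config, traj)
        prof = contacts_mod.contact_probability_profile(
            traj, residues, target, w, cutoff=float(ccfg["cutoff_nm"]))
        prof.to_tsv(out / f"contacts_replica{i}.tsv")
        profiles.append(prof)
        all_window_means.append(prof.window_means)
        weights.extend(len(idx) for idx in w.frame_indices(traj.times))
    window_means = np.concatenate(all_window_means, axis=0)
    weights = np.asarray(weights, dtype=float)
    pooled_p = np.average(window_means, weights=weights, axis=0)
    n_w = window_means.shape[0]
    pooled_sem = (np.std(window_means, axis=0, ddof=1) / np.sqrt(n_w)
                  if n_w > 1 else np.zeros_like(pooled_p))
    pooled = contacts_mod.ContactProfile(
        residue_keys=profiles[0].residue_keys,
        residue_names=profiles[0].residue_names,
        probabilities=pooled_p, sems=pooled_sem, n_windows=n_w,
        window_means=window_means)
    pooled.to_tsv(out / "contacts_pooled.tsv")
    report = ReplicaReport(
        "contacts", config.config_hash,
        outputs=[str(out / "contacts_pooled.tsv")],
        summary={"n_windows_pooled": int(n_w),
                 "max_probability": float(pooled_p.max())})
    report.to_json(out / "contacts_report.json")
    return report


def run_geometry(config: RunConfig) -> ReplicaReport:
    """d(t)/alpha(t) series, 2D density, engagement and dynamics metric."""
    topo = _load_topology(config)
    replicas = _load_replicas(config, topo)
    gcfg = config["geometry"]
    tm = _selection(config, topo, gcfg["tm_bundle"])
    nlobe = _selection(config, topo, gcfg["nlobe"])
    clobe = _selection(config, topo, gcfg["clobe"])
    fit = _selection(config, topo, gcfg["fit"])
    ref_path = config.get("reference")
    ref_structure = (load_structure(config.require_file("reference"))
                     if ref_path else topo)
    try:
        mem = _selection(config, ref_structure, "membrane")
        mframe = geometry_mod.membrane_frame(None, membrane=mem)
    except Exception:
        mframe = geometry_mod.membrane_frame(
            None, bundle=_selection(config, ref_structure, gcfg["tm_bundle"]),
            below=_selection(config, ref_structure, gcfg["nlobe"]))
    reference = geometry_mod.BindingModeReference(
        structure=ref_structure,
        fit=_selection(config, ref_structure, gcfg["fit"]),
        anchor_a=_selection(config, ref_structure, gcfg["nlobe"]),
        anchor_b=_selection(config, ref_structure, gcfg["clobe"]),
        mframe=mframe,
        descriptor=str(ref_path or config["topology"]),
    )
    out = _out_dir(config)
    _log_resolved("geometry", config, reference=reference.descriptor)
    threshold = float(gcfg["disengage_threshold_nm"])
    series_list = []
    windows = None
    for i, traj in enumerate(replicas):
        windows = _windows(config, traj)
        series = geometry_mod.binding_mode_series(
            traj, tm, nlobe, fit, nlobe, clobe, reference, windows)
        labels, frac, _ = geometry_mod.classify_engagement(series, threshold)
        frame = series.to_frame()
        frame["engagement"] = labels
        frame.to_csv(out / f"binding_mode_replica{i}.tsv", sep="\t",
                     index=False)
        series_list.append(series)
    pooled = geometry_mod.BindingModeSeries(
        times=np.concatenate([s.times + 1e6 * i
                              for i, s in enumerate(series_list)]),
        d=np.concatenate([s.d for s in series_list]),
        alpha=np.concatenate([s.alpha for s in series_list]),
        reference=reference.descriptor)
    density = geometry_mod.density2d(pooled, _edges(gcfg["d_edges"]),
                                     _edges(gcfg["alpha_edges"]))
    density.to_tsv(out / "density_d_alpha.tsv")
    metric = geometry_mod.dynamics_metric(series_list, windows)
    _, frac_dis, _ = geometry_mod.classify_engagement(pooled, threshold)
    report = ReplicaReport(
        "geometry", config.config_hash,
        outputs=[str(out / "density_d_alpha.tsv")],
        summary={
            "d_mean_nm": float(pooled.d.mean()),
            "alpha_mean_deg": float(pooled.alpha.mean()),
            "d_sd_mean_nm": metric.d_sd_mean, "d_sd_sem_nm": metric.d_sd_sem,
            "alpha_sd_mean_deg": metric.alpha_sd_mean,
            "alpha_sd_sem_deg": metric.alpha_sd_sem,
            "disengaged_fraction": frac_dis,
            "disengage_threshold_nm": threshold,
        })
    report.to_json(out / "geometry_report.json")
    return report


def run_energetics(config: RunConfig) -> ReplicaReport:
    """Windowed group-group nonbonded energies per replica."""
    topo = _load_topology(config)
    replicas = _load_replicas(config, topo)
    ecfg = config["energetics"]
    group_a = _selection(config, topo, ecfg["group_a"])
    group_b = _selection(config, topo, ecfg["group_b"])
    if config.get("params_tsv"):
        params = energetics_mod.load_params_tsv(
            config.require_file("params_tsv"), topo,
            cutoff=float(ecfg["cutoff_nm"]),
            permittivity=float(ecfg["permittivity"]))
    else:
        params = synth_mod.default_params(topo,
                                          cutoff=float(ecfg["cutoff_nm"]))
        logger.info("energetics: no params_tsv; using toy default parameters")
    out = _out_dir(config)
    _log_resolved("energetics", config)
    abs_totals = []
    for i, traj in enumerate(replicas):
        table = energetics_mod.windowed_group_energy(
            traj, group_a, group_b, params,
            window_length=float(ecfg["window_ns"]),
            burn_in=float(ecfg["burn_in_ns"]))
        table.to_csv(out / f"energy_replica{i}.tsv", sep="\t", index=False)
        abs_totals.extend(table["abs_total"].tolist())
    report = ReplicaReport(
        "energetics", config.config_hash,
        outputs=[str(out / f"energy_replica{i}.tsv")
                 for i in range(len(replicas))],
        summary={"abs_total_mean_kjmol": float(np.mean(abs_totals))
                 if abs_totals else float("nan"),
                 "n_windows": len(abs_totals)})
    report.to_json(out / "energetics_report.json")
    return report


def run_helicity(config: RunConfig) -> ReplicaReport:
    """ICL2 helical-residue counts per window, pooled across replicas."""
    topo = _load_topology(config)
    replicas = _load_replicas(config, topo)
    hcfg = config["helicity"]
    resids = list(range(int(hcfg["resids"][0]), int(hcfg["resids"][1]) + 1))
    out = _out_dir(config)
    _log_resolved("helicity", config)
    window_means, weights = [], []
    for i, traj in enumerate(replicas):
        w = _windows(config, traj)
        res = secondary_mod.helicity_timeseries(
            traj, resids, w, chain=hcfg["chain"],
            phi_window=tuple(hcfg["phi_window"]),
            psi_window=tuple(hcfg["psi_window"]),
            min_run=int(hcfg["min_run"]))
        res.to_tsv(out / f"helicity_replica{i}.tsv")
        window_means.extend(res.window_means.tolist())
        weights.extend(len(idx) for idx in w.frame_indices(traj.times))
    window_means = np.asarray(window_means)
    n = len(window_means)
    mean = float(np.average(window_means, weights=np.asarray(weights)))
    sem = float(np.std(window_means, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    report = ReplicaReport(
        "helicity", config.config_hash,
        outputs=[str(out / f"helicity_replica{i}.tsv")
                 for i in range(len(replicas))],
        summary={"helical_residues_mean": mean, "sem": sem, "n_windows": n})
    report.to_json(out / "helicity_report.json")
    return report


def run_structure_metrics(config: RunConfig) -> pd.DataFrame:
    """Single-structure table: ionic lock, d, alpha, ICL2 helicity.

    Works on experimental structures (membrane-free: the membrane normal
    falls back to the receptor bundle axis) and on toy systems alike.
    Structure-specific selections may be given per entry.
    """
    entries = config.get("structures") or []
    if not entries:
        raise ConfigError("structure-metrics needs a 'structures' list")
    gcfg = config["geometry"]
    hcfg = config["helicity"]
    ref_structure = None
    reference = None
    if config.get("reference"):
        ref_structure = load_structure(config.require_file("reference"))
    rows = []
    out = _out_dir(config)
    _log_resolved("structure-metrics", config, n_structures=len(entries))
    for entry in entries:
        if isinstance(entry, (str, pathlib.Path)):
            entry = {"path": entry}
        path = config.resolve_path(entry["path"])
        if not path.exists():
            raise ConfigError(f"structure file not found: {path}")
        s = load_structure(path)
        row: dict = {"structure": path.name}
        chain = entry.get("receptor_chain")
        try:
            row["ionic_lock_nm"] = geometry_mod.ionic_lock_distance(
                s, chain=chain,
                res_a=int(entry.get("lock_res_a", 131)),
                res_b=int(entry.get("lock_res_b", 268)))
        except ValueError as exc:
            row["ionic_lock_nm"] = float("nan")
            logger.warning("%s: ionic lock unavailable (%s)", path.name, exc)
        try:
            tm = _selection(config, s, entry.get("tm_bundle",
                                                 gcfg["tm_bundle"]))
            nlobe = _selection(config, s, entry.get("nlobe", gcfg["nlobe"]))
            try:
                mem = _selection(config, s, "membrane")
                mframe = geometry_mod.membrane_frame(None, membrane=mem)
            except Exception:
                mframe = geometry_mod.membrane_frame(None, bundle=tm,
                                                     below=nlobe)
            row["d_nm"] = geometry_mod.insertion_depth(None, tm, nlobe,
                                                       mframe)
        except Exception as exc:
            row["d_nm"] = float("nan")
            logger.warning("%s: insertion depth unavailable (%s)", path.name,
                           exc)
        try:
            resids_cfg = entry.get("icl2_resids", hcfg["resids"])
            resids = list(range(int(resids_cfg[0]), int(resids_cfg[1]) + 1))
            phi, psi = secondary_mod.backbone_dihedrals(
                s, resids, entry.get("icl2_chain", chain))
            row["icl2_helical_residues"] = int(secondary_mod.assign_helix(
                phi, psi, tuple(hcfg["phi_window"]),
                tuple(hcfg["psi_window"]), int(hcfg["min_run"])).sum())
        except Exception as exc:
            row["icl2_helical_residues"] = -1
            logger.warning("%s: helicity unavailable (%s)", path.name, exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out / "structure_metrics.tsv", sep="\t", index=False)
    ReplicaReport("structure-metrics", config.config_hash,
                  outputs=[str(out / "structure_metrics.tsv")],
                  summary={"n_structures": len(rows)}
                  ).to_json(out / "structure_metrics_report.json")
    return table


def simulate(config: RunConfig) -> pathlib.Path:
    """Build and simulate a toy fixture into the output directory."""
    scfg = config["simulate"]
    seed = int(config["seed"])
    toy = synth_mod.build_toy_complex(synth_mod.ToySystemSpec(), seed=seed)
    dyn = synth_mod.default_dynamics(n_frames=int(scfg["n_frames"]),
                                     seed=seed)
    dyn.dt = float(scfg["dt_ns"])
    bundle = synth_mod.simulate_trajectory(toy, dyn)
    out = _out_dir(config)
    synth_mod.write_fixture(bundle, out)
    logger.info("simulate: fixture written to %s (seed=%d, %d frames)",
                out, seed, dyn.n_frames)
    return out
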