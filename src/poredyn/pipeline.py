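"""Configuration-driven orchestration of the analysis stages.

A single declarative config (YAML file or dict) names the input — real
trajectory files or a synthetic-generator block — the particle groups, the
pore geometry and per-analysis parameters, and selects which stages to run.
Stages execute in dependency order (load/simulate → geometry → residency →
{occupancy, survival, velocity, maps, coordination, hbonds}); every output
file is CSV or JSON and the report records the config hash, the seed and a
manifest of files written, so every default stands on the record.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import coordination as coord_mod
from . import dynamics as dyn_mod
from . import maps as maps_mod
from .occupancy import classify_inside, occupancy_stats, z_traces
from .survival import survival_probability
from .synthetic import (DwellProcessParams, PoreModelParams,
                        simulate_confined_brownian)
from .trajectory import ConfigurationError, fit_channel_axis, load_trajectory

__all__ = ["AnalysisConfig", "run_full_analysis", "write_report"]

_STAGES = ("occupancy", "survival", "velocity", "maps", "coordination",
           "hbonds")


@dataclass
class AnalysisConfig:
    """Validated analysis configuration.

    Exactly one of ``input`` (paths) or ``synthetic`` (generator block) must
    be present.  All analysis parameters carry explicit defaults that are
    echoed into the report.
    """

    outdir: str
    seed: int = 0
    input: dict | None = None          # {topology, trajectory?, groups}
    synthetic: dict | None = None      # PoreModelParams overrides + n_particles, duration
    groups: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    geometry: dict = field(default_factory=dict)   # pore_radius, z_pad, backbone_group, lab_axis
    tracked_group: str = "mobile"
    window_start_frac: float = 0.1     # discard the first 10% of frames
    survival_params: dict = field(default_factory=dict)   # tau_max, convention
    velocity_params: dict = field(default_factory=dict)   # window, stride
    map_params: dict = field(default_factory=dict)        # bin_width, r_bins, theta_bins, planes
    coordination_params: dict = field(default_factory=dict)  # centers, contributors, r_max, dr
    hbond_params: dict = field(default_factory=dict)      # donors, acceptors, criteria

    @classmethod
    def from_file(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        problems = [f"unknown config key {k!r}" for k in raw if k not in known]
        cfg = cls(**{k: v for k, v in raw.items() if k in known}) \
            if not problems else None
        if cfg is None:
            raise ConfigurationError("; ".join(problems))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        problems: list[str] = []
        if (self.input is None) == (self.synthetic is None):
            problems.append(
                "exactly one of 'input' or 'synthetic' must be present")
        for stage in self.stages:
            if stage not in _STAGES:
                problems.append(f"unknown stage {stage!r}")
        defined = set(self.groups) | {"mobile", "backbone"} \
            if self.synthetic is not None else set(self.groups)
        for key, name in [("tracked_group", self.tracked_group),
                          ("backbone", self.geometry.get("backbone_group",
                                                         "backbone"))]:
            if defined and name not in defined:
                problems.append(f"{key} references undefined group {name!r}")
        cp = self.coordination_params
        for name in [cp.get("centers")] + list(cp.get("contributors", [])):
            if name and defined and name not in defined:
                problems.append(
                    f"coordination references undefined group {name!r}")
        if problems:
            raise ConfigurationError("; ".join(problems))

    def config_hash(self) -> str:
        """Hash of every analysis-relevant setting (output location excluded
        so identical analyses hash identically wherever they are written)."""
        payload = asdict(self)
        payload.pop("outdir", None)
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _float_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the configured stages and return the report dict.

    Each stage writes its own CSV/JSON outputs; failure of one stage is
    recorded in the report and does not corrupt completed outputs.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "files": [],
    }

    def emit(name: str, df: pd.DataFrame) -> str:
        path = os.path.join(config.outdir, name)
        _float_csv(df, path)
        report["files"].append(name)
        return path

    # --- input -----------------------------------------------------------
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        n_particles = syn.pop("n_particles", 50)
        duration = syn.pop("duration", 200.0)
        species = syn.pop("species", config.tracked_group)
        syn.setdefault("seed", config.seed)
        params = PoreModelParams(**syn)
        traj, truth = simulate_confined_brownian(
            params, n_particles, duration, species=species)
    else:
        traj = load_trajectory(config.input["topology"],
                               config.input.get("trajectory"),
                               config.input.get("groups", config.groups))

    # --- geometry & residency --------------------------------------------
    geo = config.geometry
    geom = fit_channel_axis(
        traj, geo.get("backbone_group", "backbone"),
        pore_radius=geo.get("pore_radius", 9.0),
        z_pad=geo.get("z_pad", 0.0),
        lab_axis=np.asarray(geo["lab_axis"], dtype=float)
        if geo.get("lab_axis") is not None else None)
    res = classify_inside(traj, geom, config.tracked_group)
    span = traj.times[-1] - traj.times[0]
    window_start = float(traj.times[0] + config.window_start_frac * span)

    # --- stages ----------------------------------------------------------
    for stage in config.stages:
        try:
            if stage == "occupancy":
                occ = occupancy_stats(res, window_start, float(traj.times[-1]))
                emit("occupancy.csv", pd.DataFrame(
                    {"time_ps": occ.times, "count": occ.counts}))
                zt = z_traces(res, traj, geom,
                              bin_width=config.map_params.get("z_bin_width", 0.5))
                rows = [(pid, t, z) for pid, arr in zt.traces.items()
                        for t, z in arr]
                emit("z_traces.csv", pd.DataFrame(
                    rows, columns=["particle_id", "time_ps", "z_A"]))
                centers = 0.5 * (zt.bin_edges[:-1] + zt.bin_edges[1:])
                emit("z_presence.csv", pd.DataFrame(
                    {"z_bin_center": centers,
                     "frames_with_presence": zt.presence}))
                report["stages"]["occupancy"] = {
                    "mean": occ.mean, "sd": occ.sd, "window_start_ps": window_start}
            elif stage == "survival":
                sp = config.survival_params
                tau_max = sp.get("tau_max", (traj.times[-1] - traj.times[0]) / 2)
                tau_max = res.dt * round(tau_max / res.dt)
                curve = survival_probability(
                    res, tau_max, convention=sp.get("convention", "continuous"))
                emit("survival.csv", pd.DataFrame(
                    {"tau_ps": curve.tau, "P": curve.P}))
                report["stages"]["survival"] = {
                    "tau_half_ps": curve.tau_half,
                    "convention": curve.convention}
            elif stage == "velocity":
                vp = config.velocity_params
                vel = dyn_mod.windowed_velocities(
                    traj, res, geom, window=vp.get("window", 10.0),
                    discard=vp.get("discard", window_start - traj.times[0]),
                    stride=vp.get("stride"))
                emit("velocities.csv", pd.DataFrame({
                    "particle_id": vel.particle_ids,
                    "t_start_ps": vel.t_start, "R_A": vel.R,
                    "theta_rad": vel.theta, "z_A": vel.z,
                    "vx": vel.velocity[:, 0], "vy": vel.velocity[:, 1],
                    "vz": vel.velocity[:, 2], "speed": vel.speed}))
                hist = dyn_mod.speed_distribution(vel)
                emit("speed_histogram.csv", pd.DataFrame(
                    {"edge_lo": hist.edges[:-1], "edge_hi": hist.edges[1:],
                     "probability": hist.probability}))
                report["stages"]["velocity"] = {
                    "n_samples": int(vel.n_samples),
                    "mean_speed_A_per_ps": float(vel.speed.mean())
                    if vel.n_samples else None,
                    "bin_rule": hist.rule}
            elif stage == "maps":
                mp = config.map_params
                for plane in mp.get("planes", ["XY", "XZ"]):
                    dmap = maps_mod.planar_heatmap(
                        traj, res, geom, plane,
                        bin_width=mp.get("bin_width", 0.25),
                        window_start=window_start)
                    xs = 0.5 * (dmap.x_edges[:-1] + dmap.x_edges[1:])
                    ys = 0.5 * (dmap.y_edges[:-1] + dmap.y_edges[1:])
                    gx, gy = np.meshgrid(xs, ys, indexing="ij")
                    emit(f"heatmap_{plane}.csv", pd.DataFrame(
                        {"bin_x": gx.ravel(), "bin_y": gy.ravel(),
                         "probability": dmap.probability.ravel()}))
                cyl = maps_mod.cylindrical_heatmap(
                    traj, res, geom, r_bins=mp.get("r_bins", 12),
                    theta_bins=mp.get("theta_bins", 24),
                    window_start=window_start)
                rs = 0.5 * (cyl.x_edges[:-1] + cyl.x_edges[1:])
                ts = 0.5 * (cyl.y_edges[:-1] + cyl.y_edges[1:])
                gr, gt = np.meshgrid(rs, ts, indexing="ij")
                emit("heatmap_Rtheta.csv", pd.DataFrame(
                    {"r_bin": gr.ravel(), "theta_bin": gt.ravel(),
                     "probability": cyl.probability.ravel()}))
                report["stages"]["maps"] = {
                    "planes": mp.get("planes", ["XY", "XZ"]) + ["R-theta"]}
            elif stage == "coordination":
                cp = config.coordination_params
                centers = cp.get("centers", config.tracked_group)
                contributors = cp.get("contributors")
                if not contributors:
                    raise ConfigurationError(
                        "coordination stage needs 'contributors'")
                cres = res if centers == config.tracked_group else \
                    classify_inside(traj, geom, centers)
                prof = coord_mod.rdf_decomposed(
                    traj, cres, centers, contributors,
                    r_max=cp.get("r_max", 10.0), dr=cp.get("dr", 0.1),
                    window_start=window_start)
                emit("rdf.csv", pd.DataFrame(
                    {"r_A": prof.r, **{f"g_{c}": prof.g[c]
                                       for c in contributors}}))
                shell = {}
                table_entry = {}
                for c in contributors:
                    try:
                        shell[c] = coord_mod.first_shell_radius(prof, c)
                    except ValueError:
                        shell[c] = cp.get("fallback_shell_radius", 3.5)
                table = coord_mod.coordination_numbers(
                    traj, cres, centers, contributors, shell,
                    window_start=window_start)
                emit("coordination.csv", pd.DataFrame(
                    [{"contributor": c, "mean": table.mean[c],
                      "sd": table.sd[c], "shell_radius_A": shell[c]}
                     for c in contributors]))
                report["stages"]["coordination"] = {
                    "mean": table.mean, "sd": table.sd,
                    "shell_radius_A": shell}
            elif stage == "hbonds":
                hp = config.hbond_params
                donors = [tuple(d) for d in hp.get("donors", [])]
                acceptors = list(hp.get("acceptors", []))
                crit = coord_mod.HBondCriteria(
                    **hp.get("criteria", {}))
                rows = []
                for f in range(traj.n_frames):
                    n, _ = coord_mod.count_hbonds(
                        traj.positions[f], donors, acceptors, crit)
                    rows.append((traj.times[f], n))
                df = pd.DataFrame(rows, columns=["time_ps", "count"])
                emit("hbonds.csv", df)
                report["stages"]["hbonds"] = {
                    "mean_count": float(df["count"].mean()),
                    "criteria": {"distance_cutoff": crit.distance_cutoff,
                                 "angle_cutoff": crit.angle_cutoff}}
        except Exception as exc:  # noqa: BLE001 — stage isolation contract
            report["stages"][stage] = {"error": f"{type(exc).__name__}: {exc}"}

    write_report(report, config.outdir)
    return report


def write_report(report: dict, outdir: str) -> str:
    """Write the machine-readable summary; idempotent for a given report."""
    if not report.get("stages"):
        raise ValueError("no completed stage to report")
    report = dict(report)
    report["files"] = sorted(set(report.get("files", [])))
    path = os.path.join(outdir, "report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return path
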