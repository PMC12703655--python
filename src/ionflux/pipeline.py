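"""End-to-end orchestration: config → geometry → occupancy → events → profiles → report.

A single run analyses either an existing topology+trajectory pair ("analyze"
mode) or synthetic kinetic-model trajectories over a voltage ladder
("generate" mode).  Reports are machine-readable: one JSON report plus TSV
tables, deterministic for a fixed config and seed (the config hash and seed
are recorded in the report; no timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .pore import PoreSpec, load_pore_spec, frame_geometry
from .occupancy import (aggregate_occupancy, assign_frame, assignments_to_frame,
                        encode_state, extract_particles, label_ca_bound,
                        particle_atoms)
from .permeation import compute_current, detect_events, rectification_ratio
from .profiles import axial_density, gate_distance
from .kinetics import KineticModelParams, simulate_trajectory

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline",
           "analyze_universe", "PipelineError"]

log = logging.getLogger("ionflux")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Validated run configuration (one YAML document)."""

    mode: str = "generate"                      # "generate" | "analyze"
    topology: str | None = None
    trajectory: str | None = None
    pore: dict = field(default_factory=dict)    # load_pore_spec config
    generator: dict = field(default_factory=dict)  # KineticModelParams overrides
    voltages_mV: list = field(default_factory=lambda: [-300.0, 0.0, 300.0])
    sim_time_ns: float | None = None            # analyze mode: total simulated time
    box_z: float | None = None                  # analyze mode: override box height
    profiles: dict = field(default_factory=dict)
    compute_profiles: bool = True
    compute_gate: bool = True
    compute_flexibility: bool = False
    out_dir: str | None = None
    write_trajectories: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        problems = validate_config(raw)
        if problems:
            raise PipelineError("config: " + "; ".join(problems))
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output paths excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        payload.pop("write_trajectories", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_KNOWN_KEYS = set(RunConfig.__dataclass_fields__)


def validate_config(config: Mapping[str, Any]) -> list[str]:
    """Return a list of problems (empty iff the config is runnable)."""
    problems: list[str] = []
    unknown = set(config) - _KNOWN_KEYS
    for key in sorted(unknown):
        problems.append(f"unknown key: {key}")
    mode = config.get("mode", "generate")
    if mode not in ("generate", "analyze"):
        problems.append(f"mode: must be 'generate' or 'analyze', got {mode!r}")
    if mode == "analyze":
        topology = config.get("topology")
        if not topology:
            problems.append("topology: required in analyze mode")
        elif not pathlib.Path(topology).exists():
            problems.append(f"topology: file not found: {topology}")
        trajectory = config.get("trajectory")
        if trajectory and not pathlib.Path(trajectory).exists():
            problems.append(f"trajectory: file not found: {trajectory}")
    else:
        voltages = config.get("voltages_mV", [-300.0, 0.0, 300.0])
        if not isinstance(voltages, (list, tuple)) or len(voltages) == 0:
            problems.append("voltages_mV: must be a non-empty list")
        elif len(set(map(float, voltages))) != len(voltages):
            problems.append("voltages_mV: duplicate voltage labels")
        gen = config.get("generator", {})
        if not isinstance(gen, Mapping):
            problems.append("generator: must be a mapping")
        else:
            bad = set(gen) - set(KineticModelParams.__dataclass_fields__)
            for key in sorted(bad):
                problems.append(f"generator.{key}: unknown generator parameter")
    seed = config.get("seed", 0)
    if not isinstance(seed, (int, np.integer)):
        problems.append("seed: must be an integer")
    return problems


@dataclass
class RunReport:
    """Machine-readable run report: occupancy, I–V, profiles, gate, provenance."""

    content: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.content, fh, sort_keys=True, indent=1)
            fh.write("\n")

    def write_tables(self, outdir) -> list[str]:
        """Render the report's tables as TSV files; returns written paths."""
        import pandas as pd

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        iv_rows = []
        for entry in self.content.get("voltages", []):
            v = entry["voltage_mV"]
            tag = f"{v:+.0f}mV".replace("+", "p").replace("-", "m")
            cur = entry.get("current", {})
            iv_rows.append({
                "voltage_mV": v,
                "n_out": cur.get("n_outward"),
                "n_in": cur.get("n_inward"),
                "current_pA": cur.get("current_pA"),
                "ca_f87_bound_fraction": entry.get("ca_f87_bound_fraction"),
            })
            states = entry.get("states")
            if states:
                path = outdir / f"states_{tag}.tsv"
                pd.DataFrame(states).to_csv(path, sep="\t", index=False)
                written.append(str(path))
            events = entry.get("events")
            if events:
                path = outdir / f"events_{tag}.tsv"
                pd.DataFrame(events).to_csv(path, sep="\t", index=False)
                written.append(str(path))
            gate = entry.get("gate", {})
            if "series" in gate:
                path = outdir / f"gate_{tag}.tsv"
                pd.DataFrame(gate["series"]).to_csv(path, sep="\t", index=False)
                written.append(str(path))
            flex = entry.get("flexibility", {})
            if "rmsf_per_residue" in flex:
                path = outdir / f"rmsf_{tag}.tsv"
                pd.DataFrame(flex["rmsf_per_residue"]).to_csv(path, sep="\t", index=False)
                written.append(str(path))
            prof = entry.get("profile")
            if prof:
                path = outdir / f"profile_{tag}.tsv"
                pd.DataFrame(prof).to_csv(path, sep="\t", index=False)
                written.append(str(path))
        if iv_rows:
            path = outdir / "iv.tsv"
            pd.DataFrame(iv_rows).to_csv(path, sep="\t", index=False)
            written.append(str(path))
        return written


def analyze_universe(u, spec: PoreSpec, voltage_mV: float,
                     box_z: float | None = None,
                     sim_time_ns: float | None = None,
                     profile_kwargs: Mapping | None = None,
                     compute_profiles: bool = True,
                     compute_gate: bool = True,
                     compute_flexibility: bool = False) -> dict:
    """Single-pass analysis of one trajectory at one voltage.

    Returns a dict with assignments, occupancy tables, permeation events,
    the current estimate and (optionally) density profile and gate metric.
    """
    atoms = particle_atoms(u, spec)
    if box_z is None:
        box_z = float(u.dimensions[2]) if u.dimensions is not None else 100.0

    assignments = []
    geoms = []
    permeant_ids = [int(a) for a, s in zip(atoms.ids, atoms.resnames)
                    if spec.species_of(s) in ("K", "NH4")]
    traces: dict[int, list[float]] = {pid: [] for pid in permeant_ids}
    species_by_id = {}
    for ts in u.trajectory:
        geom = frame_geometry(u, spec)
        parts = extract_particles(u, spec, atoms=atoms)
        assignments.append(assign_frame(parts, geom, spec))
        geoms.append(geom)
        z = geom.axial(parts.positions)
        for pid, sp, zz in zip(parts.ids, parts.species, z):
            pid = int(pid)
            if pid in traces:
                traces[pid].append(float(zz))
                species_by_id[pid] = str(sp)
    n_frames = len(assignments)
    if n_frames == 0:
        raise PipelineError("analysis: trajectory has no frames")

    labels = label_ca_bound(assignments)
    bound, free = aggregate_occupancy(assignments, labels, voltage_mV)
    traces_arr = {pid: np.asarray(v) for pid, v in traces.items()}
    events = detect_events(traces_arr, geoms, box_z, species=species_by_id)
    if sim_time_ns is None:
        sim_time_ns = float(n_frames)   # fallback: report per-frame units as ns
    current = compute_current(events, sim_time_ns, voltage_mV)

    out = {
        "assignments": assignments,
        "labels": labels,
        "tables": {"bound": bound, "free": free},
        "events": events,
        "current": current,
        "n_frames": n_frames,
    }
    if compute_profiles:
        out["profile"] = axial_density(u, spec, **dict(profile_kwargs or {}))
    if compute_gate:
        try:
            out["gate"] = gate_distance(u, spec)
        except ValueError as err:
            log.warning("gate metric skipped: %s", err)
    if compute_flexibility:
        import MDAnalysis as mda
        from .profiles import rmsd_rmsf

        u.trajectory[0]
        reference = mda.Merge(u.atoms)
        sf_resids = f"{spec.sf_resids[0]}-{spec.sf_resids[-1]}"
        out["flexibility"] = rmsd_rmsf(
            u, reference, selection="protein",
            fit_selection=f"protein and resid {sf_resids}")
    return out


def child_seed(seed: int, index: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all enabled stages and assemble the report.

    Deterministic given the seed and inputs; any stage error is re-raised as a
    :class:`PipelineError` tagged with the stage, and in file-writing mode a
    FAILED marker is left next to any partial outputs.
    """
    problems = validate_config({k: v for k, v in asdict(config).items()})
    if problems:
        raise PipelineError("config: " + "; ".join(problems))
    outdir = pathlib.Path(config.out_dir) if config.out_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    try:
        report = _run_stages(config, outdir)
    except Exception as err:
        if outdir:
            (outdir / "FAILED").write_text(str(err) + "\n")
        raise
    if outdir:
        report.to_json(outdir / "report.json")
        report.write_tables(outdir)
    return report


def _run_stages(config: RunConfig, outdir) -> RunReport:
    content: dict = {
        "ionflux_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "voltages": [],
    }
    if config.mode == "analyze":
        entries = [_analyze_entry(config)]
    else:
        entries = [
            _generate_entry(config, float(v), child_seed(config.seed, i), outdir)
            for i, v in enumerate(config.voltages_mV)
        ]
    content["voltages"] = entries

    # rectification ratios for matched ±V pairs
    by_v = {e["voltage_mV"]: e["current"]["current_pA"] for e in entries}
    rect = {}
    for v in sorted(by_v):
        if v > 0 and -v in by_v:
            r = rectification_ratio(by_v[v], by_v[-v])
            rect[f"{v:.0f}mV"] = None if np.isnan(r) else (
                "inf" if np.isinf(r) else r)
    content["rectification_ratio"] = rect
    return RunReport(content)


def _entry_from_analysis(analysis: dict, voltage_mV: float) -> dict:
    bound = analysis["tables"]["bound"]
    free = analysis["tables"]["free"]
    cur = analysis["current"]
    entry = {
        "voltage_mV": voltage_mV,
        "n_frames": analysis["n_frames"],
        "ca_f87_bound_fraction": float(np.mean(analysis["labels"])),
        "ca_e92_bound_fraction": float(np.mean(
            [a.ca_e92_bound for a in analysis["assignments"]])),
        "occupancy": {
            "ca_bound": _table_dict(bound),
            "ca_free": _table_dict(free),
        },
        "current": {
            "n_outward": cur.n_outward,
            "n_inward": cur.n_inward,
            "sim_time_ns": cur.sim_time_ns,
            "current_pA": cur.current_pA,
        },
        "states": assignments_to_frame(analysis["assignments"]).to_dict("list"),
        "events": [
            {"particle_id": e.particle_id, "species": e.species,
             "direction": e.direction, "entry_frame": e.entry_frame,
             "exit_frame": e.exit_frame}
            for e in analysis["events"]
        ],
    }
    if "profile" in analysis:
        entry["profile"] = analysis["profile"].to_frame().to_dict("list")
    if "gate" in analysis:
        gm = analysis["gate"]
        entry["gate"] = {
            "mean_diagonal": float(np.mean(gm.mean_per_frame)),
            "diagonal_ac_mean": float(np.mean(gm.diagonal_ac)),
            "diagonal_bd_mean": float(np.mean(gm.diagonal_bd)),
            "series": gm.to_frame().to_dict("list"),
        }
    if "flexibility" in analysis:
        fm = analysis["flexibility"]
        entry["flexibility"] = {
            "rmsd_mean": float(np.mean(fm.rmsd)),
            "rmsd_max": float(np.max(fm.rmsd)),
            "rmsf_per_residue": fm.rmsf_residues.to_dict("list"),
        }
    return entry


def _table_dict(table) -> dict:
    return {
        "n_frames": table.n_frames,
        "site_fractions": table.site_fractions,
        "state_frequencies": table.state_frequencies,
    }


def _analyze_entry(config: RunConfig) -> dict:
    import MDAnalysis as mda

    log.info("stage load: %s", config.topology)
    spec = load_pore_spec(config.topology, config.pore)
    u = mda.Universe(config.topology, *( [config.trajectory] if config.trajectory else [] ))
    voltage = float(config.voltages_mV[0]) if config.voltages_mV else 0.0
    log.info("stage analyze: %d frame(s) at %+.0f mV", len(u.trajectory), voltage)
    analysis = analyze_universe(
        u, spec, voltage, box_z=config.box_z, sim_time_ns=config.sim_time_ns,
        profile_kwargs=config.profiles, compute_profiles=config.compute_profiles,
        compute_gate=config.compute_gate,
        compute_flexibility=config.compute_flexibility,
    )
    return _entry_from_analysis(analysis, voltage)


def _generate_entry(config: RunConfig, voltage: float, seed: int, outdir) -> dict:
    log.info("stage generate: %+.0f mV (seed %d)", voltage, seed)
    params = KineticModelParams(**{**config.generator,
                                   "voltage_mV": voltage, "seed": seed})
    result = simulate_trajectory(params)
    u = result.to_universe()
    spec = PoreSpec(**config.pore) if config.pore else PoreSpec()
    log.info("stage analyze: %d frames, %d steps", len(u.trajectory),
             result.ground_truth.n_steps)
    analysis = analyze_universe(
        u, spec, voltage, box_z=params.box_z, sim_time_ns=params.duration_ns,
        profile_kwargs=config.profiles, compute_profiles=config.compute_profiles,
        compute_gate=config.compute_gate,
        compute_flexibility=config.compute_flexibility,
    )
    entry = _entry_from_analysis(analysis, voltage)
    gt = result.ground_truth
    entry["ground_truth"] = {
        "n_out": gt.n_out, "n_in": gt.n_in,
        "ca_f87_fraction": float(np.mean(gt.ca_f87)),
        "state_agreement": float(np.mean(
            [c == g for c, g in zip(
                [encode_state(a) for a in analysis["assignments"]], gt.state_codes)]
        )),
    }
    if config.write_trajectories and outdir is not None:
        result.write(pathlib.Path(outdir) / f"traj_{voltage:+.0f}mV")
    return entry
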