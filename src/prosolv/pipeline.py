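"""Config-driven orchestration of the full analysis battery.

A run takes either (structure, trajectory) input files or a synthetic
generator spec, executes hydrogen-bond census + bridging, residue contacts,
RMSD / radius of gyration, SISF + relaxation fits and the residue-cosolute
RDF/association map, and writes one CSV per stage plus a manifest that
echoes every criterion and seed (sufficient to re-run seeded stages
bit-identically).  Given three or more systems, the per-system observables
are correlated across systems.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, hbonds, structure_obs, synthetic
from .correlations import correlate_observables
from .md_io import read_structure, read_trajectory, classify_molecules, annotate_hbond_sites
from .synthetic import HBondSceneSpec, gen_toy_solution_trajectory, preset_composition


@dataclass
class RunConfig:
    """One system's inputs and analysis parameters."""

    name: str = "system"
    # exactly one of (structure+trajectory files) / generator preset
    structure: str | None = None
    trajectory: str | None = None
    generator: dict | None = None        # kwargs for the toy-solution generator
    seed: int = 0
    stride: int = 1
    hbond_distance: float = 0.35
    hbond_angle: float = 30.0
    contact_cutoff: float = 0.6
    contact_exclude_neighbours: int = 1
    q_values: tuple = dynamics.DEFAULT_Q_VALUES
    association_height: float = 1.0
    association_radius: float = 0.8
    rdf_bin_width: float = 0.02
    out_dir: str = "prosolv_out"

    def validate(self):
        has_files = self.structure is not None and self.trajectory is not None
        has_gen = self.generator is not None
        if has_files == has_gen:
            raise ValueError(
                "config needs exactly one of input files or a generator spec")

    @classmethod
    def from_toml(cls, path, **overrides) -> "RunConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _load_system(cfg: RunConfig):
    if cfg.generator is not None:
        gen = dict(cfg.generator)
        preset = gen.pop("preset", None)
        if preset:
            comp = preset_composition(preset)
            counts = comp.species_counts()
            # scale a published composition down to a desk-size toy system
            scale = gen.pop("scale", 0.01)
            counts = {k: (max(1, int(round(v * scale))) if v else 0)
                      for k, v in counts.items()}
        else:
            counts = gen.pop("counts", {"protein": 2, "water": 20,
                                        "disaccharide": 4})
        traj, ledger = gen_toy_solution_trajectory(counts, seed=cfg.seed, **gen)
        return traj, ledger
    topo, frame0 = read_structure(cfg.structure)
    classify_molecules(topo)
    traj = read_trajectory(cfg.trajectory, topo)
    if cfg.stride > 1:
        from .md_io import Trajectory
        traj = Trajectory(topo, traj.positions[::cfg.stride],
                          traj.times[::cfg.stride], traj.box,
                          unwrapped=None if traj.unwrapped is None
                          else traj.unwrapped[::cfg.stride])
    annotate_hbond_sites(topo, traj.frame(0))
    return traj, None


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    out_dir: Path
    tables: dict = field(default_factory=dict)
    observables: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig, log=sys.stderr) -> ReportBundle:
    """Run every analysis stage for one system and write the report CSVs."""
    cfg.validate()
    out = Path(cfg.out_dir) / cfg.name
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)
    bundle.manifest = {"config": asdict(cfg), "config_hash": _config_hash(cfg),
                       "seed": cfg.seed, "stages": {}}
    criterion = hbonds.HBondCriterion(cfg.hbond_distance, cfg.hbond_angle)
    param_block = {"hbond_distance_nm": cfg.hbond_distance,
                   "hbond_angle_deg": cfg.hbond_angle,
                   "contact_cutoff_nm": cfg.contact_cutoff,
                   "association_height": cfg.association_height,
                   "association_radius_nm": cfg.association_radius,
                   "seed": cfg.seed}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
            bundle.manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        except Exception as exc:      # noqa: BLE001 - recorded, not swallowed
            bundle.errors[name] = f"{type(exc).__name__}: {exc}"
            bundle.manifest["stages"][name] = {
                "status": "failed", "error": bundle.errors[name]}
            print(f"[prosolv:{cfg.name}] stage {name} failed: "
                  f"{bundle.errors[name]}", file=log)

    traj, ledger = _load_system(cfg)
    n_chains = max(len(traj.topology.chains()), 1)

    def save(name, df: pd.DataFrame):
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(param_block) + "\n")
            df.to_csv(fh)
        bundle.tables[name] = df

    def do_hbonds():
        cens = hbonds.census_trajectory(traj, criterion)
        save("hbond_census", cens.summary())
        save("hbond_series", cens.counts)
        frame_bonds = hbonds.find_hbonds(traj.frame(0), traj.topology, criterion)
        gc = hbonds.eq1_group_counts(frame_bonds, traj.topology)
        literal, variant = hbonds.bridging_eq1(gc)
        direct = hbonds.bridging_direct(frame_bonds, traj.topology)
        save("bridging", pd.DataFrame([{
            "eq1_literal_per_protein": literal,
            "eq1_difference_variant_per_protein": variant,
            "direct_bridges_per_protein": direct["per_protein"]}]))
        for cat in ("pp_intra", "pw", "ww", "dd", "dw", "pd"):
            bundle.observables[f"hb_{cat}"] = float(cens.mean[cat])
        bundle.observables["hb_bridging_direct"] = direct["per_protein"]
        bundle.observables["hb_bridging_eq1_variant"] = variant

    def do_contacts():
        cs = hbonds.contacts_summary(traj, cfg.contact_cutoff,
                                     cfg.contact_exclude_neighbours)
        save("contacts", pd.DataFrame(
            {"mean_contacts": cs["per_residue_mean"]}))
        bundle.observables["contacts_mean"] = cs["mean"]

    def do_rmsd():
        r = dynamics.rmsd_series(traj, selection="backbone")
        df = r.per_chain.copy()
        df["chain_average"] = r.chain_average
        df.index = traj.times
        save("rmsd", df)
        g = dynamics.gyration_series(traj)
        save("gyration", g)
        bundle.observables["rmsd_final"] = float(r.chain_average[-1])

    def do_sisf():
        table = dynamics.relaxation_times(traj, cfg.q_values)
        save("relaxation_times", table)
        for _, row in table.iterrows():
            bundle.observables[f"tau_q{row['q']:g}"] = float(row["tau_ps"])
        curves = []
        for q in cfg.q_values:
            c = dynamics.sisf(traj, q, selection="backbone")
            curves.append(pd.DataFrame(
                {"q": q, "lag_ps": c.lags, "F": c.F}))
        save("sisf_curves", pd.concat(curves, ignore_index=True))

    def do_rdf():
        rmap = structure_obs.com_rdf(traj, bin_width=cfg.rdf_bin_width,
                                     aggregate="position")
        structure_obs.export_colormap(rmap, out / "rdf_colormap.csv")
        assoc = structure_obs.associated_residues(
            rmap, cfg.association_height, cfg.association_radius)
        save("association", pd.DataFrame([{
            "height_threshold": assoc.height_threshold,
            "radius_threshold_nm": assoc.radius_threshold,
            "associated_residues": assoc.count}]))
        bundle.observables["associated_residues"] = assoc.count

    stage("hbonds", do_hbonds)
    stage("contacts", do_contacts)
    stage("rmsd_gyration", do_rmsd)
    stage("sisf", do_sisf)
    if traj.topology.molecule_count("disaccharide") > 0:
        stage("rdf", do_rdf)
    if ledger is not None:
        bundle.manifest["scene_ledger"] = {
            "b_star": ledger.b_star, "categories": ledger.category_counts}
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
    return bundle


def run_sweep(configs: list[RunConfig],
              pairs: list[tuple[str, str]] | None = None,
              log=sys.stderr) -> pd.DataFrame:
    """Run several systems and correlate observables across them (>=3)."""
    rows = {}
    for cfg in configs:
        bundle = run_pipeline(cfg, log=log)
        rows[cfg.name] = bundle.observables
    table = pd.DataFrame(rows).T
    if len(rows) >= 3 and pairs:
        corr = correlate_observables(table, pairs)
        base = Path(configs[0].out_dir)
        table.to_csv(base / "observables.csv")
        corr.to_csv(base / "correlations.csv", index=False)
        return corr
    return table
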