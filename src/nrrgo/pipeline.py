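"""Config-driven protocols chaining the pipeline stages
(build -> equilibrate / pull / replica-exchange -> analyze).

A :class:`RunConfig` comes from a YAML file (or a plain dict); every
command validates it, runs the stage through the library modules, writes
its outputs plus a fully resolved config and a manifest (seed, parameters,
package version) into the output directory, and returns the paths.  The
numbered scripts under ``analysis/`` are thin drivers over these commands.

Per-replicate seeds are spawned from the master seed by fixed arithmetic
(seed_k = (master + 1000003 * k) mod 2^31) and recorded in the manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .gomodel import (GoModelOptions, build_native_contacts,
                      assign_contact_energies, build_topology, CGTopology)
from .structure import (read_structure, SubdomainScheme, assign_subdomains,
                        detect_disulfides, detect_ion_coordination)
from .toys import ToySpec, make_toy_structure, make_two_domain_shielded
from .engine import run_equilibrium
from .pulling import (PullProtocol, run_smd, average_force_profile,
                      detect_force_peaks, unfolding_order)
from .remd import make_temperature_ladder, run_remd, wham_free_energy, melting_curve
from .observables import ContactSubsets, contact_fraction_series

logger = logging.getLogger("nrrgo.pipeline")

__all__ = ["RunConfig", "ConfigError", "load_config", "spawn_seed",
           "cmd_build", "cmd_equilibrate", "cmd_pull", "cmd_remd"]

CONFIG_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    structure: str                      # path to a PDB, or "toy:<kind>"
    outdir: str
    chain: str = "A"
    scheme: str | dict = "notch1_nrr"
    model: dict = field(default_factory=dict)       # GoModelOptions overrides
    protocol: dict = field(default_factory=dict)    # stage parameters
    seed: int = 1
    config_version: int = CONFIG_VERSION

    def resolved(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - {f for f in RunConfig.__dataclass_fields__}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        cfg = RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    if cfg.config_version != CONFIG_VERSION:
        raise ConfigError(f"unsupported config_version {cfg.config_version}")
    return cfg


def spawn_seed(master: int, k: int) -> int:
    return (int(master) + 1000003 * int(k)) % (2 ** 31)


def _scheme_of(cfg: RunConfig) -> SubdomainScheme | None:
    if cfg.scheme == "notch1_nrr":
        return SubdomainScheme.notch1_nrr()
    if cfg.scheme in (None, "none"):
        return None
    if isinstance(cfg.scheme, dict):
        return SubdomainScheme(primary={k: tuple(v) for k, v in
                                        cfg.scheme.get("primary", {}).items()},
                               secondary={k: tuple(v) for k, v in
                                          cfg.scheme.get("secondary", {}).items()})
    raise ConfigError(f"unknown scheme {cfg.scheme!r}")


def _load_structure(cfg: RunConfig):
    """Returns (ChainStructure, toy info dict or None)."""
    if cfg.structure.startswith("toy:"):
        kind = cfg.structure.split(":", 1)[1]
        spec = ToySpec(topology_kind=kind, seed=cfg.seed,
                       **cfg.protocol.get("toy_spec", {}))
        if kind == "two_domain_shielded":
            s, info = make_two_domain_shielded(spec)
            return s, info
        s, plan = make_toy_structure(spec)
        return s, {"contact_plan": plan}
    p = Path(cfg.structure)
    if not p.exists():
        raise ConfigError(f"structure file not found: {p}")
    return read_structure(p.read_text(), cfg.chain), None


def _build(cfg: RunConfig):
    s, info = _load_structure(cfg)
    try:
        opts = GoModelOptions(**cfg.model)
    except TypeError as exc:
        raise ConfigError(f"bad model options: {exc}") from None
    contacts = build_native_contacts(s, opts.heavy_cutoff, opts.hbond_no_cutoff,
                                     opts.hbond_min_angle)
    if info and info.get("contact_plan"):
        # designed toy well depths override statistical flavoring
        plan = {(min(i, j), max(i, j)): e for i, j, e in info["contact_plan"]}
        for c in contacts:
            key = (min(c.bead_i, c.bead_j), max(c.bead_i, c.bead_j))
            if key in plan:
                c.epsilon = plan[key]
    else:
        contacts = assign_contact_energies(
            contacts, s.sequence(), backbone_epsilon=opts.backbone_epsilon,
            baseline=opts.contact_baseline, ion_epsilon=opts.ion_epsilon)
    top = build_topology(s, contacts, opts)
    return s, top, info


def _manifest(cfg: RunConfig, outdir: Path, extra: dict):
    man = {"config": cfg.resolved(), "package_version": __version__}
    man.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(man, indent=1,
                                                     default=str))


def cmd_build(cfg: RunConfig) -> dict:
    """Build the topology; write topology JSON, contact-map TSV, subdomain
    label TSV and a build report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s, top, _info = _build(cfg)
    (outdir / "topology.json").write_text(top.to_json())
    top.contact_map_table().to_csv(outdir / "contact_map.tsv", sep="\t",
                                   index=False)
    scheme = _scheme_of(cfg)
    if scheme is not None:
        assign_subdomains(s, scheme).to_csv(outdir / "subdomains.tsv",
                                            sep="\t", index=False)
    opts = GoModelOptions(**cfg.model)
    report = {
        "n_residues": s.n_residues,
        "n_ions_in_file": len(s.ions),
        "n_ion_beads": int(top.metadata.get("n_ion_beads", 0)),
        "n_disulfides": len(detect_disulfides(s, opts.disulfide_cutoff)),
        "ion_sites": [
            {"ion_index": site.ion_index,
             "n_coordinators": len(site.coordinating_residues)}
            for site in detect_ion_coordination(s, opts.ion_coord_cutoff)],
        "n_contacts": len(top.contacts),
        "contacts_by_origin": top.contact_map_table()["origin"]
                                 .value_counts().to_dict(),
        "chain_break": top.chain_break,
    }
    (outdir / "build_report.json").write_text(json.dumps(report, indent=1))
    _manifest(cfg, outdir, {"stage": "build"})
    return {"topology": outdir / "topology.json",
            "report": report, "structure": s, "top": top}


def cmd_equilibrate(cfg: RunConfig) -> dict:
    """Equilibrium run + contact-fraction series and energy CSV."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _s, top, info = _build(cfg)
    prot = cfg.protocol
    traj = run_equilibrium(top, T=prot.get("temperature", 300.0),
                           n_steps=int(prot.get("n_steps", 100000)),
                           save_every=int(prot.get("save_every", 1000)),
                           seed=cfg.seed)
    subsets = (info or {}).get("subsets")
    qdf = contact_fraction_series(traj.frames, traj.times, top.contacts,
                                  top.author_resids, subsets)
    qdf.to_csv(outdir / "contact_fractions.csv", index=False)
    e = traj.metadata["energy_series"]
    edf_cols = ["angle", "dihedral", "contact", "repulsion", "restraint",
                "kinetic"]
    edf = {"time_ps": traj.times}
    edf.update({c: e[:, k] for k, c in enumerate(edf_cols)})
    import pandas as pd
    pd.DataFrame(edf).to_csv(outdir / "energies.csv", index=False)
    traj.write_xyz(outdir / "trajectory.xyz")
    _manifest(cfg, outdir, {"stage": "equilibrate"})
    return {"trajectory": traj, "contact_fractions": qdf, "top": top}


def cmd_pull(cfg: RunConfig) -> dict:
    """Replicated constant-velocity pulling: per-replicate CSVs, averaged
    profile TSV, peaks JSON and rupture-order JSON."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _s, top, info = _build(cfg)
    prot = dict(cfg.protocol)
    n_rep = int(prot.get("replicates", 10))
    if n_rep < 1:
        raise ConfigError("replicates must be >= 1")
    subsets = prot.get("subsets") or (info or {}).get("subsets")
    records = []
    seeds = [spawn_seed(cfg.seed, k) for k in range(n_rep)]
    for k, sd in enumerate(seeds):
        pp = PullProtocol(speed=float(prot.get("speed", 50.0)),
                          spring_k=float(prot.get("spring_k", 1.0)),
                          max_extension=float(prot.get("max_extension", 150.0)),
                          save_every=int(prot.get("save_every", 200)),
                          seed=sd)
        _traj, rec = run_smd(top, pp, T=float(prot.get("temperature", 300.0)),
                             subsets=subsets)
        rec.to_csv(outdir / f"pull_{k:03d}.csv", index=False)
        records.append(rec)
    profile = average_force_profile(records,
                                    bin_width=float(prot.get("bin_width", 1.0)),
                                    running_window=int(prot.get("running_window", 50)))
    profile.to_csv(outdir / "force_profile.tsv", sep="\t", index=False)
    peaks = detect_force_peaks(profile,
                               min_prominence=float(prot.get("min_prominence", 5.0)),
                               min_separation=float(prot.get("min_separation", 5.0)))
    (outdir / "peaks.json").write_text(json.dumps(
        [{"extension_A": e, "height_pN": h} for e, h in peaks], indent=1))
    order = None
    if subsets:
        order = unfolding_order(records)
        order.to_json(outdir / "unfolding_order.json", orient="records",
                      indent=1)
    _manifest(cfg, outdir, {"stage": "pull", "replicate_seeds": seeds})
    return {"records": records, "profile": profile, "peaks": peaks,
            "order": order, "top": top}


def cmd_remd(cfg: RunConfig) -> dict:
    """Replica exchange + WHAM: melting curve CSV, surface TSV, exchange
    log CSV."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _s, top, info = _build(cfg)
    prot = dict(cfg.protocol)
    lad = make_temperature_ladder(float(prot.get("t_min", 300.0)),
                                  float(prot.get("t_max", 400.0)),
                                  int(prot.get("n_replicas", 8)))
    run = run_remd(top, lad, cycle_ps=float(prot.get("cycle_ps", 10.0)),
                   n_cycles=int(prot.get("n_cycles", 100)), seed=cfg.seed)
    run.exchange_log.to_csv(outdir / "exchange_log.csv", index=False)
    out = {"run": run, "top": top}
    if int(prot.get("n_cycles", 100)) == 0:
        _manifest(cfg, outdir, {"stage": "remd", "note": "diagnostics only"})
        return out
    cs = ContactSubsets(top.contacts, top.author_resids,
                        (info or {}).get("subsets"))
    q = np.array([cs.fractions(c) for c in run.coords])
    q_total = np.array([d["Q_total"] for d in q])
    ncyc = int(run.records["cycle"].max()) + 1
    keep = (run.records["cycle"] >= int(0.2 * ncyc)).to_numpy()
    t_grid = np.linspace(lad.temperatures[0], lad.temperatures[-1], 101)
    curve, tm, tm_err = melting_curve(run.records["energy"].to_numpy()[keep],
                                      run.records["temperature"].to_numpy()[keep],
                                      q_total[keep], t_grid)
    curve.to_csv(outdir / "melting_curve.csv", index=False)
    surf_T = float(prot.get("surface_temperature", tm if np.isfinite(tm)
                            else lad.temperatures[len(lad) // 2]))
    qb = np.linspace(0, 1, int(prot.get("q_bins", 50)) + 1)
    surface = wham_free_energy(run, q_total, {"Q": qb}, target_T=surf_T)
    surface.to_table().to_csv(outdir / "free_energy_Q.tsv", sep="\t",
                              index=False)
    (outdir / "free_energy_Q.meta.json").write_text(json.dumps({
        "temperature_K": surface.temperature,
        "wham_iterations": surface.wham_iterations,
        "converged": surface.converged,
        "axes": {k: len(v) - 1 for k, v in surface.axes.items()},
    }, indent=1))
    _manifest(cfg, outdir, {"stage": "remd", "tm_K": tm, "tm_err_K": tm_err,
                            "acceptance": run.acceptance_rate()})
    out.update({"melting_curve": curve, "tm": tm, "tm_err": tm_err,
                "surface": surface})
    return out
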