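"""Config-driven orchestration of the full interface analysis.

One YAML config describes a study — crystal structure and chain roles, the
charged-contact watch list, trajectory replicas, nonbonded parameters, SPR /
KD(T) / DSC tables — and :func:`run_pipeline` runs every configured stage,
writing tidy CSV tables, JSON summaries and a log into the output directory.
Stages are skippable (absent config sections are skipped), failures abort
with a stage-named error while retaining partial outputs, and a rerun on the
same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import binding_kinetics as bk
from . import energetics as en
from . import structures as st
from . import trajectory as tr
from .errors import StageError, UsageError

__all__ = ["RunConfig", "run_pipeline", "STAGE_EXIT_CODES"]

logger = logging.getLogger("epistat")

#: Distinct process exit codes per failing stage (CLI contract).
STAGE_EXIT_CODES = {
    "contacts": 2, "trajectory": 3, "energetics": 4,
    "kinetics": 5, "vanthoff": 6, "dsc": 7,
}

#: Generic salt-bridge occupancy threshold (A) used when no crystal-derived
#: per-contact threshold applies (e.g. contacts absent from the crystal model).
GENERIC_THRESHOLD_A = 4.0


@dataclass
class RunConfig:
    """Validated pipeline configuration (paths resolved against the YAML's dir)."""

    output_dir: Path
    seed: int = 0
    structure: Path | None = None
    chain_roles: dict[str, str] = field(default_factory=dict)
    contacts: list[dict[str, Any]] = field(default_factory=list)
    cutoff: float = 4.5
    burn_in_ns: float | None = None
    dt_ns: float = tr.DEFAULT_DT_NS
    terminal_exclude: int = 5
    replicas: list[Path] = field(default_factory=list)
    energy: dict[str, Any] | None = None
    spr: Path | None = None
    kd_table: Path | None = None
    dsc: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def resolve(p):
            return (base / p).expanduser() if p is not None else None

        cfg = cls(
            output_dir=resolve(raw.get("output_dir", "epistat_out")),
            seed=int(raw.get("seed", 0)),
            structure=resolve(raw.get("structure")),
            chain_roles=dict(raw.get("chain_roles", {})),
            contacts=list(raw.get("contacts", [])),
            cutoff=float(raw.get("cutoff", 4.5)),
            burn_in_ns=(None if raw.get("burn_in_ns") is None
                        else float(raw["burn_in_ns"])),
            dt_ns=float(raw.get("dt_ns", tr.DEFAULT_DT_NS)),
            terminal_exclude=int(raw.get("terminal_exclude", 5)),
            replicas=[resolve(p) for p in raw.get("replicas", [])],
            energy=raw.get("energy"),
            spr=resolve(raw.get("spr")),
            kd_table=resolve(raw.get("kd_table")),
            dsc=resolve(raw.get("dsc")),
        )
        if cfg.energy and cfg.energy.get("params"):
            cfg.energy = dict(cfg.energy)
            cfg.energy["params"] = resolve(cfg.energy["params"])
        missing = [str(p) for p in
                   [cfg.structure, cfg.spr, cfg.kd_table, cfg.dsc,
                    *(cfg.replicas or []),
                    (cfg.energy or {}).get("params")]
                   if p is not None and not Path(p).exists()]
        if missing:
            raise UsageError(f"config references missing files: {missing}")
        return cfg

    def chain_of(self, role_or_chain: str) -> str:
        return self.chain_roles.get(role_or_chain, role_or_chain)


def _residue_key(cfg: RunConfig, model: st.StructureModel, spec: dict) -> st.ResidueKey:
    chain = cfg.chain_of(spec.get("role", spec.get("chain", "")))
    return model.find_residue(chain, int(spec["seq"]), str(spec.get("i_code", "")))


def _contact_definitions(cfg: RunConfig, model: st.StructureModel
                         ) -> list[st.ContactDefinition]:
    out = []
    for item in cfg.contacts:
        ka = _residue_key(cfg, model, item["a"])
        kb = _residue_key(cfg, model, item["b"])
        grp_a = st.DEFAULT_CHARGED_GROUPS[ka.res_name]
        grp_b = st.DEFAULT_CHARGED_GROUPS[kb.res_name]
        threshold = item.get("threshold")
        if threshold is None:
            # crystal-derived default: the representative-atom distance in the
            # reference structure is the occupancy threshold for that contact
            threshold = st.representative_distance(model, ka, kb)
        out.append(st.ContactDefinition(
            label=item.get("label", f"{ka}-{kb}"),
            res_a=ka, res_b=kb,
            atom_a=grp_a.representative_atom, atom_b=grp_b.representative_atom,
            threshold=float(threshold),
        ))
    return out


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


class _Stage:
    """Context manager that renames any failure to its stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, StageError):
            logger.error("stage %s: failed: %s", self.name, exc)
            raise StageError(self.name, str(exc)) from exc
        if exc is None:
            logger.info("stage %s: done", self.name)
        return False


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every configured stage; returns (and writes) the summary dict.

    Outputs land in ``config.output_dir``: per-stage CSV tables tagged with
    provenance (input file, convention, burn-in), stage JSON files, a
    ``summary.json`` and ``run.log``.  Partial outputs from completed stages
    survive a later stage's failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = logging.FileHandler(out / "run.log", mode="w")
    log_file.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(log_file)
    logger.setLevel(logging.INFO)

    summary: dict[str, Any] = {"seed": config.seed, "stages": []}
    try:
        model = None
        contacts: list[st.ContactDefinition] = []

        if config.structure is not None:
            with _Stage("contacts"):
                model = st.parse_pdb(config.structure)[0]
                contacts = _contact_definitions(config, model)
                if contacts:
                    table = st.contacts_to_frame(model, contacts)
                    table.insert(0, "source", str(config.structure))
                    table.to_csv(out / "contacts.csv", index=False)
                roles = config.chain_roles
                if {"antigen", "heavy", "light"} <= set(roles):
                    bridges = st.find_salt_bridges(
                        model, {roles["antigen"]}, {roles["heavy"], roles["light"]},
                        cutoff=config.cutoff)
                    pd.DataFrame([
                        dict(source=str(config.structure), label=b.label,
                             chain_a=b.res_a.chain_id, res_a=str(b.res_a),
                             chain_b=b.res_b.chain_id, res_b=str(b.res_b),
                             convention="representative",
                             distance_A=round(b.threshold, 3))
                        for b in bridges
                    ]).to_csv(out / "salt_bridges.csv", index=False)
                summary["stages"].append("contacts")
                summary["n_contacts"] = len(contacts)

        if config.replicas:
            with _Stage("trajectory"):
                roles = config.chain_roles
                trajs = [tr.load_trajectory_pdb(p, dt_ns=config.dt_ns)
                         for p in config.replicas]
                burn = (config.burn_in_ns if config.burn_in_ns is not None
                        else tr.default_burn_in(trajs[0]))
                ref = model if model is not None else trajs[0].topology

                lrmsd_rows, rmsd_rows, dist_rows = [], [], []
                occ_fracs: dict[str, list[float]] = {c.label: [] for c in contacts}
                lrmsd_stats = []
                for rep_i, (path, traj) in enumerate(zip(config.replicas, trajs), 1):
                    all_chains = traj.topology.chains()
                    mask_all = st.ca_mask(traj.topology, all_chains,
                                          config.terminal_exclude)
                    series = tr.rmsd_series(traj, mask_all, ref)
                    rmsd_rows.extend(
                        dict(source=str(path), replica=rep_i, time_ns=t, rmsd_A=v)
                        for t, v in series)
                    if {"antigen", "heavy", "light"} <= set(roles):
                        fit = st.ca_mask(traj.topology, [roles["antigen"]],
                                         config.terminal_exclude)
                        measure = st.ca_mask(traj.topology,
                                             [roles["heavy"], roles["light"]],
                                             config.terminal_exclude)
                        lr = tr.lrmsd_series(traj, fit, measure, ref)
                        lrmsd_stats.append((lr.mean, lr.sd))
                        lrmsd_rows.extend(
                            dict(source=str(path), replica=rep_i, time_ns=t,
                                 lrmsd_A=v)
                            for t, v in lr.series)
                    for contact in contacts:
                        ds = tr.distance_series(traj, contact)
                        dist_rows.extend(
                            dict(source=str(path), replica=rep_i,
                                 label=contact.label, convention="representative",
                                 time_ns=t, distance_A=v)
                            for t, v in ds)
                        occ_fracs[contact.label].append(
                            tr.contact_occupancy(ds, contact.threshold, burn))

                pd.DataFrame(rmsd_rows).to_csv(out / "rmsd.csv", index=False)
                if lrmsd_rows:
                    pd.DataFrame(lrmsd_rows).to_csv(out / "lrmsd.csv", index=False)
                if dist_rows:
                    pd.DataFrame(dist_rows).to_csv(out / "distances.csv", index=False)

                occ_payload = []
                for contact in contacts:
                    osum = tr.occupancy_summary(contact.label,
                                                occ_fracs[contact.label], burn)
                    occ_payload.append(dict(
                        contact=contact.label, threshold_A=contact.threshold,
                        convention="representative", burn_in_ns=burn,
                        runs=len(osum.per_replica_fraction),
                        fractions=osum.per_replica_fraction,
                        mean=osum.mean, sd=osum.sd, se=osum.se))
                _write_json(out / "occupancy.json", {"contacts": occ_payload})
                if occ_payload:
                    pd.DataFrame(occ_payload).drop(columns=["fractions"]).to_csv(
                        out / "occupancy.csv", index=False)
                summary["stages"].append("trajectory")
                summary["burn_in_ns"] = burn
                if lrmsd_stats:
                    summary["lrmsd_mean_A"] = [m for m, _ in lrmsd_stats]

        if config.energy and config.replicas:
            with _Stage("energetics"):
                params = en.NonbondedParams.from_csv(config.energy["params"])
                partner = [config.chain_of(r)
                           for r in config.energy.get("partner_roles",
                                                      ["heavy", "light"])]
                cutoff = float(config.energy.get("cutoff_A", en.DEFAULT_CUTOFF_A))
                burn = summary.get("burn_in_ns", config.burn_in_ns or 0.0)
                trajs = [tr.load_trajectory_pdb(p, dt_ns=config.dt_ns)
                         for p in config.replicas]
                breakdowns = []
                for res_spec in config.energy.get("residues", []):
                    key = _residue_key(config, trajs[0].topology, res_spec)
                    per_rep = [en.residue_interaction_energy(
                        t, params, key, partner, cutoff=cutoff, burn_in=burn)
                        for t in trajs]
                    breakdowns.append(en.aggregate_replicas(per_rep))
                table = en.energies_to_frame(breakdowns)
                table.insert(0, "source", str(config.energy["params"]))
                table.insert(1, "burn_in_ns", burn)
                table.to_csv(out / "energies.csv", index=False)
                summary["stages"].append("energetics")

        if config.spr is not None:
            with _Stage("kinetics"):
                panel = bk.read_sensorgram_csv(config.spr)
                fit = bk.fit_kinetics_global(panel)
                payload = dict(source=str(config.spr),
                               kon_per_M_s=fit.kon, koff_per_s=fit.koff,
                               rmax_RU=fit.rmax, kd_M=fit.kd, kd_nM=fit.kd * 1e9,
                               kon_sd=fit.kon_sd, koff_sd=fit.koff_sd,
                               rmax_sd=fit.rmax_sd, kd_sd_M=fit.kd_sd,
                               rss=fit.rss, n_points=fit.n_points,
                               warnings=fit.warnings,
                               rms_residual_by_conc=fit.residuals_by_conc)
                _write_json(out / "kinetics.json", payload)
                summary["stages"].append("kinetics")
                summary["kd_nM"] = fit.kd * 1e9

        if config.kd_table is not None:
            with _Stage("vanthoff"):
                pairs = bk.read_kd_table_csv(config.kd_table)
                fit = bk.vant_hoff_fit(pairs)
                dg, dg_sd = bk.delta_g_propagated(fit)
                payload = dict(source=str(config.kd_table),
                               dH_kJmol=fit.dh, dS_kJmolK=fit.ds,
                               dH_sd=fit.dh_sd, dS_sd=fit.ds_sd,
                               cov_dH_dS=fit.cov_dh_ds,
                               ref_T_K=fit.ref_temperature,
                               dG_kJmol=dg, dG_sd=dg_sd, n=fit.n_points)
                _write_json(out / "vanthoff.json", payload)
                summary["stages"].append("vanthoff")
                summary["dG_kJmol"] = dg

        if config.dsc is not None:
            with _Stage("dsc"):
                t_c, cp = bk.read_thermogram_csv(config.dsc)
                result = bk.tm_app(t_c, cp)
                payload = dict(source=str(config.dsc), tm_app_C=result.tm_app,
                               cp_max=result.cp_max, multi_peak=result.multi_peak)
                _write_json(out / "dsc.json", payload)
                summary["stages"].append("dsc")
                summary["tm_app_C"] = result.tm_app

        _write_json(out / "summary.json", summary)
        return summary
    finally:
        logger.removeHandler(log_file)
        log_file.close()
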