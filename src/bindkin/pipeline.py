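"""Config-driven orchestration: synthetic generation → fits → reports.

A single YAML (or dict) config drives an end-to-end run per compound:
radioligand assay generation-or-loading and fitting (Kd, k_on, t_1/2, K_i),
unbinding-time pooling and Poisson fitting (calculated t_1/2), and optional
toy biased-sampling stages (reweighted PMF minimum, contact fingerprint,
pose clusters). Every stage threshold is a named config key with the
field-standard default (4.5 Å contact cutoff, 50% persistence, 2.0 Å pose
RMSD, 10 Å unbound z). Reports are deterministic given the config seeds.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import assays as ak
from . import contacts as ca
from . import reweight as rw
from . import unbinding as ub
from .synthetic import (AssayParams, LangevinMetadSpec, ToySystemSpec,
                        gen_assay, gen_toy_complex_trajectory,
                        gen_unbinding_times, run_langevin_metad)
from .units import LN2, kT as thermal_kT

DEFAULT_THRESHOLDS = {
    "contact_cutoff": 4.5,     # Å
    "min_freq": 0.5,           # persistence filter
    "rmsd_threshold": 2.0,     # Å, pose clustering
    "z_threshold": 10.0,       # Å, unbound criterion
}


def subseed(seed: int, *keys) -> int:
    """Stable derived seed (< 2^31) for a named pipeline stage."""
    tag = ":".join(str(k) for k in keys).encode()
    return (int(seed) ^ zlib.crc32(tag)) % (2 ** 31 - 1)


@dataclass
class RunConfig:
    """Validated run configuration (see package docs for the YAML schema)."""

    compounds: Dict[str, dict]
    seed: int = 0
    temperature: float = 310.0
    outdir: Optional[str] = None
    thresholds: Dict[str, float] = dfield(default_factory=dict)
    reference_compound: Optional[str] = None
    toy_metad: Optional[dict] = None       # LangevinMetadSpec overrides
    toy_complex: Optional[dict] = None     # ToySystemSpec overrides

    def __post_init__(self):
        self.thresholds = {**DEFAULT_THRESHOLDS, **(self.thresholds or {})}
        for k, v in self.thresholds.items():
            if v <= 0:
                raise ValueError(f"threshold {k} must be positive")
        if not self.compounds:
            raise ValueError("config lists no compounds")
        for name, spec in self.compounds.items():
            for key in ("assays", "unbinding"):
                src = spec.get(key)
                if isinstance(src, dict):
                    for p in src.get("paths", {}).values():
                        if not Path(p).exists():
                            raise FileNotFoundError(
                                f"{name}.{key}: missing input file {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class CompoundReport:
    """Per-compound results; every numeric field carries units in its name."""

    name: str
    fits: dict = dfield(default_factory=dict)
    calc: dict = dfield(default_factory=dict)
    failures: list = dfield(default_factory=list)

    def to_dict(self) -> dict:
        return {"name": self.name, "fits": self.fits, "calc": self.calc,
                "failures": self.failures}


def _truth_params(name: str, spec: dict, mode: str, seed: int,
                  noise_cv: float) -> AssayParams:
    truth = spec.get("truth", {})
    kw = dict(mode=mode, noise_cv=noise_cv, seed=seed)
    if "Kd" in truth:
        kw["Kd"] = truth["Kd"]
    if "Bmax" in truth:
        kw["Bmax"] = truth["Bmax"]
    if "kon" in truth:
        kw["kon"] = truth["kon"]
    if "t_half_min" in truth:
        kw["koff"] = LN2 / truth["t_half_min"]
    if "Ki_naloxone" in truth:
        kw["Ki"] = truth["Ki_naloxone"]
    if "radioligand_conc" in truth:
        kw["radioligand_conc"] = truth["radioligand_conc"]
    return AssayParams(**kw)


def _run_assays(name: str, spec: dict, cfg: RunConfig, report: CompoundReport):
    src = spec.get("assays")
    if src is None:
        report.failures.append("assays: no input configured")
        return
    noise_cv = (src.get("noise_cv", 0.05) if isinstance(src, dict) else 0.05)
    tables = {}
    if isinstance(src, dict) and "paths" in src:
        for mode, path in src["paths"].items():
            tables[mode] = ak.AssayTable.from_csv(
                path, meta=src.get("meta", {}))
    else:
        for mode in ("saturation", "association", "dissociation",
                     "competition"):
            params = _truth_params(name, spec, mode,
                                   subseed(cfg.seed, name, mode), noise_cv)
            tables[mode] = gen_assay(params)

    sat = diss = None
    if "saturation" in tables:
        try:
            sat = ak.fit_saturation(tables["saturation"])
            report.fits["Kd_nM"] = sat.Kd
            report.fits["Kd_se"] = sat.Kd_se
            report.fits["Bmax_cpm"] = sat.Bmax
        except Exception as exc:
            report.failures.append(f"saturation: {exc}")
    if "dissociation" in tables:
        try:
            diss = ak.fit_dissociation(tables["dissociation"])
            if diss.ok:
                report.fits["koff_per_min"] = diss.koff
                report.fits["t_half_min"] = diss.t_half
                report.fits["t_half_se"] = diss.t_half_se
            else:
                report.failures.append(f"dissociation: {diss.message}")
        except Exception as exc:
            report.failures.append(f"dissociation: {exc}")
    if "association" in tables:
        try:
            koff = diss.koff if diss is not None and diss.ok else 0.0
            assoc = ak.fit_association(tables["association"], koff=koff)
            report.fits["kon_per_nM_min"] = assoc.kon
            report.fits["kon_se"] = assoc.kon_se
        except Exception as exc:
            report.failures.append(f"association: {exc}")
    if "competition" in tables:
        try:
            table = tables["competition"]
            Kd = sat.Kd if sat is not None else \
                spec.get("truth", {}).get("Kd")
            L = table.meta.get("radioligand_conc")
            comp = ak.fit_competition_ki(table, Kd_radioligand=Kd, L=L)
            if comp.ok:
                report.fits["Ki_naloxone_nM"] = comp.Ki
                report.fits["Ki_se"] = comp.Ki_se
            else:
                report.failures.append(f"competition: {comp.message}")
        except Exception as exc:
            report.failures.append(f"competition: {exc}")


def _run_unbinding(name: str, spec: dict, cfg: RunConfig,
                   report: CompoundReport):
    src = spec.get("unbinding")
    if src is None:
        report.calc["calc_t_half_s"] = None
        return
    try:
        if isinstance(src, dict) and "paths" in src:
            from .colvar import ColvarSeries
            traces = [ColvarSeries.read(p) for p in src["paths"].values()]
            times = ub.unbinding_times_from_traces(
                traces, z_threshold=cfg.thresholds["z_threshold"])
        elif isinstance(src, dict) and "times_file" in src:
            times = np.loadtxt(src["times_file"], ndmin=1)
        else:
            n = (src.get("n", 15) if isinstance(src, dict) else 15)
            truth = spec.get("truth", {})
            t_half = truth.get("calc_t_half_s")
            if t_half is None:
                report.failures.append("unbinding: no calc_t_half_s truth")
                return
            times = gen_unbinding_times(t_half / LN2, n,
                                        subseed(cfg.seed, name, "unbind"))
        fit = ub.fit_poisson_mle(times, seed=subseed(cfg.seed, name, "pboot"))
        report.calc.update({
            "calc_t_half_s": fit.t_half, "calc_tau_s": fit.tau,
            "calc_t_half_se": fit.se, "calc_t_half_ci": list(fit.ci),
            "ks_p": fit.ks_p, "n_trajectories": fit.n})
    except Exception as exc:
        report.failures.append(f"unbinding: {exc}")


def _run_toy_simulation_stages(cfg: RunConfig, shared: dict):
    if cfg.toy_metad is not None:
        kw = dict(cfg.toy_metad)
        kw.setdefault("seed", subseed(cfg.seed, "metad"))
        series = run_langevin_metad(LangevinMetadSpec(**kw))
        burn = len(series) // 5
        w = rw.compute_frame_weights(series)
        kT = thermal_kT(series.temperature)
        sub = slice(burn, None)
        ws = w[sub] / w[sub].sum()
        pmf = rw.reweighted_pmf(series.cv1[sub], ws,
                                np.linspace(-2.0, 2.0, 41), kT)
        smin = rw.locate_minimum(pmf)
        shared["toy_metad"] = {
            "pmf_min_cv": smin[0],
            "n_frames": len(series),
            "first_crossing_time_ns": series.meta["first_crossing_time_ns"]}
        shared["_toy_metad_series"] = series
        shared["_toy_metad_pmf"] = pmf
    if cfg.toy_complex is not None:
        kw = dict(cfg.toy_complex)
        kw.setdefault("seed", subseed(cfg.seed, "complex"))
        topo, traj = gen_toy_complex_trajectory(ToySystemSpec(**kw))
        cutoff = cfg.thresholds["contact_cutoff"]
        total = ca.contact_series(traj, topo, cutoff)
        prof = ca.residue_contact_frequency(traj, topo, cutoff)
        persistent = prof.filtered(cfg.thresholds["min_freq"])
        clusters = ca.cluster_poses(traj, topo,
                                    cfg.thresholds["rmsd_threshold"])
        shared["toy_complex"] = {
            "mean_total_contacts": float(total.counts.mean()),
            "persistent_residues_bw": sorted(
                prof.bw_labels.get(r, str(r)) for r in persistent),
            "n_pose_clusters": len(clusters),
            "largest_cluster_size": clusters[0].size}


def run_config(config: RunConfig) -> dict:
    """Execute all configured stages; returns {compound: CompoundReport}
    plus a "_shared" entry for compound-independent toy stages.

    Stage failures are collected per compound (partial reports), never
    raised, so one bad input cannot void the whole run.
    """
    reports: Dict[str, CompoundReport] = {}
    shared: dict = {}
    _run_toy_simulation_stages(config, shared)
    for name, spec in config.compounds.items():
        rep = CompoundReport(name=name)
        _run_assays(name, spec, config, rep)
        _run_unbinding(name, spec, config, rep)
        reports[name] = rep
    if config.reference_compound:
        table = compare_compounds(reports, config.reference_compound)
        shared["fold_ratios_vs_" + config.reference_compound] = table
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {n: r.to_dict() for n, r in reports.items()}
        payload["_shared"] = {k: v for k, v in shared.items()
                              if not k.startswith("_")}
        (out / "report.json").write_text(
            json.dumps(payload, sort_keys=True, indent=2, allow_nan=True)
            + "\n")
    reports["_shared"] = shared
    return reports


def compare_compounds(reports: dict, reference: str,
                      fields=("Ki_naloxone_nM", "t_half_min"),
                      decimals: int = 1) -> dict:
    """Fold ratios of selected quantities vs a reference compound.

    Accepts either pipeline reports or plain {compound: {field: value}}
    mappings (e.g. published constants). Ratios are only computed when both
    operands are present.
    """
    def get(entry, f):
        if isinstance(entry, CompoundReport):
            return entry.fits.get(f, entry.calc.get(f))
        return entry.get(f)

    names = [n for n in reports if not n.startswith("_")]
    if reference not in names:
        raise KeyError(f"reference compound {reference!r} not in reports")
    out: Dict[str, dict] = {}
    for name in names:
        row = {}
        for f in fields:
            num = get(reports[name], f)
            den = get(reports[reference], f)
            if num is not None and den not in (None, 0):
                row[f] = ak.fold_ratio(num, den, decimals)
        out[name] = row
    return out
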