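"""Pipeline orchestration: run every analysis stage over one or more
structures and emit a consolidated, reproducible comparison report.

The report is plain data (JSON + TSV): per structure the fingerprint counts
by category, metal sites and channel volumes; per configured pair the
refined RMSD/identity and, when domains are configured, the mobile-domain
rotation.  Every threshold used is echoed into the report so a regenerated
run is identical up to timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .channels import annotate_channels, channel_volumes
from .conformation import domain_rotation
from .domain_model import DomainMap, default_domain_map, load_domain_map
from .fingerprint import build_fingerprint, fingerprint_table
from .metal_sites import assign_site_labels, find_metal_sites, site_report
from .structure_io import read_structure, select

logger = logging.getLogger("polprofiler")

_KNOWN_KEYS = {"inputs", "pairs", "rotations", "domain_map", "output_dir",
               "seed", "log_level", "thresholds", "stages"}
_KNOWN_THRESHOLDS = {"hbond_min", "hbond_strong", "hbond_max",
                     "metal_cutoff", "probe_big", "probe_small",
                     "grid_spacing", "min_channel_volume",
                     "outlier_cutoff_rms", "outlier_cycles"}

DEFAULT_THRESHOLDS = {
    "hbond_min": 2.2, "hbond_strong": 3.2, "hbond_max": 4.0,
    "metal_cutoff": 2.6, "probe_big": 7.0, "probe_small": 2.7,
    "grid_spacing": 0.5, "min_channel_volume": 100.0,
    "outlier_cutoff_rms": 2.0, "outlier_cycles": 5,
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    inputs: list[str]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    rotations: list[dict] = field(default_factory=list)
    domain_map: str | None = None
    output_dir: str = "polprofiler_out"
    seed: int = 0
    log_level: str = "INFO"
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    stages: list[str] = field(
        default_factory=lambda: ["fingerprint", "metals", "channels"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        inputs = data.get("inputs") or []
        if not inputs:
            raise ConfigError("config must list at least one input")
        thresholds = dict(DEFAULT_THRESHOLDS)
        extra = data.get("thresholds") or {}
        bad = set(extra) - _KNOWN_THRESHOLDS
        if bad:
            raise ConfigError(f"unknown thresholds: {sorted(bad)}")
        thresholds.update(extra)
        return cls(
            inputs=[str(p) for p in inputs],
            pairs=[tuple(p) for p in data.get("pairs") or []],
            rotations=list(data.get("rotations") or []),
            domain_map=data.get("domain_map"),
            output_dir=str(data.get("output_dir", "polprofiler_out")),
            seed=int(data.get("seed", 0)),
            log_level=str(data.get("log_level", "INFO")),
            thresholds=thresholds,
            stages=list(data.get("stages",
                                 ["fingerprint", "metals", "channels"])),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, write: bool = True) -> dict:
    """Execute all configured stages; collect per-stage failures.

    The pipeline fails only if every stage fails for an input.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    dmap = (load_domain_map(cfg.domain_map) if cfg.domain_map
            else default_domain_map())
    th = cfg.thresholds
    report: dict = {
        "metadata": {
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "thresholds": th,
            "seed": cfg.seed,
            "domain_ranges": dmap.ranges,
        },
        "structures": {},
        "pairs": [],
        "rotations": [],
        "warnings": [],
    }
    structures = {}
    for path in cfg.inputs:
        s = read_structure(path)
        structures[path] = s
        block: dict = {"summary": {
            "id": s.id, "n_residues": len(s.residues),
            "n_atoms": s.n_atoms, "entity_counts": s.entity_counts()}}
        failures = 0
        if "fingerprint" in cfg.stages:
            try:
                fp = build_fingerprint(s, dmap, require_positions=False)
                by_class: dict[str, int] = {}
                for rec in fp.records:
                    by_class[rec.bond.klass] = \
                        by_class.get(rec.bond.klass, 0) + 1
                block["fingerprint"] = {
                    "n_records": len(fp.records),
                    "by_class": by_class,
                    "n_stacking": len(fp.stacking),
                    "n_clashes": len(fp.clashes),
                }
                if write:
                    table = fingerprint_table(fp)
                    outdir = Path(cfg.output_dir)
                    outdir.mkdir(parents=True, exist_ok=True)
                    table.to_csv(outdir / f"{Path(path).stem}_records.tsv",
                                 sep="\t", index=False)
            except Exception as exc:
                failures += 1
                report["warnings"].append(f"{path}: fingerprint: {exc}")
        if "metals" in cfg.stages:
            try:
                sites = assign_site_labels(
                    find_metal_sites(s, cutoff=th["metal_cutoff"]), s)
                block["metal_sites"] = site_report(sites)
            except Exception as exc:
                failures += 1
                report["warnings"].append(f"{path}: metals: {exc}")
        if "channels" in cfg.stages:
            try:
                atoms = select(s, "entity=protein")
                if len(atoms) == 0:
                    atoms = select(s, "not entity=water")
                cs = channel_volumes(
                    atoms, r_big=th["probe_big"], r_small=th["probe_small"],
                    spacing=th["grid_spacing"],
                    min_volume=th["min_channel_volume"])
                annotate_channels(cs, s)
                block["channels"] = {
                    "probe_radii": [th["probe_big"], th["probe_small"]],
                    "spacing": th["grid_spacing"],
                    "volumes": cs.volumes(),
                    "components": [{
                        "volume": round(c.volume, 1),
                        "min_dist_dna": c.min_dist_dna,
                        "min_dist_dntp": c.min_dist_dntp,
                        "outer": c.outer,
                    } for c in cs.channels],
                }
            except Exception as exc:
                failures += 1
                report["warnings"].append(f"{path}: channels: {exc}")
        if failures and failures == len(cfg.stages):
            raise RuntimeError(f"all stages failed for {path}")
        report["structures"][path] = block

    from .superpose import pair_calpha, refine_superposition
    for pa, pb in cfg.pairs:
        pairs = pair_calpha(structures[pa], structures[pb])
        fit = refine_superposition(pairs,
                                   cutoff_rms=th["outlier_cutoff_rms"],
                                   cycles=th["outlier_cycles"])
        report["pairs"].append({
            "a": pa, "b": pb, "rmsd": round(fit.rmsd, 3),
            "n_pairs": fit.n_pairs_final,
            "n_pairs_initial": fit.n_pairs_initial,
            "identity": round(fit.identity or 0.0, 4),
        })
    for rot in cfg.rotations:
        rep = domain_rotation(structures[rot["open"]],
                              structures[rot["closed"]], dmap,
                              mobile=rot.get("mobile", "finger"))
        report["rotations"].append({
            "open": rot["open"], "closed": rot["closed"],
            "mobile": rot.get("mobile", "finger"),
            "angle_deg": round(rep.angle, 2),
            "core_rmsd": round(rep.core_rmsd, 3),
        })
    if write:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=str))
    return report
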