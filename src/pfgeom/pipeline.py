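"""Orchestration: run the full complex analysis from one config.

A YAML (or dict) config names the structure file, maps chain roles
(kinesin / alpha1 / beta1 / alpha2 / beta2 / darpin) to chain ids, lists
motif residue ranges and comparator structures, and sets superposition /
SASA / SAXS parameters.  :func:`analyze_complex` runs every configured
stage — curvature profile, neck burial, KVD contacts, motif RMSDs, helix
rotation, SAXS validation — and returns a JSON-serializable
:class:`AnalysisReport`; stage failures are recorded per stage without
aborting the rest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .curvature import (
    ProtofilamentModel,
    SubunitModel,
    curvature_profile,
    helix_rotation,
    motif_rmsd,
)
from .interface import buried_area, contacts
from .saxs import (
    chi_square,
    debye_profile,
    guinier_fit,
    pair_distribution,
    radius_of_gyration,
    read_dat,
)
from .structio import Selection, Structure, read_structure

__all__ = ["AnalysisConfig", "AnalysisReport", "analyze_complex", "load_config"]

TUBULIN_ROLES = ("alpha1", "beta1", "alpha2", "beta2")


def _as_ranges(raw: Any) -> list[tuple[int, int]] | None:
    if raw is None:
        return None
    out = []
    for pair in raw:
        start, end = int(pair[0]), int(pair[1])
        out.append((start, end))
    return out


@dataclass
class AnalysisConfig:
    """Validated analysis configuration (see ``load_config`` for the YAML
    schema; any stage whose inputs are absent is skipped)."""

    structure_path: str
    chain_roles: dict[str, str]  # role -> chain id
    motifs: dict[str, dict[str, Any]] = field(default_factory=dict)
    comparators: list[dict[str, Any]] = field(default_factory=list)
    helix_comparison: dict[str, Any] | None = None
    interface_groups: dict[str, Any] | None = None
    superpose: dict[str, float] = field(default_factory=lambda: {
        "max_cycles": 5, "reject_factor": 2.0})
    sasa: dict[str, float] = field(default_factory=lambda: {
        "probe_radius": 1.4, "n_points": 960})
    saxs: dict[str, Any] | None = None
    output_dir: str = "."
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "structure_path": self.structure_path,
            "chain_roles": self.chain_roles,
            "motifs": self.motifs,
            "comparators": self.comparators,
            "helix_comparison": self.helix_comparison,
            "interface_groups": self.interface_groups,
            "superpose": self.superpose,
            "sasa": self.sasa,
            "saxs": self.saxs,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }


def load_config(path: str | Path) -> AnalysisConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return AnalysisConfig(
        structure_path=raw["structure_path"],
        chain_roles=dict(raw.get("chain_roles", {})),
        motifs=dict(raw.get("motifs", {})),
        comparators=list(raw.get("comparators", [])),
        helix_comparison=raw.get("helix_comparison"),
        interface_groups=raw.get("interface_groups"),
        superpose=dict(raw.get("superpose", {"max_cycles": 5, "reject_factor": 2.0})),
        sasa=dict(raw.get("sasa", {"probe_radius": 1.4, "n_points": 960})),
        saxs=raw.get("saxs"),
        output_dir=str(raw.get("output_dir", ".")),
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class AnalysisReport:
    """Machine-readable results of one full analysis run."""

    schema_version: str = "1"
    bend_reports: list[dict] = field(default_factory=list)
    interface_reports: dict[str, dict] = field(default_factory=dict)
    motif_comparisons: dict[str, dict] = field(default_factory=dict)
    helix_rotations: dict[str, float] = field(default_factory=dict)
    saxs_fits: dict[str, Any] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.__dict__, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _selection_from(cfg: dict[str, Any], default_chain: str | None = None) -> Selection:
    return Selection(
        chain_id=cfg.get("chain", default_chain),
        residue_ranges=_as_ranges(cfg.get("ranges")),
        atom_names=tuple(cfg["atoms"]) if cfg.get("atoms") else None,
    )


def _build_protofilament(config: AnalysisConfig) -> ProtofilamentModel:
    subunits = []
    for role in TUBULIN_ROLES:
        if role not in config.chain_roles:
            raise ValueError(f"chain role {role!r} missing from config")
        chain_id = config.chain_roles[role]
        core = config.motifs.get(f"{role}_core")
        sel = (_selection_from(core, chain_id) if core
               else Selection(chain_id, None, atom_names=("CA",)))
        subunits.append(SubunitModel(role=role.rstrip("12"), chain_id=chain_id,
                                     core_selection=sel))
    return ProtofilamentModel(subunits)


def analyze_complex(config: AnalysisConfig) -> AnalysisReport:
    """Run every configured stage; failures are recorded, not raised."""
    report = AnalysisReport()
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    report.provenance = {
        "software_version": __version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "structure_checksum": _checksum(config.structure_path),
        "seed": config.seed,
    }
    structure = read_structure(config.structure_path)
    sp = config.superpose
    cycles, reject = int(sp.get("max_cycles", 5)), float(sp.get("reject_factor", 2.0))

    # --- curvature profile -------------------------------------------------
    try:
        model = _build_protofilament(config)
        reports = curvature_profile(structure, model,
                                    max_cycles=cycles, reject_factor=reject)
        report.bend_reports = [r.to_dict() for r in reports]
    except Exception as exc:  # noqa: BLE001 - per-stage fault isolation
        report.failures["curvature"] = str(exc)

    # --- interface burial and contacts ------------------------------------
    if config.interface_groups:
        for name, spec in config.interface_groups.items():
            try:
                ga = [_selection_from(g) for g in spec["group_a"]]
                gb = [_selection_from(g) for g in spec["group_b"]]
                kind = spec.get("kind", "buried_area")
                if kind == "buried_area":
                    res = buried_area(
                        structure, ga, gb,
                        probe_radius=float(config.sasa.get("probe_radius", 1.4)),
                        n_points=int(config.sasa.get("n_points", 960)),
                    )
                else:
                    res = contacts(structure, ga, gb,
                                   cutoff=float(spec.get("cutoff", 4.0)))
                report.interface_reports[name] = res.to_dict()
            except Exception as exc:  # noqa: BLE001
                report.failures[f"interface:{name}"] = str(exc)

    # --- motif comparisons -------------------------------------------------
    for comp in config.comparators:
        name = comp.get("name", comp["path"])
        try:
            other = read_structure(comp["path"])
            mc = motif_rmsd(
                structure, other,
                frame=(_selection_from(comp["frame_a"]),
                       _selection_from(comp["frame_b"])),
                motif=(_selection_from(comp["motif_a"]),
                       _selection_from(comp["motif_b"])),
                max_cycles=cycles, reject_factor=reject,
            )
            report.motif_comparisons[name] = mc.to_dict()
        except Exception as exc:  # noqa: BLE001
            report.failures[f"motif:{name}"] = str(exc)

    # --- helix rotation ----------------------------------------------------
    if config.helix_comparison:
        hc = config.helix_comparison
        name = hc.get("name", "helix_rotation")
        try:
            other = read_structure(hc["path"])
            angle = helix_rotation(
                structure, other,
                frame=(_selection_from(hc["frame_a"]),
                       _selection_from(hc["frame_b"])),
                helices=(_selection_from(hc["helices_a"]),
                         _selection_from(hc["helices_b"])),
                max_cycles=cycles, reject_factor=reject,
            )
            report.helix_rotations[name] = float(angle)
        except Exception as exc:  # noqa: BLE001
            report.failures[f"helix:{name}"] = str(exc)

    # --- SAXS validation ---------------------------------------------------
    if config.saxs:
        try:
            report.saxs_fits = _saxs_stage(structure, config.saxs)
        except Exception as exc:  # noqa: BLE001
            report.failures["saxs"] = str(exc)
    return report


def _saxs_stage(structure: Structure, cfg: dict[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    out["model_rg_A"] = radius_of_gyration(structure)
    pofr = pair_distribution(structure)
    out["model_dmax_A"] = pofr.dmax
    exp_path = cfg.get("experimental_profile")
    if exp_path:
        exp = read_dat(exp_path)
        gf = guinier_fit(exp, qrg_limit=float(cfg.get("qrg_limit", 1.3)))
        out["experimental_guinier"] = gf.to_dict()
        qmax = float(cfg.get("qmax", min(0.3, exp.q[-1])))
        # evaluate the model on the experimental grid: no interpolation error
        q_grid = exp.q[exp.q <= qmax]
        calc = debye_profile(structure, q_grid, mode=cfg.get("mode", "auto"))
        fit = chi_square(calc, exp)
        out["chi2_fit"] = fit.to_dict()
        lo, hi = out["model_dmax_A"] * 0.7, out["model_dmax_A"] * 1.3
        exp_pofr = pair_distribution(exp, dmax_search=(lo, hi, 13))
        out["experimental_dmax_A"] = exp_pofr.dmax
    return out
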