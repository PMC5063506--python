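"""End-to-end orchestration: alignment positions -> structural context ->
docking region -> binding modes -> assay summaries, in one JSON report.

A :class:`RunConfig` names the inputs (alignment + labels, a receptor
complex with chain roles and a ligand selection, a scored pose file, an
assay plate table) and the cutoff constants; :func:`run_pipeline` executes
the stages in dependency order, logging one structured line per stage with
a parameter hash, and writes a report that is byte-reproducible for a fixed
config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignment import find_separating_positions, read_alignment
from .assay import (curve_for_condition, fit_pec50, read_plate_table,
                    spline_auc, trapezoid_auc)
from .docking import (DEFAULT_EXHAUSTIVENESS, DEFAULT_NUM_MODES,
                      compute_search_box, emit_docking_config,
                      select_flexible_shell)
from .errors import ComputationError, InputError
from .poses import (cluster_poses, contact_residues, mode_score_gap,
                    read_poses, summarize_score_gaps)
from .structure import classify_residue_context, read_structure

logger = logging.getLogger("specmap")


@dataclass
class RunConfig:
    alignment: str = ""
    labels: str = ""
    reference_species: str = ""
    structure: str = ""
    chain_roles: dict[str, str] = field(default_factory=dict)
    ligand: list[tuple[str, int]] = field(default_factory=list)
    context_residues: list[tuple[str, int]] = field(default_factory=list)
    poses: str = ""
    assay_table: str = ""
    pocket_cutoff: float = 3.4
    interface_cutoff: float = 4.0
    contact_cutoff: float = 4.0
    cluster_rmsd: float = 2.0
    box_padding: float = 6.0
    exhaustiveness: int = DEFAULT_EXHAUSTIVENESS
    num_modes: int = DEFAULT_NUM_MODES
    seed: int = 0
    output_dir: str = "specmap_out"

    def validate(self) -> None:
        for name in ("pocket_cutoff", "interface_cutoff", "contact_cutoff",
                     "cluster_rmsd"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.box_padding < 0:
            raise InputError("box_padding must be non-negative")
        for name in ("alignment", "labels", "structure", "poses", "assay_table"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise InputError(f"{name} file does not exist: {path}")
        if self.alignment and not self.labels:
            raise InputError("an alignment requires a labels file")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ligand"] = [list(t) for t in self.ligand]
        d["context_residues"] = [list(t) for t in self.context_residues]
        return d

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "ligand" in data:
            data["ligand"] = [(c, int(n)) for c, n in data["ligand"]]
        if "context_residues" in data:
            data["context_residues"] = [(c, int(n)) for c, n in data["context_residues"]]
        return cls(**data)


def _param_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _stage(name: str, params: dict):
    logger.info("stage=%s params_hash=%s", name, _param_hash(params))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the report dict."""
    config.validate()
    report: dict = {
        "specmap_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    structure = None
    separating = None
    try:
        if config.alignment:
            _stage("positions", {"alignment": config.alignment})
            aln = read_alignment(config.alignment, config.labels,
                                 config.reference_species or None
                                 or _first_species(config.labels))
            sep = find_separating_positions(aln)
            separating = sep
            report["stages"]["positions"] = {
                "n_columns": aln.length,
                "separating": sep.to_rows(),
                "gapped_columns_excluded": list(sep.gapped_columns),
            }
    except InputError:
        raise
    except Exception as exc:
        raise ComputationError(f"stage positions failed: {exc}") from exc

    try:
        if config.structure:
            _stage("context", {"structure": config.structure})
            structure = read_structure(Path(config.structure).read_text(),
                                       roles=config.chain_roles,
                                       ligand=config.ligand)
            residues = config.context_residues
            if not residues and separating is not None:
                # default: look up separating reference residues on the accessory chain
                acc = [c for c, role in config.chain_roles.items()
                       if role == "accessory-C"]
                if acc:
                    chain = structure.chain(acc[0])
                    present = {r.seqnum for r in chain.residues}
                    residues = [(acc[0], p.reference_residue)
                                for p in separating.positions
                                if p.reference_residue in present]
            contexts = classify_residue_context(
                structure, residues,
                pocket_cutoff=config.pocket_cutoff,
                interface_cutoff=config.interface_cutoff) if residues else []
            report["stages"]["context"] = [
                {"chain": c.chain_id, "residue": c.seqnum, "resname": c.resname,
                 "ligand_distance": round(c.ligand_distance, 3),
                 "partner_distance": (round(c.partner_distance, 3)
                                      if c.partner_distance is not None else None),
                 "context": c.context}
                for c in contexts
            ]
    except InputError:
        raise
    except Exception as exc:
        raise ComputationError(f"stage context failed: {exc}") from exc

    try:
        if structure is not None and structure.ligand:
            _stage("dockprep", {"padding": config.box_padding})
            lig = structure.ligand_coords()
            box = compute_search_box(lig, padding=config.box_padding)
            shell = select_flexible_shell(structure, [lig])
            cfg_text = emit_docking_config(
                box, shell, config.structure, "ligand.pdbqt",
                str(outdir / "poses.pdbqt"),
                exhaustiveness=config.exhaustiveness,
                num_modes=config.num_modes)
            (outdir / "docking.cfg").write_text(cfg_text)
            report["stages"]["dockprep"] = {
                "box_center": [round(v, 3) for v in box.center],
                "box_size": [round(v, 3) for v in box.size],
                "flexible_shell": [
                    {"chain": m.chain_id, "residue": m.seqnum, "role": m.role,
                     "cutoff": m.cutoff, "min_distance": round(m.min_distance, 3)}
                    for m in shell.members],
                "config_file": str(outdir / "docking.cfg"),
            }
    except InputError:
        raise
    except Exception as exc:
        raise ComputationError(f"stage dockprep failed: {exc}") from exc

    try:
        if config.poses:
            _stage("poses", {"poses": config.poses, "cluster_rmsd": config.cluster_rmsd})
            pose_set = read_poses(Path(config.poses).read_text())
            modes = cluster_poses(pose_set, rmsd_threshold=config.cluster_rmsd)
            gap = mode_score_gap(modes) if len(modes) >= 2 else None
            entry = {
                "n_poses": len(pose_set),
                "n_modes": len(modes),
                "modes": [
                    {"members": list(m.members), "best_score": m.best_score,
                     "centroid": [round(float(v), 3) for v in m.centroid.mean(axis=0)]}
                    for m in modes],
                "score_gap": gap,
                "gap_summary": summarize_score_gaps({"run1": modes}),
            }
            if structure is not None:
                best = pose_set.poses[modes[0].representative]
                entry["best_pose_contacts"] = [
                    {"chain": c, "residue": n, "resname": rn, "distance": round(d, 3)}
                    for c, n, rn, d in contact_residues(
                        structure, best, cutoff=config.contact_cutoff)]
            report["stages"]["poses"] = entry
    except InputError:
        raise
    except Exception as exc:
        raise ComputationError(f"stage poses failed: {exc}") from exc

    try:
        if config.assay_table:
            _stage("assay", {"table": config.assay_table})
            df = read_plate_table(config.assay_table)
            per_condition = {}
            for cond in sorted(df["condition"].unique()):
                curve = curve_for_condition(df, cond)
                fit = fit_pec50(curve)
                per_condition[cond] = {
                    "spline_auc": round(spline_auc(curve), 6),
                    "trapezoid_auc": round(trapezoid_auc(curve), 6),
                    "pec50": round(fit.pec50, 4),
                    "converged": fit.converged,
                }
            report["stages"]["assay"] = per_condition
    except InputError:
        raise
    except Exception as exc:
        raise ComputationError(f"stage assay failed: {exc}") from exc

    text = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(text)
    report["report_sha256"] = hashlib.sha256(text.encode()).hexdigest()
    return report


def _first_species(labels_path: str) -> str:
    from .alignment import read_labels_tsv
    return next(iter(read_labels_tsv(labels_path)))
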