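"""Scored docking-pose analysis: clustering into binding modes, contacts,
inter-mode score gaps, and overlap with a reference ligand pose.

Poses live in the receptor frame, so pose-pose RMSD is computed without
refitting and without symmetry correction (a documented limitation for
symmetric ligands).  Clustering is greedy best-score-first, in the spirit of
Vina's internal mode separation: the best-scored unassigned pose seeds a
mode and absorbs every unassigned pose within the RMSD threshold.  Scores
are binding-energy-like: more negative is better, "best" = minimum.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from statistics import median

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError, ParseError
from .structure import StructureModel

DEFAULT_CLUSTER_RMSD = 2.0
DEFAULT_CONTACT_CUTOFF = 4.0
DEFAULT_OVERLAP_CUTOFF = 2.0

_VINA_RESULT = re.compile(r"REMARK\s+VINA\s+RESULT:\s+(-?\d+\.?\d*)")
_SCORE = re.compile(r"REMARK\s+SCORE\s+(-?\d+\.?\d*)")


@dataclass(frozen=True)
class Pose:
    coords: np.ndarray      # (n_atoms, 3)
    score: float
    run_id: str = "run1"


@dataclass
class PoseSet:
    atom_names: tuple[str, ...]
    poses: list[Pose] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.atom_names)
        for i, p in enumerate(self.poses):
            if p.coords.shape != (n, 3):
                raise InputError(
                    f"pose {i} has {p.coords.shape[0]} atoms, expected {n}")
            if not math.isfinite(p.score) and not math.isnan(p.score):
                raise InputError(f"pose {i} has non-finite score {p.score}")

    def __len__(self):
        return len(self.poses)

    def runs(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, p in enumerate(self.poses):
            out.setdefault(p.run_id, []).append(i)
        return out

    def subset(self, indices) -> "PoseSet":
        return PoseSet(self.atom_names, [self.poses[i] for i in indices])


@dataclass(frozen=True)
class BindingMode:
    members: tuple[int, ...]        # pose indices into the PoseSet
    representative: int             # member with the best (minimum) score
    centroid: np.ndarray            # mean ligand coordinates over members
    best_score: float


# ---------------------------------------------------------------------------
# pose file I/O
# ---------------------------------------------------------------------------

def read_poses(text: str, run_id: str = "run1",
               missing_score: str = "error") -> PoseSet:
    """Parse multi-model PDB (``REMARK SCORE``) or PDBQT (``REMARK VINA RESULT``).

    Poses are returned in file order.  Atom count and atom-name consistency
    across models is enforced.  ``missing_score``: ``"error"`` or ``"nan"``.
    """
    if missing_score not in ("error", "nan"):
        raise InputError(f"missing_score must be 'error' or 'nan', got {missing_score!r}")
    models: list[tuple[list[str], np.ndarray, float | None]] = []
    names: list[str] = []
    coords: list[list[float]] = []
    score: float | None = None
    in_model = False
    saw_model_records = False

    def flush(model_index: int):
        nonlocal names, coords, score
        if not coords:
            raise ParseError(f"model {model_index} contains no atoms")
        models.append((names, np.asarray(coords, dtype=float), score))
        names, coords, score = [], [], None

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if in_model:
                raise ParseError("nested MODEL record", lineno)
            in_model = True
            saw_model_records = True
        elif rec == "ENDMDL":
            if not in_model:
                raise ParseError("ENDMDL without MODEL", lineno)
            flush(len(models) + 1)
            in_model = False
        elif rec == "REMARK":
            m = _VINA_RESULT.search(line) or _SCORE.search(line)
            if m:
                score = float(m.group(1))
        elif rec in ("ATOM", "HETATM"):
            try:
                names.append(line[12:16].strip())
                coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except (ValueError, IndexError):
                raise ParseError("malformed coordinate fields", lineno)
    if in_model:
        raise ParseError(f"model {len(models) + 1} truncated (missing ENDMDL)")
    if not saw_model_records and coords:
        flush(1)  # single un-MODELed pose block
    if not models:
        raise ParseError("no poses found")

    ref_names = tuple(models[0][0])
    poses = []
    for i, (nm, xyz, sc) in enumerate(models, start=1):
        if tuple(nm) != ref_names:
            raise ParseError(f"model {i} atom names/count differ from model 1")
        if sc is None:
            if missing_score == "error":
                raise ParseError(f"model {i} has no score remark")
            sc = float("nan")
        poses.append(Pose(xyz, sc, run_id))
    return PoseSet(ref_names, poses)


def write_poses(pose_set: PoseSet, resname: str = "LIG", chain_id: str = "L") -> str:
    """Multi-model PDB with a ``REMARK SCORE`` line per model."""
    lines = []
    for i, pose in enumerate(pose_set.poses, start=1):
        lines.append(f"MODEL     {i:>4d}")
        lines.append(f"REMARK SCORE {pose.score:.3f}")
        for j, (name, xyz) in enumerate(zip(pose_set.atom_names, pose.coords), start=1):
            lines.append(
                f"HETATM{j:>5d} {name:<4s} {resname:<3s} {chain_id}{1:>4d} "
                f"  {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {name[:1]:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def pose_rmsd(a: Pose | np.ndarray, b: Pose | np.ndarray) -> float:
    """In-place coordinate RMSD (no refitting, no symmetry correction)."""
    A = a.coords if isinstance(a, Pose) else np.asarray(a, dtype=float)
    B = b.coords if isinstance(b, Pose) else np.asarray(b, dtype=float)
    if A.shape != B.shape:
        raise InputError(f"atom mismatch: {A.shape} vs {B.shape}")
    return float(np.sqrt(((A - B) ** 2).sum() / len(A)))


def cluster_poses(pose_set: PoseSet,
                  rmsd_threshold: float = DEFAULT_CLUSTER_RMSD) -> list[BindingMode]:
    """Greedy best-score-first clustering into binding modes.

    Repeatedly take the best-scored unassigned pose as a new mode seed and
    absorb all unassigned poses within ``rmsd_threshold`` of it.  Score ties
    break by input order.  Modes are returned ordered by best score.
    """
    if rmsd_threshold <= 0:
        raise InputError("rmsd_threshold must be positive")
    if len(pose_set) == 0:
        raise InputError("empty pose set")
    order = sorted(range(len(pose_set)), key=lambda i: (pose_set.poses[i].score, i))
    unassigned = set(order)
    modes = []
    for seed in order:
        if seed not in unassigned:
            continue
        seed_pose = pose_set.poses[seed]
        members = [i for i in order
                   if i in unassigned and pose_rmsd(seed_pose, pose_set.poses[i]) <= rmsd_threshold]
        unassigned -= set(members)
        centroid = np.mean([pose_set.poses[i].coords for i in members], axis=0)
        modes.append(BindingMode(tuple(sorted(members)), seed, centroid,
                                 seed_pose.score))
    modes.sort(key=lambda m: m.best_score)
    return modes


def contact_residues(receptor: StructureModel, pose: Pose | np.ndarray,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     heavy_only: bool = False) -> list[tuple[str, int, str, float]]:
    """Receptor residues with any atom within ``cutoff`` of any pose atom.

    The receptor's own ligand selection is excluded.  Returns
    (chain id, resnum, resname, min distance) sorted by distance.
    """
    P = pose.coords if isinstance(pose, Pose) else np.asarray(pose, dtype=float).reshape(-1, 3)
    if len(P) == 0:
        raise InputError("empty pose")
    own_ligand = set(receptor.ligand)
    out = []
    for chain, res in receptor.iter_residues():
        if (chain.id, res.seqnum) in own_ligand:
            continue
        coords = res.heavy_coords() if heavy_only else res.coords()
        if len(coords) == 0:
            continue
        d = float(cdist(coords, P).min())
        if d <= cutoff:
            out.append((chain.id, res.seqnum, res.name, d))
    out.sort(key=lambda t: (t[3], t[0], t[1]))
    return out


# ---------------------------------------------------------------------------
# score gaps
# ---------------------------------------------------------------------------

def mode_score_gap(modes: list[BindingMode]) -> float | None:
    """|best score of mode 1 - best score of mode 2|; None (with a warning)
    when fewer than two modes exist."""
    if len(modes) < 2:
        import warnings
        warnings.warn("fewer than two binding modes: score gap undefined", stacklevel=2)
        return None
    ordered = sorted(modes, key=lambda m: m.best_score)
    return abs(ordered[0].best_score - ordered[1].best_score)


def summarize_score_gaps(runs: dict[str, list[BindingMode]]) -> dict:
    """Per-run top-two score gaps with their median and max across runs."""
    per_run = {}
    for run_id, modes in runs.items():
        gap = mode_score_gap(modes) if len(modes) >= 2 else None
        per_run[run_id] = gap
    gaps = [g for g in per_run.values() if g is not None]
    return {
        "per_run": per_run,
        "median": median(gaps) if gaps else None,
        "max": max(gaps) if gaps else None,
    }


# ---------------------------------------------------------------------------
# reference-ligand overlap
# ---------------------------------------------------------------------------

def reference_overlap(pose_set: PoseSet, reference_coords: np.ndarray,
                      superposition=None,
                      receptor: StructureModel | None = None,
                      atom_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
                      contact_cutoff: float = DEFAULT_CONTACT_CUTOFF) -> list[dict]:
    """Per-pose overlap with a reference ligand pose.

    The reference coordinates are brought into the pose frame via the given
    ``Superposition`` (e.g. an accessory-on-accessory fit between the
    reference complex and the docking receptor) when one is supplied.  Two
    metrics are reported per pose: the fraction of pose atoms within
    ``atom_cutoff`` of any reference atom, and — when a receptor is given —
    the Jaccard index of the pose's and reference's contact-residue sets.
    """
    ref = np.asarray(reference_coords, dtype=float).reshape(-1, 3)
    if len(ref) == 0:
        raise InputError("empty reference ligand")
    if superposition is not None:
        ref = superposition.apply(ref)
    ref_contacts = None
    if receptor is not None:
        ref_contacts = {(c, n) for c, n, _, _ in
                        contact_residues(receptor, ref, cutoff=contact_cutoff)}
    reports = []
    for i, pose in enumerate(pose_set.poses):
        d = cdist(pose.coords, ref)
        frac = float((d.min(axis=1) <= atom_cutoff).mean())
        entry = {"pose": i, "score": pose.score, "atom_fraction": frac}
        if ref_contacts is not None:
            pc = {(c, n) for c, n, _, _ in
                  contact_residues(receptor, pose, cutoff=contact_cutoff)}
            union = pc | ref_contacts
            entry["contact_jaccard"] = (len(pc & ref_contacts) / len(union)) if union else 0.0
        reports.append(entry)
    return reports
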