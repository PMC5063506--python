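"""Docking-input construction: search box, flexible shell, engine config.

The search region is the axis-aligned bounding box of a reference ligand
expanded by a fixed padding (6 A by default) on every face.  The flexible
shell is the set of receptor residues with any atom within a per-chain-role
cutoff of any reference ligand atom: 3.4 A for the primary receptor and
accessory chains, 4.0 A for the partner chain of the dimer.  Several
reference ligands (e.g. the native ligand from each species' structure,
brought into one frame by superposition) contribute by union.

The emitted configuration is plain Vina/Smina-dialect text and round-trips
through :func:`parse_docking_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .structure import (ACCESSORY_C, PARTNER_B, RECEPTOR_A, StructureModel,
                        min_distance)

DEFAULT_CUTOFFS = {RECEPTOR_A: 3.4, ACCESSORY_C: 3.4, PARTNER_B: 4.0}
DEFAULT_PADDING = 6.0
DEFAULT_EXHAUSTIVENESS = 48     # independent search trajectories per run
CONVERGENCE_EXHAUSTIVENESS = (96, 144)
DEFAULT_NUM_MODES = 9           # top-ranked pose clusters saved per run


@dataclass(frozen=True)
class SearchBox:
    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.size):
            raise InputError(f"box sizes must be positive, got {self.size}")

    def contains(self, points: np.ndarray, shrink: float = 0.0) -> np.ndarray:
        """Boolean mask: points inside the box shrunk by ``shrink`` per face."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        half = np.asarray(self.size) / 2.0 - shrink
        return np.all(np.abs(pts - np.asarray(self.center)) <= half + 1e-9, axis=1)


@dataclass(frozen=True)
class ShellResidue:
    chain_id: str
    seqnum: int
    role: str
    cutoff: float
    min_distance: float


@dataclass(frozen=True)
class FlexibleShell:
    members: tuple[ShellResidue, ...]
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    n_reference_ligands: int = 1

    def selection_string(self) -> str:
        return ",".join(f"{m.chain_id}:{m.seqnum}" for m in self.members)


def compute_search_box(ligand_coords: np.ndarray,
                       padding: float = DEFAULT_PADDING) -> SearchBox:
    """Axis-aligned bounding box of the ligand, each face pushed out by padding."""
    coords = np.asarray(ligand_coords, dtype=float).reshape(-1, 3)
    if len(coords) == 0:
        raise InputError("empty ligand coordinate set")
    if padding < 0:
        raise InputError("padding must be non-negative")
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    center = (lo + hi) / 2.0
    size = hi - lo
    return SearchBox(tuple(float(v) for v in center), tuple(float(v) for v in size))


def select_flexible_shell(receptor: StructureModel,
                          reference_ligands: list[np.ndarray],
                          cutoffs: dict[str, float] | None = None,
                          heavy_only: bool = False) -> FlexibleShell:
    """Residues with any atom within their role's cutoff of any reference ligand.

    Reference ligands must already be in the receptor frame (use
    ``structure.superpose_by_selection`` to bring a second species' ligand
    over).  Only chains with a role in ``cutoffs`` participate; residues in
    the receptor's own ligand selection are excluded.  Output is ordered by
    (chain id, residue number).
    """
    if not reference_ligands:
        raise InputError("at least one reference ligand required")
    refs = [np.asarray(r, dtype=float).reshape(-1, 3) for r in reference_ligands]
    if any(len(r) == 0 for r in refs):
        raise InputError("empty reference ligand coordinate set")
    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    own_ligand = set(receptor.ligand)

    members = []
    for chain in receptor.chains:
        role = receptor.role_of(chain.id)
        if role not in cutoffs:
            continue
        cutoff = cutoffs[role]
        for res in chain.residues:
            if (chain.id, res.seqnum) in own_ligand:
                continue
            coords = res.heavy_coords() if heavy_only else res.coords()
            if len(coords) == 0:
                continue
            d = min(min_distance(coords, ref) for ref in refs)
            if d <= cutoff:
                members.append(ShellResidue(chain.id, res.seqnum, role, cutoff, d))
    members.sort(key=lambda m: (m.chain_id, m.seqnum))
    return FlexibleShell(tuple(members), cutoffs, len(refs))


def emit_docking_config(box: SearchBox, shell: FlexibleShell,
                        receptor_path: str, ligand_path: str,
                        out_path: str = "poses.pdbqt",
                        exhaustiveness: int = DEFAULT_EXHAUSTIVENESS,
                        num_modes: int = DEFAULT_NUM_MODES) -> str:
    """Vina/Smina-dialect config text for the given box and flexible shell."""
    for label, path in (("receptor", receptor_path), ("ligand", ligand_path),
                        ("out", out_path)):
        if not path:
            raise InputError(f"{label} path must be non-empty")
    if exhaustiveness < 1 or num_modes < 1:
        raise InputError("exhaustiveness and num_modes must be >= 1")
    lines = [
        f"receptor = {receptor_path}",
        f"ligand = {ligand_path}",
        f"out = {out_path}",
        # repr keeps full float precision so the config round-trips bit-exactly
        f"center_x = {box.center[0]!r}",
        f"center_y = {box.center[1]!r}",
        f"center_z = {box.center[2]!r}",
        f"size_x = {box.size[0]!r}",
        f"size_y = {box.size[1]!r}",
        f"size_z = {box.size[2]!r}",
        f"exhaustiveness = {exhaustiveness}",
        f"num_modes = {num_modes}",
    ]
    if shell.members:
        lines.append(f"flex_residues = {shell.selection_string()}")
    return "\n".join(lines) + "\n"


def parse_docking_config(text: str) -> dict:
    """Parse emitted config text back to values (round-trips the SearchBox)."""
    kv: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InputError(f"bad config line {line!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    try:
        box = SearchBox(
            tuple(float(kv[f"center_{a}"]) for a in "xyz"),
            tuple(float(kv[f"size_{a}"]) for a in "xyz"),
        )
        out = {
            "receptor": kv["receptor"],
            "ligand": kv["ligand"],
            "out": kv["out"],
            "box": box,
            "exhaustiveness": int(kv["exhaustiveness"]),
            "num_modes": int(kv["num_modes"]),
        }
    except KeyError as exc:
        raise InputError(f"config missing key {exc}")
    if "flex_residues" in kv:
        out["flex_residues"] = kv["flex_residues"]
    return out
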