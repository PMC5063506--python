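"""Structure handling: PDB I/O, Kabsch superposition, residue-context rules.

The in-memory model is deliberately small: ordered chains of ordered
residues of atoms with Cartesian coordinates, plus two annotations that
drive every downstream rule — a role tag per chain (primary receptor,
accessory protein, partner receptor of the dimer) and a ligand selection.

Residue context follows distance rules on "any atom": a residue is in the
*pocket* if any of its atoms is within the pocket cutoff (3.4 A by default)
of any ligand atom; otherwise it is on the *dimerization interface* if
within the interface cutoff (4.0 A) of the partner chain; otherwise it is
*surface-distal*.  Hydrogens count when present in the file; a
heavy-atom-only switch is provided.
"""

from __future__ import annotations

import copy as _copy
import string
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import InputError, ParseError

# chain role tags
RECEPTOR_A = "receptor-A"
ACCESSORY_C = "accessory-C"
PARTNER_B = "partner-B"
OTHER = "other"
ROLES = (RECEPTOR_A, ACCESSORY_C, PARTNER_B, OTHER)

POCKET = "pocket"
INTERFACE = "interface"
SURFACE_DISTAL = "surface-distal"


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,)

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise InputError(f"atom {self.name!r} has invalid coordinates {self.coord!r}")


@dataclass
class Residue:
    name: str
    seqnum: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.seqnum, self.icode)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms if a.element != "H"], dtype=float)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seqnum: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.key == (seqnum, icode):
                return r
        raise InputError(f"residue {seqnum}{icode} not in chain {self.id}")


@dataclass
class StructureModel:
    """Chains -> residues -> atoms with chain roles and a ligand selection."""

    chains: list[Chain] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)        # chain id -> role
    ligand: list[tuple[str, int]] = field(default_factory=list)  # (chain id, resnum)

    # -- access ------------------------------------------------------------
    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise InputError(f"no chain {chain_id!r} in structure")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.id == chain_id for c in self.chains)

    def role_of(self, chain_id: str) -> str:
        return self.roles.get(chain_id, OTHER)

    def chains_with_role(self, role: str) -> list[Chain]:
        return [c for c in self.chains if self.role_of(c.id) == role]

    def iter_residues(self):
        for c in self.chains:
            for r in c.residues:
                yield c, r

    def ligand_residues(self) -> list[Residue]:
        if not self.ligand:
            raise InputError("no ligand selection tagged on structure")
        return [self.chain(cid).residue(num) for cid, num in self.ligand]

    def ligand_coords(self, heavy_only: bool = False) -> np.ndarray:
        parts = [r.heavy_coords() if heavy_only else r.coords()
                 for r in self.ligand_residues()]
        coords = np.vstack([p for p in parts if len(p)])
        if len(coords) == 0:
            raise InputError("ligand selection contains no atoms")
        return coords

    def chain_coords(self, chain_id: str, heavy_only: bool = False,
                     exclude_ligand: bool = True) -> np.ndarray:
        lig = set(self.ligand) if exclude_ligand else set()
        parts = []
        for r in self.chain(chain_id).residues:
            if (chain_id, r.seqnum) in lig:
                continue
            parts.append(r.heavy_coords() if heavy_only else r.coords())
        parts = [p for p in parts if len(p)]
        if not parts:
            return np.empty((0, 3))
        return np.vstack(parts)

    def all_coords(self) -> np.ndarray:
        return np.vstack([r.coords() for _, r in self.iter_residues()])

    # -- mutation ----------------------------------------------------------
    def copy(self) -> "StructureModel":
        return _copy.deepcopy(self)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = self.copy()
        for _, res in out.iter_residues():
            for atom in res.atoms:
                atom.coord = rotation @ atom.coord + translation
        return out


# ---------------------------------------------------------------------------
# PDB fixed-column I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or " "
        seqnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record: {exc}", lineno) from None
    if not element:
        element = name.lstrip("0123456789")[:1]
    return {
        "name": name, "altloc": altloc, "resname": resname, "chain": chain_id,
        "seqnum": seqnum, "icode": icode, "coord": (x, y, z),
        "occupancy": occupancy, "element": element, "het": line.startswith("HETATM"),
        "lineno": lineno,
    }


def read_structure(pdb_text: str,
                   roles: dict[str, str] | None = None,
                   ligand: list[tuple[str, int]] | None = None) -> StructureModel:
    """Parse fixed-column PDB text (first model only) into a StructureModel.

    Alternate locations keep the highest-occupancy conformer (ties -> altloc
    'A').  A duplicate (chain, resnum, icode, atom name) key after altloc
    resolution is an error.  Chain roles are assigned by explicit config,
    never inferred.
    """
    model = StructureModel(roles=dict(roles or {}), ligand=list(ligand or []))
    chain_map: dict[str, Chain] = {}
    res_map: dict[tuple[str, int, str], Residue] = {}
    # atom key -> (altloc, occupancy, Atom) for altloc resolution
    seen: dict[tuple[str, int, str, str], tuple[str, float, Atom, int]] = {}

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "ENDMDL":
            break
        if rec not in ("ATOM", "HETATM"):
            continue
        f = _parse_atom_line(line, lineno)
        key = (f["chain"], f["seqnum"], f["icode"], f["name"])
        atom = Atom(f["name"], f["element"], f["coord"])
        if key in seen:
            prev_alt, prev_occ, prev_atom, prev_line = seen[key]
            if not f["altloc"] and not prev_alt:
                raise ParseError(
                    f"duplicate atom key {key} (first at line {prev_line})", lineno)
            # altloc resolution: highest occupancy, ties -> altloc 'A'
            if (f["occupancy"], f["altloc"] == "A") > (prev_occ, prev_alt == "A"):
                seen[key] = (f["altloc"], f["occupancy"], atom, lineno)
                prev_atom.name = "\0DROPPED"
                _replace_atom(res_map[(f["chain"], f["seqnum"], f["icode"])], prev_atom, atom)
            continue
        seen[key] = (f["altloc"], f["occupancy"], atom, lineno)

        if f["chain"] not in chain_map:
            chain_map[f["chain"]] = Chain(f["chain"])
            model.chains.append(chain_map[f["chain"]])
        rkey = (f["chain"], f["seqnum"], f["icode"])
        if rkey not in res_map:
            res_map[rkey] = Residue(f["resname"], f["seqnum"], f["icode"], het=f["het"])
            chain_map[f["chain"]].residues.append(res_map[rkey])
        res_map[rkey].atoms.append(atom)

    if not model.chains:
        raise ParseError("no ATOM/HETATM records found")
    return model


def _replace_atom(residue: Residue, old: Atom, new: Atom) -> None:
    for i, a in enumerate(residue.atoms):
        if a is old:
            residue.atoms[i] = new
            return


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: element right-justified in cols 13-14 for 1-char elements
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(model: StructureModel) -> str:
    """Serialize to fixed-column PDB text (coordinates at 3 decimals)."""
    lines = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            rec = "HETATM" if res.het else "ATOM  "
            for atom in res.atoms:
                serial += 1
                lines.append(
                    f"{rec}{serial:>5d} {_format_atom_name(atom.name, atom.element)}"
                    f" {res.name:<3s} {chain.id}{res.seqnum:>4d}{res.icode or ' '}"
                    f"   {atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def parse_selection(text: str) -> set[tuple[str, int]]:
    """Parse ``"C:5-10,A:3"`` into a set of (chain, resnum) pairs."""
    out: set[tuple[str, int]] = set()
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        try:
            chain, nums = part.split(":")
            if "-" in nums:
                lo, hi = nums.split("-")
                for n in range(int(lo), int(hi) + 1):
                    out.add((chain, n))
            else:
                out.add((chain, int(nums)))
        except ValueError:
            raise InputError(f"bad selection syntax {part!r} (expected chain:resnum[-resnum])")
    if not out:
        raise InputError("empty selection")
    return out


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray      # (3,3) proper rotation
    translation: np.ndarray   # (3,)
    rmsd: float
    n_atoms: int
    unmatched_moving: tuple = ()
    unmatched_fixed: tuple = ()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares rigid superposition (proper rotations only).

    Returns the transform ``x -> R x + t`` minimizing the RMSD of the moving
    set onto the fixed set.  Reflections are forbidden (det(R) = +1 enforced
    by the standard sign correction on the smallest singular vector).
    Collinear/degenerate point sets produce a warning and a best-effort fit.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape:
        raise InputError(f"point counts differ: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise InputError("need >= 3 points of dimension 3")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    rank = np.sum(S > max(S[0], 1.0) * 1e-12) if S[0] > 0 else 0
    if rank < 2:
        warnings.warn("degenerate (collinear) point set in superposition; "
                      "rotation is not uniquely determined", stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return Superposition(R, t, rmsd, len(P))


def _atom_index(model: StructureModel, use_roles: bool):
    """(chain key, resnum, icode, atom name) -> (coord, chain id).

    The chain key is the chain role when matching by role (so equivalent
    chains pair across structures with different chain ids), else the id.
    """
    index = {}
    for chain, res in model.iter_residues():
        ckey = model.role_of(chain.id) if use_roles else chain.id
        for atom in res.atoms:
            index[(ckey, res.seqnum, res.icode, atom.name)] = (atom.coord, chain.id)
    return index


def superpose_by_selection(moving: StructureModel, fixed: StructureModel,
                           selection=None, match_by_role: bool = True):
    """Fit ``moving`` onto ``fixed`` using atoms matched within a selection.

    Atoms pair by (chain role, residue number, insertion code, atom name);
    chain ids are used instead when ``match_by_role`` is False or either
    structure has no role tags.  ``selection`` is a set of (chain-or-role,
    resnum) pairs, a ``"C:1-10"`` string, or None for all shared atoms.
    Returns ``(transformed moving copy, Superposition)``.
    """
    if isinstance(selection, str):
        selection = parse_selection(selection)
    use_roles = match_by_role and bool(moving.roles) and bool(fixed.roles)
    mi = _atom_index(moving, use_roles)
    fi = _atom_index(fixed, use_roles)

    def in_sel(key, index):
        if selection is None:
            return True
        chain_id = index[key][1]
        return (key[0], key[1]) in selection or (chain_id, key[1]) in selection

    shared = sorted(k for k in mi.keys() & fi.keys()
                    if in_sel(k, mi) or in_sel(k, fi))
    if len(shared) < 3:
        raise InputError(f"only {len(shared)} matched atoms in selection (need >= 3)")
    P = np.array([mi[k][0] for k in shared])
    Q = np.array([fi[k][0] for k in shared])
    sup = kabsch_superpose(P, Q)
    sup = replace(
        sup,
        unmatched_moving=tuple(sorted(k for k in mi if k not in fi and in_sel(k, mi))),
        unmatched_fixed=tuple(sorted(k for k in fi if k not in mi and in_sel(k, fi))),
    )
    return moving.transform(sup.rotation, sup.translation), sup


# ---------------------------------------------------------------------------
# distances and residue context
# ---------------------------------------------------------------------------

def min_distance(coords_a: np.ndarray, coords_b: np.ndarray,
                 method: str = "kdtree") -> float:
    """Minimum Euclidean distance between two atom coordinate sets."""
    A = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    B = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if len(A) == 0 or len(B) == 0:
        raise InputError("empty coordinate selection")
    if method == "brute":
        return float(cdist(A, B).min())
    if method == "kdtree":
        d, _ = cKDTree(B).query(A, k=1)
        return float(d.min())
    raise InputError(f"unknown distance method {method!r}")


def residue_min_distance(struct: StructureModel, chain_id: str, seqnum: int,
                         target: np.ndarray, heavy_only: bool = False,
                         method: str = "kdtree") -> float:
    res = struct.chain(chain_id).residue(seqnum)
    coords = res.heavy_coords() if heavy_only else res.coords()
    return min_distance(coords, target, method=method)


@dataclass(frozen=True)
class ResidueContext:
    chain_id: str
    seqnum: int
    resname: str
    ligand_distance: float
    partner_distance: float | None
    context: str
    pocket_cutoff: float
    interface_cutoff: float


def classify_residue_context(struct: StructureModel,
                             residues: list[tuple[str, int]],
                             pocket_cutoff: float = 3.4,
                             interface_cutoff: float = 4.0,
                             heavy_only: bool = False) -> list[ResidueContext]:
    """Classify residues as pocket / interface / surface-distal.

    A residue within both cutoffs is classed pocket — ligand proximity takes
    precedence over the interface.  The partner chain is the chain tagged
    ``partner-B``; without one, the interface class is unavailable and
    classification reduces to pocket vs surface-distal.
    """
    lig = struct.ligand_coords(heavy_only=heavy_only)  # raises if untagged
    partners = struct.chains_with_role(PARTNER_B)
    partner_coords = None
    if partners:
        stacks = [struct.chain_coords(c.id, heavy_only=heavy_only) for c in partners]
        stacks = [s for s in stacks if len(s)]
        if stacks:
            partner_coords = np.vstack(stacks)

    out = []
    for chain_id, seqnum in residues:
        res = struct.chain(chain_id).residue(seqnum)
        d_lig = residue_min_distance(struct, chain_id, seqnum, lig, heavy_only=heavy_only)
        d_par = None
        if partner_coords is not None:
            d_par = residue_min_distance(struct, chain_id, seqnum, partner_coords,
                                         heavy_only=heavy_only)
        if d_lig <= pocket_cutoff:
            ctx = POCKET
        elif d_par is not None and d_par <= interface_cutoff:
            ctx = INTERFACE
        else:
            ctx = SURFACE_DISTAL
        out.append(ResidueContext(chain_id, seqnum, res.name, d_lig, d_par, ctx,
                                  pocket_cutoff, interface_cutoff))
    return out


def conformational_rmsd(bound: StructureModel, unbound: StructureModel,
                        residues: list[tuple[str, int]],
                        fit_selection=None,
                        atom_names: set[str] | None = None) -> float:
    """RMSD over ``residues`` after superposing unbound onto bound.

    ``fit_selection`` defaults to the residues themselves.  ``atom_names``
    restricts the comparison (e.g. backbone only).  Atoms missing from one
    model are listed in a warning and dropped from the comparison.
    """
    if fit_selection is None:
        fit_selection = set(residues)
    moved, _ = superpose_by_selection(unbound, bound, selection=fit_selection)

    use_roles = bool(moved.roles) and bool(bound.roles)
    mi = _atom_index(moved, use_roles)
    bi = _atom_index(bound, use_roles)
    pairs_m, pairs_b, missing = [], [], []
    wanted = set(residues)

    def wanted_key(key):
        if (key[0], key[1]) in wanted:
            return True
        for index in (mi, bi):
            if key in index and (index[key][1], key[1]) in wanted:
                return True
        return False

    for key in sorted(set(mi) | set(bi)):
        if not wanted_key(key):
            continue
        if atom_names is not None and key[3] not in atom_names:
            continue
        if key in mi and key in bi:
            pairs_m.append(mi[key][0])
            pairs_b.append(bi[key][0])
        else:
            missing.append(key)
    if missing:
        warnings.warn(f"{len(missing)} atoms missing from one model, "
                      f"computing on the intersection: {missing[:5]}...", stacklevel=2)
    if not pairs_m:
        raise InputError("no shared atoms in the requested residues")
    diff = np.asarray(pairs_m) - np.asarray(pairs_b)
    return float(np.sqrt((diff ** 2).sum() / len(pairs_m)))


# ---------------------------------------------------------------------------
# chimeric assembly
# ---------------------------------------------------------------------------

def build_chimeric_receptor(donor: StructureModel, acceptor: StructureModel,
                            shared_selection, graft_chains: list[str]):
    """Graft donor chains onto the acceptor after fitting on a shared selection.

    The donor is rigidly fitted to the acceptor over ``shared_selection``
    (typically the accessory chain both structures contain); the listed donor
    chains are then appended.  Colliding chain ids are remapped to the first
    free letter; provenance (original id, transform RMSD) is returned.
    """
    moved, sup = superpose_by_selection(donor, acceptor, selection=shared_selection)
    out = acceptor.copy()
    taken = {c.id for c in out.chains}
    provenance = {"fit_rmsd": sup.rmsd, "fit_atoms": sup.n_atoms, "chain_map": {}}
    for cid in graft_chains:
        chain = moved.chain(cid)
        new_id = cid
        if new_id in taken:
            free = [l for l in string.ascii_uppercase if l not in taken]
            if not free:
                raise InputError(f"chain id collision for {cid!r} and no free id to remap to")
            new_id = free[0]
        taken.add(new_id)
        grafted = _copy.deepcopy(chain)
        grafted.id = new_id
        out.chains.append(grafted)
        out.roles[new_id] = donor.role_of(cid)
        provenance["chain_map"][cid] = new_id
    return out, provenance
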