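"""Synthetic-data generators with planted, recoverable ground truth.

Every input the pipeline consumes can be generated here: a labelled
ortholog alignment with planted phenotype-separating columns, toy
bound/unbound receptor complexes with planted pocket / interface / distal
residues and a mobile loop, two-mode scored pose sets, 4PL dose-response
tables, and two-group cytokine replicate tables.

Defaults emulate the study conditions the pipeline targets: a 7-species
accessory-protein alignment (3 responders, 4 non-responders, 160 columns)
whose planted columns mirror the observed pattern at positions 130/131/132
— a responder-conserved column, an adjacent near-universally conserved
column with a single-species exception, and a non-responder-conserved
column; a two-binding-mode pose set with best-score means 0.2 kcal/mol
apart; and reporter titrations around micromolar EC50s.

Each generator is a pure function of (parameters, seed) — identical inputs
give byte-identical outputs; no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import (STANDARD_AA, AlignedRecord, PhenotypeAlignment,
                        RESPONDER, NONRESPONDER)
from .assay import DoseResponseCurve, GroupAssayTable, four_pl
from .errors import InputError
from .poses import Pose, PoseSet
from .structure import (ACCESSORY_C, Atom, Chain, PARTNER_B, RECEPTOR_A,
                        Residue, StructureModel)

AA_LIST = sorted(STANDARD_AA)

RESPONDER_SPECIES = ("human", "macaque", "guinea_pig")
NONRESPONDER_SPECIES = ("mouse", "rat", "ferret", "rabbit")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedColumn:
    """A separating column: per-group identities, one per species in order."""
    responder_identities: tuple[str, ...]
    nonresponder_identities: tuple[str, ...]

    def __post_init__(self):
        r, n = set(self.responder_identities), set(self.nonresponder_identities)
        if r & n:
            raise InputError("planted separating column has overlapping identity sets")
        bad = (r | n) - STANDARD_AA
        if bad:
            raise InputError(f"planted identities must be standard amino acids, got {sorted(bad)}")

    @property
    def pattern(self) -> str:
        r1 = len(set(self.responder_identities)) == 1
        n1 = len(set(self.nonresponder_identities)) == 1
        if r1 and n1:
            return "both-conserved"
        if r1:
            return "conserved-in-responders"
        if n1:
            return "conserved-in-nonresponders"
        return "both-variable"


@dataclass(frozen=True)
class PlantedConservedColumn:
    identity: str
    exception_species: str | None = None   # one species deviating
    exception_identity: str | None = None

    def __post_init__(self):
        if self.identity not in STANDARD_AA:
            raise InputError(f"conserved identity {self.identity!r} not a standard amino acid")
        if (self.exception_species is None) != (self.exception_identity is None):
            raise InputError("exception species and identity must be given together")
        if self.exception_identity is not None and self.exception_identity == self.identity:
            raise InputError("exception identity equals the conserved identity")


@dataclass(frozen=True)
class PlantedAlignmentTruth:
    """Ground truth for a synthetic alignment (1-based column indices)."""
    separating: dict[int, PlantedColumn] = field(default_factory=dict)
    conserved: dict[int, PlantedConservedColumn] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.separating) & set(self.conserved)
        if overlap:
            raise InputError(f"columns planted as both separating and conserved: {sorted(overlap)}")

    @property
    def separating_columns(self) -> list[int]:
        return sorted(self.separating)

    @property
    def conserved_columns(self) -> list[int]:
        return sorted(self.conserved)


def default_alignment_truth() -> PlantedAlignmentTruth:
    """Truth mirroring the observed 130/131/132 motif.

    Column 130: responder-conserved Lys vs His/His/Arg/Gln in non-responders.
    Column 131: Tyr in every species except one non-responder (His) — shared,
    hence NOT separating.  Column 132: non-responder-conserved Arg vs
    Lys/Lys/Tyr in responders.
    """
    return PlantedAlignmentTruth(
        separating={
            130: PlantedColumn(("K", "K", "K"), ("H", "H", "R", "Q")),
            132: PlantedColumn(("K", "K", "Y"), ("R", "R", "R", "R")),
        },
        conserved={
            131: PlantedConservedColumn("Y", exception_species="rat",
                                        exception_identity="H"),
        },
    )


def gen_labeled_alignment(n_responders: int = 3, n_nonresponders: int = 4,
                          length: int = 160,
                          truth: PlantedAlignmentTruth | None = None,
                          seed: int = 0,
                          background_share_prob: float = 0.7) -> PhenotypeAlignment:
    """Alignment whose planted columns reproduce ``truth`` exactly.

    Non-planted columns draw i.i.d. identities but always place a shared
    identity in at least one responder and one non-responder, so planted
    separating columns are the only separating columns by construction.
    """
    if n_responders < 1 or n_nonresponders < 1:
        raise InputError("need at least one species in each phenotype group")
    if length < 1:
        raise InputError("alignment length must be >= 1")
    truth = default_alignment_truth() if truth is None else truth
    for col in list(truth.separating) + list(truth.conserved):
        if not 1 <= col <= length:
            raise InputError(f"planted column {col} out of range 1..{length}")
    for col, pc in truth.separating.items():
        if (len(pc.responder_identities) != n_responders
                or len(pc.nonresponder_identities) != n_nonresponders):
            raise InputError(f"planted column {col} identity counts do not match group sizes")

    if n_responders <= len(RESPONDER_SPECIES):
        resp_names = list(RESPONDER_SPECIES[:n_responders])
    else:
        resp_names = [f"responder_{i+1}" for i in range(n_responders)]
    if n_nonresponders <= len(NONRESPONDER_SPECIES):
        non_names = list(NONRESPONDER_SPECIES[:n_nonresponders])
    else:
        non_names = [f"nonresponder_{i+1}" for i in range(n_nonresponders)]
    species = resp_names + non_names
    phenos = [RESPONDER] * n_responders + [NONRESPONDER] * n_nonresponders

    for col, cc in truth.conserved.items():
        if cc.exception_species is not None and cc.exception_species not in species:
            raise InputError(f"exception species {cc.exception_species!r} not in alignment "
                             f"(species are {species})")

    rng = np.random.default_rng(seed)
    n = len(species)
    columns = np.empty((length, n), dtype="<U1")
    for c in range(1, length + 1):
        if c in truth.separating:
            pc = truth.separating[c]
            columns[c - 1, :] = list(pc.responder_identities) + list(pc.nonresponder_identities)
        elif c in truth.conserved:
            cc = truth.conserved[c]
            col = [cc.identity] * n
            if cc.exception_species is not None:
                col[species.index(cc.exception_species)] = cc.exception_identity
            columns[c - 1, :] = col
        else:
            shared = AA_LIST[rng.integers(len(AA_LIST))]
            col = [shared if rng.random() < background_share_prob
                   else AA_LIST[rng.integers(len(AA_LIST))] for _ in range(n)]
            # guarantee the shared identity appears in both phenotype groups
            col[int(rng.integers(n_responders))] = shared
            col[n_responders + int(rng.integers(n_nonresponders))] = shared
            columns[c - 1, :] = col

    records = tuple(
        AlignedRecord(sp, "".join(columns[:, i]), ph)
        for i, (sp, ph) in enumerate(zip(species, phenos))
    )
    return PhenotypeAlignment(records, reference_id=species[0])


# ---------------------------------------------------------------------------
# toy complexes
# ---------------------------------------------------------------------------

def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


@dataclass(frozen=True)
class PlantedStructureTruth:
    """Planted residue classes on the accessory chain plus the loop and the
    rigid transform relating the unbound copy to the bound one."""
    pocket_ids: tuple[int, ...] = (5, 6)
    interface_ids: tuple[int, ...] = (9,)
    surface_ids: tuple[int, ...] = (2, 15, 18)
    loop_ids: tuple[int, ...] = (20, 21, 22, 23)
    loop_displacement: tuple[float, float, float] = (3.0, 0.0, 0.0)
    rotation_axis: tuple[float, float, float] = (0.3, 1.0, 0.2)
    rotation_angle_deg: float = 25.0
    translation: tuple[float, float, float] = (5.0, -3.0, 2.0)

    def __post_init__(self):
        groups = [set(self.pocket_ids), set(self.interface_ids),
                  set(self.surface_ids), set(self.loop_ids)]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] & groups[j]:
                    raise InputError("planted residue id groups must be disjoint")

    @property
    def all_planted(self) -> set[int]:
        return (set(self.pocket_ids) | set(self.interface_ids)
                | set(self.surface_ids) | set(self.loop_ids))

    @property
    def rotation(self) -> np.ndarray:
        return _rotation_matrix(np.asarray(self.rotation_axis), self.rotation_angle_deg)


def md2_like_structure_truth() -> PlantedStructureTruth:
    """Planted classes echoing the accessory-protein residue layout: a
    pocket-lining conserved aromatic position (131), a dimer-interface-edge
    position (86), distal-surface positions (22/31/42/49/53/130/132/156/159)
    flanking the pocket-lining one, and a mobile 120-129 loop.  Use with
    ``gen_toy_complex(n_residues=160, ...)`` so numbering matches the
    default alignment truth."""
    return PlantedStructureTruth(
        pocket_ids=(131,),
        interface_ids=(86,),
        surface_ids=(22, 31, 42, 49, 53, 130, 132, 156, 159),
        loop_ids=tuple(range(120, 130)),
    )


LIGAND_CENTER = np.array([0.0, 0.0, 0.0])
PARTNER_CENTER = np.array([14.0, 0.0, 0.0])
LIGAND_CHAIN, LIGAND_RESNUM = "L", 201


def gen_toy_complex(n_residues: int = 30,
                    truth: PlantedStructureTruth | None = None,
                    seed: int = 0) -> tuple[StructureModel, StructureModel]:
    """Bound/unbound toy complex pair with planted residue-context classes.

    The bound copy holds chains A (primary receptor), C (accessory, one CA
    atom per residue), B (dimer partner) and a multi-atom ligand on its own
    chain.  Planted pocket residues sit within 3.4 A of the ligand, planted
    interface residues within 4.0 A of chain B (but > 4.4 A from the
    ligand), planted surface residues beyond both cutoffs with >= 1 A
    margin.  The unbound copy lacks chain B and the ligand, has the planted
    loop displaced by the stated vector, and is rigidly transformed by the
    stated rotation/translation.
    """
    truth = PlantedStructureTruth() if truth is None else truth
    if n_residues < 10:
        raise InputError("n_residues must be >= 10")
    if truth.all_planted and max(truth.all_planted) > n_residues:
        raise InputError(f"planted residue ids exceed n_residues={n_residues}")
    rng = np.random.default_rng(seed)

    # ligand: small multi-atom cluster around the origin
    lig_atoms = [Atom(f"C{i+1}", "C", LIGAND_CENTER + off) for i, off in enumerate(
        [(0.0, 0.0, 0.0), (1.2, 0.0, 0.0), (0.0, 1.2, 0.0), (0.0, 0.0, 1.2)])]
    lig_res = Residue("LIG", LIGAND_RESNUM, atoms=lig_atoms, het=True)

    # partner chain B: a short strand near PARTNER_CENTER
    chain_b = Chain("B")
    for i in range(4):
        pos = PARTNER_CENTER + np.array([0.0, 2.0 * i, 0.0])
        chain_b.residues.append(
            Residue("GLY", 301 + i, atoms=[Atom("CA", "C", pos)]))
    partner_coords = np.array([r.atoms[0].coord for r in chain_b.residues])

    # primary receptor chain A: distal strand
    chain_a = Chain("A")
    for i in range(5):
        pos = np.array([-6.0 + 2.0 * i, 20.0, 4.0])
        chain_a.residues.append(
            Residue("ALA", 101 + i, atoms=[Atom("CA", "C", pos)]))

    lig_coords = np.array([a.coord for a in lig_atoms])

    def far_enough(pos, margin_lig, margin_par):
        d_lig = np.linalg.norm(lig_coords - pos, axis=1).min()
        d_par = np.linalg.norm(partner_coords - pos, axis=1).min()
        return d_lig >= margin_lig and d_par >= margin_par

    chain_c = Chain("C")
    pocket = set(truth.pocket_ids)
    interface = set(truth.interface_ids)
    for resnum in range(1, n_residues + 1):
        if resnum in pocket:
            # 2.2-3.0 A from a ligand atom, away from the partner
            base = lig_coords[int(rng.integers(len(lig_coords)))]
            direction = np.array([-1.0, 0.0, 0.0]) + rng.normal(0, 0.1, 3)
            direction /= np.linalg.norm(direction)
            pos = base + direction * rng.uniform(2.2, 3.0)
        elif resnum in interface:
            # 3.6-3.9 A from a partner atom, > 4.4 A from the ligand
            base = partner_coords[int(rng.integers(len(partner_coords)))]
            for _ in range(200):
                direction = rng.normal(0, 1, 3)
                direction /= np.linalg.norm(direction)
                pos = base + direction * rng.uniform(3.6, 3.9)
                if np.linalg.norm(lig_coords - pos, axis=1).min() >= 4.4:
                    break
        else:
            # background / surface / loop: >= 5 A from ligand and partner
            for _ in range(500):
                pos = np.array([rng.uniform(-15, 25), rng.uniform(-15, 15),
                                rng.uniform(5, 18)])
                if far_enough(pos, 5.0, 5.0):
                    break
        chain_c.residues.append(Residue("ALA", resnum, atoms=[Atom("CA", "C", pos)]))

    lig_chain = Chain(LIGAND_CHAIN, residues=[lig_res])
    bound = StructureModel(
        chains=[chain_a, chain_b, chain_c, lig_chain],
        roles={"A": RECEPTOR_A, "B": PARTNER_B, "C": ACCESSORY_C},
        ligand=[(LIGAND_CHAIN, LIGAND_RESNUM)],
    )

    # unbound: drop partner and ligand, displace the loop, apply rigid transform
    disp = np.asarray(truth.loop_displacement, dtype=float)
    R, t = truth.rotation, np.asarray(truth.translation, dtype=float)
    unbound = StructureModel(
        chains=[], roles={"A": RECEPTOR_A, "C": ACCESSORY_C}, ligand=[])
    for chain in (chain_a, chain_c):
        new_chain = Chain(chain.id)
        for res in chain.residues:
            atoms = []
            for atom in res.atoms:
                pos = atom.coord.copy()
                if chain.id == "C" and res.seqnum in truth.loop_ids:
                    pos = pos + disp
                atoms.append(Atom(atom.name, atom.element, R @ pos + t))
            new_chain.residues.append(Residue(res.name, res.seqnum, res.icode, atoms))
        unbound.chains.append(new_chain)
    return bound, unbound


# ---------------------------------------------------------------------------
# pose sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPoseTruth:
    mode_labels: tuple[int, ...]
    mode_centers: tuple[tuple[float, float, float], ...]
    score_means: tuple[float, ...]


_POSE_TEMPLATE = np.array([
    [0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [0.0, 1.4, 0.0],
    [0.0, 0.0, 1.4], [-1.0, -1.0, 0.0],
])


def gen_pose_set(n_poses_per_mode: int = 9,
                 mode_centers=((0.0, 0.0, 0.0), (20.0, 0.0, 0.0)),
                 spread: float = 0.5,
                 score_means=(-7.0, -6.8),
                 score_sd: float = 0.05,
                 seed: int = 0) -> tuple[PoseSet, PlantedPoseTruth]:
    """Scored poses drawn around mode centers with ground-truth labels.

    ``spread`` is a hard displacement radius: each pose is the rigid ligand
    template translated by a vector drawn uniformly in a ball of that
    radius, so the maximum within-mode pose RMSD is 2*spread and recovery
    at any clustering threshold in [2*spread, separation/2] is exact.
    """
    if spread <= 0:
        raise InputError("spread must be positive")
    if n_poses_per_mode < 1:
        raise InputError("need at least one pose per mode")
    centers = [np.asarray(c, dtype=float) for c in mode_centers]
    if len(centers) != len(score_means):
        raise InputError("one score mean per mode center required")
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            sep = np.linalg.norm(centers[i] - centers[j])
            if sep <= 4 * spread:
                raise InputError(
                    f"mode centers {i} and {j} separated by {sep:.2f} <= 4*spread")
    rng = np.random.default_rng(seed)
    atom_names = tuple(f"C{i+1}" for i in range(len(_POSE_TEMPLATE)))
    poses, labels = [], []
    for mode, (center, mu) in enumerate(zip(centers, score_means)):
        for _ in range(n_poses_per_mode):
            direction = rng.normal(0, 1, 3)
            direction /= np.linalg.norm(direction)
            offset = direction * spread * rng.random() ** (1.0 / 3.0)
            coords = _POSE_TEMPLATE + center + offset
            score = float(rng.normal(mu, score_sd))
            poses.append(Pose(coords, score))
            labels.append(mode)
    order = list(rng.permutation(len(poses)))
    pose_set = PoseSet(atom_names, [poses[i] for i in order])
    truth = PlantedPoseTruth(tuple(labels[i] for i in order),
                             tuple(tuple(c) for c in centers),
                             tuple(score_means))
    return pose_set, truth


# ---------------------------------------------------------------------------
# assay data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedAssayTruth:
    ec50: float = 1e-6          # molar
    hill: float = 1.0
    floor: float = 0.05         # OD-like units
    ceiling: float = 1.5
    noise_sd: float = 0.0       # absolute response units

    def __post_init__(self):
        if self.ec50 <= 0:
            raise InputError("EC50 must be positive")
        if self.ceiling <= self.floor:
            raise InputError("ceiling must exceed floor")
        if self.noise_sd < 0:
            raise InputError("noise sd must be non-negative")

    @property
    def pec50(self) -> float:
        return -float(np.log10(self.ec50))


def default_concentrations(ec50: float = 1e-6, n: int = 8,
                           decades: float = 3.5) -> np.ndarray:
    """Log-spaced titration bracketing the EC50 symmetrically."""
    lo = np.log10(ec50) - decades / 2
    return np.logspace(lo, lo + decades, n)


def gen_dose_response(truth: PlantedAssayTruth | None = None,
                      concentrations: np.ndarray | None = None,
                      n_replicates: int = 3,
                      seed: int = 0) -> DoseResponseCurve:
    """4PL responses in log10 molar plus Gaussian noise of the stated sd."""
    truth = PlantedAssayTruth() if truth is None else truth
    conc = (default_concentrations(truth.ec50) if concentrations is None
            else np.asarray(concentrations, dtype=float))
    if np.any(conc <= 0):
        raise InputError("concentrations must be strictly positive")
    if len(np.unique(conc)) < 4:
        raise InputError("need >= 4 distinct concentrations")
    if not (conc.min() < truth.ec50 < conc.max()):
        raise InputError("concentrations must span the true EC50")
    if n_replicates < 1:
        raise InputError("need >= 1 replicate")
    rng = np.random.default_rng(seed)
    x = np.log10(conc)
    mean = four_pl(x, truth.floor, truth.ceiling - truth.floor,
                   float(np.log10(truth.ec50)), truth.hill)
    all_conc, all_resp, all_rep = [], [], []
    for rep in range(1, n_replicates + 1):
        noise = rng.normal(0.0, truth.noise_sd, size=len(conc)) if truth.noise_sd > 0 \
            else np.zeros(len(conc))
        all_conc.append(conc)
        all_resp.append(mean + noise)
        all_rep.append(np.full(len(conc), rep))
    return DoseResponseCurve(np.concatenate(all_conc), np.concatenate(all_resp),
                             np.concatenate(all_rep))


def gen_group_assay(mean_ref: float, mean_cmp: float, cv: float,
                    n_per_group: int = 3, seed: int = 0,
                    species: str = "", cytokine: str = "") -> tuple[GroupAssayTable, float]:
    """Two lognormal replicate vectors at the stated CV.

    Returns the table and the true percent difference
    100*(mean_cmp - mean_ref)/mean_ref.  The lognormal is parameterized so
    the arithmetic mean and coefficient of variation match the requested
    values (strictly positive draws, matching multiplex-assay behaviour).
    """
    if mean_ref <= 0 or mean_cmp <= 0:
        raise InputError("group means must be positive")
    if cv < 0:
        raise InputError("cv must be non-negative")
    if n_per_group < 2:
        raise InputError("need >= 2 replicates per group")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv ** 2)
    sigma = np.sqrt(sigma2)

    def draw(mean):
        mu = np.log(mean) - sigma2 / 2.0
        return np.exp(rng.normal(mu, sigma, size=n_per_group)) if cv > 0 \
            else np.full(n_per_group, mean)

    table = GroupAssayTable(draw(mean_ref), draw(mean_cmp), species, cytokine)
    true_pct = 100.0 * (mean_cmp - mean_ref) / mean_ref
    return table, true_pct
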