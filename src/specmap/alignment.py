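"""Phenotype-separating position analysis on a labelled protein alignment.

The central object is a :class:`PhenotypeAlignment`: one aligned sequence per
species, each labelled *responder* or *nonresponder* for the phenotype under
study (here, activation by a ligand class).  A column *separates* the
phenotypes when the set of amino-acid identities seen in responders is
disjoint from the set seen in non-responders — the classic
specificity-determining-position criterion, applied with explicit gap and
ambiguity handling.

Ortholog selection mirrors common curation practice: among a species'
isoforms, keep the one with the highest alignment coverage against reference
structure sequences, preferring RefSeq entries on ties.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .errors import InputError

RESPONDER = "responder"
NONRESPONDER = "nonresponder"
PHENOTYPES = (RESPONDER, NONRESPONDER)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = set("BXZJUO")
GAP = "-"

# pattern labels for a separating column
CONSERVED_IN_RESPONDERS = "conserved-in-responders"
CONSERVED_IN_NONRESPONDERS = "conserved-in-nonresponders"
BOTH_VARIABLE = "both-variable"
BOTH_CONSERVED = "both-conserved"


@dataclass(frozen=True)
class AlignedRecord:
    species: str
    sequence: str
    phenotype: str

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise InputError(
                f"phenotype for {self.species!r} must be one of {PHENOTYPES}, "
                f"got {self.phenotype!r}"
            )


@dataclass(frozen=True)
class PhenotypeAlignment:
    """Aligned sequences keyed by species with responder/non-responder labels."""

    records: tuple[AlignedRecord, ...]
    reference_id: str

    def __post_init__(self):
        if not self.records:
            raise InputError("alignment has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise InputError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
        if self.length == 0:
            raise InputError("alignment has zero columns")
        species = [r.species for r in self.records]
        if len(set(species)) != len(species):
            raise InputError("duplicate species ids in alignment")
        if self.reference_id not in species:
            raise InputError(f"reference id {self.reference_id!r} not among species")
        phenos = {r.phenotype for r in self.records}
        if phenos != set(PHENOTYPES):
            raise InputError("alignment must contain at least one responder and one non-responder")

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def reference(self) -> AlignedRecord:
        return next(r for r in self.records if r.species == self.reference_id)

    def group(self, phenotype: str) -> tuple[AlignedRecord, ...]:
        return tuple(r for r in self.records if r.phenotype == phenotype)

    def column(self, col: int) -> dict[str, str]:
        """1-based column as a species -> character map."""
        if not 1 <= col <= self.length:
            raise InputError(f"column {col} out of range 1..{self.length}")
        return {r.species: r.sequence[col - 1] for r in self.records}

    def swap_labels(self) -> "PhenotypeAlignment":
        flipped = tuple(
            AlignedRecord(r.species, r.sequence,
                          RESPONDER if r.phenotype == NONRESPONDER else NONRESPONDER)
            for r in self.records
        )
        return PhenotypeAlignment(flipped, self.reference_id)


@dataclass(frozen=True)
class SeparatingPosition:
    column: int                     # 1-based alignment column
    reference_residue: int | None   # 1-based ungapped reference numbering, None on ref gap
    responder_identities: tuple[str, ...]
    nonresponder_identities: tuple[str, ...]
    pattern: str
    ambiguous: bool = False         # column contained an ambiguity code

    def __post_init__(self):
        if set(self.responder_identities) & set(self.nonresponder_identities):
            raise InputError("separating position with overlapping identity sets")


@dataclass(frozen=True)
class SeparationReport:
    positions: tuple[SeparatingPosition, ...]
    gapped_columns: tuple[int, ...]      # columns excluded under the default gap policy
    gap_policy: str

    def to_rows(self):
        return [
            {
                "column": p.column,
                "reference_residue": p.reference_residue,
                "responder_identities": "".join(sorted(set(p.responder_identities))),
                "nonresponder_identities": "".join(sorted(set(p.nonresponder_identities))),
                "pattern": p.pattern,
                "ambiguous": p.ambiguous,
            }
            for p in self.positions
        ]


# ---------------------------------------------------------------------------
# ortholog candidate selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologCandidate:
    source_id: str
    sequence: str
    is_refseq: bool = False


@dataclass
class OrthologCandidateSet:
    """Per-species candidate isoforms to choose one ortholog from."""

    candidates: dict[str, list[OrthologCandidate]] = field(default_factory=dict)

    def __post_init__(self):
        for sp, cands in self.candidates.items():
            if not cands:
                raise InputError(f"species {sp!r} has no candidates")


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _check_protein(seq: str, what: str) -> None:
    if not seq:
        raise InputError(f"{what} sequence is empty")
    bad = set(seq.upper()) - STANDARD_AA - AMBIGUOUS_AA
    if bad:
        raise InputError(f"{what} sequence contains invalid characters {sorted(bad)}")


def pairwise_coverage(candidate: str, reference: str,
                      aligner: Align.PairwiseAligner | None = None) -> float:
    """Fraction of reference positions aligned to a candidate residue.

    Uses an optimal global alignment with affine gaps (BLOSUM62, -11/-1 by
    default).  Coverage is computed on the reference axis, so it is not
    symmetric in its arguments.
    """
    _check_protein(candidate, "candidate")
    _check_protein(reference, "reference")
    if aligner is None:
        aligner = _default_aligner()
    aln = aligner.align(reference.upper(), candidate.upper())[0]
    ref_blocks = aln.aligned[0]
    aligned_ref = int(sum(end - start for start, end in ref_blocks))
    return aligned_ref / len(reference)


def select_orthologs(candidates: OrthologCandidateSet,
                     references: str | list[str],
                     aligner: Align.PairwiseAligner | None = None):
    """Pick one sequence per species: max coverage, RefSeq on ties, then id.

    ``references`` may be several representative sequences (e.g. one per
    reference structure); a candidate's coverage is the maximum over them.
    Returns ``(chosen, report)`` where ``report`` records per-candidate
    coverage against every representative.
    """
    if isinstance(references, str):
        references = [references]
    if not references:
        raise InputError("at least one reference sequence required")
    if aligner is None:
        aligner = _default_aligner()

    chosen: dict[str, OrthologCandidate] = {}
    report: dict[str, list[dict]] = {}
    for species, cands in candidates.candidates.items():
        scored = []
        rows = []
        for cand in cands:
            per_ref = [pairwise_coverage(cand.sequence, ref, aligner) for ref in references]
            cov = max(per_ref)
            scored.append((-cov, not cand.is_refseq, cand.source_id, cand))
            rows.append({"source_id": cand.source_id, "is_refseq": cand.is_refseq,
                         "coverage": cov, "coverage_per_reference": per_ref})
        scored.sort(key=lambda t: t[:3])
        chosen[species] = scored[0][3]
        report[species] = rows
    return chosen, report


# ---------------------------------------------------------------------------
# column analysis
# ---------------------------------------------------------------------------

def column_to_residue_map(alignment: PhenotypeAlignment) -> dict[int, int | None]:
    """Map 1-based alignment columns to 1-based ungapped reference residues."""
    ref = alignment.reference.sequence
    mapping: dict[int, int | None] = {}
    count = 0
    for col, char in enumerate(ref, start=1):
        if char == GAP:
            mapping[col] = None
        else:
            count += 1
            mapping[col] = count
    return mapping


def _pattern_label(resp: set[str], nonresp: set[str]) -> str:
    r1, n1 = len(resp) == 1, len(nonresp) == 1
    if r1 and n1:
        return BOTH_CONSERVED
    if r1:
        return CONSERVED_IN_RESPONDERS
    if n1:
        return CONSERVED_IN_NONRESPONDERS
    return BOTH_VARIABLE


def find_separating_positions(alignment: PhenotypeAlignment,
                              gap_policy: str = "exclude") -> SeparationReport:
    """Columns whose responder/non-responder identity sets are disjoint.

    gap_policy:
      * ``"exclude"`` (default) — any column containing a gap in any sequence
        is skipped for the separation test and listed in ``gapped_columns``.
      * ``"identity"`` — the gap character is treated as a 21st identity.

    Ambiguity codes (X, B, Z, ...) never contribute to the overlap test but
    flag the column as ambiguous.
    """
    if gap_policy not in ("exclude", "identity"):
        raise InputError(f"unknown gap_policy {gap_policy!r}")
    responders = alignment.group(RESPONDER)
    nonresponders = alignment.group(NONRESPONDER)
    col_map = column_to_residue_map(alignment)

    positions: list[SeparatingPosition] = []
    gapped: list[int] = []
    for col in range(1, alignment.length + 1):
        resp_chars = [r.sequence[col - 1].upper() for r in responders]
        non_chars = [r.sequence[col - 1].upper() for r in nonresponders]
        all_chars = resp_chars + non_chars
        if gap_policy == "exclude" and GAP in all_chars:
            gapped.append(col)
            continue
        ambiguous = any(c in AMBIGUOUS_AA for c in all_chars)
        resp_set = {c for c in resp_chars if c not in AMBIGUOUS_AA}
        non_set = {c for c in non_chars if c not in AMBIGUOUS_AA}
        if not resp_set or not non_set:
            continue  # group entirely ambiguous: no evidence of separation
        if resp_set & non_set:
            continue
        positions.append(SeparatingPosition(
            column=col,
            reference_residue=col_map[col],
            responder_identities=tuple(resp_chars),
            nonresponder_identities=tuple(non_chars),
            pattern=_pattern_label(resp_set, non_set),
            ambiguous=ambiguous,
        ))
    return SeparationReport(tuple(positions), tuple(gapped), gap_policy)


@dataclass(frozen=True)
class ConservationProfile:
    column: int
    responder_counts: dict[str, int]
    nonresponder_counts: dict[str, int]
    majority_identity: str
    exceptions: tuple[str, ...]   # species deviating from the column majority


def conservation_profile(alignment: PhenotypeAlignment, column: int) -> ConservationProfile:
    """Per-group identity counts at a column plus majority-deviating species."""
    col = alignment.column(column)  # raises on out-of-range
    resp = Counter(col[r.species].upper() for r in alignment.group(RESPONDER))
    non = Counter(col[r.species].upper() for r in alignment.group(NONRESPONDER))
    total = resp + non
    # majority by count, ties broken alphabetically for determinism
    majority = min(total.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    exceptions = tuple(sp for sp, c in sorted(col.items()) if c.upper() != majority)
    return ConservationProfile(column, dict(resp), dict(non), majority, exceptions)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_labels_tsv(path) -> dict[str, str]:
    """Two-column TSV (species, phenotype) -> mapping."""
    labels: dict[str, str] = {}
    text = Path(path).read_text()
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"labels line {i}: expected 2 tab-separated fields, got {len(parts)}")
        species, phenotype = parts
        if phenotype not in PHENOTYPES:
            raise InputError(f"labels line {i}: unknown phenotype {phenotype!r}")
        labels[species] = phenotype
    if not labels:
        raise InputError("labels file is empty")
    return labels


def read_alignment(fasta_path, labels_path, reference_id: str) -> PhenotypeAlignment:
    """Aligned FASTA + labels TSV -> PhenotypeAlignment."""
    labels = read_labels_tsv(labels_path)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in labels:
            raise InputError(f"species {rec.id!r} in alignment has no phenotype label")
        records.append(AlignedRecord(rec.id, str(rec.seq).upper(), labels[rec.id]))
    return PhenotypeAlignment(tuple(records), reference_id)


def write_alignment(alignment: PhenotypeAlignment, fasta_path, labels_path) -> None:
    with open(fasta_path, "w") as fh:
        for r in alignment.records:
            fh.write(f">{r.species}\n{r.sequence}\n")
    with open(labels_path, "w") as fh:
        for r in alignment.records:
            fh.write(f"{r.species}\t{r.phenotype}\n")


def write_separation_report(report: SeparationReport, path) -> None:
    cols = ["column", "reference_residue", "responder_identities",
            "nonresponder_identities", "pattern", "ambiguous"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in report.to_rows():
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def write_selection_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
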