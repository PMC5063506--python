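# Methods

This note documents the models, rules, numerical choices and limitations
behind `specmap`, and what the synthetic-data generators do and do not
emulate.

## Separating-position analysis

A labelled alignment holds one aligned sequence per species with a binary
phenotype (responder / non-responder). A column separates the phenotypes
when the responder identity set and the non-responder identity set are
disjoint. This is a purely set-based criterion: it makes no correction for
phylogenetic non-independence of the species, so with few species many
columns can separate by shared ancestry alone — the analysis ranks
candidates for structural follow-up, it does not test significance.

Pattern labels are derived from the two set cardinalities. The natural
three-way scheme (conserved in responders / conserved in non-responders /
both variable) does not cover a column where *both* groups are conserved
on different identities, and a three-way labelling cannot be symmetric
under swapping the phenotype labels; we therefore use four labels, adding
`both-conserved`. Swapping all phenotype labels exchanges the two
`conserved-in-*` labels and fixes the other two, a property the tests
enforce.

Gap policy: a column containing a gap in any sequence is excluded from the
separation test by default and reported separately, because an indel
column "separating" on gap presence is an alignment artifact, not a
residue-identity statement. An optional mode treats the gap as a 21st
identity. Ambiguity codes (X, B, Z, J, U, O) contribute to neither identity
set — they can never create a separation — and flag the column.

Reference numbering: column *c* maps to the count of non-gap reference
characters in columns 1..*c* (None where the reference is gapped). Any
offset convention (e.g. whether a signal peptide is counted) is the
caller's responsibility via the choice of reference sequence.

Ortholog selection: one isoform per species, chosen by maximal coverage of
reference sequences under an optimal global alignment (BLOSUM62, affine
gaps −11/−1, end gaps penalized). Coverage is the fraction of reference
positions aligned to a candidate residue. With several reference
representatives the maximum coverage over them is used (per-representative
values are recorded). Ties prefer RefSeq entries, then the lexicographically
smallest source id. The aligner is Biopython's `PairwiseAligner`; where the
optimum is degenerate, the reported coverage is that of the aligner's
first-ranked optimal alignment.

## Structure handling

The structure model is minimal: ordered chains → residues → atoms with
Cartesian coordinates, a role tag per chain (`receptor-A`, `accessory-C`,
`partner-B`, `other`) assigned explicitly by configuration (never inferred),
and a ligand selection. The PDB reader is fixed-column, keeps the first
model, resolves alternate locations to the highest-occupancy conformer
(ties → altloc `A`), preserves insertion codes, and treats a duplicate
(chain, resnum, icode, atom name) key or malformed coordinate field as a
parse error carrying the line number. Written output uses 3-decimal
coordinates, so round trips are exact to PDB precision. mmCIF is out of
scope.

Superposition is the closed-form least-squares rigid fit (SVD with the
determinant sign correction; reflections forbidden). Collinear point sets
leave the rotation underdetermined: a warning is emitted and a best-effort
fit returned. Atom pairing for whole-structure fits uses (chain role,
residue number, insertion code, atom name), falling back to chain ids when
either structure is untagged; selections accept `chain:resnum[-resnum]`
strings and match against chain ids as well as roles.

Residue context uses "any atom" minimum distances — hydrogens count when
present in the file, with a heavy-atom-only switch. Classification:
`pocket` if the ligand distance ≤ 3.4 Å; otherwise `interface` if the
partner-chain distance ≤ 4.0 Å; otherwise `surface-distal`. A residue
within both cutoffs is classed pocket — ligand proximity is the stronger
structural statement. "Surface" is operationalized purely as
distal-by-distance; no solvent-accessibility computation is performed.
Distance queries go through a k-d tree with a brute-force path kept for
verification; tests require exact agreement.

Bound-vs-unbound conformational change is an RMSD over chosen residues
after superposing on a fit selection (default: the residues themselves);
the atom set (backbone, side chain, all) is a parameter because different
choices answer different questions. Atoms missing from one model are
warned about and dropped from the comparison.

Chimeric assembly (grafting a chain from a donor complex onto an acceptor
after fitting on a shared selection, e.g. adding the receptor chain to a
structure solved with the accessory protein alone) records the fit RMSD
and remaps colliding chain ids to the first free letter.

## Docking setup

The search box is the axis-aligned bounding box of the reference ligand in
the input frame, each face pushed outward 6 Å (padding applied to the
bounding box, not to per-atom van der Waals extents). The flexible shell
takes every chain-A/C residue with any atom within 3.4 Å — chain-B
residues within 4.0 Å — of any reference ligand atom; several reference
ligands (e.g. the native ligand of each species' structure after
cross-species superposition on the accessory chain) contribute by union.
Shell membership is monotone in the cutoff. The emitted config is plain
`key = value` text in the Vina dialect with `exhaustiveness = 48` and
`num_modes = 9` defaults (96/144 as convergence-check presets); box
coordinates are written at full float precision so configs round-trip
bit-exactly. Engine invocation itself is out of scope: the package builds
docking inputs and analyzes outputs, it does not wrap a force field.

## Pose analysis

Poses share the receptor frame, so pose–pose RMSD is computed in place with
no refitting and no symmetry/automorphism correction — a known limitation
for symmetric ligands, where the reported RMSD upper-bounds the
symmetry-corrected one. Clustering is greedy best-score-first at a 2.0 Å
threshold: the best-scored unassigned pose seeds a mode and absorbs all
unassigned poses within the threshold; ties in score break by input order,
making the procedure deterministic and order-invariant for distinct
scores. The threshold is a parameter; mode count is non-increasing in it.
Scores follow the binding-energy convention (more negative is better). The
inter-mode score gap is the absolute difference of the top two modes' best
scores per run, summarized as median and max across runs. Overlap with a
reference ligand pose is reported with two deliberately different metrics —
fraction of pose atoms within 2.0 Å of any reference atom, and the Jaccard
index of contact-residue sets at 4.0 Å — because "overlap" has no single
canonical definition; neither is privileged.

## Assay metrics

AUCs integrate response against log10 molar concentration: a natural cubic
spline (boundary condition configurable; natural by default, and the choice
is part of the result's provenance) integrated analytically, and the
composite trapezoid rule. For replicated curves the default is
integrate-per-replicate-then-average, with a means-mode switch; the two
orders differ only through spline nonlinearity. Spline and trapezoid agree
exactly on collinear data.

The 4PL model is `y = floor + (ceiling − floor) / (1 + 10^((logEC50 − x)·h))`
with `x = log10` molar, fitted by bounded least squares; `pEC50 = −logEC50`.
Initialization comes from data quantiles (floor/ceiling from the response
range, logEC50 from the half-maximal point); bounds keep the span
non-negative and the Hill slope positive (ascending curves). Convergence
status and whether the data bracket the fitted inflection are reported;
non-convergence is flagged, never silently replaced.

Percent difference from a reference stimulus is `100·(m₁ − m₀)/m₀` on
group means. The default CI is Fieller's theorem on the ratio of
independent means (solving `(m₁ − ρm₀)² ≤ t²(v₁ + ρ²v₀)` with
Welch–Satterthwaite degrees of freedom); when the reference mean is not
significantly away from zero the solution set is unbounded and the result
is flagged rather than truncated. A seeded percentile bootstrap (10,000
resamples) is the robustness alternative. Significance is lower CI bound
above 0% — with a 90% two-sided interval this is a one-sided 5% rule, and
the null-calibration test verifies the empirical rate is near 5% under
lognormal noise at CV 0.2 and n = 3. Zero-variance groups yield a
degenerate point interval.

## Synthetic data: what passing tests show

The generators are pure functions of (parameters, seed).

*Alignments* (default 3 responders / 4 non-responders, 160 columns) plant
the target motif exactly — a responder-conserved column (Lys vs
His/His/Arg/Gln), a non-responder-conserved column (Arg vs Lys/Lys/Tyr),
and an adjacent near-universally conserved column with a single-species
exception — and draw background columns with a shared identity forced into
both groups, so the planted columns are the only separating ones by
construction. Background sharing probability 0.7 gives realistic-looking
variability while keeping the guarantee. This emulates identity patterns
only: no phylogenetic correlation, no indel structure beyond the explicit
gap policy tests, no rate variation.

*Toy complexes* use one CA atom per protein residue plus a four-atom
ligand — just enough geometry to exercise every distance rule, with planted
pocket residues inside 3.4 Å, interface residues inside 4.0 Å of the
partner but ≥ 1 Å outside the pocket cutoff, and surface residues ≥ 1 Å
outside both. The unbound copy drops the partner and ligand, displaces a
planted loop by a stated vector (default 3 Å, emulating a
binding-induced loop rearrangement) and applies a stated rigid transform.
Nothing about protein realism (packing, secondary structure, side chains)
is emulated; recovery tests certify the geometric rules, not behaviour on
crystallographic coordinates.

*Pose sets* translate a rigid 5-atom template by offsets drawn uniformly in
a ball of radius `spread` around each mode center. The hard radius (rather
than a Gaussian σ) makes recovery deterministic: within-mode RMSD is
≤ 2·spread, so any clustering threshold in [2·spread, separation/2]
recovers the planted modes exactly, which is the guarantee the recovery
tests rely on. Defaults: two centers 20 Å apart, spread 0.5 Å, 9 poses per
mode, best-score means −7.0 / −6.8 kcal/mol with 0.05 kcal/mol score noise
(small relative to the 0.2 gap so the median gap across seeds stays near
0.2). Real docking output has rotational pose scatter and heavier-tailed
score distributions.

*Assay data*: Gaussian noise on 4PL responses (OD-like measurements),
lognormal noise for cytokine replicates (strictly positive, matching
multiplex-assay behaviour), parameterized so the arithmetic mean and CV
match the requested values. Default titrations are 8 log-spaced
concentrations spanning 3.5 decades centered on the EC50.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
these sizes, chosen to make every recovery statement exact or tightly
bounded while completing in seconds: 100 seeded alignments (7 × 160) for
position recovery, ≥ 1000 randomized geometry queries against brute-force
oracles, 100 seeded pose sets for mode recovery and the score-gap median,
and 2000 simulated two-group tables for the significance-rule calibration
and CI coverage.

## Known limitations

- No phylogenetic correction in the separation test; no SASA in the
  context classification; no mmCIF input.
- Pose RMSD is not symmetry-corrected.
- Fieller intervals assume approximately normal group means; at n = 3 with
  skewed noise the empirical one-sided rate (~4%) sits slightly below the
  nominal 5%, as the calibration test documents.
- The docking engine itself, ligand preparation (3D generation, charges,
  PDBQT typing) and alignment construction are upstream/downstream of this
  package and out of scope.
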