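# Methods

## Digestion model

Digestion is modelled as complete, rule-based proteolysis. For an
enzyme with specificity on the C-terminal side, the bond between
residues P1 and P1′ is cleavable when P1 belongs to the enzyme's target
set; for N-terminal-side enzymes (thermolysin) the target sits at P1′.
Blocking contexts are predicates over the window P2–P2′ that veto a cut
(the classical example is proline in P1′ protecting Lys/Arg bonds from
trypsin). The shipped baseline table is:

| enzyme | cuts | targets | blocked when |
|---|---|---|---|
| TR (trypsin) | C-side | K, R | P1′ = P |
| CTR (chymotrypsin, low specificity) | C-side | F, L, M, W, Y | P1′ = P |
| PEP (pepsin, pH 1.3) | C-side | F, L | P1′ = P |
| TLN (thermolysin) | N-side | A, F, I, L, M, V | P1 = P |
| LysC (endoproteinase Lys-C) | C-side | K | — |
| PROK (proteinase K) | C-side | A, E, F, I, L, T, V, W, Y | — |

These baseline rules are deliberately the uncontested core of each
enzyme's published specificity. The full positional-exception matrices
(Keil-style P4–P2′ contexts) fit the same `POS=RESIDUES` schema, so
higher-fidelity tables can be dropped in as data files without code
changes; the active table's name is recorded in datastore metadata.
Kinetics, partial digestion and missed cleavages are out of scope: the
engine emits the unique complete-digestion tiling (fragments down to
single residues — length filtering is a query concern, not an engine
concern).

A *workflow* is one or two steps of simultaneously applied enzymes
(`+` within a step, `-` between steps). A simultaneous step cuts at the
union of the per-enzyme site sets. In a two-step workflow every step-1
fragment (level 0) is re-digested by the step-2 set and each product —
including fragments step 2 leaves uncut — is emitted as a level-1 event
carrying its parent's enzymes and sequence, at absolute protein
coordinates. Emitting uncut fragments at level 1 keeps each level a
complete tiling of the protein, which is the invariant the test suite
leans on. The default panel is the 15 workflows CTR, CTR-PEP, CTR-TR,
LysC, LysC+TR, LysC+TR+CTR, PEP, PEP-CTR, PEP-CTR+TR, PEP-TR, PROK,
TLN, TR, TR-CTR, TR-PEP; `LysC+TR+CTR` is interpreted per its `+`
notation as one simultaneous three-enzyme step.

Unknown residues are handled conservatively and deterministically: `X`
and the ambiguity letters B/Z/U/O are never cleavage targets and never
satisfy a blocking context, so bonds flanking them stay intact unless a
neighbouring standard residue triggers a cut.

## Masses

Peptide mass = Σ residue masses + water (18.010565 Da monoisotopic /
18.01528 average); [M+H]⁺ adds one proton (1.007276 Da). The default
residue table holds the standard monoisotopic and average masses of the
20 amino-acid residues (G 57.02146, F 147.06841, P 97.05276,
Q 128.05858, …) as a data file that can be overridden per run. The
table is anchored by the requirement that any peptide of composition
F₁P₂Q₅ display [M+H]⁺ = 1000.4847 at 4 decimals — a release-blocking
test — and cross-checked against pyteomics' compositional calculator on
random sequences. Display rounding is 4 decimals; stored and compared
values are unrounded. A sequence containing any residue without a table
entry (X, B, Z, and by default U/O) has *undefined* masses — stored as
NaN, never as 0 — while #UA counts only literal `X` characters, so
B/Z/U/O make a mass undefined without inflating #UA. Neutral
monoisotopic mass and protonated mass are kept as two separate columns
throughout; consumers choose explicitly. No modifications, adducts or
charge states beyond +1 are modelled.

## Epitope matching

Matching is exact substring equality after uppercasing — no
substitutions and no deamidation (Q→E) variants, since assay-grade
identity is the point of a 100 %-identity screen. All overlapping and
repeated occurrences are recorded as separate match rows; count-based
statistics therefore count occurrences unless the distinct-epitopes
mode is requested. Epitopes identical in (sequence, cell type, disease)
collapse to one matching representative while the epitope table keeps
every assay row. Peptide-level matching runs against the deduplicated
peptide sequences: an epitope survives a workflow iff it lies within a
single product peptide, which makes the peptide–epitope table a
digestion-resistance readout consistent by construction with the
protein-level table (every peptide match translates to a protein match
at the event's absolute coordinate).

## Datastore and query semantics

Storage is one SQLite file (no server) holding the six tables plus
metadata (package version, rule-table identity, workflow list, input
checksum). Identifiers are content hashes — peptides by sequence,
events by (accession, workflow, level, start, sequence, parent
sequence) — so rebuilding from identical inputs is byte-identical; for
that reason the metadata timestamp defaults to empty and is recorded
only on request. The event-identity key makes protein–peptide
multiplicity explicit: the same peptide found at two positions, two
levels, or in two proteins is that many events, while the peptide list
view stays strictly unique by sequence.

Column filters are case-insensitive substring matches by default (the
behaviour of a list-view search box), with an exact-match flag per
filter; a filter chain reports the row count after every step and is
provably equal to the single conjunctive filter. Mass search defaults
to display-rounded equality at 4 decimals — typing a printed mass must
find the peptide it was printed from — with absolute-Da and ppm windows
as alternatives. Peptide-count matrices count digestion events by
default and unique peptides behind a flag, since a "number of peptides"
grouped by enzyme and protein type is ambiguous between the two.
In the specificity summary, the per-protein copy number is the count of
distinct start positions within a source protein, and the reported
value is the maximum over proteins when several differ. Epitope density
is (match rows passing the epitope filter) / (distinct proteins in the
group with ≥ 1 passing match); groups with no matching protein are
absent from the output, not 0/0, and duplicating a zero-match protein
provably leaves densities unchanged. Without expression data these
densities rank epitope prevalence, not allergenicity.

## Synthetic data

The fixture generator emulates the structural features the analyses
rely on: proteins are 5–9 lightly mutated copies (substitution-only,
rate 0.06, so planted coordinates stay exact) of a type-specific
P/Q-rich repeat motif between random 8-residue unique flanks, with K/R
linkers inserted between repeat blocks with probability 0.5 as designed
trypsin/Lys-C sites, and 0–3 cysteines in the C-terminal flank. Four
protein types (alpha/gamma/omega gliadin-like and an HMW-glutenin-like
motif) cycle across six Triticeae-like (organism, genome, genotype)
labels. The alpha motif is FQQPQPQQ so that thermolysin releases an
intact [M+H]⁺ = 1000.4847 marker from unmutated copies. A seven-epitope
panel (celiac T-cell 9-mers, two of them core-flagged; allergy-related
B-cell sequences; two epitopes with an internal K/R so trypsin destroys
them) is planted by overwriting at random positions with probability
0.5 per protein.

Ground truth is established *after* generation by an independent naive
scan of the finished sequences, so the manifest lists every occurrence
— planted or incidental, including partially clobbered plants — each
flagged for whether a K/R-not-before-P bond falls inside it. Randomness
is NumPy's seeded PCG64 generator; the same seed reproduces the output
files byte for byte. The generator does not emulate allele frequencies,
expression levels, indel variation or realistic length distributions
(fixture proteins are ~60–90 residues versus hundreds in real
prolamins), so passing tests demonstrate correctness of the machinery
on prolamin-*like* structure, not biological coverage of any real
sequence collection.

## Scale of the shipped checks

The test suite and acceptance script run at desk scale by design:
10–12 fixture proteins × 15 workflows (~1000–1300 events), 1000
randomized union-property cases, and exhaustive oracle comparisons on
restricted alphabets — every {K,P,Q} sequence to length 12 for trypsin
(797 160 sequences), every {F,P,Q} (or {K,P,Q}) sequence to length 8
for the other enzymes, and every target/epitope pair to lengths 7/3 for
the matcher. These alphabets cover each rule branch (target, blocker,
inert residue, N- vs C-side) exhaustively where a full 20-letter
enumeration would be astronomically redundant. Database-scale corpus
counts depend on external snapshot curation and are intentionally not
reproduced; the structural invariants above are what the package
guarantees instead.
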