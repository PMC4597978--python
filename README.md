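# cerepep

In-silico digestion and epitope analysis of cereal prolamin proteins.

Prolamins — the proline/glutamine-rich seed storage proteins of wheat,
barley, rye and oats (gliadins, glutenins, hordeins, secalins, avenins) —
are the molecular substrate of celiac disease and several wheat
allergies, and notoriously awkward for mass-spectrometry proteomics:
their P/Q-rich repeats resist trypsin, so practical workflows use other
proteases and multi-enzyme combinations. `cerepep` is a toolkit for the
computational side of that problem, aimed at proteomics and food-allergy
researchers who need to relate detected peptide masses to proteins,
species and immune-reactive epitopes:

- **Digestion engine** — predicts the peptides produced from a protein
  by six proteases (trypsin TR, chymotrypsin-low CTR, pepsin pH 1.3 PEP,
  thermolysin TLN, Lys-C, proteinase K PROK) applied singly,
  simultaneously (`LysC+TR`: union of cut sites) or sequentially
  (`PEP-CTR+TR`: the step-2 enzymes re-digest every step-1 fragment).
  Every fragment is recorded as a *digestion event* with its 1-based
  position, its level (0 = directly from the protein, 1 = from a step-1
  peptide) and full parent lineage. Cleavage specificity lives in an
  editable rule table: a bond between residues P1 and P1′ is cut when
  the residue on the enzyme's specificity side is a target and no
  blocking context (e.g. proline in P1′ for trypsin) matches.
- **Mass annotation** — average mass [M], neutral monoisotopic mass and
  singly-protonated monoisotopic mass [M+H]⁺ = Σ residues + H₂O + H⁺
  for every unique peptide, plus the count of unrecognized residues
  (#UA, the `X` characters); masses are flagged undefined rather than
  guessed when a sequence contains an `X`.
- **Epitope mapping** — exact (100 % identity) substring search of
  linear T- and B-cell epitopes against proteins and against digestion
  peptides, overlapping occurrences included. An epitope that spans a
  cut site keeps its protein-level match but disappears from the
  peptide-level table, so the peptide–epitope table reads out digestion
  resistance.
- **Datastore and queries** — the six cross-linked tables (protein,
  peptide and epitope list views; digestion events; protein–epitope and
  peptide–epitope matches) persist as a single SQLite file with CSV
  export. Query operations mirror the workflows of peptide-biomarker
  work: chained column filters with per-step hit counts, mass search
  over [M+H]⁺, per-peptide specificity summaries (proteins / copies /
  species / types / genotypes per workflow), grouped peptide-count
  matrices, and normalized epitope density — match count divided by the
  number of proteins in the group with at least one match.
- **Fixture generator** — a seeded generator of prolamin-like proteins
  (mutated repeat motifs, K/R linkers, unique flanks) with a
  ground-truth manifest of every planted epitope occurrence and its
  tryptic-cut-spanning flag, so the whole pipeline is testable offline.

## Worked example

```sh
cerepep make-fixtures --seed 1 --outdir demo
cerepep build --fasta demo/proteins.fasta --annotations demo/annotations.csv \
              --epitopes demo/epitopes.csv --out demo/store.sqlite
cerepep mass-search --store demo/store.sqlite --mass 1000.4847
```

The build digests 12 synthetic prolamins with all 15 default workflows
(`datastore demo/store.sqlite: 12 proteins, 278 peptides, 1245 events,
7 epitopes`), and the mass search prints every peptide whose displayed
[M+H]⁺ equals the query:

```
peptide_id,sequence,length,average_mass,monoisotopic_mass,protonated_monoisotopic_mass,unrecognized_count
pep-2ce2648ce56d,FQQPQPQQ,8,1000.0787799999998,999.4773950000001,1000.4846710000002,0
pep-0717b84534cf,QQPQPQQF,8,1000.0787799999998,999.477395,1000.484671,0
```

Both hits have the composition F₁P₂Q₅, so they share the mass
1000.4847 at the 4-decimal display precision (the table stores the
unrounded sums); only the sequence, and therefore the producing enzyme
and source protein, distinguishes them. Asking which workflows yield
the first hit and how specific it is:

```sh
cerepep specificity --store demo/store.sqlite --peptide FQQPQPQQ
```
```
peptide_sequence,workflow_id,n_proteins,n_peptides_in_protein,n_species,n_types,n_genotypes
FQQPQPQQ,TLN,2,2,2,1,2
```

— thermolysin releases it, from 2 proteins of 2 species but a single
protein type: a usable type-specific marker, not a species-specific
one. Normalized epitope densities per protein type × genome:

```sh
cerepep density --store demo/store.sqlite --cell-type "T cell" --disease celiac
```
```
protein_type,genome,n_matches,n_proteins_with_match,density
HMW glutenin x-type,D,4,2,2.0
alpha gliadin,D,2,1,2.0
gamma gliadin,A,3,1,3.0
...
```

`density` is celiac T-cell match rows divided by the number of proteins
in the group that carry at least one such match; groups with no
matching protein are omitted rather than reported as 0/0.

The same operations are importable directly
(`from cerepep import build_datastore, mass_search, ...`).

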