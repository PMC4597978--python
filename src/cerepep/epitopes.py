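"""Exact-substring (100%-identity) mapping of linear epitopes.

Epitopes are mapped both onto full protein sequences and onto digestion
peptides.  A peptide-level match exists only when the epitope survives
digestion intact inside a single peptide — an epitope spanning a cut
site keeps its protein-level match but loses all peptide-level matches,
which is what makes the peptide–epitope table a digestion-resistance
readout.  Matching is exact residue equality after case normalisation:
no substitutions, no deamidation variants, and ``X`` in a target never
matches any epitope letter.  Overlapping and repeated occurrences are
all recorded (the repetitive prolamin domains make these common).
"""

from __future__ import annotations

from collections.abc import Iterable

from .core import EpitopeMatch, EpitopeRecord, PeptideRecord, ProteinRecord

__all__ = [
    "find_exact_matches",
    "dedupe_epitopes",
    "match_epitopes_to_proteins",
    "match_epitopes_to_peptides",
]


def find_exact_matches(epitope_sequence: str, target_sequence: str) -> list[int]:
    """All 1-based start positions of the epitope in the target.

    Overlapping occurrences are included; positions are ascending.
    """
    if not epitope_sequence or not target_sequence:
        raise ValueError("epitope and target sequences must be non-empty")
    positions = []
    start = target_sequence.find(epitope_sequence)
    while start != -1:
        positions.append(start + 1)
        start = target_sequence.find(epitope_sequence, start + 1)
    return positions


def dedupe_epitopes(
    epitopes: Iterable[EpitopeRecord],
) -> list[EpitopeRecord]:
    """Collapse epitopes that are identical for matching purposes.

    Records reported by multiple assays collapse on the key
    (sequence, cell type, disease); the first record of each group (in
    input order) represents the group in match rows, while the full
    epitope table retains assay provenance.
    """
    seen: set[tuple[str, str, str]] = set()
    unique = []
    for ep in epitopes:
        key = (ep.sequence, ep.cell_type, ep.disease)
        if key not in seen:
            seen.add(key)
            unique.append(ep)
    return unique


def match_epitopes_to_proteins(
    epitopes: Iterable[EpitopeRecord],
    proteins: Iterable[ProteinRecord],
    dedupe: bool = True,
) -> list[EpitopeMatch]:
    """One match row per (epitope, protein, occurrence position)."""
    eps = dedupe_epitopes(epitopes) if dedupe else list(epitopes)
    matches = []
    for protein in proteins:
        for ep in eps:
            for pos in find_exact_matches(ep.sequence, protein.sequence):
                matches.append(
                    EpitopeMatch(
                        epitope_id=ep.epitope_id,
                        target_kind="protein",
                        target_id=protein.accession,
                        position=pos,
                    )
                )
    return matches


def match_epitopes_to_peptides(
    epitopes: Iterable[EpitopeRecord],
    peptides: Iterable[PeptideRecord],
    dedupe: bool = True,
) -> list[EpitopeMatch]:
    """Digestion-resistant epitopes and their harbouring peptides.

    A match exists iff the epitope is an exact substring of a single
    digestion peptide; positions are 1-based within the peptide.
    """
    eps = dedupe_epitopes(epitopes) if dedupe else list(epitopes)
    matches = []
    for peptide in peptides:
        for ep in eps:
            if len(ep.sequence) > peptide.length:
                continue
            for pos in find_exact_matches(ep.sequence, peptide.sequence):
                matches.append(
                    EpitopeMatch(
                        epitope_id=ep.epitope_id,
                        target_kind="peptide",
                        target_id=peptide.peptide_id,
                        position=pos,
                    )
                )
    return matches
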