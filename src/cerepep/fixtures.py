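"""Seeded generator of prolamin-like test data with ground truth.

Cereal seed storage proteins (prolamins) are dominated by short
proline/glutamine-rich repeat units stacked between unique N- and
C-terminal domains, which is exactly what makes their peptides and
epitopes so repetitive and their digestion so atypical.  The generator
emulates that structure: each synthetic protein is a run of lightly
mutated copies of a type-specific repeat motif, with occasional K/R
linkers between blocks (designed cleavage sites for trypsin/Lys-C) and
random unique flanks.  A panel of epitopes — some fitting inside repeat
blocks, some deliberately containing an internal K/R so that trypsin
splits them — is planted by overwriting the sequence at random
positions.

Ground truth is not inferred from the planting bookkeeping but from a
full independent scan of the finished sequences, so the manifest lists
*every* occurrence of every panel epitope (planted or incidental),
each with a flag saying whether a trypsin cut site falls inside it.
That makes the manifest an exact oracle for the epitope mapper and for
digestion-resistance behaviour.

Same seed, same spec — byte-identical outputs (NumPy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpitopeRecord, ProteinRecord

__all__ = ["FixtureSpec", "FixtureSet", "generate_fixture", "DEFAULT_EPITOPE_PANEL"]

#: (protein type, repeat motif) panel; motifs are P/Q-rich repeat units
#: of the kind the respective prolamin families carry.  The alpha motif
#: starts with F so that thermolysin (which cuts N-terminally to F)
#: releases the intact repeat FQQPQPQQ — an [M+H]+ 1000.4847 marker —
#: from unmutated copies.
DEFAULT_TYPE_PANEL: tuple[tuple[str, str], ...] = (
    ("alpha gliadin", "FQQPQPQQ"),
    ("gamma gliadin", "PQQPFPQQ"),
    ("HMW glutenin x-type", "PGQGQQ"),
    ("omega gliadin", "PFPQQPQQ"),
)

#: (organism, genome, genotype) panel cycled over the proteins.
DEFAULT_SPECIES_PANEL: tuple[tuple[str, str, str], ...] = (
    ("Triticum aestivum", "D", "Chinese Spring"),
    ("Triticum urartu", "A", ""),
    ("Aegilops tauschii", "D", ""),
    ("Hordeum vulgare", "H", "Morex"),
    ("Secale cereale", "R", "Lo7"),
    ("Aegilops speltoides", "S", ""),
)

#: Columns: id, name, sequence, cell type, core flag, disease,
#: antibody, MHC serotype, host.  The two epitopes containing an
#: internal K/R (not followed by P) are the designed cut-spanners:
#: trypsin destroys them, so they must vanish from peptide-level
#: matches while keeping their protein-level ones.
DEFAULT_EPITOPE_PANEL: tuple[tuple[str, str, str, str, bool, str, str, str, str], ...] = (
    ("EPI-T1", "alpha-9mer core", "PQPQLPYPQ", "T cell", True, "celiac disease", "", "DQ2.5", "Homo sapiens"),
    ("EPI-T2", "gamma-9mer core", "PFPQPQQPF", "T cell", True, "celiac disease", "", "DQ8", "Homo sapiens"),
    ("EPI-T3", "gamma-9mer", "QQPFPQQPQ", "T cell", False, "celiac disease", "", "DQ2.5", "Homo sapiens"),
    ("EPI-B1", "HMW repeat", "QQPGQGQQ", "B cell", False, "wheat allergy WDEIA", "IgE", "", "Homo sapiens"),
    ("EPI-B2", "omega repeat", "PQQPFPQQPQQ", "B cell", False, "allergy", "IgG", "", "Homo sapiens"),
    ("EPI-K1", "tryptic-labile T", "PQQKQQPF", "T cell", False, "celiac disease", "", "DQ2.5", "Homo sapiens"),
    ("EPI-K2", "tryptic-labile B", "QPQRFPQQ", "B cell", False, "wheat allergy WDEIA", "IgA", "", "Homo sapiens"),
)

_FLANK_ALPHABET = "ASTGVNDEM"
_SUBSTITUTION_ALPHABET = "SLYFQT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    seed: int = 1
    n_proteins: int = 12
    type_panel: tuple[tuple[str, str], ...] = DEFAULT_TYPE_PANEL
    species_panel: tuple[tuple[str, str, str], ...] = DEFAULT_SPECIES_PANEL
    epitope_panel: tuple = DEFAULT_EPITOPE_PANEL
    n_repeats_range: tuple[int, int] = (5, 9)
    flank_length: int = 8
    linker_probability: float = 0.5  # chance of a K/R linker between repeat blocks
    substitution_rate: float = 0.06  # per-residue motif mutation rate
    n_cysteines_range: tuple[int, int] = (0, 3)
    plant_probability: float = 0.5  # chance each epitope is planted in a protein

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not self.type_panel or not self.species_panel:
            raise ValueError("type and species panels must be non-empty")


@dataclass
class FixtureSet:
    """Generated records plus the ground-truth manifest."""

    spec: FixtureSpec
    proteins: list[ProteinRecord]
    epitopes: list[EpitopeRecord]
    annotations: pd.DataFrame
    manifest: pd.DataFrame  # every epitope occurrence, with resistance flag
    designed_cuts: pd.DataFrame  # K/R linker positions written between blocks

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA, annotation/epitope CSVs and the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "annotations": outdir / "annotations.csv",
            "epitopes": outdir / "epitopes.csv",
            "manifest": outdir / "manifest.csv",
            "designed_cuts": outdir / "designed_cuts.csv",
        }
        with open(paths["fasta"], "w") as fh:
            for p in self.proteins:
                fh.write(f">{p.accession}\n")
                for i in range(0, len(p.sequence), 60):
                    fh.write(p.sequence[i : i + 60] + "\n")
        self.annotations.to_csv(paths["annotations"], index=False, lineterminator="\n")
        pd.DataFrame(
            [
                {
                    "epitope_id": e.epitope_id,
                    "name": e.name,
                    "sequence": e.sequence,
                    "cell_type": e.cell_type,
                    "is_core": str(e.is_core).lower(),
                    "disease": e.disease,
                    "antibody": e.antibody,
                    "mhc_serotype": e.mhc_serotype,
                    "host": e.host,
                }
                for e in self.epitopes
            ]
        ).to_csv(paths["epitopes"], index=False, lineterminator="\n")
        self.manifest.to_csv(paths["manifest"], index=False, lineterminator="\n")
        self.designed_cuts.to_csv(paths["designed_cuts"], index=False, lineterminator="\n")
        return paths


def _scan_occurrences(sequence: str, epitope: str) -> list[int]:
    # Deliberately naive sliding-window scan: the manifest's oracle must
    # stay independent of the matcher it later validates.
    hits = []
    for p in range(len(sequence) - len(epitope) + 1):
        if sequence[p : p + len(epitope)] == epitope:
            hits.append(p + 1)
    return hits


def _has_internal_tryptic_site(sequence: str, start: int, length: int) -> bool:
    # A trypsin cut between residues j and j+1 (K/R not followed by P)
    # strictly inside [start, start+length-1] splits the occurrence.
    for j in range(start, start + length - 1):  # 1-based residue j
        if sequence[j - 1] in "KR" and sequence[j] != "P":
            return True
    return False


def _mutate(motif: str, rng: np.random.Generator, rate: float) -> str:
    out = []
    for ch in motif:
        if rng.random() < rate:
            out.append(_SUBSTITUTION_ALPHABET[rng.integers(len(_SUBSTITUTION_ALPHABET))])
        else:
            out.append(ch)
    return "".join(out)


def generate_fixture(spec: FixtureSpec, outdir: str | Path | None = None) -> FixtureSet:
    """Generate a deterministic prolamin-like dataset with ground truth."""
    rng = np.random.default_rng(spec.seed)
    proteins: list[ProteinRecord] = []
    ann_rows = []
    cut_rows = []

    panel_epitopes = [
        EpitopeRecord(
            epitope_id=eid,
            name=name,
            sequence=seq,
            cell_type=cell,
            is_core=core,
            disease=disease,
            antibody=antibody,
            mhc_serotype=mhc,
            host=host,
        )
        for eid, name, seq, cell, core, disease, antibody, mhc, host in spec.epitope_panel
    ]

    for i in range(spec.n_proteins):
        ptype, motif = spec.type_panel[i % len(spec.type_panel)]
        organism, genome, genotype = spec.species_panel[i % len(spec.species_panel)]
        accession = f"SYN{i + 1:04d}"

        n_repeats = int(rng.integers(spec.n_repeats_range[0], spec.n_repeats_range[1] + 1))
        parts = ["".join(_FLANK_ALPHABET[rng.integers(len(_FLANK_ALPHABET))] for _ in range(spec.flank_length))]
        linker_positions = []
        for r in range(n_repeats):
            parts.append(_mutate(motif, rng, spec.substitution_rate))
            if r < n_repeats - 1 and rng.random() < spec.linker_probability:
                linker_positions.append(sum(len(p) for p in parts) + 1)
                parts.append("K" if rng.random() < 0.5 else "R")
        c_flank = list(
            _FLANK_ALPHABET[rng.integers(len(_FLANK_ALPHABET))] for _ in range(spec.flank_length)
        )
        for _ in range(int(rng.integers(spec.n_cysteines_range[0], spec.n_cysteines_range[1] + 1))):
            c_flank[int(rng.integers(len(c_flank)))] = "C"
        parts.append("".join(c_flank))
        sequence = list("".join(parts))

        # Plant epitopes by overwriting; the final scan records whatever
        # survives, so later plants may legitimately clobber earlier ones.
        for ep in panel_epitopes:
            if len(ep.sequence) > len(sequence):
                raise ValueError(
                    f"epitope {ep.epitope_id} ({len(ep.sequence)} aa) longer than "
                    f"protein {accession} ({len(sequence)} aa)"
                )
            if rng.random() < spec.plant_probability:
                lo = spec.flank_length
                hi = len(sequence) - len(ep.sequence) - spec.flank_length
                pos = int(rng.integers(lo, max(lo + 1, hi)))
                sequence[pos : pos + len(ep.sequence)] = list(ep.sequence)

        seq_str = "".join(sequence)
        proteins.append(
            ProteinRecord(
                accession=accession,
                sequence=seq_str,
                protein_type=ptype,
                organism=organism,
                genotype=genotype,
                genome=genome,
            )
        )
        ann_rows.append(
            {
                "accession": accession,
                "protein_type": ptype,
                "organism": organism,
                "genotype": genotype,
                "genome": genome,
                "chromosome": "",
                "allele": "",
                "gene_ids": "",
            }
        )
        for pos in linker_positions:
            cut_rows.append(
                {"accession": accession, "position": pos, "residue": seq_str[pos - 1]}
            )

    manifest_rows = []
    for protein in proteins:
        for ep in panel_epitopes:
            for pos in _scan_occurrences(protein.sequence, ep.sequence):
                manifest_rows.append(
                    {
                        "accession": protein.accession,
                        "epitope_id": ep.epitope_id,
                        "epitope_sequence": ep.sequence,
                        "position": pos,
                        "spans_tryptic_cut": _has_internal_tryptic_site(
                            protein.sequence, pos, len(ep.sequence)
                        ),
                    }
                )

    fixture = FixtureSet(
        spec=spec,
        proteins=proteins,
        epitopes=panel_epitopes,
        annotations=pd.DataFrame(ann_rows),
        manifest=pd.DataFrame(
            manifest_rows,
            columns=[
                "accession",
                "epitope_id",
                "epitope_sequence",
                "position",
                "spans_tryptic_cut",
            ],
        ),
        designed_cuts=pd.DataFrame(cut_rows, columns=["accession", "position", "residue"]),
    )
    if outdir is not None:
        fixture.write(outdir)
    return fixture
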