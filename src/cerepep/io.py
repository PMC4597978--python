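"""Readers for the delimited inputs: FASTA, annotation and epitope tables.

Annotation and epitope tables accept comma- or tab-separated text; the
delimiter is sniffed from the header line (a tab wins if present, since
curation tables commonly come out of spreadsheets either way).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .core import EpitopeRecord, ProteinRecord

__all__ = [
    "RunConfig",
    "read_fasta",
    "read_annotation_table",
    "read_epitope_table",
    "apply_annotations",
    "sniff_delimiter",
]

logger = logging.getLogger("cerepep")

ANNOTATION_REQUIRED = ("accession",)
ANNOTATION_OPTIONAL = (
    "protein_type",
    "organism",
    "genotype",
    "genome",
    "chromosome",
    "allele",
    "gene_ids",
)
EPITOPE_REQUIRED = ("epitope_id", "sequence", "cell_type")
EPITOPE_OPTIONAL = ("name", "is_core", "disease", "antibody", "mhc_serotype", "host")


@dataclass
class RunConfig:
    """Resolved configuration of one run (mirrors the CLI flags)."""

    fasta: str = ""
    annotations: str = ""
    epitopes: str = ""
    rule_table: str = ""
    mass_table: str = ""
    workflows: tuple[str, ...] = ("default15",)
    output_dir: str = "."
    unique_peptides: bool = False
    distinct_epitopes: bool = False
    seed: int = 0
    log_level: str = "INFO"
    extra: dict[str, str] = field(default_factory=dict)


def sniff_delimiter(path: str | Path) -> str:
    """Guess the column delimiter from the first non-empty line."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: empty file")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences; the accession is the first header token.

    Annotation fields are left empty for a later join against an
    annotation table.  Duplicate accessions are rejected.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id.strip()
        if not accession:
            raise ValueError(f"{path}: FASTA entry with empty header")
        if accession in seen:
            raise ValueError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        records.append(ProteinRecord(accession=accession, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_annotation_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a protein annotation table keyed by accession.

    Required column: accession.  Recognized optional columns:
    protein_type, organism, genotype, genome, chromosome, allele,
    gene_ids (``;``-separated).  Empty cells stay empty strings.
    """
    df = pd.read_csv(path, sep=sniff_delimiter(path), dtype=str).fillna("")
    df.columns = [c.strip() for c in df.columns]
    missing = set(ANNOTATION_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    mapping: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        acc = row["accession"].strip()
        mapping[acc] = {
            col: row.get(col, "").strip() for col in ANNOTATION_OPTIONAL if col in df.columns
        }
    return mapping


def apply_annotations(
    proteins: list[ProteinRecord], annotations: dict[str, dict[str, str]]
) -> list[ProteinRecord]:
    """Join annotation fields onto protein records by accession.

    Annotation rows for accessions absent from the protein set are
    warned about but not fatal.
    """
    known = {p.accession for p in proteins}
    for acc in annotations:
        if acc not in known:
            logger.warning("annotation for unknown accession %r ignored", acc)
    annotated = []
    for p in proteins:
        ann = annotations.get(p.accession, {})
        gene_ids = tuple(g for g in ann.get("gene_ids", "").split(";") if g)
        annotated.append(
            ProteinRecord(
                accession=p.accession,
                sequence=p.sequence,
                protein_type=ann.get("protein_type", p.protein_type),
                organism=ann.get("organism", p.organism),
                genotype=ann.get("genotype", p.genotype),
                genome=ann.get("genome", p.genome),
                chromosome=ann.get("chromosome", p.chromosome),
                allele=ann.get("allele", p.allele),
                gene_ids=gene_ids or p.gene_ids,
            )
        )
    return annotated


_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def _parse_bool(value: str, *, context: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise ValueError(f"{context}: cannot interpret {value!r} as a boolean")


def read_epitope_table(path: str | Path) -> list[EpitopeRecord]:
    """Read and validate an epitope table.

    Required columns: epitope_id, sequence, cell_type.  The record
    constructor enforces the domain invariants (known cell type; the
    core flag only on 9-residue T-cell epitopes).
    """
    df = pd.read_csv(path, sep=sniff_delimiter(path), dtype=str).fillna("")
    df.columns = [c.strip() for c in df.columns]
    missing = set(EPITOPE_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            EpitopeRecord(
                epitope_id=row["epitope_id"].strip(),
                sequence=row["sequence"],
                cell_type=row["cell_type"].strip(),
                name=row.get("name", "").strip(),
                is_core=_parse_bool(
                    row.get("is_core", ""), context=f"epitope {row['epitope_id']}"
                ),
                disease=row.get("disease", "").strip(),
                antibody=row.get("antibody", "").strip(),
                mhc_serotype=row.get("mhc_serotype", "").strip(),
                host=row.get("host", "").strip(),
            )
        )
    return records
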