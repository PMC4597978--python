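"""Relational datastore over proteins, peptides, epitopes and their links.

Six tables mirror the list and connection views of a prolamin peptide
resource: the protein, peptide and epitope list views, the digestion
(protein–peptide) events, and the protein–epitope and peptide–epitope
matching tables, cross-connected by deterministic content-hash ids.
Persistence is a single-file SQLite database plus CSV import/export; a
rebuild from identical inputs reproduces byte-identical tables.

The query layer implements the workflows a user of such a resource
runs: chained column filters with per-step hit counts, search by
detected [M+H]+ mass, per-peptide specificity summaries (how many
proteins/species/types/genotypes yield a peptide, per workflow),
grouped peptide-count matrices, and normalized epitope density
(matches divided by the number of proteins with at least one match).
"""

from __future__ import annotations

import hashlib
import sqlite3
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cleavage import EnzymeRule, default_rules, digest_all
from .core import (
    DigestionWorkflow,
    EpitopeRecord,
    ProteinRecord,
    default_workflows,
    peptide_id_for,
)
from .epitopes import match_epitopes_to_peptides, match_epitopes_to_proteins
from .masses import (
    MassTable,
    average_mass,
    count_unrecognized,
    default_mass_table,
    display_round,
    monoisotopic_mass,
    protonated_mass,
)

__all__ = [
    "Datastore",
    "SpecificityRow",
    "build_datastore",
    "filter_chain",
    "mass_search",
    "peptide_specificity_summary",
    "peptide_count_matrix",
    "epitope_density",
    "export_csv",
    "import_csv",
]

TABLE_NAMES = (
    "proteins",
    "peptides",
    "epitopes",
    "digestion_events",
    "protein_epitope_matches",
    "peptide_epitope_matches",
)

PROTEIN_COLUMNS = [
    "accession",
    "length",
    "sequence",
    "protein_type",
    "organism",
    "genotype",
    "genome",
    "chromosome",
    "allele",
    "gene_ids",
]
PEPTIDE_COLUMNS = [
    "peptide_id",
    "sequence",
    "length",
    "average_mass",
    "monoisotopic_mass",
    "protonated_monoisotopic_mass",
    "unrecognized_count",
]
EPITOPE_COLUMNS = [
    "epitope_id",
    "name",
    "sequence",
    "cell_type",
    "is_core",
    "disease",
    "antibody",
    "mhc_serotype",
    "host",
]
EVENT_COLUMNS = [
    "event_id",
    "protein_accession",
    "workflow_id",
    "level",
    "step_enzymes",
    "start",
    "peptide_sequence",
    "peptide_id",
    "parent_enzymes",
    "parent_peptide_sequence",
]
MATCH_COLUMNS = ["epitope_id", "target_kind", "target_id", "position"]


@dataclass
class Datastore:
    """In-memory image of the six cross-linked tables plus metadata."""

    proteins: pd.DataFrame
    peptides: pd.DataFrame
    epitopes: pd.DataFrame
    digestion_events: pd.DataFrame
    protein_epitope_matches: pd.DataFrame
    peptide_epitope_matches: pd.DataFrame
    metadata: dict[str, str] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLE_NAMES:
            raise KeyError(f"unknown table {name!r}; choose from {TABLE_NAMES}")
        return getattr(self, name)

    def validate(self) -> None:
        """Check referential integrity and uniqueness invariants."""
        accessions = set(self.proteins["accession"])
        if len(accessions) != len(self.proteins):
            raise ValueError("duplicate protein accessions")
        if self.peptides["sequence"].duplicated().any():
            raise ValueError("duplicate peptide sequences")
        if self.digestion_events["event_id"].duplicated().any():
            raise ValueError("duplicate digestion events")
        bad = set(self.digestion_events["protein_accession"]) - accessions
        if bad:
            raise ValueError(f"events reference unknown accessions: {sorted(bad)}")
        epitope_ids = set(self.epitopes["epitope_id"])
        peptide_ids = set(self.peptides["peptide_id"])
        for tbl, targets in (
            (self.protein_epitope_matches, accessions),
            (self.peptide_epitope_matches, peptide_ids),
        ):
            if not set(tbl["epitope_id"]) <= epitope_ids:
                raise ValueError("match rows reference unknown epitopes")
            if not set(tbl["target_id"]) <= targets:
                raise ValueError("match rows reference unknown targets")

    def save(self, path: str | Path) -> None:
        """Write all tables and metadata to a single SQLite file."""
        path = Path(path)
        if path.exists():
            path.unlink()
        with sqlite3.connect(path) as conn:
            for name in TABLE_NAMES:
                self.table(name).to_sql(name, conn, index=False)
            meta = pd.DataFrame(
                sorted(self.metadata.items()), columns=["key", "value"]
            )
            meta.to_sql("metadata", conn, index=False)
        conn.close()

    @classmethod
    def load(cls, path: str | Path) -> "Datastore":
        with sqlite3.connect(Path(path)) as conn:
            tables = {
                name: pd.read_sql(f"SELECT * FROM {name}", conn)
                for name in TABLE_NAMES
            }
            meta_df = pd.read_sql("SELECT * FROM metadata", conn)
        conn.close()
        tables["epitopes"]["is_core"] = tables["epitopes"]["is_core"].astype(bool)
        for tbl in ("proteins", "epitopes", "digestion_events"):
            tables[tbl] = tables[tbl].fillna("")
        return cls(metadata=dict(zip(meta_df["key"], meta_df["value"])), **tables)


@dataclass(frozen=True)
class SpecificityRow:
    """One row of a per-peptide specificity summary."""

    peptide_sequence: str
    workflow_id: str
    n_proteins: int
    n_peptides_in_protein: int
    n_species: int
    n_types: int
    n_genotypes: int


def _input_checksum(proteins: Sequence[ProteinRecord], epitopes: Sequence[EpitopeRecord]) -> str:
    h = hashlib.sha1()
    for p in sorted(proteins, key=lambda p: p.accession):
        h.update(f"{p.accession}:{p.sequence}\n".encode())
    for e in sorted(epitopes, key=lambda e: e.epitope_id):
        h.update(f"{e.epitope_id}:{e.sequence}\n".encode())
    return h.hexdigest()


def build_datastore(
    proteins: Sequence[ProteinRecord],
    epitopes: Sequence[EpitopeRecord] = (),
    workflows: Sequence[DigestionWorkflow] | None = None,
    rules: dict[str, EnzymeRule] | None = None,
    mass_table: MassTable | None = None,
    rule_table_name: str = "baseline",
    timestamp: str = "",
) -> Datastore:
    """Digest, annotate and cross-link everything into one datastore.

    Runs every workflow on every protein, deduplicates peptides by
    sequence, annotates each peptide with its masses and #UA, maps the
    epitopes onto both proteins and peptides, and assembles the six
    tables.  ``timestamp`` is empty by default so that two builds from
    identical inputs are byte-identical; pass a value to record one.
    """
    proteins = list(proteins)
    epitopes = list(epitopes)
    accs = [p.accession for p in proteins]
    if len(set(accs)) != len(accs):
        dupes = sorted({a for a in accs if accs.count(a) > 1})
        raise ValueError(f"duplicate protein accessions: {dupes}")
    eids = [e.epitope_id for e in epitopes]
    if len(set(eids)) != len(eids):
        raise ValueError("duplicate epitope ids")
    if workflows is None:
        workflows = default_workflows()
    if rules is None:
        rules = default_rules()
    if mass_table is None:
        mass_table = default_mass_table()

    events = digest_all(proteins, workflows, rules)

    protein_df = pd.DataFrame(
        [
            {
                "accession": p.accession,
                "length": p.length,
                "sequence": p.sequence,
                "protein_type": p.protein_type,
                "organism": p.organism,
                "genotype": p.genotype,
                "genome": p.genome,
                "chromosome": p.chromosome,
                "allele": p.allele,
                "gene_ids": ";".join(p.gene_ids),
            }
            for p in proteins
        ],
        columns=PROTEIN_COLUMNS,
    )

    unique_sequences = sorted({e.peptide_sequence for e in events})
    peptide_rows = []
    for seq in unique_sequences:
        mono = monoisotopic_mass(seq, mass_table)
        peptide_rows.append(
            {
                "peptide_id": peptide_id_for(seq),
                "sequence": seq,
                "length": len(seq),
                "average_mass": average_mass(seq, mass_table),
                "monoisotopic_mass": mono,
                "protonated_monoisotopic_mass": protonated_mass(seq, mass_table),
                "unrecognized_count": count_unrecognized(seq),
            }
        )
    peptide_df = pd.DataFrame(peptide_rows, columns=PEPTIDE_COLUMNS).astype(
        {
            "average_mass": float,
            "monoisotopic_mass": float,
            "protonated_monoisotopic_mass": float,
        }
    )

    epitope_df = pd.DataFrame(
        [
            {
                "epitope_id": e.epitope_id,
                "name": e.name,
                "sequence": e.sequence,
                "cell_type": e.cell_type,
                "is_core": e.is_core,
                "disease": e.disease,
                "antibody": e.antibody,
                "mhc_serotype": e.mhc_serotype,
                "host": e.host,
            }
            for e in epitopes
        ],
        columns=EPITOPE_COLUMNS,
    )
    if epitope_df.empty:
        epitope_df = epitope_df.astype({"is_core": bool})

    event_df = pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "protein_accession": e.protein_accession,
                "workflow_id": e.workflow_id,
                "level": e.level,
                "step_enzymes": "+".join(e.step_enzymes),
                "start": e.start,
                "peptide_sequence": e.peptide_sequence,
                "peptide_id": peptide_id_for(e.peptide_sequence),
                "parent_enzymes": "+".join(e.parent_enzymes),
                "parent_peptide_sequence": e.parent_peptide_sequence,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )
    if event_df.empty:
        event_df = event_df.astype({"level": int, "start": int})

    # Peptide-level matches run against the deduplicated peptide set;
    # digestion resistance is a property of the sequence, not the event.
    from .core import PeptideRecord  # local import to avoid cycle at module load

    peptide_records = [PeptideRecord(sequence=s) for s in unique_sequences]
    prot_matches = match_epitopes_to_proteins(epitopes, proteins)
    pep_matches = match_epitopes_to_peptides(epitopes, peptide_records)
    prot_match_df = pd.DataFrame(
        [
            {
                "epitope_id": m.epitope_id,
                "target_kind": m.target_kind,
                "target_id": m.target_id,
                "position": m.position,
            }
            for m in prot_matches
        ],
        columns=MATCH_COLUMNS,
    )
    pep_match_df = pd.DataFrame(
        [
            {
                "epitope_id": m.epitope_id,
                "target_kind": m.target_kind,
                "target_id": m.target_id,
                "position": m.position,
            }
            for m in pep_matches
        ],
        columns=MATCH_COLUMNS,
    )
    for df in (prot_match_df, pep_match_df):
        if df.empty:
            df["position"] = df["position"].astype(int)

    store = Datastore(
        proteins=protein_df,
        peptides=peptide_df,
        epitopes=epitope_df,
        digestion_events=event_df,
        protein_epitope_matches=prot_match_df,
        peptide_epitope_matches=pep_match_df,
        metadata={
            "package_version": _pkg_version,
            "rule_table": rule_table_name,
            "n_workflows": str(len(workflows)),
            "workflow_ids": ",".join(w.workflow_id for w in workflows),
            "input_checksum": _input_checksum(proteins, epitopes),
            "build_timestamp": timestamp,
        },
    )
    store.validate()
    return store


def filter_chain(
    table: pd.DataFrame,
    filters: Sequence[tuple],
) -> tuple[pd.DataFrame, list[int]]:
    """Apply ordered conjunctive column filters, reporting hit counts.

    Each filter is ``(column, pattern)`` or ``(column, pattern, exact)``.
    The default is a case-insensitive substring match (the behaviour of
    a column search box); pass ``exact=True`` for whole-value equality.
    Returns the surviving rows and the row count after each step —
    the "number of entries" readout of a step-by-step query.
    """
    subset = table
    counts: list[int] = []
    for spec in filters:
        if len(spec) == 2:
            column, pattern = spec
            exact = False
        else:
            column, pattern, exact = spec
        if column not in subset.columns:
            raise KeyError(f"unknown column {column!r}")
        col = subset[column].astype(str)
        if exact:
            mask = col.str.lower() == str(pattern).lower()
        else:
            mask = col.str.contains(str(pattern), case=False, regex=False)
        subset = subset[mask]
        counts.append(len(subset))
    return subset, counts


def mass_search(
    store: Datastore,
    query_mass: float,
    mode: str = "display",
    tolerance: float = 0.0,
) -> pd.DataFrame:
    """Peptides whose [M+H]+ matches a detected mass.

    Modes: ``display`` — equality after rounding both sides to the
    4-decimal display precision (the behaviour of typing a printed mass
    into a column search box); ``absolute`` — |m - q| <= tolerance Da;
    ``ppm`` — |m - q| <= q * tolerance * 1e-6.  Peptides with undefined
    mass (#UA > 0) never match.
    """
    if mode not in ("display", "absolute", "ppm"):
        raise ValueError(f"unknown mass-search mode {mode!r}")
    if mode != "display" and tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    masses = store.peptides["protonated_monoisotopic_mass"]
    defined = masses.notna()
    if mode == "display":
        mask = defined & (masses.round(4) == round(query_mass, 4))
    elif mode == "absolute":
        mask = defined & ((masses - query_mass).abs() <= tolerance)
    else:
        mask = defined & (
            (masses - query_mass).abs() <= abs(query_mass) * tolerance * 1e-6
        )
    return store.peptides[mask].reset_index(drop=True)


def peptide_specificity_summary(
    store: Datastore, peptide_sequence: str
) -> pd.DataFrame:
    """Per-workflow specificity of one peptide across the protein set.

    For every workflow that yields the peptide: the number of distinct
    source proteins, the copy count within a source protein (distinct
    start positions; the maximum over proteins when several differ),
    and the numbers of distinct species, protein types and genotypes
    carrying the peptide.
    """
    events = store.digestion_events
    hits = events[events["peptide_sequence"] == peptide_sequence]
    if hits.empty:
        raise KeyError(f"peptide {peptide_sequence!r} not found in datastore")
    joined = hits.merge(
        store.proteins, left_on="protein_accession", right_on="accession"
    )
    rows = []
    for workflow_id, grp in joined.groupby("workflow_id", sort=True):
        copies = grp.groupby("protein_accession")["start"].nunique()
        genotypes = grp.loc[grp["genotype"] != "", "genotype"]
        rows.append(
            {
                "peptide_sequence": peptide_sequence,
                "workflow_id": workflow_id,
                "n_proteins": int(grp["protein_accession"].nunique()),
                "n_peptides_in_protein": int(copies.max()),
                "n_species": int(grp["organism"].nunique()),
                "n_types": int(grp["protein_type"].nunique()),
                "n_genotypes": int(genotypes.nunique()),
            }
        )
    return pd.DataFrame(rows)


def peptide_count_matrix(
    store: Datastore,
    row_group: str = "protein_type",
    col_group: str = "workflow_id",
    scope: Sequence[tuple] = (),
    unique_peptides: bool = False,
) -> pd.DataFrame:
    """Counts of digestion products grouped two ways, with margins.

    Cells count digestion events by default, or distinct peptide
    sequences with ``unique_peptides=True``.  ``scope`` is a filter
    chain applied to the event table joined with protein annotations
    before counting.  A "Grand Total" row and column hold the margins.
    """
    joined = store.digestion_events.merge(
        store.proteins, left_on="protein_accession", right_on="accession"
    )
    if scope:
        joined, _ = filter_chain(joined, scope)
    for col in (row_group, col_group):
        if col not in joined.columns:
            raise KeyError(f"unknown grouping column {col!r}")
    if joined.empty:
        return pd.DataFrame({"Grand Total": [0]}, index=pd.Index(["Grand Total"], name=row_group))
    if unique_peptides:
        counts = joined.groupby([row_group, col_group])["peptide_id"].nunique()
    else:
        counts = joined.groupby([row_group, col_group])["event_id"].count()
    matrix = counts.unstack(col_group, fill_value=0)
    matrix["Grand Total"] = matrix.sum(axis=1)
    matrix.loc["Grand Total"] = matrix.sum(axis=0)
    return matrix


def epitope_density(
    store: Datastore,
    group_by: Sequence[str] = ("protein_type", "genome"),
    cell_type: str | None = None,
    disease: str | None = None,
    core_only: bool = False,
    distinct_epitopes: bool = False,
) -> pd.DataFrame:
    """Normalized epitope density per protein group.

    For each group of proteins (e.g. protein type × genome), the number
    of protein–epitope match rows passing the epitope filter divided by
    the number of distinct proteins in the group with at least one
    passing match.  Groups without any matching protein are absent from
    the result rather than reported as 0/0.  ``distinct_epitopes``
    counts distinct epitopes instead of match rows (overlapping and
    repeated occurrences otherwise count separately).
    """
    matches = store.protein_epitope_matches.merge(
        store.epitopes, on="epitope_id"
    ).merge(store.proteins, left_on="target_id", right_on="accession")
    if cell_type is not None:
        matches = matches[matches["cell_type"] == cell_type]
    if disease is not None:
        matches = matches[
            matches["disease"].str.contains(disease, case=False, regex=False)
        ]
    if core_only:
        matches = matches[matches["is_core"]]
    group_by = list(group_by)
    for col in group_by:
        if col not in matches.columns:
            raise KeyError(f"unknown grouping column {col!r}")
    if matches.empty:
        return pd.DataFrame(
            columns=[*group_by, "n_matches", "n_proteins_with_match", "density"]
        )
    rows = []
    for key, grp in matches.groupby(group_by, sort=True):
        if len(group_by) == 1:
            key = (key,)
        n_matches = (
            int(grp["epitope_id"].nunique()) if distinct_epitopes else len(grp)
        )
        n_proteins = int(grp["accession"].nunique())
        rows.append(
            {
                **dict(zip(group_by, key)),
                "n_matches": n_matches,
                "n_proteins_with_match": n_proteins,
                "density": n_matches / n_proteins,
            }
        )
    return pd.DataFrame(rows)


def export_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as RFC-4180-style CSV (header row, UTF-8, LF)."""
    df = table.reset_index() if table.index.name else table
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def import_csv(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`export_csv`.

    Empty cells stay empty strings in text columns (they are real
    values in the annotation schema) but become NaN in numeric columns
    (undefined masses).
    """
    df = pd.read_csv(path, keep_default_na=False, dtype=str)
    for col in df.columns:
        non_empty = df[col][df[col] != ""]
        if non_empty.empty:
            continue
        numeric = pd.to_numeric(non_empty, errors="coerce")
        if not numeric.isna().any():
            df[col] = pd.to_numeric(df[col].replace("", np.nan))
    return df
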