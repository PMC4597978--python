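"""Domain types shared across the toolkit.

The objects here mirror the three list views of a prolamin peptide
datastore (proteins, peptides, epitopes) and the connection records that
link them: digestion events with level-0/level-1 lineage and exact
epitope matches.  Positions are 1-based and inclusive throughout; the
residue at position ``p`` of a sequence ``s`` is ``s[p - 1]``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

__all__ = [
    "ENZYME_CODES",
    "AMBIGUOUS_RESIDUES",
    "STANDARD_RESIDUES",
    "ProteinRecord",
    "DigestionWorkflow",
    "DigestionEvent",
    "PeptideRecord",
    "EpitopeRecord",
    "EpitopeMatch",
    "parse_workflow",
    "format_workflow",
    "default_workflows",
    "peptide_id_for",
    "event_id_for",
    "normalize_sequence",
]

#: The six proteolytic enzymes of the default digestion panel:
#: trypsin, chymotrypsin (low specificity), pepsin at pH 1.3,
#: thermolysin, endoproteinase Lys-C and proteinase K.
ENZYME_CODES = ("TR", "CTR", "PEP", "TLN", "LysC", "PROK")

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Letters with ambiguous or non-standard meaning.  They are never a
#: cleavage target, never satisfy a blocking context and carry no mass
#: in the default table.  Only ``X`` counts toward #UA.
AMBIGUOUS_RESIDUES = frozenset("XBZUO")

#: Ids of the 15 default digestion workflows.  ``+`` joins enzymes
#: applied simultaneously within one step, ``-`` separates step 1 from
#: step 2 of a sequential digestion.
DEFAULT_WORKFLOW_IDS = (
    "CTR",
    "CTR-PEP",
    "CTR-TR",
    "LysC",
    "LysC+TR",
    "LysC+TR+CTR",
    "PEP",
    "PEP-CTR",
    "PEP-CTR+TR",
    "PEP-TR",
    "PROK",
    "TLN",
    "TR",
    "TR-CTR",
    "TR-PEP",
)


def normalize_sequence(sequence: str) -> str:
    """Uppercase a residue string, stripping surrounding whitespace."""
    return sequence.strip().upper()


def _validate_sequence(sequence: str, *, what: str = "sequence") -> None:
    bad = set(sequence) - STANDARD_RESIDUES - AMBIGUOUS_RESIDUES
    if bad:
        raise ValueError(f"{what} contains non-residue characters: {sorted(bad)}")


@dataclass(frozen=True)
class ProteinRecord:
    """An annotated full-length protein sequence (one Protein-view row).

    Only ``accession`` and ``sequence`` are required; the curation
    columns (protein type, organism, genotype, genome, chromosome,
    allele, coding-gene ids) are joined later from an annotation table.
    """

    accession: str
    sequence: str
    protein_type: str = ""
    organism: str = ""
    genotype: str = ""
    genome: str = ""
    chromosome: str = ""
    allele: str = ""
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.accession}: empty sequence")
        _validate_sequence(self.sequence, what=f"protein {self.accession}")

    @property
    def length(self) -> int:
        """Sequence length L in residues."""
        return len(self.sequence)


@dataclass(frozen=True)
class DigestionWorkflow:
    """An ordered one- or two-step enzymatic digestion recipe.

    ``steps`` holds, per step, the enzyme codes applied simultaneously
    in that step, in the order they appear in the workflow id (order is
    cosmetic; cleavage uses the set union).
    """

    workflow_id: str
    steps: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.steps) <= 2:
            raise ValueError("a workflow has one or two steps")
        for step in self.steps:
            if not step:
                raise ValueError("empty digestion step")
            for code in step:
                if code not in ENZYME_CODES:
                    raise ValueError(f"unknown enzyme code: {code!r}")
            if len(set(step)) != len(step):
                raise ValueError(f"duplicate enzyme within a step: {step}")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def step_enzymes(self, step_index: int) -> frozenset[str]:
        """Enzyme codes of step ``step_index`` (0-based) as a set."""
        return frozenset(self.steps[step_index])


def parse_workflow(notation: str) -> DigestionWorkflow:
    """Parse a workflow id such as ``"PEP-CTR+TR"``.

    ``+`` joins enzymes applied simultaneously within one step; ``-``
    separates the first from the second step.  At most two steps are
    allowed and every code must be one of the six known enzymes.
    """
    notation = notation.strip()
    if not notation:
        raise ValueError("empty workflow notation")
    step_parts = notation.split("-")
    if len(step_parts) > 2:
        raise ValueError(f"workflow {notation!r}: more than two '-'-separated steps")
    steps = []
    for part in step_parts:
        codes = tuple(c.strip() for c in part.split("+"))
        for code in codes:
            if code not in ENZYME_CODES:
                raise ValueError(
                    f"workflow {notation!r}: unknown enzyme code {code!r}"
                )
        steps.append(codes)
    return DigestionWorkflow(workflow_id=format_workflow_steps(tuple(steps)), steps=tuple(steps))


def format_workflow_steps(steps: tuple[tuple[str, ...], ...]) -> str:
    return "-".join("+".join(step) for step in steps)


def format_workflow(workflow: DigestionWorkflow) -> str:
    """Inverse of :func:`parse_workflow`."""
    return format_workflow_steps(workflow.steps)


def default_workflows() -> list[DigestionWorkflow]:
    """The 15 standard single- and multi-step digestion workflows."""
    return [parse_workflow(w) for w in DEFAULT_WORKFLOW_IDS]


def peptide_id_for(sequence: str) -> str:
    """Deterministic content-hash id for a peptide sequence."""
    digest = hashlib.sha1(sequence.encode("ascii")).hexdigest()
    return f"pep-{digest[:12]}"


def event_id_for(
    protein_accession: str,
    workflow_id: str,
    level: int,
    start: int,
    peptide_sequence: str,
    parent_peptide_sequence: str = "",
) -> str:
    """Deterministic id for a digestion event.

    Event identity is the tuple (protein accession, workflow, level,
    start, peptide sequence, parent peptide sequence); rebuilding a
    datastore from identical inputs therefore reproduces identical ids.
    """
    key = "|".join(
        (
            protein_accession,
            workflow_id,
            str(level),
            str(start),
            peptide_sequence,
            parent_peptide_sequence,
        )
    )
    return f"evt-{hashlib.sha1(key.encode('ascii')).hexdigest()[:16]}"


@dataclass(frozen=True)
class DigestionEvent:
    """One peptide produced from one parent by one digestion step.

    ``level`` 0 means the peptide came directly from the protein
    (step 1); level 1 means it came from a level-0 peptide in step 2 of
    a sequential workflow, in which case ``parent_enzymes`` and
    ``parent_peptide_sequence`` identify the step-1 fragment.  ``start``
    is the 1-based position of the peptide's first residue in the
    protein, also for level-1 events (absolute coordinates).
    """

    protein_accession: str
    workflow_id: str
    step_enzymes: tuple[str, ...]
    peptide_sequence: str
    start: int
    level: int
    parent_enzymes: tuple[str, ...] = ()
    parent_peptide_sequence: str = ""

    def __post_init__(self) -> None:
        if self.level not in (0, 1):
            raise ValueError("level must be 0 or 1")
        if self.start < 1:
            raise ValueError("start is 1-based and must be >= 1")
        if self.level == 0 and (self.parent_enzymes or self.parent_peptide_sequence):
            raise ValueError("level-0 events have empty parent fields")
        if self.level == 1:
            if not self.parent_peptide_sequence or not self.parent_enzymes:
                raise ValueError("level-1 events require parent lineage")
            if self.peptide_sequence not in self.parent_peptide_sequence:
                raise ValueError("level-1 peptide must be a substring of its parent")

    @property
    def event_id(self) -> str:
        return event_id_for(
            self.protein_accession,
            self.workflow_id,
            self.level,
            self.start,
            self.peptide_sequence,
            self.parent_peptide_sequence,
        )

    @property
    def end(self) -> int:
        """1-based inclusive position of the peptide's last residue."""
        return self.start + len(self.peptide_sequence) - 1

    def check_against(self, protein_sequence: str) -> None:
        """Raise unless the positional invariant holds for this event."""
        sub = protein_sequence[self.start - 1 : self.end]
        if sub != self.peptide_sequence:
            raise AssertionError(
                f"event {self.event_id}: protein[{self.start}:{self.end}] = "
                f"{sub!r} != {self.peptide_sequence!r}"
            )


@dataclass(frozen=True)
class PeptideRecord:
    """A deduplicated peptide sequence with mass annotations.

    Masses are ``None`` (undefined) whenever the sequence contains a
    residue without a defined mass; ``unrecognized_count`` (#UA) counts
    only literal ``X`` characters.
    """

    sequence: str
    average_mass: float | None = None
    monoisotopic_mass: float | None = None
    protonated_monoisotopic_mass: float | None = None
    unrecognized_count: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")

    @property
    def peptide_id(self) -> str:
        return peptide_id_for(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EpitopeRecord:
    """A linear T- or B-cell epitope (one Epitope-view row)."""

    epitope_id: str
    sequence: str
    cell_type: str  # "T cell" or "B cell"
    name: str = ""
    is_core: bool = False
    disease: str = ""
    antibody: str = ""  # IgE/IgG/IgA, B-cell epitopes only
    mhc_serotype: str = ""
    host: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if not self.sequence:
            raise ValueError(f"epitope {self.epitope_id}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"epitope {self.epitope_id}: non-standard residues {sorted(bad)}"
            )
        if self.cell_type not in ("T cell", "B cell"):
            raise ValueError(
                f"epitope {self.epitope_id}: cell_type must be 'T cell' or "
                f"'B cell', got {self.cell_type!r}"
            )
        # Core epitopes are the 9-residue celiac T-cell registers.
        if self.is_core and (self.cell_type != "T cell" or len(self.sequence) != 9):
            raise ValueError(
                f"epitope {self.epitope_id}: core flag allowed only for "
                f"9-residue T-cell epitopes"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EpitopeMatch:
    """An exact-substring occurrence of an epitope in a target sequence.

    ``target_kind`` is ``"protein"`` or ``"peptide"``; ``position`` is
    the 1-based start of the epitope within the target.
    """

    epitope_id: str
    target_kind: str
    target_id: str
    position: int

    def __post_init__(self) -> None:
        if self.target_kind not in ("protein", "peptide"):
            raise ValueError("target_kind must be 'protein' or 'peptide'")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
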