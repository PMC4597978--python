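"""Rule-table-driven in-silico proteolytic digestion.

An enzyme's specificity is expressed as (i) the side of the scissile
bond carrying the specificity letter (C-terminal: target at P1;
N-terminal: target at P1'), (ii) the set of target residues and (iii)
blocking contexts — predicates over the positions P2, P1, P1', P2'
around the candidate bond that leave the bond intact when matched
(e.g. trypsin does not cleave Lys-Pro or Arg-Pro bonds).

Cut sites are bond indices: site ``i`` cuts between residues ``i`` and
``i + 1`` (1-based residue numbering), so valid sites lie strictly
between 0 and the sequence length.  Digestion is modelled as complete:
fragments are the maximal substrings between cut sites.  A simultaneous
multi-enzyme step uses the union of the per-enzyme site sets; a
sequential two-step workflow digests each step-1 fragment again with
the step-2 enzyme set, yielding level-0 and level-1 digestion events
with full parent lineage.

Unknown residues (X, and the ambiguity letters B/Z/U/O) are handled
conservatively: they are never a cleavage target and never satisfy a
blocking context, so bonds flanking them stay intact unless another
residue triggers cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .core import (
    AMBIGUOUS_RESIDUES,
    DigestionEvent,
    DigestionWorkflow,
    ProteinRecord,
)

__all__ = [
    "EnzymeRule",
    "CutSiteSet",
    "load_rule_table",
    "default_rules",
    "find_cut_sites",
    "digest_simultaneous",
    "run_workflow",
    "digest_all",
]

#: Offsets of the Schechter–Berger context positions relative to the
#: bond between residues i and i+1 (offset is added to i).
_POSITION_OFFSETS = {"P2": -1, "P1": 0, "P1'": 1, "P2'": 2}


@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage specificity of one enzyme.

    ``site_side`` is ``"C"`` (cleave C-terminal to a target residue) or
    ``"N"`` (N-terminal).  ``blocking_contexts`` is a tuple of
    (position label, residue set) pairs; the bond is not cleaved when
    the residue at any listed position belongs to its set.
    """

    enzyme_code: str
    site_side: str
    target_residues: frozenset[str]
    blocking_contexts: tuple[tuple[str, frozenset[str]], ...] = ()

    def __post_init__(self) -> None:
        if self.site_side not in ("C", "N"):
            raise ValueError("site_side must be 'C' or 'N'")
        if not self.target_residues:
            raise ValueError(f"{self.enzyme_code}: empty target set")
        for pos, _ in self.blocking_contexts:
            if pos not in _POSITION_OFFSETS:
                raise ValueError(
                    f"{self.enzyme_code}: blocking position must be one of "
                    f"P2/P1/P1'/P2', got {pos!r}"
                )


@dataclass(frozen=True)
class CutSiteSet:
    """Sorted set of bond indices predicted cleavable in a sequence."""

    sequence_length: int
    sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(not 0 < s < self.sequence_length for s in self.sites):
            raise ValueError("cut sites must lie strictly inside the sequence")
        if list(self.sites) != sorted(set(self.sites)):
            raise ValueError("cut sites must be sorted and unique")


def _parse_blockers(expr: str) -> tuple[tuple[str, frozenset[str]], ...]:
    blockers = []
    for clause in expr.split(";"):
        clause = clause.strip()
        if not clause:
            continue
        pos, _, residues = clause.partition("=")
        blockers.append((pos.strip(), frozenset(residues.strip())))
    return tuple(blockers)


def load_rule_table(path: str | Path) -> dict[str, EnzymeRule]:
    """Read an enzyme rule table from a tab-separated file.

    Columns: enzyme, side (C/N), targets (residue letters run
    together), and an optional blocked_when column holding
    semicolon-separated ``POS=RESIDUES`` context predicates.
    Lines starting with ``#`` are comments.
    """
    rules: dict[str, EnzymeRule] = {}
    text = Path(path).read_text()
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            continue
        row = dict(zip(header, fields))
        code = row["enzyme"].strip()
        if code in rules:
            raise ValueError(f"duplicate enzyme code in rule table: {code}")
        rules[code] = EnzymeRule(
            enzyme_code=code,
            site_side=row["side"].strip(),
            target_residues=frozenset(row["targets"].strip()),
            blocking_contexts=_parse_blockers(row.get("blocked_when", "") or ""),
        )
    if not rules:
        raise ValueError(f"no rules found in {path}")
    return rules


def default_rules() -> dict[str, EnzymeRule]:
    """The packaged baseline rule table for the six-enzyme panel."""
    with resources.as_file(
        resources.files("cerepep.data").joinpath("enzyme_rules.tsv")
    ) as p:
        return load_rule_table(p)


def find_cut_sites(sequence: str, enzyme: EnzymeRule) -> CutSiteSet:
    """Predict the cleavable bonds of one enzyme in a sequence.

    Bond ``i`` (between residues ``i`` and ``i + 1``) is a site iff the
    residue on the enzyme's specificity side is a target and no blocking
    context matches.  Ambiguous residues neither trigger nor block.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    sites = []
    for i in range(1, n):
        trigger = sequence[i - 1] if enzyme.site_side == "C" else sequence[i]
        if trigger not in enzyme.target_residues or trigger in AMBIGUOUS_RESIDUES:
            continue
        blocked = False
        for pos, residues in enzyme.blocking_contexts:
            j = i + _POSITION_OFFSETS[pos]  # 1-based residue position
            if 1 <= j <= n:
                r = sequence[j - 1]
                if r in residues and r not in AMBIGUOUS_RESIDUES:
                    blocked = True
                    break
        if not blocked:
            sites.append(i)
    return CutSiteSet(sequence_length=n, sites=tuple(sites))


def _union_sites(sequence: str, enzymes) -> CutSiteSet:
    all_sites: set[int] = set()
    for rule in enzymes:
        all_sites.update(find_cut_sites(sequence, rule).sites)
    return CutSiteSet(sequence_length=len(sequence), sites=tuple(sorted(all_sites)))


def digest_simultaneous(
    sequence: str, enzymes
) -> list[tuple[str, int]]:
    """Digest a sequence with several enzymes applied together.

    Fragments are the maximal substrings between the union of all
    enzymes' cut sites, returned as (fragment sequence, 1-based start)
    ordered by start.  Their concatenation reproduces the input.
    """
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("empty enzyme set")
    cut = _union_sites(sequence, enzymes)
    bounds = [0, *cut.sites, len(sequence)]
    return [
        (sequence[a:b], a + 1) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def _resolve(rules: dict[str, EnzymeRule], codes) -> list[EnzymeRule]:
    missing = [c for c in codes if c not in rules]
    if missing:
        raise KeyError(f"unknown enzyme code(s): {missing}")
    return [rules[c] for c in codes]


def run_workflow(
    protein: ProteinRecord,
    workflow: DigestionWorkflow,
    rules: dict[str, EnzymeRule] | None = None,
) -> list[DigestionEvent]:
    """Apply a one- or two-step workflow to a protein.

    Step-1 fragments are emitted as level-0 events.  For two-step
    workflows every level-0 fragment is digested again with the step-2
    enzyme set and each resulting fragment — including fragments the
    second step leaves uncut — is emitted as a level-1 event whose
    parent fields reference the step-1 fragment.  Level-1 starts are
    absolute protein coordinates.
    """
    if rules is None:
        rules = default_rules()
    step1 = _resolve(rules, workflow.steps[0])
    events: list[DigestionEvent] = []
    level0 = digest_simultaneous(protein.sequence, step1)
    for frag, start in level0:
        events.append(
            DigestionEvent(
                protein_accession=protein.accession,
                workflow_id=workflow.workflow_id,
                step_enzymes=workflow.steps[0],
                peptide_sequence=frag,
                start=start,
                level=0,
            )
        )
    if workflow.n_steps == 2:
        step2 = _resolve(rules, workflow.steps[1])
        for parent_seq, parent_start in level0:
            for frag, rel_start in digest_simultaneous(parent_seq, step2):
                events.append(
                    DigestionEvent(
                        protein_accession=protein.accession,
                        workflow_id=workflow.workflow_id,
                        step_enzymes=workflow.steps[1],
                        peptide_sequence=frag,
                        start=parent_start + rel_start - 1,
                        level=1,
                        parent_enzymes=workflow.steps[0],
                        parent_peptide_sequence=parent_seq,
                    )
                )
    return events


def digest_all(
    proteins,
    workflows,
    rules: dict[str, EnzymeRule] | None = None,
) -> list[DigestionEvent]:
    """Run every workflow on every protein; deduplicate by event identity.

    Event identity is (protein accession, workflow, level, start,
    peptide sequence, parent peptide sequence), so the same sequence
    listed under two accessions yields distinct events.
    """
    if rules is None:
        rules = default_rules()
    seen: set[str] = set()
    events: list[DigestionEvent] = []
    for protein in proteins:
        for workflow in workflows:
            for event in run_workflow(protein, workflow, rules):
                eid = event.event_id
                if eid not in seen:
                    seen.add(eid)
                    events.append(event)
    return events
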