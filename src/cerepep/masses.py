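"""Peptide mass annotation.

A peptide's mass is the sum of its residue masses plus one water (the
terminal H and OH), computed either with monoisotopic or with average
residue masses; the singly-protonated monoisotopic mass [M+H]+ adds one
proton.  Masses are undefined — returned as ``None`` — whenever the
sequence contains a residue absent from the active mass table (X and
the ambiguity letters B/Z/U/O in the default table).  The number of
unrecognized amino acids (#UA) counts literal ``X`` characters only.

Printed mass values are rounded to 4 decimal places for display; all
comparisons and stored values use the unrounded sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "MassTable",
    "default_mass_table",
    "load_mass_table",
    "count_unrecognized",
    "monoisotopic_mass",
    "average_mass",
    "protonated_mass",
    "display_round",
]

DISPLAY_DECIMALS = 4


@dataclass(frozen=True)
class MassTable:
    residue_monoisotopic: dict[str, float]
    residue_average: dict[str, float]
    water_monoisotopic: float
    water_average: float
    proton: float

    def __post_init__(self) -> None:
        standard = set("ACDEFGHIKLMNPQRSTVWY")
        for name, mapping in (
            ("monoisotopic", self.residue_monoisotopic),
            ("average", self.residue_average),
        ):
            missing = standard - mapping.keys()
            if missing:
                raise ValueError(
                    f"{name} mass table missing residues: {sorted(missing)}"
                )
        if min(self.water_monoisotopic, self.water_average, self.proton) <= 0:
            raise ValueError("mass constants must be positive")


def load_mass_table(path: str | Path) -> MassTable:
    """Read a residue-mass table from a tab-separated file.

    Columns: residue, monoisotopic, average.  The special rows ``water``
    and ``proton`` supply the terminal-water and protonation constants.
    """
    mono: dict[str, float] = {}
    avg: dict[str, float] = {}
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            continue
        row = dict(zip(header, fields))
        mono[row["residue"].strip()] = float(row["monoisotopic"])
        avg[row["residue"].strip()] = float(row["average"])
    water_mono = mono.pop("water")
    water_avg = avg.pop("water")
    proton = mono.pop("proton")
    avg.pop("proton")
    return MassTable(
        residue_monoisotopic=mono,
        residue_average=avg,
        water_monoisotopic=water_mono,
        water_average=water_avg,
        proton=proton,
    )


def default_mass_table() -> MassTable:
    """The packaged table of standard residue masses."""
    with resources.as_file(
        resources.files("cerepep.data").joinpath("mass_table.tsv")
    ) as p:
        return load_mass_table(p)


def count_unrecognized(sequence: str) -> int:
    """#UA: the number of literal ``X`` characters in a sequence."""
    return sequence.count("X")


def _sum_masses(
    sequence: str, residue_masses: dict[str, float], water: float
) -> float | None:
    if not sequence:
        raise ValueError("empty sequence")
    total = water
    for residue in sequence:
        mass = residue_masses.get(residue)
        if mass is None:
            return None
        total += mass
    return total


def monoisotopic_mass(sequence: str, table: MassTable | None = None) -> float | None:
    """Neutral monoisotopic mass [M] in Da, or ``None`` if undefined."""
    if table is None:
        table = default_mass_table()
    return _sum_masses(sequence, table.residue_monoisotopic, table.water_monoisotopic)


def average_mass(sequence: str, table: MassTable | None = None) -> float | None:
    """Average (isotope-weighted) mass [M] in Da, or ``None``."""
    if table is None:
        table = default_mass_table()
    return _sum_masses(sequence, table.residue_average, table.water_average)


def protonated_mass(sequence: str, table: MassTable | None = None) -> float | None:
    """Singly-charged monoisotopic mass [M+H]+ in Da, or ``None``."""
    if table is None:
        table = default_mass_table()
    mono = monoisotopic_mass(sequence, table)
    return None if mono is None else mono + table.proton


def display_round(mass: float | None) -> float | None:
    """Round a mass to the 4-decimal display precision."""
    return None if mass is None else round(mass, DISPLAY_DECIMALS)
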