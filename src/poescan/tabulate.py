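"""Multinomial cell categories and per-SNP count tables.

At a biallelic SNP a case-parent trio falls into one of 15 Mendelian-
consistent genotype categories (gm, gf, gc); a case-parent duo falls into
one of 7 observable (g_parent, g_child) categories. The all-heterozygous
category (trio cell 9, duo cell 4) is the only one in which the parental
origin of the child's minor allele is not determined by the single SNP; when
phasing resolves it the unit is counted in cell 9a/4a (minor allele from the
father) or 9b/4b (from the mother) instead.

Cells are ordered by mating type (mt1..mt6, see ``_mendel.mating_type``),
then by descending parental and child dosages; under this ordering cell 9 is
(1,1,1), cell 10 is (1,1,0) and duo cell 4 is (1,1). Counts may be
non-integer (the downstream multinomial likelihood does not require integer
counts).
"""
from __future__ import annotations

import dataclasses
from itertools import product

import numpy as np

from ._mendel import MISSING, duo_transmissions, mating_type, transmissions
from .pedio import FamilyUnit, GenotypeMatrix
from .phasing import Origin, OriginCall


def enumerate_trio_cells() -> list[tuple[int, int, int]]:
    """The 15 Mendelian-consistent (gm, gf, gc) categories, in canonical order."""
    cells = [
        (gm, gf, gc)
        for gm, gf, gc in product(range(3), repeat=3)
        if transmissions(gm, gf, gc)
    ]
    cells.sort(key=lambda c: (mating_type(c[0], c[1]), -c[0], -c[1], -c[2]))
    return cells


def enumerate_duo_cells(parent: str = "mother") -> list[tuple[int, int]]:
    """The 7 observable (g_parent, g_child) duo categories, in canonical order.

    The genotype-pair set is identical for case-mother and case-father duos.
    """
    if parent not in ("mother", "father"):
        raise ValueError(f"unknown parent type: {parent}")
    cells = [
        (gp, gc)
        for gp, gc in product(range(3), repeat=2)
        if duo_transmissions(gp, gc)
    ]
    cells.sort(key=lambda c: (-c[0], -c[1]))
    return cells


TRIO_CELLS = enumerate_trio_cells()
TRIO_CELL_INDEX = {cell: i + 1 for i, cell in enumerate(TRIO_CELLS)}
DUO_CELLS = enumerate_duo_cells()
DUO_CELL_INDEX = {cell: i + 1 for i, cell in enumerate(DUO_CELLS)}

TRIO_AMBIGUOUS_CELL = TRIO_CELL_INDEX[(1, 1, 1)]  # cell 9
DUO_AMBIGUOUS_CELL = DUO_CELL_INDEX[(1, 1)]       # cell 4

TRIO_LABELS = list(range(1, 16)) + ["9a", "9b"]
DUO_LABELS = list(range(1, 8)) + ["4a", "4b"]


@dataclasses.dataclass
class TrioCellCounts:
    """Counts in the 15 trio categories plus the origin-resolved 9a/9b cells.

    ``n`` is indexed 1..15 (slot 0 unused); ``n[9]`` holds only unphased
    all-heterozygous trios.
    """

    n: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(16))
    n9a: float = 0.0
    n9b: float = 0.0

    @property
    def total(self) -> float:
        return float(self.n[1:].sum() + self.n9a + self.n9b)

    def get(self, label) -> float:
        if label == "9a":
            return self.n9a
        if label == "9b":
            return self.n9b
        return float(self.n[label])

    def add(self, label, amount: float = 1.0) -> None:
        if label == "9a":
            self.n9a += amount
        elif label == "9b":
            self.n9b += amount
        else:
            self.n[label] += amount


@dataclasses.dataclass
class DuoCellCounts:
    """Counts in the 7 duo categories plus the origin-resolved 4a/4b cells."""

    parent: str = "mother"
    n: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(8))
    n4a: float = 0.0  # minor allele inherited from the father
    n4b: float = 0.0  # minor allele inherited from the mother

    @property
    def total(self) -> float:
        return float(self.n[1:].sum() + self.n4a + self.n4b)

    def get(self, label) -> float:
        if label == "4a":
            return self.n4a
        if label == "4b":
            return self.n4b
        return float(self.n[label])

    def add(self, label, amount: float = 1.0) -> None:
        if label == "4a":
            self.n4a += amount
        elif label == "4b":
            self.n4b += amount
        else:
            self.n[label] += amount


def classify_trio(gm: int, gf: int, gc: int,
                  origin: OriginCall | None = None):
    """Cell label (1..15, '9a' or '9b') for a Mendelian-consistent triple.

    The all-heterozygous triple maps to 9a/9b when the origin call resolves
    the child's minor allele to the father/mother, and to cell 9 otherwise;
    origin is ignored for every other triple.
    """
    try:
        cell = TRIO_CELL_INDEX[(gm, gf, gc)]
    except KeyError:
        raise ValueError(f"Mendelian-inconsistent triple ({gm},{gf},{gc})")
    if cell == TRIO_AMBIGUOUS_CELL and origin is not None:
        if origin.value == Origin.PATERNAL_MINOR:
            return "9a"
        if origin.value == Origin.MATERNAL_MINOR:
            return "9b"
    return cell


def classify_duo(gp: int, gc: int, parent: str = "mother",
                 origin: OriginCall | None = None):
    """Cell label (1..7, '4a' or '4b') for an observable duo pair."""
    try:
        cell = DUO_CELL_INDEX[(gp, gc)]
    except KeyError:
        raise ValueError(f"impossible duo genotype pair ({gp},{gc})")
    if cell == DUO_AMBIGUOUS_CELL and origin is not None:
        if origin.value == Origin.PATERNAL_MINOR:
            return "4a"
        if origin.value == Origin.MATERNAL_MINOR:
            return "4b"
    return cell


def tabulate_snp(units: list[FamilyUnit],
                 origin_calls,
                 genotypes: GenotypeMatrix,
                 snp: int) -> tuple[TrioCellCounts, DuoCellCounts, DuoCellCounts]:
    """Classify each family unit at one SNP and assemble the count tables.

    ``origin_calls`` is a sequence aligned with ``units`` (or None, in which
    case every all-heterozygous unit stays in the combined cell 9/4). Units
    with a missing member genotype at the SNP, and Mendelian-inconsistent
    units, contribute nothing at this SNP.
    """
    trio = TrioCellCounts()
    duo_m = DuoCellCounts(parent="mother")
    duo_f = DuoCellCounts(parent="father")
    for k, unit in enumerate(units):
        call = origin_calls[k] if origin_calls is not None else None
        gc = int(genotypes.dosage_row(unit.child_id)[snp])
        if gc == MISSING:
            continue
        if unit.unit_type == "trio":
            gm = int(genotypes.dosage_row(unit.mother_id)[snp])
            gf = int(genotypes.dosage_row(unit.father_id)[snp])
            if gm == MISSING or gf == MISSING:
                continue
            if (gm, gf, gc) not in TRIO_CELL_INDEX:
                continue  # Mendelian error: treated as missing at this SNP
            trio.add(classify_trio(gm, gf, gc, call))
        else:
            parent = "mother" if unit.unit_type == "duo_mother" else "father"
            pid = unit.mother_id if parent == "mother" else unit.father_id
            gp = int(genotypes.dosage_row(pid)[snp])
            if gp == MISSING or (gp, gc) not in DUO_CELL_INDEX:
                continue
            table = duo_m if parent == "mother" else duo_f
            table.add(classify_duo(gp, gc, parent, call))
    return trio, duo_m, duo_f
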