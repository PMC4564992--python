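"""PLINK pedigree I/O and family-unit selection.

Reads .ped/.map text and .bed/.bim/.fam binary pedigree files into a
minor-allele dosage matrix plus pedigree structures, selects one analysis
unit (case-parent trio, case-mother duo, or case-father duo) per pedigree,
and writes the PLINK binary files used as phasing input.

Dosages always count copies of the minor allele, where the minor allele is
re-derived from founder genotypes on read (ties at frequency 0.5 are broken
by taking the lexicographically smaller allele label as minor).
"""
from __future__ import annotations

import dataclasses
import struct
from pathlib import Path

import numpy as np

from ._mendel import MISSING

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

_BED_MAGIC = b"\x6c\x1b\x01"


class PlinkFormatError(ValueError):
    """Raised for malformed PLINK files."""


@dataclasses.dataclass
class SnpInfo:
    snp_id: str
    chromosome: str
    position_bp: int
    allele_minor: str
    allele_major: str
    maf: float


@dataclasses.dataclass
class GenotypeMatrix:
    """Per-individual, per-SNP minor-allele dosages (0/1/2, -1 = missing)."""

    individuals: list[str]
    snps: list[SnpInfo]
    dosages: np.ndarray  # (n_individuals, n_snps) int8

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.individuals), len(self.snps)):
            raise ValueError("dosage matrix shape does not match labels")
        if len(set(self.individuals)) != len(self.individuals):
            raise PlinkFormatError("duplicate individual ids across pedigrees")
        self._index = {iid: i for i, iid in enumerate(self.individuals)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def row(self, individual_id: str) -> int:
        return self._index[individual_id]

    def dosage_row(self, individual_id: str) -> np.ndarray:
        return self.dosages[self._index[individual_id]]

    def has_individual(self, individual_id: str) -> bool:
        return individual_id in self._index

    @property
    def mafs(self) -> np.ndarray:
        return np.array([s.maf for s in self.snps])


@dataclasses.dataclass
class PedigreeMember:
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    affection: str  # affected / unaffected / unknown


@dataclasses.dataclass
class Pedigree:
    family_id: str
    members: list[PedigreeMember]

    def member(self, individual_id: str) -> PedigreeMember | None:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        return None

    def founders(self) -> list[PedigreeMember]:
        return [m for m in self.members
                if m.father_id is None and m.mother_id is None]


@dataclasses.dataclass
class FamilyUnit:
    unit_type: str  # trio | duo_mother | duo_father
    family_id: str
    child_id: str
    mother_id: str | None = None
    father_id: str | None = None

    def member_ids(self) -> list[str]:
        ids = []
        if self.father_id is not None:
            ids.append(self.father_id)
        if self.mother_id is not None:
            ids.append(self.mother_id)
        ids.append(self.child_id)
        return ids


def _parse_affection(token: str) -> str:
    if token == "2":
        return AFFECTED
    if token == "1":
        return UNAFFECTED
    return UNKNOWN


def _parse_sex(token: str) -> int:
    return int(token) if token in ("1", "2") else 0


def _derive_minor(allele_counts: dict[str, int]) -> tuple[str, str, float]:
    """Minor/major allele and MAF from founder allele counts."""
    alleles = sorted(a for a in allele_counts if a != "0")
    total = sum(allele_counts[a] for a in alleles)
    if not alleles:
        return "0", "0", 0.0
    if len(alleles) == 1:
        return "0", alleles[0], 0.0
    a, b = alleles
    fa = allele_counts[a] / total if total else 0.5
    if fa < 0.5 or (fa == 0.5):  # tie -> lexicographically smaller is minor
        minor, major = a, b
        maf = fa
    else:
        minor, major = b, a
        maf = 1.0 - fa
    return minor, major, maf


def read_map(map_path: str | Path) -> list[SnpInfo]:
    snps = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) == 4:
            chrom, snp_id, _cm, pos = tokens
        elif len(tokens) == 3:
            chrom, snp_id, pos = tokens
        else:
            raise PlinkFormatError(f"{map_path}: malformed line {lineno}")
        snps.append(SnpInfo(snp_id, chrom, int(pos), "0", "0", 0.0))
    return snps


def read_plink_text(ped_path: str | Path,
                    map_path: str | Path) -> tuple[GenotypeMatrix, list[Pedigree]]:
    """Read a PLINK .ped/.map text file pair.

    Dosages are recoded to minor-allele counts (minor allele derived from
    founder genotypes); half-missing calls are treated as fully missing.
    """
    snps = read_map(map_path)
    n_snps = len(snps)

    individuals: list[str] = []
    fam_rows: list[tuple[str, str, str, str, str, str]] = []
    allele_rows: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 6 + 2 * n_snps:
            raise PlinkFormatError(
                f"{ped_path}: line {lineno} has {len(tokens)} fields, "
                f"expected {6 + 2 * n_snps}")
        fam_rows.append(tuple(tokens[:6]))
        individuals.append(tokens[1])
        pairs = [(tokens[6 + 2 * j], tokens[7 + 2 * j]) for j in range(n_snps)]
        allele_rows.append(pairs)

    pedigrees = _build_pedigrees(fam_rows)
    founder_idx = _founder_rows(fam_rows)

    dosages = np.full((len(individuals), n_snps), MISSING, dtype=np.int8)
    for j, snp in enumerate(snps):
        observed: set[str] = set()
        for pairs in allele_rows:
            observed.update(pairs[j])
        observed.discard("0")
        if len(observed) > 2:
            raise PlinkFormatError(
                f"{ped_path}: SNP {snp.snp_id} shows more than two alleles: "
                f"{sorted(observed)}")
        counts: dict[str, int] = {a: 0 for a in observed}
        for i in founder_idx:
            a1, a2 = allele_rows[i][j]
            if a1 != "0" and a2 != "0":
                counts[a1] += 1
                counts[a2] += 1
        minor, major, maf = _derive_minor(counts)
        snp.allele_minor, snp.allele_major, snp.maf = minor, major, maf
        for i, pairs in enumerate(allele_rows):
            a1, a2 = pairs[j]
            if a1 == "0" or a2 == "0":
                continue  # half-missing treated as missing
            dosages[i, j] = (a1 == minor) + (a2 == minor)

    return GenotypeMatrix(individuals, snps, dosages), pedigrees


def _build_pedigrees(fam_rows) -> list[Pedigree]:
    by_family: dict[str, list[PedigreeMember]] = {}
    for fid, iid, father, mother, sex, pheno in fam_rows:
        member = PedigreeMember(
            individual_id=iid,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex=_parse_sex(sex),
            affection=_parse_affection(pheno),
        )
        by_family.setdefault(fid, []).append(member)
    return [Pedigree(fid, members) for fid, members in by_family.items()]


def _founder_rows(fam_rows) -> list[int]:
    rows = [i for i, r in enumerate(fam_rows) if r[2] == "0" and r[3] == "0"]
    return rows if rows else list(range(len(fam_rows)))


def read_plink_binary(bed_path: str | Path, bim_path: str | Path,
                      fam_path: str | Path) -> tuple[GenotypeMatrix, list[Pedigree]]:
    """Read a PLINK binary (.bed/.bim/.fam, SNP-major) file set."""
    fam_rows = []
    for line in Path(fam_path).read_text().splitlines():
        tokens = line.split()
        if tokens:
            fam_rows.append(tuple(tokens[:6]))
    individuals = [r[1] for r in fam_rows]
    n_ind = len(individuals)

    snps: list[SnpInfo] = []
    a1a2: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(bim_path).read_text().splitlines(), 1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 6:
            raise PlinkFormatError(f"{bim_path}: malformed line {lineno}")
        chrom, snp_id, _cm, pos, a1, a2 = tokens
        snps.append(SnpInfo(snp_id, chrom, int(pos), a1, a2, 0.0))
        a1a2.append((a1, a2))

    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not SNP-major .bed)")
    bytes_per_snp = (n_ind + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size < bytes_per_snp * len(snps):
        raise IOError(f"{bed_path}: truncated genotype block")
    body = body[: bytes_per_snp * len(snps)].reshape(len(snps), bytes_per_snp)

    # 2-bit codes per individual: 00 -> 2 copies of A1, 10 -> het,
    # 11 -> 0 copies of A1, 01 -> missing.
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(len(snps), bytes_per_snp * 4)[:, :n_ind]
    decode = np.array([2, MISSING, 1, 0], dtype=np.int8)
    dosages = decode[codes].T.copy()  # (n_ind, n_snps), counting A1

    pedigrees = _build_pedigrees(fam_rows)
    founder_idx = _founder_rows(fam_rows)

    for j, snp in enumerate(snps):
        col = dosages[founder_idx, j]
        ok = col != MISSING
        a1, a2 = a1a2[j]
        if a1 == "0":
            f1 = 0.0
        elif ok.any():
            f1 = float(col[ok].sum()) / (2 * int(ok.sum()))
        else:
            f1 = 0.0
        flip = f1 > 0.5 or (f1 == 0.5 and a2 != "0" and a2 < a1)
        if flip:
            keep = dosages[:, j] != MISSING
            dosages[keep, j] = 2 - dosages[keep, j]
            snp.allele_minor, snp.allele_major = a2, a1
            snp.maf = 1.0 - f1
        else:
            snp.allele_minor, snp.allele_major = a1, a2
            snp.maf = f1

    return GenotypeMatrix(individuals, snps, dosages), pedigrees


def write_plink_binary(genotypes: GenotypeMatrix,
                       fam_rows: list[tuple[str, str, str, str, str, str]],
                       out_prefix: str | Path) -> None:
    """Write a SNP-major .bed/.bim/.fam file set for the given fam rows."""
    out_prefix = str(out_prefix)
    iids = [r[1] for r in fam_rows]
    rows = [genotypes.row(iid) for iid in iids]
    sub = genotypes.dosages[rows]  # counts of minor allele (= A1)

    with open(out_prefix + ".fam", "w") as fh:
        for r in fam_rows:
            fh.write(" ".join(r) + "\n")
    with open(out_prefix + ".bim", "w") as fh:
        for s in genotypes.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\t"
                     f"{s.allele_minor}\t{s.allele_major}\n")

    n_ind = len(iids)
    bytes_per_snp = (n_ind + 3) // 4
    encode = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
    with open(out_prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(genotypes.n_snps):
            buf = bytearray(bytes_per_snp)
            for i in range(n_ind):
                buf[i // 4] |= encode[int(sub[i, j])] << ((i % 4) * 2)
            fh.write(struct.pack(f"{bytes_per_snp}B", *buf))


def select_family_units(pedigrees: list[Pedigree],
                        genotypes: GenotypeMatrix,
                        missing_threshold: float = 0.5) -> list[FamilyUnit]:
    """Select at most one analysis unit per pedigree.

    Trios are chosen first (candidate with the least missing genotype data,
    ties broken by smallest child id, accepted only if the non-missing
    fraction across its members is >= missing_threshold), then case-mother
    duos in pedigrees without a trio, then case-father duos. The child of
    every unit is affected.
    """
    if not 0.0 <= missing_threshold <= 1.0:
        raise ValueError("missing_threshold must lie in [0, 1]")
    units: list[FamilyUnit] = []

    def nonmissing_fraction(ids: list[str]) -> float:
        rows = [genotypes.row(i) for i in ids]
        block = genotypes.dosages[rows]
        return float(np.mean(block != MISSING)) if block.size else 0.0

    def pick(candidates: list[tuple[list[str], FamilyUnit]]) -> FamilyUnit | None:
        best = None
        for ids, unit in candidates:
            frac = nonmissing_fraction(ids)
            key = (-frac, unit.child_id)
            if best is None or key < best[0]:
                best = (key, frac, unit)
        if best is not None and best[1] >= missing_threshold:
            return best[2]
        return None

    for ped in sorted(pedigrees, key=lambda p: p.family_id):
        affected = [m for m in ped.members
                    if m.affection == AFFECTED
                    and genotypes.has_individual(m.individual_id)]

        trio_cands = []
        for child in affected:
            if (child.mother_id and child.father_id
                    and genotypes.has_individual(child.mother_id)
                    and genotypes.has_individual(child.father_id)):
                unit = FamilyUnit("trio", ped.family_id, child.individual_id,
                                  mother_id=child.mother_id,
                                  father_id=child.father_id)
                trio_cands.append((unit.member_ids(), unit))
        chosen = pick(trio_cands)
        if chosen is None:
            duo_m = []
            for child in affected:
                if child.mother_id and genotypes.has_individual(child.mother_id):
                    unit = FamilyUnit("duo_mother", ped.family_id,
                                      child.individual_id,
                                      mother_id=child.mother_id)
                    duo_m.append((unit.member_ids(), unit))
            chosen = pick(duo_m)
        if chosen is None:
            duo_f = []
            for child in affected:
                if child.father_id and genotypes.has_individual(child.father_id):
                    unit = FamilyUnit("duo_father", ped.family_id,
                                      child.individual_id,
                                      father_id=child.father_id)
                    duo_f.append((unit.member_ids(), unit))
            chosen = pick(duo_f)
        if chosen is not None:
            units.append(chosen)
    return units


def write_phasing_input(units: list[FamilyUnit], genotypes: GenotypeMatrix,
                        out_prefix: str | Path) -> None:
    """Write .bed/.bim/.fam restricted to the members of the selected units."""
    fam_rows = []
    for u in units:
        if u.father_id is not None:
            fam_rows.append((u.family_id, u.father_id, "0", "0", "1", "-9"))
        if u.mother_id is not None:
            fam_rows.append((u.family_id, u.mother_id, "0", "0", "2", "-9"))
        fam_rows.append((u.family_id, u.child_id,
                         u.father_id or "0", u.mother_id or "0", "0", "2"))
    write_plink_binary(genotypes, fam_rows, out_prefix)
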