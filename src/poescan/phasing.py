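"""Parental-origin resolution at ambiguous SNPs.

At a biallelic SNP the parental origin of an affected child's minor allele
is forced by Mendelian rules unless every genotyped member of the unit is
heterozygous (trio: mother, father and child; duo: the typed parent and the
child). Those ambiguous configurations are resolved probabilistically using
the surrounding SNPs: the two possible phase completions at the test SNP are
scored by population haplotype frequencies over a local window (estimated by
EM across the sample, assuming random mating and no recombination within the
window), and the maximum-a-posteriori origin is committed.

Externally phased haplotypes in SHAPEIT haps/sample format can be ingested
instead of running the built-in window phaser.
"""
from __future__ import annotations

import dataclasses
import warnings
from enum import Enum
from itertools import product
from pathlib import Path

import numpy as np

from ._mendel import MISSING, transmissions
from .pedio import FamilyUnit, GenotypeMatrix


class Origin(str, Enum):
    PATERNAL_MINOR = "paternal_minor"
    MATERNAL_MINOR = "maternal_minor"
    AMBIGUOUS = "ambiguous"
    NOT_APPLICABLE = "not_applicable"


@dataclasses.dataclass
class OriginCall:
    value: Origin
    posterior_paternal: float | None = None


class MendelianInconsistencyError(ValueError):
    """A dosage triple impossible under Mendelian transmission."""


def mendelian_origin(gm: int, gf: int, gc: int) -> OriginCall:
    """Origin of the child's minor allele forced by single-SNP Mendelian rules.

    Returns the forced origin whenever any member is homozygous, AMBIGUOUS
    iff gm = gf = gc = 1, and NOT_APPLICABLE when the child is homozygous
    (no single minor-allele copy whose origin is in question).
    """
    trans = transmissions(gm, gf, gc)
    if not trans:
        raise MendelianInconsistencyError(
            f"inconsistent trio dosages ({gm},{gf},{gc})")
    if gc != 1:
        return OriginCall(Origin.NOT_APPLICABLE)
    if len(trans) == 1:
        am, ap = trans[0]
        if ap == 1:
            return OriginCall(Origin.PATERNAL_MINOR, 1.0)
        return OriginCall(Origin.MATERNAL_MINOR, 0.0)
    return OriginCall(Origin.AMBIGUOUS)


def duo_mendelian_origin(gp: int, gc: int, parent: str = "mother") -> OriginCall:
    """Single-SNP origin call for a duo with typed parent dosage gp."""
    if (gp, gc) in ((2, 0), (0, 2)):
        raise MendelianInconsistencyError(
            f"inconsistent duo dosages ({gp},{gc})")
    if gc != 1:
        return OriginCall(Origin.NOT_APPLICABLE)
    if gp == 1:
        return OriginCall(Origin.AMBIGUOUS)
    typed_minor = gp == 2  # typed parent transmitted the minor allele
    typed_is_father = parent == "father"
    if typed_minor == typed_is_father:
        return OriginCall(Origin.PATERNAL_MINOR, 1.0)
    return OriginCall(Origin.MATERNAL_MINOR, 0.0)


# ---------------------------------------------------------------------------
# Window machinery

def _window_indices(genotypes: GenotypeMatrix, test_snp: int,
                    window_snps: int) -> np.ndarray:
    """Window of up to window_snps SNP indices centred on test_snp,
    truncated at the ends of the test SNP's chromosome."""
    chrom = genotypes.snps[test_snp].chromosome
    half = window_snps // 2
    lo = test_snp
    while lo > 0 and test_snp - lo < half \
            and genotypes.snps[lo - 1].chromosome == chrom:
        lo -= 1
    hi = test_snp
    while hi < genotypes.n_snps - 1 and hi - test_snp < half \
            and genotypes.snps[hi + 1].chromosome == chrom:
        hi += 1
    return np.arange(lo, hi + 1)


def _trio_site_choices(gm, gf, gc):
    return transmissions(int(gm), int(gf), int(gc))


def _duo_site_choices(gp, gc):
    # (typed-parent transmitted allele, untyped-parent transmitted allele)
    out = []
    for a in ((0,), (0, 1), (1,))[int(gp)]:
        b = int(gc) - a
        if b in (0, 1):
            out.append((a, b))
    return out


def _unit_configs(unit: FamilyUnit, genotypes: GenotypeMatrix,
                  window: np.ndarray, test_pos: int,
                  max_ambiguous: int = 12):
    """Founder-haplotype configurations of one unit over a window.

    For a trio each configuration is 4 founder haplotypes (maternal
    transmitted/untransmitted, paternal transmitted/untransmitted); for a duo
    it is 3 (typed parent's two plus the untyped parent's transmitted one).
    Returns (configs, paternal_minor_at_test) where configs is a list of
    haplotype tuples and paternal_minor_at_test a parallel bool list, or
    (None, None) when the unit cannot be enumerated (missing data, Mendelian
    error, or too many ambiguous sites).
    """
    gc_row = genotypes.dosage_row(unit.child_id)[window]
    if unit.unit_type == "trio":
        gm_row = genotypes.dosage_row(unit.mother_id)[window]
        gf_row = genotypes.dosage_row(unit.father_id)[window]
        rows = (gm_row, gf_row, gc_row)
    else:
        pid = unit.mother_id if unit.unit_type == "duo_mother" else unit.father_id
        gp_row = genotypes.dosage_row(pid)[window]
        rows = (gp_row, gc_row)
    if any((r == MISSING).any() for r in rows):
        return None, None

    site_choices = []
    for s in range(len(window)):
        if unit.unit_type == "trio":
            ch = _trio_site_choices(gm_row[s], gf_row[s], gc_row[s])
        else:
            ch = _duo_site_choices(rows[0][s], gc_row[s])
        if not ch:
            return None, None  # Mendelian inconsistency in window
        site_choices.append(ch)

    n_amb = sum(1 for ch in site_choices if len(ch) > 1)
    if n_amb > max_ambiguous:
        return None, None

    configs = []
    pat_minor = []
    t = int(np.where(window == test_pos)[0][0])
    for combo in product(*site_choices):
        a1 = np.fromiter((c[0] for c in combo), dtype=np.int8)
        a2 = np.fromiter((c[1] for c in combo), dtype=np.int8)
        if unit.unit_type == "trio":
            hm_t, hf_t = a1, a2
            hm_u = rows[0] - hm_t
            hf_u = rows[1] - hf_t
            haps = (tuple(hm_t), tuple(hm_u), tuple(hf_t), tuple(hf_u))
            ap_test = int(hf_t[t])
        else:
            hp_t = a1            # typed parent's transmitted haplotype
            hp_u = rows[0] - hp_t
            ho_t = a2            # untyped parent's transmitted haplotype
            haps = (tuple(hp_t), tuple(hp_u), tuple(ho_t))
            if unit.unit_type == "duo_mother":
                ap_test = int(ho_t[t])
            else:
                ap_test = int(hp_t[t])
        configs.append(haps)
        pat_minor.append(bool(ap_test))
    return configs, pat_minor


@dataclasses.dataclass
class HaplotypeFrequencies:
    """EM-estimated haplotype frequencies over a SNP window."""

    window: np.ndarray           # SNP indices covered
    haplotypes: list[tuple]      # minor-allele indicator tuples
    freq: np.ndarray             # same length; sums to 1
    loglik_path: list[float]
    converged: bool

    def as_dict(self) -> dict[tuple, float]:
        return dict(zip(self.haplotypes, self.freq))


def estimate_window_haplotypes(units: list[FamilyUnit],
                               genotypes: GenotypeMatrix,
                               test_snp: int,
                               window_snps: int = 7,
                               max_iter: int = 200,
                               tol: float = 1e-6,
                               max_ambiguous: int = 12) -> HaplotypeFrequencies:
    """EM estimate of window haplotype frequencies from trio or duo units.

    Each unit's likelihood sums over the founder-haplotype configurations
    consistent with all observed genotypes in the window (random mating, no
    recombination within the window). The log-likelihood is non-decreasing
    across iterations; a non-convergence warning returns the last iterate.
    """
    if len(units) < 1:
        raise ValueError("at least one family unit is required")
    window = _window_indices(genotypes, test_snp, window_snps)

    hap_index: dict[tuple, int] = {}
    cfg_haps: list[list[int]] = []
    cfg_unit: list[int] = []
    n_used = 0
    for unit in units:
        configs, _ = _unit_configs(unit, genotypes, window, test_snp,
                                   max_ambiguous)
        if configs is None:
            continue
        for haps in configs:
            idx = [hap_index.setdefault(h, len(hap_index)) for h in haps]
            cfg_haps.append(idx)
            cfg_unit.append(n_used)
        n_used += 1
    if not cfg_haps:
        raise ValueError("no unit could be phased in this window")

    haps = [None] * len(hap_index)
    for h, i in hap_index.items():
        haps[i] = h
    idx = np.array(cfg_haps)           # (n_cfg, k)
    unit_of = np.array(cfg_unit)
    n_hap = len(haps)
    k = idx.shape[1]

    freq = np.full(n_hap, 1.0 / n_hap)
    loglik_path: list[float] = []
    converged = False
    for _ in range(max_iter):
        w = freq[idx].prod(axis=1)
        unit_sum = np.bincount(unit_of, weights=w, minlength=n_used)
        ll = float(np.log(unit_sum).sum())
        wn = w / unit_sum[unit_of]
        counts = np.bincount(idx.ravel(), weights=np.repeat(wn, k),
                             minlength=n_hap)
        freq = counts / counts.sum()
        if loglik_path and abs(ll - loglik_path[-1]) < tol:
            loglik_path.append(ll)
            converged = True
            break
        loglik_path.append(ll)
    if not converged:
        warnings.warn("haplotype EM did not converge; returning last iterate")
    return HaplotypeFrequencies(window, haps, freq, loglik_path, converged)


def _posterior_paternal(unit: FamilyUnit, genotypes: GenotypeMatrix,
                        test_snp: int, freqs: HaplotypeFrequencies,
                        max_ambiguous: int = 12) -> float | None:
    configs, pat = _unit_configs(unit, genotypes, freqs.window, test_snp,
                                 max_ambiguous)
    if configs is None:
        return None
    table = freqs.as_dict()
    w_pat = 0.0
    w_tot = 0.0
    for haps, is_pat in zip(configs, pat):
        w = 1.0
        for h in haps:
            w *= table.get(h, 0.0)
        w_tot += w
        if is_pat:
            w_pat += w
    if w_tot == 0.0:
        return None
    return w_pat / w_tot


def _map_call(posterior: float | None, tie_tol: float = 1e-9) -> OriginCall:
    if posterior is None:
        return OriginCall(Origin.AMBIGUOUS)
    if posterior > 0.5 + tie_tol:
        return OriginCall(Origin.PATERNAL_MINOR, posterior)
    if posterior < 0.5 - tie_tol:
        return OriginCall(Origin.MATERNAL_MINOR, posterior)
    return OriginCall(Origin.AMBIGUOUS, posterior)


def resolve_duo_origin(unit: FamilyUnit, genotypes: GenotypeMatrix,
                       test_snp: int,
                       freqs: HaplotypeFrequencies) -> OriginCall:
    """MAP origin of an ambiguous duo's minor allele given window haplotype
    frequencies; delegates to the forced single-SNP rule when the
    configuration is not parent-het/child-het."""
    parent = "mother" if unit.unit_type == "duo_mother" else "father"
    pid = unit.mother_id if parent == "mother" else unit.father_id
    gp = int(genotypes.dosage_row(pid)[test_snp])
    gc = int(genotypes.dosage_row(unit.child_id)[test_snp])
    if gp == MISSING or gc == MISSING:
        return OriginCall(Origin.AMBIGUOUS)
    if not (gp == 1 and gc == 1):
        return duo_mendelian_origin(gp, gc, parent)
    return _map_call(_posterior_paternal(unit, genotypes, test_snp, freqs))


def phase_trio_window(unit: FamilyUnit, genotypes: GenotypeMatrix,
                      test_snp: int, window_snps: int = 15,
                      freqs: HaplotypeFrequencies | None = None,
                      units: list[FamilyUnit] | None = None) -> OriginCall:
    """Origin call for a trio at a test SNP using the surrounding window.

    Non-ambiguous configurations return the Mendelian-forced call unchanged.
    The all-heterozygous configuration is scored by window haplotype
    frequencies (``freqs``; estimated from ``units`` — by default the single
    trio itself — when not supplied); if the window carries no information
    the call stays AMBIGUOUS.
    """
    gm = int(genotypes.dosage_row(unit.mother_id)[test_snp])
    gf = int(genotypes.dosage_row(unit.father_id)[test_snp])
    gc = int(genotypes.dosage_row(unit.child_id)[test_snp])
    if MISSING in (gm, gf, gc):
        return OriginCall(Origin.AMBIGUOUS)
    call = mendelian_origin(gm, gf, gc)
    if call.value != Origin.AMBIGUOUS:
        return call
    if freqs is None:
        freqs = estimate_window_haplotypes(units or [unit], genotypes,
                                           test_snp, window_snps)
    return _map_call(_posterior_paternal(unit, genotypes, test_snp, freqs))


def estimate_origins(units: list[FamilyUnit], genotypes: GenotypeMatrix,
                     test_snp: int, window_snps: int | None = None,
                     max_ambiguous: int = 12,
                     max_iter: int = 200, tol: float = 1e-6) -> list[OriginCall]:
    """Origin calls for a homogeneous list of units at one SNP.

    Forced configurations get their Mendelian call; ambiguous ones are
    resolved by the window phaser with haplotype frequencies estimated by EM
    across the whole sample (configurations enumerated once and reused for
    the posteriors). Units that cannot be resolved stay AMBIGUOUS.
    """
    kinds = {u.unit_type for u in units}
    if len(kinds) > 1:
        raise ValueError("estimate_origins requires units of a single type")
    if not units:
        return []
    kind = kinds.pop()
    if window_snps is None:
        window_snps = 15 if kind == "trio" else 7

    # single-SNP forced calls first
    calls: list[OriginCall | None] = []
    ambiguous_idx: list[int] = []
    for u_i, unit in enumerate(units):
        gc = int(genotypes.dosage_row(unit.child_id)[test_snp])
        try:
            if kind == "trio":
                gm = int(genotypes.dosage_row(unit.mother_id)[test_snp])
                gf = int(genotypes.dosage_row(unit.father_id)[test_snp])
                if MISSING in (gm, gf, gc):
                    calls.append(OriginCall(Origin.AMBIGUOUS))
                    continue
                call = mendelian_origin(gm, gf, gc)
            else:
                parent = "mother" if kind == "duo_mother" else "father"
                pid = unit.mother_id if parent == "mother" else unit.father_id
                gp = int(genotypes.dosage_row(pid)[test_snp])
                if MISSING in (gp, gc):
                    calls.append(OriginCall(Origin.AMBIGUOUS))
                    continue
                call = duo_mendelian_origin(gp, gc, parent)
        except MendelianInconsistencyError:
            calls.append(OriginCall(Origin.AMBIGUOUS))
            continue
        if call.value == Origin.AMBIGUOUS:
            ambiguous_idx.append(u_i)
            calls.append(None)
        else:
            calls.append(call)
    if not ambiguous_idx:
        return calls  # nothing to phase

    # enumerate configurations once for all units, run EM, read posteriors
    window = _window_indices(genotypes, test_snp, window_snps)
    hap_index: dict[tuple, int] = {}
    cfg_haps: list[list[int]] = []
    cfg_unit: list[int] = []
    cfg_pat: list[bool] = []
    cfg_range: dict[int, tuple[int, int]] = {}
    n_used = 0
    for u_i, unit in enumerate(units):
        configs, pat = _unit_configs(unit, genotypes, window, test_snp,
                                     max_ambiguous)
        if configs is None:
            continue
        start = len(cfg_haps)
        for haps, is_pat in zip(configs, pat):
            cfg_haps.append([hap_index.setdefault(h, len(hap_index))
                             for h in haps])
            cfg_unit.append(n_used)
            cfg_pat.append(is_pat)
        cfg_range[u_i] = (start, len(cfg_haps))
        n_used += 1
    if not cfg_haps:
        for u_i in ambiguous_idx:
            calls[u_i] = OriginCall(Origin.AMBIGUOUS)
        return calls

    idx = np.array(cfg_haps)
    unit_of = np.array(cfg_unit)
    pat_flag = np.array(cfg_pat)
    n_hap = len(hap_index)
    k = idx.shape[1]
    freq = np.full(n_hap, 1.0 / n_hap)
    last_ll = None
    for _ in range(max_iter):
        w = freq[idx].prod(axis=1)
        unit_sum = np.bincount(unit_of, weights=w, minlength=n_used)
        ll = float(np.log(unit_sum).sum())
        wn = w / unit_sum[unit_of]
        counts = np.bincount(idx.ravel(), weights=np.repeat(wn, k),
                             minlength=n_hap)
        freq = counts / counts.sum()
        if last_ll is not None and abs(ll - last_ll) < tol:
            break
        last_ll = ll

    w = freq[idx].prod(axis=1)
    for u_i in ambiguous_idx:
        rng_cfg = cfg_range.get(u_i)
        if rng_cfg is None:
            calls[u_i] = OriginCall(Origin.AMBIGUOUS)
            continue
        lo, hi = rng_cfg
        w_tot = float(w[lo:hi].sum())
        if w_tot <= 0.0:
            calls[u_i] = OriginCall(Origin.AMBIGUOUS)
            continue
        w_pat = float(w[lo:hi][pat_flag[lo:hi]].sum())
        calls[u_i] = _map_call(w_pat / w_tot)
    return calls


# ---------------------------------------------------------------------------
# SHAPEIT haps/sample ingestion

@dataclasses.dataclass
class PhasedUnit:
    """A family unit with the child's haplotypes labelled by parental origin.

    Haplotypes are minor-allele indicator arrays over all SNPs in the haps
    file; the transmitted parental haplotype matches the corresponding child
    haplotype (up to phaser error).
    """

    unit: FamilyUnit
    child_maternal: np.ndarray
    child_paternal: np.ndarray
    parent_haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]

    def origin_call(self, snp: int) -> OriginCall:
        hm = int(self.child_maternal[snp])
        hp = int(self.child_paternal[snp])
        if hm + hp != 1:
            return OriginCall(Origin.NOT_APPLICABLE)
        if hp == 1:
            return OriginCall(Origin.PATERNAL_MINOR, 1.0)
        return OriginCall(Origin.MATERNAL_MINOR, 0.0)

    def origin_calls(self) -> list[OriginCall]:
        return [self.origin_call(j) for j in range(len(self.child_maternal))]


def _read_sample_ids(sample_path: str | Path) -> list[str]:
    lines = [ln.split() for ln in Path(sample_path).read_text().splitlines()
             if ln.split()]
    if len(lines) < 2:
        raise PlinkLikeFormatError(f"{sample_path}: too short for sample file")
    return [ln[1] for ln in lines[2:]]


class PlinkLikeFormatError(ValueError):
    pass


def read_shapeit_haps(haps_path: str | Path, sample_path: str | Path,
                      units: list[FamilyUnit],
                      mismatch_tol: float = 0.1,
                      expected_snps: int | None = None) -> list[PhasedUnit]:
    """Read SHAPEIT haps/sample output and label child haplotypes.

    Child haplotypes are labelled maternal/paternal by matching against the
    typed parents' haplotypes; a unit whose best assignment mismatches more
    than ``mismatch_tol`` of SNPs is dropped with a warning. Alleles are
    recoded so haplotype entries indicate the minor allele (frequency taken
    over the units' parental haplotypes).
    """
    sample_ids = _read_sample_ids(sample_path)
    rows = [ln.split() for ln in Path(haps_path).read_text().splitlines()
            if ln.split()]
    if expected_snps is not None and len(rows) != expected_snps:
        raise PlinkLikeFormatError(
            f"{haps_path}: {len(rows)} SNP rows, expected {expected_snps}")
    n_hap_cols = 2 * len(sample_ids)
    alleles = []
    hap_bits = np.empty((len(rows), n_hap_cols), dtype=np.int8)
    for i, row in enumerate(rows):
        if len(row) != 5 + n_hap_cols:
            raise PlinkLikeFormatError(
                f"{haps_path}: row {i + 1} has {len(row)} columns, expected "
                f"{5 + n_hap_cols} for {len(sample_ids)} samples")
        alleles.append((row[3], row[4]))
        hap_bits[i] = [int(x) for x in row[5:]]

    col = {iid: 2 * i for i, iid in enumerate(sample_ids)}

    def haps_of(iid: str) -> tuple[np.ndarray, np.ndarray]:
        c = col[iid]
        return hap_bits[:, c], hap_bits[:, c + 1]

    # minor-allele orientation from parental (founder) haplotypes
    parent_cols = []
    for u in units:
        for pid in (u.mother_id, u.father_id):
            if pid is not None and pid in col:
                parent_cols.extend([col[pid], col[pid] + 1])
    founder = hap_bits[:, parent_cols] if parent_cols else hap_bits
    freq_b = founder.mean(axis=1)
    minor_is_b = (freq_b < 0.5) | (
        (freq_b == 0.5)
        & np.array([b < a for a, b in alleles]))

    def minor_coded(h: np.ndarray) -> np.ndarray:
        return np.where(minor_is_b, h, 1 - h).astype(np.int8)

    def dist(a, b) -> int:
        return int(np.sum(a != b))

    phased: list[PhasedUnit] = []
    n_snps = len(rows)
    for u in units:
        for iid in u.member_ids():
            if iid not in col:
                raise PlinkLikeFormatError(
                    f"{sample_path}: unit member {iid} not present")
        c1, c2 = haps_of(u.child_id)
        parents: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if u.unit_type == "trio":
            m1, m2 = haps_of(u.mother_id)
            f1, f2 = haps_of(u.father_id)
            score_a = min(dist(c1, m1), dist(c1, m2)) \
                + min(dist(c2, f1), dist(c2, f2))
            score_b = min(dist(c2, m1), dist(c2, m2)) \
                + min(dist(c1, f1), dist(c1, f2))
            cm, cp = (c1, c2) if score_a <= score_b else (c2, c1)
            best = min(score_a, score_b)
            parents = {u.mother_id: (m1, m2), u.father_id: (f1, f2)}
        else:
            pid = u.mother_id if u.unit_type == "duo_mother" else u.father_id
            p1, p2 = haps_of(pid)
            score_a = min(dist(c1, p1), dist(c1, p2))
            score_b = min(dist(c2, p1), dist(c2, p2))
            typed, other = (c1, c2) if score_a <= score_b else (c2, c1)
            best = min(score_a, score_b)
            if u.unit_type == "duo_mother":
                cm, cp = typed, other
            else:
                cm, cp = other, typed
            parents = {pid: (p1, p2)}
        if best > mismatch_tol * max(n_snps, 1):
            warnings.warn(
                f"unit {u.family_id}/{u.child_id}: child haplotypes match no "
                f"parent ({best}/{n_snps} mismatches); unit dropped")
            continue
        phased.append(PhasedUnit(
            unit=u,
            child_maternal=minor_coded(cm),
            child_paternal=minor_coded(cp),
            parent_haplotypes={k: (minor_coded(a), minor_coded(b))
                               for k, (a, b) in parents.items()},
        ))
    return phased
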