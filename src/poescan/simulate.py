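"""Synthetic ascertained family data with haplotype-block LD.

Families are generated on a chromosome made of independent haplotype blocks
(default 25 blocks of 8 SNPs, 200 SNPs total): parental haplotypes are drawn
from a per-block pool (linkage equilibrium across blocks, no recombination
within a block), one haplotype is transmitted from each parent, and the
child is ascertained as affected by rejection sampling with probability
proportional to a multiplicative risk evaluated at the causal SNP (the
100th by default),

    risk = R_gc * S_gm * Im^am * Ip^ap,

where am/ap indicate a minor allele inherited from the mother/father. The
baseline penetrance cancels under ascertainment and is not a parameter.
True parental origins are retained for every SNP, including for duos, whose
untyped parent is dropped from the genotype matrix after sampling.

``run_study`` drives power and type-I-error studies: per replicate it
simulates, resolves origins (known truth, window-phaser estimate, or not at
all), tabulates, optionally applies the genome-wide duo-count adjustment,
fits the imprinting LRT, and scores detection within a window of SNPs
around the causal position.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from . import adjust as adjust_mod
from . import phasing
from .model import genomic_control, lrt_test
from .pedio import (FamilyUnit, GenotypeMatrix, Pedigree, PedigreeMember,
                    SnpInfo)
from .phasing import Origin, OriginCall
from .tabulate import tabulate_snp


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    n_units: int = 1500
    unit_type: str = "trio"  # trio | duo_mother | duo_father
    block_size: int = 8
    n_blocks: int = 25
    causal_index: int = 100  # 1-based SNP position of the causal variant
    Im: float = 1.0
    Ip: float = 1.0
    R1: float = 1.0
    R2: float = 1.0
    S1: float = 1.0
    S2: float = 1.0
    haplotype_pool: list | None = None  # per-block [(haplotype, freq), ...]
    n_haplotypes: int = 6
    seed: int = 0

    @property
    def n_snps(self) -> int:
        return self.block_size * self.n_blocks

    def __post_init__(self) -> None:
        if self.unit_type not in ("trio", "duo_mother", "duo_father"):
            raise ValueError(f"unknown unit type {self.unit_type!r}")
        if not 1 <= self.causal_index <= self.n_snps:
            raise ValueError("causal_index outside the simulated SNP range")
        if self.haplotype_pool is not None \
                and len(self.haplotype_pool) != self.n_blocks:
            raise ValueError("haplotype_pool must supply one pool per block")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def make_haplotype_pool(block_size: int, seed: int, n_haps: int = 6,
                        maf_range: tuple[float, float] = (0.1, 0.4),
                        max_tries: int = 20000) -> list[tuple[tuple, float]]:
    """A pool of distinct block haplotypes with Dirichlet frequencies.

    Resampled until every SNP position in the block has a pool minor-allele
    frequency inside ``maf_range`` (so whichever position is causal is
    well-behaved and within-block LD is informative). Deterministic given
    the seed.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n_haps = min(n_haps, 2 ** block_size)
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    for _ in range(max_tries):
        haps = rng.integers(0, 2, size=(n_haps, block_size))
        if len({tuple(h) for h in haps}) != n_haps:
            continue
        freq = rng.dirichlet(np.ones(n_haps))
        col = freq @ haps
        # relabel alleles so bit 1 is the minor allele at every position
        flip = col > 0.5
        haps[:, flip] = 1 - haps[:, flip]
        col = np.where(flip, 1.0 - col, col)
        if np.all((col >= lo) & (col <= hi)):
            return [(tuple(int(a) for a in h), float(f))
                    for h, f in zip(haps, freq)]
    raise RuntimeError("could not construct a haplotype pool; "
                       "loosen maf_range or increase max_tries")


@dataclasses.dataclass
class SimulatedDataset:
    """Genotypes, family units and per-SNP true parental origins."""

    config: SimConfig
    genotypes: GenotypeMatrix
    units: list[FamilyUnit]
    pedigrees: list[Pedigree]
    am: np.ndarray  # (n_units, n_snps) maternally transmitted minor allele
    ap: np.ndarray  # (n_units, n_snps) paternally transmitted minor allele

    def true_origin_call(self, unit_index: int, snp: int) -> OriginCall:
        a_m = int(self.am[unit_index, snp])
        a_p = int(self.ap[unit_index, snp])
        if a_m + a_p != 1:
            return OriginCall(Origin.NOT_APPLICABLE)
        if a_p == 1:
            return OriginCall(Origin.PATERNAL_MINOR, 1.0)
        return OriginCall(Origin.MATERNAL_MINOR, 0.0)

    def true_origin_calls(self, snp: int) -> list[OriginCall]:
        return [self.true_origin_call(i, snp) for i in range(len(self.units))]


def _max_risk(config: SimConfig) -> float:
    r = (1.0, config.R1, config.R2)
    s = (1.0, config.S1, config.S2)
    best = 0.0
    for am in (0, 1):
        for ap in (0, 1):
            for other in (0, 1):  # mother's untransmitted allele
                gm = am + other
                risk = (r[am + ap] * s[gm]
                        * config.Im ** am * config.Ip ** ap)
                best = max(best, risk)
    return best


def _risk(config: SimConfig, gm, am, ap) -> np.ndarray:
    r = np.array([1.0, config.R1, config.R2])
    s = np.array([1.0, config.S1, config.S2])
    return (r[am + ap] * s[gm]
            * config.Im ** am * config.Ip ** ap)


def _pools(config: SimConfig) -> list[list[tuple[tuple, float]]]:
    if config.haplotype_pool is not None:
        return config.haplotype_pool
    seed_rng = np.random.default_rng(config.seed)
    pool_seeds = seed_rng.integers(0, 2 ** 31 - 1, size=config.n_blocks)
    return [make_haplotype_pool(config.block_size, int(s),
                                config.n_haplotypes)
            for s in pool_seeds]


def sample_family(config: SimConfig, rng: np.random.Generator,
                  pools: list | None = None) -> dict:
    """Draw a single ascertained family (mother, father, child dosage
    vectors plus true transmitted alleles)."""
    ds = _sample_units(config.replace(n_units=1), rng,
                       pools if pools is not None else _pools(config))
    mother_d, father_d, child_d, am, ap = ds
    return {
        "mother": mother_d[0], "father": father_d[0], "child": child_d[0],
        "am": am[0], "ap": ap[0],
    }


def _sample_units(config: SimConfig, rng: np.random.Generator, pools):
    n, S = config.n_units, config.n_snps
    mother_d = np.zeros((n, S), dtype=np.int8)
    father_d = np.zeros((n, S), dtype=np.int8)
    child_d = np.zeros((n, S), dtype=np.int8)
    am = np.zeros((n, S), dtype=np.int8)
    ap = np.zeros((n, S), dtype=np.int8)

    causal_block = (config.causal_index - 1) // config.block_size
    causal_off = (config.causal_index - 1) % config.block_size
    max_risk = _max_risk(config)

    for b, pool in enumerate(pools):
        H = np.array([h for h, _ in pool], dtype=np.int8)
        f = np.array([w for _, w in pool], dtype=float)
        f = f / f.sum()
        cols = slice(b * config.block_size, (b + 1) * config.block_size)

        if b == causal_block and max_risk > 0 and n > 0:
            idx = np.zeros((n, 4), dtype=np.int64)
            tm = np.zeros(n, dtype=np.int64)
            tp = np.zeros(n, dtype=np.int64)
            remaining = np.arange(n)
            while remaining.size:
                m = remaining.size
                cand = rng.choice(len(pool), size=(m, 4), p=f)
                ctm = rng.integers(0, 2, size=m)
                ctp = rng.integers(0, 2, size=m)
                h_mt = H[cand[np.arange(m), ctm], causal_off]
                h_pt = H[cand[np.arange(m), 2 + ctp], causal_off]
                gm_c = H[cand[:, 0], causal_off] + H[cand[:, 1], causal_off]
                risk = _risk(config, gm_c, h_mt, h_pt)
                accept = rng.random(m) < risk / max_risk
                rows = remaining[accept]
                idx[rows] = cand[accept]
                tm[rows] = ctm[accept]
                tp[rows] = ctp[accept]
                remaining = remaining[~accept]
        else:
            idx = rng.choice(len(pool), size=(n, 4), p=f)
            tm = rng.integers(0, 2, size=n)
            tp = rng.integers(0, 2, size=n)

        rows = np.arange(n)
        hm_t = H[idx[rows, tm]]
        hf_t = H[idx[rows, 2 + tp]]
        mother_d[:, cols] = H[idx[:, 0]] + H[idx[:, 1]]
        father_d[:, cols] = H[idx[:, 2]] + H[idx[:, 3]]
        child_d[:, cols] = hm_t + hf_t
        am[:, cols] = hm_t
        ap[:, cols] = hf_t
    return mother_d, father_d, child_d, am, ap


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Simulate an ascertained trio or duo dataset under the config."""
    rng = np.random.default_rng(config.seed)
    pools = _pools(config)
    mother_d, father_d, child_d, am, ap = _sample_units(config, rng, pools)
    n = config.n_units

    keep_mother = config.unit_type in ("trio", "duo_mother")
    keep_father = config.unit_type in ("trio", "duo_father")

    individuals: list[str] = []
    rows: list[np.ndarray] = []
    units: list[FamilyUnit] = []
    pedigrees: list[Pedigree] = []
    for i in range(n):
        fid = f"F{i}"
        mid = f"F{i}_M" if keep_mother else None
        pid = f"F{i}_F" if keep_father else None
        cid = f"F{i}_C"
        members = []
        if keep_father:
            individuals.append(pid)
            rows.append(father_d[i])
            members.append(PedigreeMember(pid, None, None, 1, "unknown"))
        if keep_mother:
            individuals.append(mid)
            rows.append(mother_d[i])
            members.append(PedigreeMember(mid, None, None, 2, "unknown"))
        individuals.append(cid)
        rows.append(child_d[i])
        members.append(PedigreeMember(cid, pid, mid, 0, "affected"))
        pedigrees.append(Pedigree(fid, members))
        units.append(FamilyUnit(config.unit_type, fid, cid,
                                mother_id=mid, father_id=pid))

    dosages = (np.vstack(rows) if rows
               else np.zeros((0, config.n_snps), dtype=np.int8))

    # founder (typed-parent) minor allele frequencies
    parent_rows = []
    if keep_father:
        parent_rows.append(father_d)
    if keep_mother:
        parent_rows.append(mother_d)
    founders = np.vstack(parent_rows) if parent_rows and n > 0 else None
    snps = []
    for j in range(config.n_snps):
        if founders is not None and founders.shape[0]:
            freq = float(founders[:, j].mean()) / 2.0
        else:
            freq = 0.0
        snps.append(SnpInfo(
            snp_id=f"snp{j + 1}",
            chromosome="1",
            position_bp=(j + 1) * 1000,
            allele_minor="2",
            allele_major="1",
            maf=min(freq, 0.5),
        ))

    genotypes = GenotypeMatrix(individuals, snps, dosages)
    return SimulatedDataset(config, genotypes, units, pedigrees, am, ap)


def significance_thresholds(fwer: float, n_tests: int) -> float:
    """Bonferroni per-test p-value threshold for a family-wise error rate."""
    if not 0.0 < fwer < 1.0:
        raise ValueError("fwer must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return fwer / n_tests


@dataclasses.dataclass
class StudyModeResult:
    origin_mode: str
    power: float
    power_ci: tuple[float, float]
    detections: np.ndarray          # (n_replicates,) bool
    p_values: np.ndarray            # (n_replicates, n_tested)
    lrt_values: np.ndarray          # (n_replicates, n_tested)
    lambda_gc: float
    tested_snps: np.ndarray         # 0-based SNP indices tested

    def rejection_rate(self, alpha: float = 0.05) -> float:
        return float(np.mean(self.p_values < alpha))

    def power_at(self, threshold: float,
                 window: np.ndarray | None = None) -> float:
        """Detection proportion at an alternative p-value threshold."""
        cols = (np.isin(self.tested_snps, window) if window is not None
                else slice(None))
        return float((self.p_values[:, cols] < threshold).any(axis=1).mean())


def _replicate_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2 ** 31 - 1) for s in state]


def run_study(config: SimConfig, n_replicates: int, mode: str = "power",
              origin_modes="estimated", test_param: str = "Im",
              conditioning=frozenset(), fwer: float = 0.05,
              n_tests: int = 8, detection_window: tuple[int, int] = (97, 104),
              window_snps: int | None = None, adjust_duo: bool | None = None,
              adjust_degree: int = 3) -> dict[str, StudyModeResult]:
    """Power / type-I-error study over seeded replicates.

    All origin modes ('known', 'estimated', 'unknown') are evaluated on the
    same simulated datasets so mode comparisons share the sampling noise.
    In power mode only the detection window is tested; in type1 mode every
    SNP is tested (all risk parameters must be 1). Duo counts in estimated
    mode are adjusted genome-wide unless ``adjust_duo`` is False.
    """
    if mode not in ("power", "type1"):
        raise ValueError("mode must be 'power' or 'type1'")
    if mode == "type1":
        for name in ("Im", "Ip", "R1", "R2", "S1", "S2"):
            if getattr(config, name) != 1.0:
                raise ValueError("type1 mode requires all risk parameters 1")
    if isinstance(origin_modes, str):
        origin_modes = (origin_modes,)
    for om in origin_modes:
        if om not in ("known", "estimated", "unknown"):
            raise ValueError(f"unknown origin mode {om!r}")

    is_duo = config.unit_type != "trio"
    threshold = significance_thresholds(fwer, n_tests)
    lo, hi = detection_window
    window_idx = np.array([j for j in range(lo - 1, hi)
                           if 0 <= j < config.n_snps])
    if mode == "power":
        tested = window_idx
    else:
        tested = np.arange(config.n_snps)

    seeds = _replicate_seeds(config.seed, n_replicates)
    pvals = {om: np.ones((n_replicates, len(tested))) for om in origin_modes}
    lrts = {om: np.zeros((n_replicates, len(tested))) for om in origin_modes}

    for r, rep_seed in enumerate(seeds):
        ds = simulate_dataset(config.replace(seed=rep_seed))
        for om in origin_modes:
            do_adjust = (adjust_duo if adjust_duo is not None
                         else (is_duo and om == "estimated"))
            snps_needed = (np.arange(config.n_snps)
                           if (is_duo and do_adjust and om == "estimated")
                           else tested)
            tables = {}
            for j in snps_needed:
                j = int(j)
                if om == "known":
                    calls = ds.true_origin_calls(j)
                elif om == "estimated":
                    calls = phasing.estimate_origins(
                        ds.units, ds.genotypes, j, window_snps)
                else:
                    calls = None
                tables[j] = tabulate_snp(ds.units, calls, ds.genotypes, j)

            if is_duo and do_adjust and om == "estimated":
                parent = "mother" if config.unit_type == "duo_mother" \
                    else "father"
                which = 1 if parent == "mother" else 2
                records = [(ds.genotypes.snps[j].maf,
                            tables[j][which].n4a, tables[j][which].n4b)
                           for j in range(config.n_snps)]
                model_adj = adjust_mod.fit_adjustment(
                    records, degree=adjust_degree, parent=parent)
                for j in tables:
                    t, dm, df = tables[j]
                    maf = ds.genotypes.snps[j].maf
                    if parent == "mother":
                        dm = adjust_mod.apply_adjustment(dm, maf, model_adj)
                    else:
                        df = adjust_mod.apply_adjustment(df, maf, model_adj)
                    tables[j] = (t, dm, df)

            for k, j in enumerate(tested):
                trio, dm, df = tables[int(j)]
                result = lrt_test(
                    trio if config.unit_type == "trio" else None,
                    dm if config.unit_type == "duo_mother" else None,
                    df if config.unit_type == "duo_father" else None,
                    test_param=test_param, conditioning=conditioning,
                    snp=ds.genotypes.snps[int(j)])
                pvals[om][r, k] = result.p_value
                lrts[om][r, k] = result.lrt

    out: dict[str, StudyModeResult] = {}
    in_window = np.isin(tested, window_idx)
    for om in origin_modes:
        detections = (pvals[om][:, in_window] < threshold).any(axis=1)
        k = int(detections.sum())
        ci = stats.binomtest(k, n_replicates).proportion_ci(0.95)
        out[om] = StudyModeResult(
            origin_mode=om,
            power=k / n_replicates,
            power_ci=(float(ci.low), float(ci.high)),
            detections=detections,
            p_values=pvals[om],
            lrt_values=lrts[om],
            lambda_gc=genomic_control(lrts[om].ravel()),
            tested_snps=tested,
        )
    return out


def duo_bias_adjustment_study(config: SimConfig,
                              bias=lambda p: 0.25 * (0.5 - p),
                              test_param: str = "Im",
                              adjust_degree: int = 3) -> dict:
    """Demonstrate the duo-count adjustment on biased origin assignments.

    Simulates a null duo dataset, assigns each ambiguous duo's origin with a
    p-dependent paternal probability pi0(p) + bias(p) (mimicking a
    frequency-dependent phaser bias), and compares the genomic-control
    inflation factor of the imprinting test before and after fitting and
    applying the genome-wide adjustment.
    """
    if config.unit_type == "trio":
        raise ValueError("bias study requires a duo config")
    parent = "mother" if config.unit_type == "duo_mother" else "father"
    which = 1 if parent == "mother" else 2
    ds = simulate_dataset(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    tables = {}
    for j in range(config.n_snps):
        p = ds.genotypes.snps[j].maf
        prob_pat = float(np.clip(
            adjust_mod.null_paternal_fraction(max(p, 1e-6), parent)
            + bias(p), 0.0, 1.0))
        calls = []
        for i, unit in enumerate(ds.units):
            gp_id = unit.mother_id if parent == "mother" else unit.father_id
            gp = int(ds.genotypes.dosage_row(gp_id)[j])
            gc = int(ds.genotypes.dosage_row(unit.child_id)[j])
            if gp == 1 and gc == 1:
                if rng.random() < prob_pat:
                    calls.append(OriginCall(Origin.PATERNAL_MINOR, 1.0))
                else:
                    calls.append(OriginCall(Origin.MATERNAL_MINOR, 0.0))
            else:
                calls.append(ds.true_origin_call(i, j))
        tables[j] = tabulate_snp(ds.units, calls, ds.genotypes, j)

    def lambda_of(tabs) -> float:
        vals = []
        for j in range(config.n_snps):
            _, dm, df = tabs[j]
            res = lrt_test(None,
                           dm if parent == "mother" else None,
                           df if parent == "father" else None,
                           test_param=test_param)
            vals.append(res.lrt)
        return genomic_control(vals)

    lambda_before = lambda_of(tables)

    records = [(ds.genotypes.snps[j].maf,
                tables[j][which].n4a, tables[j][which].n4b)
               for j in range(config.n_snps)]
    model_adj = adjust_mod.fit_adjustment(records, degree=adjust_degree,
                                          parent=parent)
    adjusted = {}
    for j in range(config.n_snps):
        t, dm, df = tables[j]
        maf = ds.genotypes.snps[j].maf
        if parent == "mother":
            dm = adjust_mod.apply_adjustment(dm, maf, model_adj)
        else:
            df = adjust_mod.apply_adjustment(df, maf, model_adj)
        adjusted[j] = (t, dm, df)
    lambda_after = lambda_of(adjusted)

    return {"lambda_before": lambda_before, "lambda_after": lambda_after,
            "n_snps": config.n_snps, "model": model_adj}
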