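"""Multinomial likelihood for parent-of-origin effects and LRT machinery.

Cell probabilities are proportional to weights built from the genetic
parameters: child relative risks R1/R2, maternal-genotype relative risks
S1/S2, maternal and paternal imprinting factors Im/Ip, an optional
mother-child interaction gamma11 (carried but fixed at 1 by default), and
mating-type stratification nuisances mu1..mu6 (mu6 = 1 as reference).

A trio in cell (gm, gf, gc) has weight

    mu_mt(gm,gf) * S_gm * R_gc * gamma * sum over consistent ordered
    transmissions (am, ap) of Im^am * Ip^ap

so e.g. the all-heterozygous cell 9 has weight mu4*R1*S1*(Ip+Im)*gamma11,
which splits into mu4*R1*S1*Ip*gamma11 (cell 9a, paternal minor) and
mu4*R1*S1*Im*gamma11 (cell 9b). Duo cell weights are the trio weights summed
over the untyped parent's genotype. Tables with partially phased data use 17
(trio) and 9 (duo) categories — 9/9a/9b and 4/4a/4b kept separate, sharing
parameters — with the 15- and 7-cell normalizers (cell 9 counted once as
w9a + w9b).
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize, stats

from ._mendel import mating_type, transmissions
from .pedio import SnpInfo
from .tabulate import (DUO_CELLS, TRIO_CELLS, TRIO_AMBIGUOUS_CELL,
                       DUO_AMBIGUOUS_CELL, DuoCellCounts, TrioCellCounts)

PARAM_NAMES = ("R1", "R2", "S1", "S2", "Im", "Ip", "gamma11",
               "mu1", "mu2", "mu3", "mu4", "mu5", "mu6")

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # ~0.454936


@dataclasses.dataclass
class ParameterSet:
    """Relative risks, imprinting factors and mating-type nuisances."""

    R1: float = 1.0
    R2: float = 1.0
    S1: float = 1.0
    S2: float = 1.0
    Im: float = 1.0
    Ip: float = 1.0
    gamma11: float = 1.0
    mu: np.ndarray = dataclasses.field(
        default_factory=lambda: np.ones(6))

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (6,):
            raise ValueError("mu must hold six mating-type parameters")

    def get(self, name: str) -> float:
        if name.startswith("mu"):
            return float(self.mu[int(name[2:]) - 1])
        return float(getattr(self, name))

    def set(self, name: str, value: float) -> None:
        if name.startswith("mu"):
            self.mu[int(name[2:]) - 1] = value
        else:
            setattr(self, name, float(value))

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.R1, self.R2, self.S1, self.S2,
                            self.Im, self.Ip, self.gamma11, self.mu.copy())


@dataclasses.dataclass
class ModelSpec:
    """Which parameters are free; the rest stay at their fixed values."""

    free: tuple[str, ...]
    fixed: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [p for p in self.free if p not in PARAM_NAMES]
        if bad:
            raise ValueError(f"unknown parameters: {bad}")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {overlap}")


@dataclasses.dataclass
class FitResult:
    loglik: float
    estimates: ParameterSet
    converged: bool
    n_evals: int


@dataclasses.dataclass
class TestResult:
    snp: SnpInfo | None
    lrt: float
    df: int
    p_value: float
    or_estimate: float
    test_param: str = "Im"
    converged: bool = True
    loglik_alt: float = math.nan
    loglik_null: float = math.nan


# ---------------------------------------------------------------------------
# Cell weights

def _risk_terms(params: ParameterSet):
    r = (1.0, params.R1, params.R2)
    s = (1.0, params.S1, params.S2)
    return r, s


def _gamma(params: ParameterSet, gm: int, gc: int) -> float:
    return params.gamma11 if (gm == 1 and gc == 1) else 1.0


def _trio_weight_terms(gm: int, gf: int, gc: int, params: ParameterSet,
                       restrict_ap: int | None = None) -> float:
    """Sum of transmission terms for one trio cell; restrict_ap selects
    transmissions with the given paternal allele (for 9a/9b splits)."""
    r, s = _risk_terms(params)
    base = (params.mu[mating_type(gm, gf) - 1] * s[gm] * r[gc]
            * _gamma(params, gm, gc))
    acc = 0.0
    for am, ap in transmissions(gm, gf, gc):
        if restrict_ap is not None and ap != restrict_ap:
            continue
        acc += params.Im ** am * params.Ip ** ap
    return base * acc


def trio_cell_weight(cell, params: ParameterSet) -> float:
    """Unnormalized multinomial weight of a trio category (1..15, '9a', '9b')."""
    if cell == "9a":
        return _trio_weight_terms(1, 1, 1, params, restrict_ap=1)
    if cell == "9b":
        return _trio_weight_terms(1, 1, 1, params, restrict_ap=0)
    if not isinstance(cell, (int, np.integer)) or not 1 <= cell <= 15:
        raise ValueError(f"unknown trio cell {cell!r}")
    gm, gf, gc = TRIO_CELLS[cell - 1]
    return _trio_weight_terms(gm, gf, gc, params)


def duo_cell_weight(cell, parent: str, params: ParameterSet) -> float:
    """Unnormalized weight of a duo category (1..7, '4a', '4b').

    Equals the corresponding trio weights summed over the untyped parent's
    genotype (maternal risk terms attach to the mother whether or not she is
    the typed parent).
    """
    if parent not in ("mother", "father"):
        raise ValueError(f"unknown parent type: {parent}")
    restrict = None
    if cell in ("4a", "4b"):
        restrict = 1 if cell == "4a" else 0
        gp, gc = DUO_CELLS[DUO_AMBIGUOUS_CELL - 1]
    else:
        if not isinstance(cell, (int, np.integer)) or not 1 <= cell <= 7:
            raise ValueError(f"unknown duo cell {cell!r}")
        gp, gc = DUO_CELLS[cell - 1]
    acc = 0.0
    for gu in range(3):
        gm, gf = (gp, gu) if parent == "mother" else (gu, gp)
        acc += _trio_weight_terms(gm, gf, gc, params, restrict_ap=restrict)
    return acc


def _trio_weight_vector(params: ParameterSet) -> tuple[np.ndarray, float, float]:
    """Weights for trio cells 1..15 (index 0 unused; cell 9 = w9a + w9b)
    plus the 9a/9b split weights."""
    w = np.zeros(16)
    for c in range(1, 16):
        if c == TRIO_AMBIGUOUS_CELL:
            continue
        w[c] = trio_cell_weight(c, params)
    w9a = trio_cell_weight("9a", params)
    w9b = trio_cell_weight("9b", params)
    w[TRIO_AMBIGUOUS_CELL] = w9a + w9b
    return w, w9a, w9b


def _duo_weight_vector(parent: str, params: ParameterSet):
    w = np.zeros(8)
    for c in range(1, 8):
        if c == DUO_AMBIGUOUS_CELL:
            continue
        w[c] = duo_cell_weight(c, parent, params)
    w4a = duo_cell_weight("4a", parent, params)
    w4b = duo_cell_weight("4b", parent, params)
    w[DUO_AMBIGUOUS_CELL] = w4a + w4b
    return w, w4a, w4b


def _xlogy(n: float, w: float) -> float:
    if n == 0.0:
        return 0.0
    if w <= 0.0:
        return -math.inf
    return n * math.log(w)


def _trio_loglik(counts: TrioCellCounts, params: ParameterSet) -> float:
    w, w9a, w9b = _trio_weight_vector(params)
    total = counts.total
    if total == 0.0:
        return 0.0
    keep = w[1:] > 0.0
    W = float(w[1:][keep].sum())
    ll = -total * math.log(W)
    for c in range(1, 16):
        ll += _xlogy(float(counts.n[c]), w[c])
    ll += _xlogy(counts.n9a, w9a)
    ll += _xlogy(counts.n9b, w9b)
    return ll


def _duo_loglik(counts: DuoCellCounts, params: ParameterSet) -> float:
    w, w4a, w4b = _duo_weight_vector(counts.parent, params)
    total = counts.total
    if total == 0.0:
        return 0.0
    keep = w[1:] > 0.0
    W = float(w[1:][keep].sum())
    ll = -total * math.log(W)
    for c in range(1, 8):
        ll += _xlogy(float(counts.n[c]), w[c])
    ll += _xlogy(counts.n4a, w4a)
    ll += _xlogy(counts.n4b, w4b)
    return ll


def loglik(trio_counts: TrioCellCounts | None,
           duo_counts_m: DuoCellCounts | None,
           duo_counts_f: DuoCellCounts | None,
           params: ParameterSet) -> float:
    """Joint multinomial log-likelihood (multinomial constant omitted).

    The overall likelihood is the product of the likelihoods of the tables
    present; each table is normalized by its own 15- or 7-cell total (cell
    9/4 counted once as the sum of its split weights). Returns -inf when a
    positive count sits on a zero-weight cell.
    """
    ll = 0.0
    if trio_counts is not None:
        ll += _trio_loglik(trio_counts, params)
    if duo_counts_m is not None:
        if duo_counts_m.parent != "mother":
            raise ValueError("duo_counts_m must be a mother-duo table")
        ll += _duo_loglik(duo_counts_m, params)
    if duo_counts_f is not None:
        if duo_counts_f.parent != "father":
            raise ValueError("duo_counts_f must be a father-duo table")
        ll += _duo_loglik(duo_counts_f, params)
    return ll


# ---------------------------------------------------------------------------
# Fitting

_TRIO_CELL_MT = {c: mating_type(*TRIO_CELLS[c - 1][:2]) for c in range(1, 16)}

# mating types feeding each duo cell's weight, per typed parent
_DUO_CELL_MTS: dict[str, dict] = {}
for _parent in ("mother", "father"):
    d = {}
    for _c in range(1, 8):
        gp, gc = DUO_CELLS[_c - 1]
        mts = set()
        for gu in range(3):
            gm, gf = (gp, gu) if _parent == "mother" else (gu, gp)
            if transmissions(gm, gf, gc):
                mts.add(mating_type(gm, gf))
        d[_c] = mts
    d["4a"] = d[DUO_AMBIGUOUS_CELL]
    d["4b"] = d[DUO_AMBIGUOUS_CELL]
    _DUO_CELL_MTS[_parent] = d


def _observed_mating_types(trio_counts, duo_m, duo_f) -> set[int]:
    """Mating types whose mu parameter supports at least one positive count."""
    seen: set[int] = set()
    if trio_counts is not None:
        for c in range(1, 16):
            if trio_counts.n[c] > 0:
                seen.add(_TRIO_CELL_MT[c])
        if trio_counts.n9a > 0 or trio_counts.n9b > 0:
            seen.add(_TRIO_CELL_MT[TRIO_AMBIGUOUS_CELL])
    for table in (duo_m, duo_f):
        if table is None:
            continue
        mts = _DUO_CELL_MTS[table.parent]
        for c in range(1, 8):
            if table.n[c] > 0:
                seen |= mts[c]
        if table.n4a > 0 or table.n4b > 0:
            seen |= mts["4a"]
    return seen


def _profile_mu_loglik(counts: TrioCellCounts, params: ParameterSet) -> float:
    """Trio log-likelihood profiled over free mating-type parameters.

    Valid when the trio table is the only table and all observed mating
    types' mu are free: the mating-type margin then attains n_mt/N exactly
    and the within-stratum terms depend only on the non-mu parameters.
    """
    total = counts.total
    if total == 0.0:
        return 0.0
    unit = params.copy()
    unit.mu = np.ones(6)
    w, w9a, w9b = _trio_weight_vector(unit)

    n_mt = np.zeros(7)
    v_mt = np.zeros(7)
    for c in range(1, 16):
        mt = _TRIO_CELL_MT[c]
        n_mt[mt] += counts.n[c]
        v_mt[mt] += w[c]
    mt9 = _TRIO_CELL_MT[TRIO_AMBIGUOUS_CELL]
    n_mt[mt9] += counts.n9a + counts.n9b

    ll = 0.0
    for mt in range(1, 7):
        if n_mt[mt] > 0:
            ll += n_mt[mt] * (math.log(n_mt[mt] / total) - math.log(v_mt[mt]))
    for c in range(1, 16):
        ll += _xlogy(float(counts.n[c]), w[c])
    ll += _xlogy(counts.n9a, w9a)
    ll += _xlogy(counts.n9b, w9b)
    return ll


def _profile_mu_estimates(counts: TrioCellCounts,
                          params: ParameterSet) -> np.ndarray:
    """mu attaining the profiled optimum, scaled so the reference (mt6 when
    observed, otherwise the largest-count stratum) equals 1."""
    unit = params.copy()
    unit.mu = np.ones(6)
    w, _, _ = _trio_weight_vector(unit)
    n_mt = np.zeros(7)
    v_mt = np.zeros(7)
    for c in range(1, 16):
        mt = _TRIO_CELL_MT[c]
        n_mt[mt] += counts.n[c]
        v_mt[mt] += w[c]
    n_mt[_TRIO_CELL_MT[TRIO_AMBIGUOUS_CELL]] += counts.n9a + counts.n9b
    raw = np.zeros(6)
    for mt in range(1, 7):
        raw[mt - 1] = n_mt[mt] / v_mt[mt] if v_mt[mt] > 0 else 0.0
    ref = raw[5] if n_mt[6] > 0 else raw.max()
    return raw / ref if ref > 0 else raw


_MU_NAMES = tuple(f"mu{i}" for i in range(1, 7))

# log-space search bound: e^15 ~ 3e6, far beyond any plausible relative
# risk or mating-type ratio; prevents drift along flat likelihood directions
_LOG_BOUND = 15.0


def _optimizer_converged(res) -> bool:
    """Success flag robust to finite-difference noise.

    Near the optimum the numerical gradient bottoms out at roughly machine
    epsilon times the objective magnitude over the step size; a line search
    that stalls there is converged even when the optimizer reports an
    abnormal termination.
    """
    if res.success:
        return True
    jac = np.atleast_1d(getattr(res, "jac", np.array([np.inf])))
    noise_floor = 1e-6 * max(1.0, abs(float(res.fun)))
    return bool(np.all(np.abs(jac) <= noise_floor))


def fit(trio_counts: TrioCellCounts | None,
        duo_counts_m: DuoCellCounts | None,
        duo_counts_f: DuoCellCounts | None,
        spec: ModelSpec,
        start: ParameterSet | None = None) -> FitResult:
    """Maximize the joint log-likelihood over the spec's free parameters.

    Optimization runs over log-transformed parameters (unconstrained).
    Free mating-type parameters whose stratum supports no positive count are
    fixed at their MLE limit of exactly 0. When only a trio table is present
    and every supported mating-type parameter is free, the mu block is
    profiled out analytically and only the remaining parameters are
    optimized numerically.
    """
    tables = [t for t in (trio_counts, duo_counts_m, duo_counts_f)
              if t is not None and t.total > 0]
    if not tables:
        raise ValueError("fit requires a positive total count")
    trio_only = (len(tables) == 1 and isinstance(tables[0], TrioCellCounts))
    trio_counts = trio_counts if trio_counts is not None \
        and trio_counts.total > 0 else None
    duo_counts_m = duo_counts_m if duo_counts_m is not None \
        and duo_counts_m.total > 0 else None
    duo_counts_f = duo_counts_f if duo_counts_f is not None \
        and duo_counts_f.total > 0 else None

    params0 = (start.copy() if start is not None else ParameterSet())
    for name, value in spec.fixed.items():
        params0.set(name, value)

    observed = _observed_mating_types(trio_counts, duo_counts_m, duo_counts_f)
    free = list(spec.free)
    for i in range(1, 7):
        name = f"mu{i}"
        if name in free and i not in observed:
            free.remove(name)
            params0.set(name, 0.0)

    free_mu = [p for p in free if p in _MU_NAMES]
    free_other = [p for p in free if p not in _MU_NAMES]
    supported_mu = {f"mu{i}" for i in observed if i != 6}
    profile = (trio_only and trio_counts is not None
               and supported_mu <= set(free_mu))

    if profile:
        def objective_params(x: np.ndarray) -> ParameterSet:
            p = params0.copy()
            for name, xi in zip(free_other, x):
                p.set(name, math.exp(xi))
            return p

        def neg_ll(x: np.ndarray) -> float:
            return -_profile_mu_loglik(trio_counts, objective_params(x))

        if not free_other:
            ll = _profile_mu_loglik(trio_counts, params0)
            est = params0.copy()
            est.mu = _profile_mu_estimates(trio_counts, est)
            return FitResult(ll, est, True, 1)
        x0 = np.array([math.log(max(params0.get(p), 1e-8))
                       for p in free_other])
        res = optimize.minimize(neg_ll, x0, method="L-BFGS-B",
                                bounds=[(-_LOG_BOUND, _LOG_BOUND)] * len(x0),
                                options={"maxiter": 500, "ftol": 1e-10,
                                         "gtol": 1e-6})
        est = objective_params(res.x)
        est.mu = _profile_mu_estimates(trio_counts, est)
        return FitResult(-float(res.fun), est, _optimizer_converged(res),
                         int(res.nfev))

    free_all = free_other + free_mu

    def build(x: np.ndarray) -> ParameterSet:
        p = params0.copy()
        for name, xi in zip(free_all, x):
            p.set(name, math.exp(xi))
        return p

    def neg_ll(x: np.ndarray) -> float:
        val = loglik(trio_counts, duo_counts_m, duo_counts_f, build(x))
        return -val if math.isfinite(val) else 1e12

    if not free_all:
        ll = loglik(trio_counts, duo_counts_m, duo_counts_f, params0)
        return FitResult(ll, params0.copy(), True, 1)
    x0 = np.array([math.log(max(params0.get(p), 1e-8)) for p in free_all])
    res = optimize.minimize(neg_ll, x0, method="L-BFGS-B",
                            bounds=[(-_LOG_BOUND, _LOG_BOUND)] * len(x0),
                            options={"maxiter": 1000, "ftol": 1e-10,
                                     "gtol": 1e-6})
    return FitResult(-float(res.fun), build(res.x), _optimizer_converged(res),
                     int(res.nfev))


def build_specs(test_param: str,
                conditioning=frozenset()) -> tuple[ModelSpec, ModelSpec]:
    """Alternative and null model specs for an imprinting LRT.

    The alternative frees the tested imprinting parameter plus R1/R2 if
    conditioning on child effects and S1/S2 if conditioning on maternal
    effects, always with the mating-type nuisances; the null fixes the
    tested parameter at 1.
    """
    if test_param not in ("Im", "Ip"):
        raise ValueError("test_param must be 'Im' or 'Ip'")
    conditioning = set(conditioning)
    unknown = conditioning - {"child", "maternal"}
    if unknown:
        raise ValueError(f"unknown conditioning terms: {unknown}")
    base = ["mu1", "mu2", "mu3", "mu4", "mu5"]
    if "child" in conditioning:
        base += ["R1", "R2"]
    if "maternal" in conditioning:
        base += ["S1", "S2"]
    alt = ModelSpec(free=tuple([test_param] + base))
    null = ModelSpec(free=tuple(base), fixed={test_param: 1.0})
    return alt, null


def lrt_test(trio_counts: TrioCellCounts | None,
             duo_counts_m: DuoCellCounts | None,
             duo_counts_f: DuoCellCounts | None,
             test_param: str = "Im",
             conditioning=frozenset(),
             snp: SnpInfo | None = None) -> TestResult:
    """1-df likelihood-ratio test of an imprinting parameter at one SNP."""
    alt_spec, null_spec = build_specs(test_param, conditioning)
    alt = fit(trio_counts, duo_counts_m, duo_counts_f, alt_spec)
    null = fit(trio_counts, duo_counts_m, duo_counts_f, null_spec)
    lrt = max(0.0, 2.0 * (alt.loglik - null.loglik))
    p = float(stats.chi2.sf(lrt, 1))
    return TestResult(
        snp=snp,
        lrt=lrt,
        df=1,
        p_value=p,
        or_estimate=alt.estimates.get(test_param),
        test_param=test_param,
        converged=alt.converged and null.converged,
        loglik_alt=alt.loglik,
        loglik_null=null.loglik,
    )


def genomic_control(lrt_values) -> float:
    """Genomic-control inflation factor: median LRT over the chi2(1) median."""
    values = np.asarray(list(lrt_values), dtype=float)
    if values.size == 0:
        raise ValueError("genomic_control requires at least one value")
    return float(np.median(values) / CHI2_1_MEDIAN)
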