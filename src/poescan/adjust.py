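"""Genome-wide bias adjustment for phased duo counts.

Haplotype-based origin assignment in duos can be systematically biased
toward one parent, as a function of the minor allele frequency p, which
inflates the imprinting test. Because a genome scan tests many SNPs of which
the vast majority carry no parent-of-origin effect, the bias is estimable
genome-wide: the expected paternal-origin fraction among ambiguous duos
under the null is a known function of p, and the per-SNP deviation of the
observed cell-4a count from that expectation is fitted as a smooth curve
f(p). Counts are then adjusted by subtracting f(p) from cell 4a and adding
it to cell 4b, preserving totals (adjusted counts may be non-integer). A
genuinely skewed causal SNP moves the genome-wide fit only marginally, so
its own signal survives the adjustment. The procedure is not suitable for a
small candidate-SNP panel.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .tabulate import DuoCellCounts


@dataclasses.dataclass
class AdjustmentModel:
    """Fitted deviation curve f(p) for one duo parent type."""

    parent: str
    coefficients: np.ndarray  # ascending powers of p
    degree: int
    n_snps_fit: int

    def f(self, p) -> np.ndarray | float:
        p = np.asarray(p, dtype=float)
        out = np.polynomial.polynomial.polyval(p, self.coefficients)
        return float(out) if out.ndim == 0 else out


def null_paternal_fraction(p: float, parent: str = "mother") -> float:
    """Expected paternal-origin fraction of ambiguous duos under the null.

    For a case-mother duo with mother and child heterozygous, under random
    mating and HWE with no effects: the mother transmits the major allele
    with probability 1/2 while a random paternal allele is minor with
    probability p, and symmetrically for the maternal-origin term, so the
    paternal fraction is p/(p+q) = p. Case-father duos give 1 - p by the
    mother/father symmetry.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0.0) or np.any(p_arr > 0.5):
        raise ValueError("minor allele frequency must lie in (0, 0.5]")
    frac = p_arr if parent == "mother" else 1.0 - p_arr
    return float(frac) if frac.ndim == 0 else frac


def fit_adjustment(records, degree: int = 3, parent: str = "mother",
                   min_snps: int = 50) -> AdjustmentModel:
    """Fit the genome-wide deviation curve f(p) by weighted least squares.

    ``records`` is an iterable of per-SNP (maf, n4a, n4b) triples (or a
    3-column array). The deviation d = n4a - (n4a + n4b) * pi0(p) is modeled
    as a polynomial in p, weighted by the informative count n4a + n4b.
    """
    arr = np.asarray([tuple(r) for r in records], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("records must be (maf, n4a, n4b) triples")
    maf, n4a, n4b = arr.T
    tot = n4a + n4b
    keep = tot > 0
    if int(keep.sum()) < min_snps:
        raise ValueError(
            f"only {int(keep.sum())} SNPs have informative duo counts "
            f"(< {min_snps}); the adjustment needs a genome-wide SNP set and "
            f"is not suitable for a small number of candidate SNPs")
    p = np.clip(maf[keep], 1e-6, 0.5)
    dev = n4a[keep] - tot[keep] * null_paternal_fraction(p, parent)
    coef = np.polynomial.polynomial.polyfit(
        p, dev, deg=degree, w=np.sqrt(tot[keep]))
    return AdjustmentModel(parent=parent, coefficients=np.atleast_1d(coef),
                           degree=degree, n_snps_fit=int(keep.sum()))


def adjustment_report(records, model: AdjustmentModel,
                      n_bins: int = 10) -> list[dict]:
    """Per-MAF-bin summary of observed deviations and the fitted curve."""
    arr = np.asarray([tuple(r) for r in records], dtype=float)
    maf, n4a, n4b = arr.T
    tot = n4a + n4b
    keep = tot > 0
    p = np.clip(maf[keep], 1e-6, 0.5)
    dev = n4a[keep] - tot[keep] * null_paternal_fraction(p, model.parent)
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (p > lo) & (p <= hi)
        if not mask.any():
            continue
        mid = (lo + hi) / 2
        rows.append({
            "maf_bin_low": float(lo), "maf_bin_high": float(hi),
            "n_snps": int(mask.sum()),
            "mean_deviation": float(dev[mask].mean()),
            "fitted_f": float(model.f(mid)),
        })
    return rows


def apply_adjustment(counts: DuoCellCounts, maf: float,
                     model: AdjustmentModel) -> DuoCellCounts:
    """Shift f(p) of the ambiguous phased mass from cell 4a to cell 4b.

    Clips at zero while preserving n4a + n4b; every other cell is unchanged.
    """
    if counts.parent != model.parent:
        raise ValueError(
            f"adjustment fitted for {model.parent}-duos applied to a "
            f"{counts.parent}-duo table")
    f = float(model.f(maf))
    total = counts.n4a + counts.n4b
    a = counts.n4a - f
    b = counts.n4b + f
    if a < 0.0:
        a, b = 0.0, total
    elif b < 0.0:
        a, b = total, 0.0
    return DuoCellCounts(parent=counts.parent, n=counts.n.copy(),
                         n4a=a, n4b=b)
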