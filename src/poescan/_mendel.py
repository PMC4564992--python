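"""Core Mendelian transmission combinatorics shared across modules.

Genotypes are coded as minor-allele dosages in {0, 1, 2}. A transmission is
an ordered pair (am, ap): the number of minor alleles (0 or 1) passed by the
mother and by the father, so the child dosage is gc = am + ap.
"""
from __future__ import annotations

MISSING = -1

_ALLELES = {0: (0,), 1: (0, 1), 2: (1,)}


def transmissions(gm: int, gf: int, gc: int) -> list[tuple[int, int]]:
    """Ordered (maternal, paternal) transmissions consistent with a trio.

    Returns the empty list for Mendelian-inconsistent dosage triples.
    """
    return [
        (am, ap)
        for am in _ALLELES[gm]
        for ap in _ALLELES[gf]
        if am + ap == gc
    ]


def is_consistent(gm: int, gf: int, gc: int) -> bool:
    return bool(transmissions(gm, gf, gc))


def duo_transmissions(gp: int, gc: int) -> list[tuple[int, int]]:
    """Consistent (typed-parent allele, other-parent allele) pairs for a duo.

    The untyped parent may carry any genotype, so their transmitted allele is
    free in {0, 1} subject to gc = a_typed + a_other.
    """
    return [
        (a, gc - a)
        for a in _ALLELES[gp]
        if gc - a in (0, 1)
    ]


def mating_type(g1: int, g2: int) -> int:
    """Mating-type stratum (1..6) of an unordered parental genotype pair.

    mt1 = 2x2, mt2 = 2x1, mt3 = 2x0, mt4 = 1x1, mt5 = 1x0, mt6 = 0x0
    (numbers are minor-allele dosages; pairs are unordered).
    """
    hi, lo = max(g1, g2), min(g1, g2)
    return {
        (2, 2): 1,
        (2, 1): 2,
        (2, 0): 3,
        (1, 1): 4,
        (1, 0): 5,
        (0, 0): 6,
    }[(hi, lo)]
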