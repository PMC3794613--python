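"""Independent brute-force oracles, exact rational arithmetic throughout.

These deliberately re-derive every quantity from first principles with
explicit nested loops and :class:`fractions.Fraction`, sharing no code
path with the package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb


def brute_pair_frequencies(
    codon_lists: list[list[str]], assignment: dict[str, str]
) -> tuple[dict[tuple[str, str], Fraction], int, int]:
    """Pooled unordered-pair frequencies from explicit dicodon enumeration.

    Returns (freqs, usable_total, dropped).  Pair keys are sorted id tuples.
    """
    counts: dict[tuple[str, str], int] = {}
    dropped = 0
    for codons in codon_lists:
        for i in range(len(codons) - 1):
            x, y = codons[i], codons[i + 1]
            ax, ay = assignment.get(x), assignment.get(y)
            if ax is None or ay is None:
                dropped += 1
                continue
            key = (ax, ay) if ax <= ay else (ay, ax)
            counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    freqs = {k: Fraction(n, total) for k, n in counts.items()} if total else {}
    return freqs, total, dropped


def brute_mean_frequencies(
    codon_lists: list[list[str]], assignment: dict[str, str]
) -> dict[tuple[str, str], Fraction]:
    """Equal-weight-per-transcript average of per-record frequency vectors."""
    vectors = []
    for codons in codon_lists:
        freqs, total, _ = brute_pair_frequencies([codons], assignment)
        if total:
            vectors.append(freqs)
    acc: dict[tuple[str, str], Fraction] = {}
    for vec in vectors:
        for k, f in vec.items():
            acc[k] = acc.get(k, Fraction(0)) + f / len(vectors)
    return acc


def brute_efactors(
    poi: dict[tuple[str, str], Fraction],
    bg: dict[tuple[str, str], Fraction],
    universe: list[tuple[str, str]],
) -> dict[tuple[str, str], Fraction | float]:
    """E = f_poi / f_bg per universe pair; 0 when f_poi = 0, inf when bg = 0."""
    out: dict[tuple[str, str], Fraction | float] = {}
    for pair in universe:
        fp = poi.get(pair, Fraction(0))
        fb = bg.get(pair, Fraction(0))
        if fp == 0:
            out[pair] = Fraction(0)
        elif fb == 0:
            out[pair] = math.inf
        else:
            out[pair] = fp / fb
    return out


def brute_rarity_ranks(
    bg: dict[tuple[str, str], Fraction], universe: list[tuple[str, str]]
) -> dict[tuple[str, str], int]:
    """Competition rank of background frequency, 1 = rarest, ties share minimum."""
    out = {}
    for pair in universe:
        f = bg.get(pair, Fraction(0))
        out[pair] = 1 + sum(
            1 for q in universe if bg.get(q, Fraction(0)) < f
        )
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p by exhaustive hypergeometric tail summation.

    Sums, over all tables with the same margins, the point probabilities
    that do not exceed the observed table's probability (exact rational
    comparison, ties included).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return Fraction(1)
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum((pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs), Fraction(0))
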