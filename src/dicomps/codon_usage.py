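"""Relative codon usage and between-set codon enrichment testing.

Pools codon counts over a set of CDSs and compares the relative usage of a
chosen codon between two sets (e.g. a viral transcriptome versus host
sequences) with a two-sided Fisher's exact test on the 2x2 table of codon
versus rest-of-denominator counts.  The denominator is either all sense
codons (default) or the codon's synonymous family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Mapping

from scipy.stats import chi2_contingency, fisher_exact

from .cds_io import Transcriptome
from .genetic_code import CODON_TO_AA3, SENSE_CODONS, SYNONYMOUS_FAMILY

Denominator = Literal["all_codons", "synonymous_family"]


@dataclass(frozen=True)
class CodonUsageTable:
    """Pooled codon counts and relative frequencies over the 61 sense codons."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the summed codon counts")

    @property
    def freqs(self) -> dict[str, Fraction]:
        return {c: Fraction(n, self.total) for c, n in self.counts.items()}

    def to_tsv(self) -> str:
        lines = ["codon\tcount\tfrequency"]
        for codon in SENSE_CODONS:
            n = self.counts.get(codon, 0)
            lines.append(f"{codon}\t{n}\t{n / self.total:.6g}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class EnrichmentResult:
    codon: str
    fold: float | None  # None when undefined (codon absent from both sets)
    table2x2: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    test_name: str
    denominator: str
    flags: frozenset[str] = frozenset()

    def to_json_dict(self) -> dict:
        return {
            "codon": self.codon,
            "fold": self.fold,
            "p_value": self.p_value,
            "table": [list(self.table2x2[0]), list(self.table2x2[1])],
            "test_name": self.test_name,
            "denominator": self.denominator,
            "flags": sorted(self.flags),
        }


def codon_usage(transcriptome: Transcriptome) -> CodonUsageTable:
    """Pooled codon counts over all records (terminal stops already stripped)."""
    counts: Counter[str] = Counter()
    for rec in transcriptome:
        counts.update(rec.codons)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no usable codons in transcriptome")
    return CodonUsageTable(counts=dict(counts), total=total)


def _denominator_counts(usage: CodonUsageTable, codon: str, denominator: Denominator) -> int:
    if denominator == "all_codons":
        return usage.total
    family = SYNONYMOUS_FAMILY[CODON_TO_AA3[codon]]
    return sum(usage.counts.get(c, 0) for c in family)


def codon_enrichment_test(
    codon: str,
    set_a: Transcriptome,
    set_b: Transcriptome,
    denominator: Denominator = "all_codons",
    test: Literal["fisher", "g_test"] = "fisher",
) -> EnrichmentResult:
    """Test whether ``codon`` is used more in set A than in set B.

    fold = (relative usage in A) / (relative usage in B); the p-value comes
    from a two-sided Fisher's exact test (default) or a G-test on the 2x2
    table [[codon_A, rest_A], [codon_B, rest_B]].
    """
    if codon not in CODON_TO_AA3:
        raise ValueError(f"{codon!r} is not a sense codon")
    usage_a, usage_b = codon_usage(set_a), codon_usage(set_b)
    a = usage_a.counts.get(codon, 0)
    b = usage_b.counts.get(codon, 0)
    denom_a = _denominator_counts(usage_a, codon, denominator)
    denom_b = _denominator_counts(usage_b, codon, denominator)
    table = ((a, denom_a - a), (b, denom_b - b))

    flags: set[str] = set()
    if a == 0 and b == 0:
        return EnrichmentResult(
            codon=codon, fold=None, table2x2=table, p_value=1.0,
            test_name="undefined", denominator=denominator,
            flags=frozenset({"absent_from_both"}),
        )
    if a == 0 or b == 0:
        flags.add("zero_in_one_set")
        fold = None if b == 0 else 0.0
        if b == 0:
            flags.add("infinite_fold")
    else:
        fold = float(Fraction(a, denom_a) / Fraction(b, denom_b))

    if test == "fisher":
        _, p = fisher_exact(table, alternative="two-sided")
        name = "fisher_exact_two_sided"
    elif test == "g_test":
        if min(denom_a, denom_b) == 0:
            raise ValueError("G-test requires nonzero denominators")
        res = chi2_contingency(table, correction=False, lambda_="log-likelihood")
        p, name = float(res.pvalue), "g_test"
    else:
        raise ValueError(f"unknown test {test!r}")
    return EnrichmentResult(
        codon=codon, fold=fold, table2x2=table, p_value=float(p),
        test_name=name, denominator=denominator, flags=frozenset(flags),
    )
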