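"""Dicodon counting and unordered tRNA-pair frequency estimation.

A *dicodon* is an ordered pair of adjacent codons; during elongation its
two codons occupy the ribosome's P and A sites simultaneously, so the two
decoding isoacceptors sit side by side — the physical basis of the FRET
signal.  This module counts overlapping dicodons (width 2, step 1, never
spanning record boundaries), maps them through a codon assignment to
unordered isoacceptor-pair counts, and normalizes to frequencies.

Frequencies are kept as exact :class:`fractions.Fraction` internally so
that normalization and downstream enrichment ratios are reproducible to
the last bit; they are rendered as decimals only at serialization time.

Background estimation assumes uniform transcript and translation levels:
either all records are pooled into one dicodon population (``pooled``,
default) or per-record frequency vectors are averaged with equal weight
per transcript (``mean``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Mapping

from .cds_io import CodingSequence, Transcriptome
from .decoding import CodonAssignment, TrnaPair

BackgroundMode = Literal["pooled", "mean"]


@dataclass(frozen=True)
class DicodonCounts:
    """Counts of ordered adjacent codon pairs."""

    counts: Mapping[tuple[str, str], int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of dicodon counts")


@dataclass(frozen=True)
class PairCounts:
    """Unordered isoacceptor-pair counts derived from dicodon counts.

    ``dropped`` counts dicodons whose codons had no assigned isoacceptor;
    ``total + dropped`` equals the originating dicodon total.
    """

    counts: Mapping[TrnaPair, int]
    total: int
    dropped: int = 0


@dataclass(frozen=True)
class PairFrequencies:
    """Normalized unordered-pair frequencies over a support of dicodons.

    Pairs absent from ``freqs`` have frequency exactly 0.  ``support_total``
    is the denominator (usable dicodons for pooled/single-CDS estimates).
    """

    freqs: Mapping[TrnaPair, Fraction]
    support_total: int
    mode: str = "pooled"
    label: str = ""
    dropped: int = 0

    def __post_init__(self) -> None:
        if self.support_total > 0 and sum(self.freqs.values()) != 1:
            raise ValueError("frequencies must sum to exactly 1")

    def get(self, pair: TrnaPair) -> Fraction:
        return self.freqs.get(pair, Fraction(0))

    def counts(self) -> dict[TrnaPair, Fraction]:
        """Effective counts (frequency x support); exact for pooled mode."""
        return {p: f * self.support_total for p, f in self.freqs.items()}

    def to_tsv(self) -> str:
        lines = [
            f"# mode={self.mode}",
            f"# label={self.label}",
            f"# support_total={self.support_total}",
            f"# dropped={self.dropped}",
            "pair_id\tcount\tfrequency",
        ]
        for pair in sorted(self.freqs):
            f = self.freqs[pair]
            lines.append(f"{pair.id}\t{float(f * self.support_total):.6g}\t{float(f):.6g}")
        return "\n".join(lines) + "\n"


def count_dicodons(source: CodingSequence | Transcriptome) -> DicodonCounts:
    """Count overlapping dicodons (width 2, step 1) in a CDS or transcriptome.

    Windows never span record boundaries, and a window is only counted when
    its two codons were adjacent in the original transcript (codons dropped
    for ambiguity leave gaps that suppress both overlapping windows).
    """
    records = source.records if isinstance(source, Transcriptome) else (source,)
    counts: Counter[tuple[str, str]] = Counter()
    for rec in records:
        codons, positions = rec.codons, rec.positions
        for i in range(len(codons) - 1):
            if positions[i + 1] - positions[i] == 1:
                counts[(codons[i], codons[i + 1])] += 1
    return DicodonCounts(counts=dict(counts), total=sum(counts.values()))


def aggregate_pair_counts(dicodons: DicodonCounts, assignment: CodonAssignment) -> PairCounts:
    """Fold ordered dicodon counts into unordered isoacceptor-pair counts.

    A dicodon (x, y) contributes to the unordered pair {assign(x), assign(y)};
    dicodons touching an unassignable codon are tallied as ``dropped``.
    """
    counts: Counter[TrnaPair] = Counter()
    dropped = 0
    for (x, y), n in dicodons.counts.items():
        ax, ay = assignment.get(x), assignment.get(y)
        if ax is None or ay is None:
            dropped += n
        else:
            counts[TrnaPair.of(ax, ay)] += n
    return PairCounts(counts=dict(counts), total=sum(counts.values()), dropped=dropped)


def _frequencies_from_counts(
    pc: PairCounts, mode: str, label: str
) -> PairFrequencies:
    if pc.total == 0:
        raise ValueError(f"{label or 'input'}: no usable dicodons to normalize")
    freqs = {p: Fraction(n, pc.total) for p, n in pc.counts.items()}
    return PairFrequencies(
        freqs=freqs, support_total=pc.total, mode=mode, label=label, dropped=pc.dropped
    )


def poi_frequencies(poi: CodingSequence, assignment: CodonAssignment) -> PairFrequencies:
    """Unordered-pair frequencies of a single protein of interest."""
    if len(poi) < 2:
        raise ValueError(f"{poi.id}: POI too short for dicodon analysis (< 2 codons)")
    pc = aggregate_pair_counts(count_dicodons(poi), assignment)
    return _frequencies_from_counts(pc, mode="poi", label=poi.id)


def pooled_background_frequencies(
    transcriptome: Transcriptome,
    assignment: CodonAssignment,
    mode: BackgroundMode = "pooled",
) -> PairFrequencies:
    """Background pair frequencies under uniform transcript/translation levels.

    ``pooled`` (default) pools all records' pair counts and divides by the
    pooled usable-dicodon total; ``mean`` averages per-record frequency
    vectors with equal weight per transcript (records without usable
    dicodons are excluded from the average).
    """
    if mode == "pooled":
        pc = aggregate_pair_counts(count_dicodons(transcriptome), assignment)
        return _frequencies_from_counts(pc, mode="pooled", label=transcriptome.label)

    if mode != "mean":
        raise ValueError(f"unknown background mode {mode!r}")
    per_record: list[dict[TrnaPair, Fraction]] = []
    support = 0
    dropped = 0
    for rec in transcriptome:
        pc = aggregate_pair_counts(count_dicodons(rec), assignment)
        dropped += pc.dropped
        if pc.total == 0:
            continue
        support += pc.total
        per_record.append({p: Fraction(n, pc.total) for p, n in pc.counts.items()})
    if not per_record:
        raise ValueError(f"{transcriptome.label or 'transcriptome'}: no usable dicodons")
    acc: dict[TrnaPair, Fraction] = {}
    w = Fraction(1, len(per_record))
    for vec in per_record:
        for p, f in vec.items():
            acc[p] = acc.get(p, Fraction(0)) + w * f
    return PairFrequencies(
        freqs=acc, support_total=support, mode="mean",
        label=transcriptome.label, dropped=dropped,
    )
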