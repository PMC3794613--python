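"""Enrichment factors (E-factors) for tRNA pairs and the leading-pair survey.

The E-factor of a tRNA pair is the frequency of the pair among the
dicodons of a protein of interest divided by its estimated frequency in
the background transcriptome.  A high E-factor means that FRET signal from
a fluorescently labelled version of that pair is attributable mostly to
synthesis of the protein of interest; pairs absent from the POI but common
in the background make negative controls.

Zero backgrounds are handled explicitly: by default a pair present in the
POI but absent from the background gets an infinite E-factor sentinel
(never a silent division error); alternatively an add-alpha pseudocount on
background counts may be requested, which is flagged in every record it
touches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .cds_io import Transcriptome
from .decoding import CodonAssignment, TrnaPair
from .dicodon_stats import PairFrequencies, poi_frequencies

#: default survey thresholds: strict >100, non-strict >=20, strict <10
DEFAULT_THRESHOLDS = {"above_strict": (100,), "above_inclusive": (20,), "below_strict": (10,)}


@dataclass(frozen=True)
class ZeroPolicy:
    """How to score a pair with positive POI frequency but zero background.

    ``kind='sentinel'`` (default) reports +inf; ``kind='pseudocount'`` adds
    ``alpha`` to every universe pair's background count and renormalizes.
    """

    kind: str = "sentinel"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("sentinel", "pseudocount"):
            raise ValueError(f"unknown zero policy {self.kind!r}")
        if self.kind == "pseudocount" and self.alpha <= 0:
            raise ValueError("pseudocount alpha must be positive")


@dataclass(frozen=True)
class EFactorRecord:
    pair: TrnaPair
    f_poi: Fraction
    f_bg: Fraction
    efactor: Fraction | float  # Fraction, 0, or math.inf sentinel
    bg_rank_rarity: int
    flags: frozenset[str] = frozenset()

    @property
    def efactor_float(self) -> float:
        return float(self.efactor) if self.efactor != math.inf else math.inf


@dataclass(frozen=True)
class EFactorTable:
    """One E-factor record per pair of the universe, sorted by descending E.

    Tie-break within equal E-factors: lower background frequency first,
    then lexicographic pair id.
    """

    records: tuple[EFactorRecord, ...]
    poi_id: str = ""
    background_label: str = ""
    mode: str = "pooled"
    zero_policy: ZeroPolicy = field(default_factory=ZeroPolicy)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, pair: TrnaPair) -> EFactorRecord:
        for r in self.records:
            if r.pair == pair:
                return r
        raise KeyError(pair.id)

    def to_tsv(self, highlight_threshold: float | None = None) -> str:
        lines = [
            f"# poi={self.poi_id}",
            f"# background={self.background_label}",
            f"# mode={self.mode}",
            f"# zero_policy={self.zero_policy.kind}"
            + (f" alpha={self.zero_policy.alpha:g}" if self.zero_policy.kind == "pseudocount" else ""),
            "pair_id\tf_poi\tf_bg\tefactor\tbg_rank_rarity\tflags",
        ]
        for r in self.records:
            e = "inf" if r.efactor == math.inf else f"{float(r.efactor):.6g}"
            flags = set(r.flags)
            if highlight_threshold is not None and r.efactor_float > highlight_threshold:
                flags.add("highlight")
            lines.append(
                f"{r.pair.id}\t{float(r.f_poi):.6g}\t{float(r.f_bg):.6g}\t{e}"
                f"\t{r.bg_rank_rarity}\t{','.join(sorted(flags))}"
            )
        return "\n".join(lines) + "\n"


def _sort_key(r: EFactorRecord):
    # descending efactor, then ascending f_bg, then pair id
    e = r.efactor if r.efactor != math.inf else Fraction(10**30)
    return (-e, r.f_bg, r.pair.id)


def compute_efactors(
    poi: PairFrequencies,
    bg: PairFrequencies,
    universe: Sequence[TrnaPair],
    zero_policy: ZeroPolicy | None = None,
) -> EFactorTable:
    """Compute E-factors for every pair of the universe.

    E = f_poi / f_bg; pairs with f_poi = 0 score 0; f_bg = 0 with positive
    f_poi yields the +inf sentinel (or a pseudocounted ratio under the
    pseudocount policy).  ``bg_rank_rarity`` ranks background frequencies
    ascending with competition ranking (ties share the minimum rank,
    1 = rarest).
    """
    zero_policy = zero_policy or ZeroPolicy()
    universe = list(universe)
    if not universe:
        raise ValueError("empty pair universe")
    stray = (set(poi.freqs) | set(bg.freqs)) - set(universe)
    if stray:
        raise ValueError(
            f"frequencies reference pairs outside the universe: {sorted(p.id for p in stray)[:3]}"
        )

    if zero_policy.kind == "pseudocount":
        alpha = Fraction(zero_policy.alpha).limit_denominator(10**9)
        counts = bg.counts()
        denom = bg.support_total + alpha * len(universe)
        bg_eff = {p: (counts.get(p, Fraction(0)) + alpha) / denom for p in universe}
    else:
        bg_eff = {p: bg.get(p) for p in universe}

    # competition ranking of background rarity over the raw background
    raw_bg = sorted(bg.get(p) for p in universe)
    rank_of: dict[Fraction, int] = {}
    for i, f in enumerate(raw_bg):
        rank_of.setdefault(f, i + 1)

    records = []
    for pair in universe:
        f_poi = poi.get(pair)
        f_bg = bg_eff[pair]
        flags: set[str] = set()
        if bg.get(pair) == 0:
            flags.add("zero_background")
            if zero_policy.kind == "pseudocount":
                flags.add("pseudocounted")
        if f_poi == 0:
            e: Fraction | float = Fraction(0)
        elif f_bg == 0:
            e = math.inf
        else:
            e = f_poi / f_bg
        records.append(
            EFactorRecord(
                pair=pair, f_poi=f_poi, f_bg=f_bg, efactor=e,
                bg_rank_rarity=rank_of[bg.get(pair)], flags=frozenset(flags),
            )
        )
    records.sort(key=_sort_key)
    return EFactorTable(
        records=tuple(records), poi_id=poi.label, background_label=bg.label,
        mode=bg.mode, zero_policy=zero_policy,
    )


def leading_pair(table: EFactorTable) -> EFactorRecord:
    """The maximal-E-factor record (the table's documented tie-break order).

    If every E-factor is zero the first record under the tie-break is
    returned with a ``no_signal`` flag.
    """
    if not table.records:
        raise ValueError("empty E-factor table")
    best = table.records[0]
    if best.efactor == 0:
        return EFactorRecord(
            pair=best.pair, f_poi=best.f_poi, f_bg=best.f_bg, efactor=best.efactor,
            bg_rank_rarity=best.bg_rank_rarity, flags=best.flags | {"no_signal"},
        )
    return best


def select_control_pair(
    poi: PairFrequencies,
    bg: PairFrequencies,
    universe: Sequence[TrnaPair],
    min_bg_multiple: float = 2.0,
) -> list[TrnaPair]:
    """Candidate negative-control pairs, best first.

    A control pair must be absent from the POI (f_poi = 0) yet common in
    the background: f_bg >= min_bg_multiple / |universe|, i.e. a multiple
    of the uniform pair frequency.  Sorted by descending background
    frequency, then pair id.
    """
    if min_bg_multiple <= 0:
        raise ValueError("min_bg_multiple must be positive")
    floor = Fraction(min_bg_multiple).limit_denominator(10**9) / len(universe)
    hits = [p for p in universe if poi.get(p) == 0 and bg.get(p) >= floor]
    hits.sort(key=lambda p: (-bg.get(p), p.id))
    return hits


@dataclass(frozen=True)
class SurveySummary:
    """Transcriptome-wide leading-pair survey results."""

    n_transcripts: int
    leading: Mapping[str, tuple[TrnaPair, float]]  # transcript id -> (pair, efactor)
    fraction_above: Mapping[int, float]  # {100: frac(E>100), 20: frac(E>=20)}
    fraction_below: Mapping[int, float]  # {10: frac(E<10)}

    def to_json_dict(self) -> dict:
        return {
            "n_transcripts": self.n_transcripts,
            "fraction_above": {str(k): v for k, v in self.fraction_above.items()},
            "fraction_below": {str(k): v for k, v in self.fraction_below.items()},
        }


def survey_transcriptome(
    targets: Transcriptome,
    bg: PairFrequencies,
    assignment: CodonAssignment,
    universe: Sequence[TrnaPair],
    thresholds: Mapping[str, Iterable[int]] | None = None,
    zero_policy: ZeroPolicy | None = None,
) -> SurveySummary:
    """Per-transcript leading pair and E-factor against a fixed background.

    Each transcript with at least 2 usable codons is scored against the
    full background (which normally includes the transcript itself — no
    leave-one-out); fractions of transcripts whose leading E-factor clears
    each threshold are reported (>t strict for ``above_strict``, >=t for
    ``above_inclusive``, <t strict for ``below_strict``).
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    leading: dict[str, tuple[TrnaPair, float]] = {}
    leading_values: list[float] = []
    for rec in targets:
        if len(rec) < 2:
            continue
        try:
            fp = poi_frequencies(rec, assignment)
        except ValueError:
            continue
        table = compute_efactors(fp, bg, universe, zero_policy)
        top = leading_pair(table)
        e = top.efactor_float
        leading[rec.id] = (top.pair, e)
        leading_values.append(e)
    if not leading_values:
        raise ValueError("no surveyable transcripts (all too short)")
    n = len(leading_values)
    fraction_above = {
        t: sum(e > t for e in leading_values) / n for t in thresholds.get("above_strict", ())
    }
    fraction_above.update(
        {t: sum(e >= t for e in leading_values) / n for t in thresholds.get("above_inclusive", ())}
    )
    fraction_below = {
        t: sum(e < t for e in leading_values) / n for t in thresholds.get("below_strict", ())
    }
    return SurveySummary(
        n_transcripts=n, leading=leading,
        fraction_above=fraction_above, fraction_below=fraction_below,
    )
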