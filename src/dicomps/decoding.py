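"""tRNA isoacceptors, pair enumeration and codon -> isoacceptor assignment.

An *isoacceptor* is a tRNA species identified by its amino acid and
anticodon; the set of isoacceptors expressed in a cell defines both the
universe of unordered tRNA pairs (the candidates for a fluorescent FRET
donor/acceptor pair) and a decoding map from each sense codon to the single
isoacceptor assumed to read it during elongation.

Decoding model
--------------
A codon may be read by an isoacceptor when (a) the isoacceptor's amino acid
matches the codon's translation and (b) the anticodon pairs with the codon:
positions 35 and 36 of the anticodon must be Watson-Crick complementary to
codon positions 2 and 1, while position 34 (the wobble position) may read
the codon's third base according to a configurable wobble matrix.  A34 is
interpreted as inosine.  When several isoacceptors can read a codon, an
exact Watson-Crick decoder wins over a wobble decoder; remaining ties are
broken by higher gene count, then lexicographic anticodon.  Explicit
per-codon overrides take absolute precedence.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

from .genetic_code import (
    COMPLEMENT,
    RNA_BASES,
    SENSE_CODONS,
    STANDARD_AA3,
    normalize_rna,
    reverse_complement,
    translate_codon,
)

logger = logging.getLogger(__name__)

#: amino-acid labels found in gtRNAdb-style tables that are not part of the
#: elongation decoding set
_NONCANONICAL_AA = {"SEC", "SELC", "SUP", "UNDET", "UND"}
_INITIATOR_AA = {"IMET", "FMET", "MET_I", "INI"}


class DecodingError(ValueError):
    """Raised on malformed isoacceptor tables or inconsistent rule sets."""


@dataclass(frozen=True, order=True)
class Isoacceptor:
    """A tRNA isoacceptor: amino acid (3-letter code) plus anticodon (RNA 5'->3')."""

    amino_acid: str
    anticodon: str
    gene_count: int | None = None

    def __post_init__(self) -> None:
        if self.amino_acid not in STANDARD_AA3:
            raise DecodingError(
                f"amino acid {self.amino_acid!r} is not one of the 20 standard residues"
            )
        if len(self.anticodon) != 3 or any(b not in RNA_BASES for b in self.anticodon):
            raise DecodingError(f"malformed anticodon {self.anticodon!r}")
        if self.gene_count is not None and self.gene_count < 0:
            raise DecodingError("gene_count must be non-negative")

    @property
    def id(self) -> str:
        return f"{self.amino_acid}-{self.anticodon}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.id


@dataclass(frozen=True)
class IsoacceptorSet:
    """An ordered, duplicate-free collection of isoacceptors for one species."""

    members: tuple[Isoacceptor, ...]
    species_label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise DecodingError("no isoacceptors: the set must contain at least one member")
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DecodingError(f"duplicate isoacceptor ids: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Isoacceptor]:
        return iter(self.members)

    def __getitem__(self, iso_id: str) -> Isoacceptor:
        for m in self.members:
            if m.id == iso_id:
                return m
        raise KeyError(iso_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.members)


@dataclass(frozen=True, order=True)
class TrnaPair:
    """An unordered pair of isoacceptor ids, stored in sorted canonical order."""

    first_id: str
    second_id: str

    def __post_init__(self) -> None:
        if self.first_id > self.second_id:
            raise DecodingError("TrnaPair ids must be canonically ordered; use TrnaPair.of()")

    @classmethod
    def of(cls, a: str, b: str) -> "TrnaPair":
        return cls(*sorted((a, b)))

    @property
    def homotypic(self) -> bool:
        return self.first_id == self.second_id

    @property
    def id(self) -> str:
        return f"{self.first_id}:{self.second_id}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.id


#: Standard (revised-Crick) wobble matrix: anticodon position-34 base -> set of
#: codon third bases it can read.  A34 is treated as inosine.
DEFAULT_WOBBLE: Mapping[str, frozenset[str]] = {
    "G": frozenset({"C", "U"}),
    "U": frozenset({"A", "G"}),
    "C": frozenset({"G"}),
    "A": frozenset({"U", "C", "A"}),  # inosine
}


@dataclass(frozen=True)
class DecodingRuleSet:
    """Wobble matrix, tie-break priority and explicit codon overrides.

    ``wobble_matrix`` maps the anticodon 5' base (position 34) to the codon
    third bases it may read; Watson-Crick reading must always be included.
    ``overrides`` maps sense codons directly to isoacceptor ids and wins over
    every rule.
    """

    wobble_matrix: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_WOBBLE)
    )
    overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for base34, readable in self.wobble_matrix.items():
            wc = COMPLEMENT[base34] if base34 != "A" else "U"
            if wc not in readable:
                raise DecodingError(
                    f"wobble matrix for {base34}34 omits the Watson-Crick partner {wc}"
                )
        for codon in self.overrides:
            if codon not in SENSE_CODONS:
                raise DecodingError(f"override codon {codon!r} is not a sense codon")


@dataclass(frozen=True)
class CodonAssignment:
    """Total map from the 61 sense codons to a decoding isoacceptor id.

    Codons no isoacceptor in the set can read are listed ``unassignable``
    instead; the two groups partition the sense codons exactly.
    """

    table: Mapping[str, str]
    unassignable: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        covered = set(self.table) | set(self.unassignable)
        if covered != set(SENSE_CODONS) or set(self.table) & set(self.unassignable):
            raise DecodingError(
                "assignment must cover the 61 sense codons exactly, "
                "with assigned and unassignable disjoint"
            )

    def get(self, codon: str) -> str | None:
        return self.table.get(codon)

    def to_tsv(self) -> str:
        """Serialize as ``codon<TAB>isoacceptor_id`` rows for all 61 sense codons."""
        lines = ["codon\tisoacceptor_id"]
        for codon in SENSE_CODONS:
            lines.append(f"{codon}\t{self.table.get(codon, '')}")
        return "\n".join(lines) + "\n"


def _normalize_aa(raw: str) -> tuple[str, bool, bool]:
    """Return (3-letter code or raw, is_initiator, is_noncanonical)."""
    token = raw.strip()
    upper = token.upper()
    if upper in _INITIATOR_AA:
        return "Met", True, False
    if upper in _NONCANONICAL_AA:
        return token, False, True
    return token[:1].upper() + token[1:].lower(), False, False


def parse_isoacceptor_table(
    source: str | Path | TextIO,
    species_label: str = "",
    include_initiator: bool = False,
) -> IsoacceptorSet:
    """Parse a gtRNAdb-style TSV of isoacceptors.

    Expected header: ``amino_acid<TAB>anticodon[<TAB>gene_count]``.  DNA
    anticodons (T) are normalized to RNA (U); duplicate (amino acid,
    anticodon) rows are merged with gene counts summed.  Initiator-Met rows
    are excluded from the elongation set unless ``include_initiator`` (in
    which case they merge into elongator Met); selenocysteine/suppressor
    rows are always dropped with a warning.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        with open(source, "rt", encoding="utf-8") as fh:
            return parse_isoacceptor_table(fh, species_label, include_initiator)
    if isinstance(source, str):
        source = io.StringIO(source)

    reader = csv.reader(
        (line for line in source if line.strip() and not line.startswith("#")),
        delimiter="\t",
    )
    try:
        header = [h.strip().lower() for h in next(reader)]
    except StopIteration:
        raise DecodingError("no isoacceptors: empty table") from None
    if header[:2] != ["amino_acid", "anticodon"]:
        raise DecodingError(
            f"expected header 'amino_acid<TAB>anticodon[<TAB>gene_count]', got {header!r}"
        )
    has_gc = len(header) > 2 and header[2] == "gene_count"

    merged: dict[tuple[str, str], int | None] = {}
    order: list[tuple[str, str]] = []
    for row_no, row in enumerate(reader, start=2):
        if len(row) < 2:
            raise DecodingError(f"row {row_no}: expected at least 2 columns")
        aa, initiator, noncanonical = _normalize_aa(row[0])
        if noncanonical or (initiator and not include_initiator):
            logger.warning("row %d: skipping non-elongation tRNA %s-%s", row_no, row[0], row[1])
            continue
        anticodon = normalize_rna(row[1].strip())
        if len(anticodon) != 3 or any(b not in RNA_BASES for b in anticodon):
            raise DecodingError(f"row {row_no}: malformed anticodon {row[1]!r}")
        gc: int | None = None
        if has_gc and len(row) > 2 and row[2].strip():
            try:
                gc = int(row[2])
            except ValueError:
                raise DecodingError(f"row {row_no}: gene_count {row[2]!r} is not an integer")
            if gc < 0:
                raise DecodingError(f"row {row_no}: negative gene_count")
        key = (aa, anticodon)
        if key in merged:
            prev = merged[key]
            merged[key] = (prev or 0) + (gc or 0) if (prev is not None or gc is not None) else None
        else:
            merged[key] = gc
            order.append(key)

    if not merged:
        raise DecodingError("no isoacceptors: table has no usable rows")
    members = tuple(Isoacceptor(aa, ac, merged[(aa, ac)]) for aa, ac in order)
    return IsoacceptorSet(members=members, species_label=species_label)


def enumerate_pairs(iso_set: IsoacceptorSet) -> list[TrnaPair]:
    """All distinct unordered isoacceptor pairs, homotypic included.

    For n isoacceptors there are (n^2 - n)/2 + n such pairs; the list is
    returned in canonical lexicographic order.
    """
    ids = sorted(iso_set.ids)
    return [TrnaPair(ids[i], ids[j]) for i in range(len(ids)) for j in range(i, len(ids))]


def _read_mode(anticodon: str, codon: str, wobble: Mapping[str, frozenset[str]]) -> str | None:
    """'wc' for exact Watson-Crick reading, 'wobble' for wobble reading, else None."""
    if anticodon == reverse_complement(codon):
        return "wc"
    # positions 35/36 must be Watson-Crick; position 34 reads codon base 3
    if anticodon[1] != COMPLEMENT[codon[1]] or anticodon[2] != COMPLEMENT[codon[0]]:
        return None
    readable = wobble.get(anticodon[0], frozenset())
    return "wobble" if codon[2] in readable else None


def build_codon_assignment(
    iso_set: IsoacceptorSet, rules: DecodingRuleSet | None = None
) -> CodonAssignment:
    """Deterministically assign one decoding isoacceptor to each sense codon.

    Candidates must carry the codon's amino acid and read it under the rule
    set's wobble matrix.  Priority: override > Watson-Crick > wobble; ties
    broken by higher gene count, then lexicographic anticodon.  Codons with
    no candidate are reported as unassignable.
    """
    rules = rules or DecodingRuleSet()
    known_ids = set(iso_set.ids)
    for codon, iso_id in rules.overrides.items():
        if iso_id not in known_ids:
            raise DecodingError(f"override for {codon} names unknown isoacceptor {iso_id!r}")

    table: dict[str, str] = {}
    unassignable: list[str] = []
    for codon in SENSE_CODONS:
        if codon in rules.overrides:
            table[codon] = rules.overrides[codon]
            continue
        aa = translate_codon(codon)
        candidates: list[tuple[int, int, str, Isoacceptor]] = []
        for iso in iso_set:
            if iso.amino_acid != aa:
                continue
            mode = _read_mode(iso.anticodon, codon, rules.wobble_matrix)
            if mode is None:
                continue
            candidates.append(
                (0 if mode == "wc" else 1, -(iso.gene_count or 0), iso.anticodon, iso)
            )
        if not candidates:
            unassignable.append(codon)
            continue
        candidates.sort(key=lambda t: t[:3])
        best = candidates[0]
        if best[0] == 1:
            logger.debug("codon %s resolved by wobble to %s", codon, best[3].id)
        table[codon] = best[3].id
    return CodonAssignment(table=table, unassignable=tuple(unassignable))


def parse_override_table(source: str | Path | TextIO) -> dict[str, str]:
    """Parse a ``codon<TAB>isoacceptor_id`` TSV into an overrides mapping."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        with open(source, "rt", encoding="utf-8") as fh:
            return parse_override_table(fh)
    if isinstance(source, str):
        source = io.StringIO(source)
    overrides: dict[str, str] = {}
    for line in source:
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("codon\t"):
            continue
        codon, iso_id = line.split("\t")[:2]
        overrides[normalize_rna(codon.strip())] = iso_id.strip()
    return overrides
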