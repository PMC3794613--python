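"""Reading, validating and codonizing coding sequences from FASTA.

Every FASTA record is treated as one in-frame CDS.  Sequences are
normalized to RNA, the terminal stop codon is stripped, and validation is
controlled by a policy: ``strict`` raises on any defect, ``lenient``
repairs what it defensibly can (truncate at an internal stop, drop a
trailing partial codon) and logs a warning.  Codons containing ambiguity
letters are dropped from the codon list but their original positions are
retained so that downstream dicodon counting can exclude the two windows
overlapping each gap.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import STOP_CODONS, is_sense_codon, normalize_rna

logger = logging.getLogger(__name__)

Policy = Literal["strict", "lenient"]


class CdsValidationError(ValueError):
    """Raised when a CDS record fails validation under the strict policy."""


def codonize(sequence: str, frame_offset: int = 0) -> list[str]:
    """Split a nucleotide string into non-overlapping triplets.

    ``frame_offset`` is 0-based; a trailing partial triplet is dropped with
    a warning.  The sequence is normalized to uppercase RNA first.
    """
    if not 0 <= frame_offset <= 2:
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    seq = normalize_rna(sequence)[frame_offset:]
    if len(seq) % 3:
        logger.warning("dropping trailing partial triplet of %d nt", len(seq) % 3)
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame CDS reduced to its sense codons.

    ``codons`` holds only valid sense codons; ``positions`` gives each
    codon's 0-based index in the original reading frame, so two codons are
    adjacent in the transcript iff their positions differ by 1 (gaps arise
    from dropped ambiguous codons).
    """

    id: str
    codons: tuple[str, ...]
    source_length_nt: int
    positions: tuple[int, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        if not self.positions:
            object.__setattr__(self, "positions", tuple(range(len(self.codons))))
        if len(self.positions) != len(self.codons):
            raise ValueError("positions and codons must be parallel")
        for c in self.codons:
            if not is_sense_codon(c):
                raise ValueError(f"{self.id}: {c!r} is not a sense codon")

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def has_gaps(self) -> bool:
        return len(self.codons) != (self.positions[-1] + 1 if self.positions else 0)

    def to_rna(self) -> str:
        """Concatenated codons (gap-free sequences only)."""
        if self.has_gaps:
            raise ValueError(f"{self.id}: cannot reconstruct sequence across dropped codons")
        return "".join(self.codons)


@dataclass(frozen=True)
class Transcriptome:
    """A labelled collection of coding sequences with unique ids."""

    records: tuple[CodingSequence, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("transcriptome must contain at least one record")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in transcriptome")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CodingSequence]:
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> CodingSequence:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


def _validate_record(
    rec_id: str, sequence: str, policy: Policy, frame_offset: int
) -> CodingSequence | None:
    seq = normalize_rna(sequence)
    usable = seq[frame_offset:]
    if len(usable) % 3:
        if policy == "strict":
            raise CdsValidationError(f"{rec_id}: length {len(usable)} not a multiple of 3")
        logger.warning("%s: dropping trailing %d nt (partial codon)", rec_id, len(usable) % 3)
    triplets = [usable[i : i + 3] for i in range(0, len(usable) - len(usable) % 3, 3)]

    if triplets and triplets[-1] in STOP_CODONS:
        triplets = triplets[:-1]

    codons: list[str] = []
    positions: list[int] = []
    for idx, t in enumerate(triplets):
        if t in STOP_CODONS:
            if policy == "strict":
                raise CdsValidationError(
                    f"{rec_id}: internal stop codon {t} at codon {idx + 1}"
                )
            logger.warning("%s: truncating at internal stop codon %s (codon %d)", rec_id, t, idx + 1)
            break
        if is_sense_codon(t):
            codons.append(t)
            positions.append(idx)
        else:
            if policy == "strict":
                raise CdsValidationError(f"{rec_id}: ambiguous codon {t!r} at codon {idx + 1}")
            logger.warning("%s: dropping ambiguous codon %s at codon %d", rec_id, t, idx + 1)
    if not codons:
        if policy == "strict":
            raise CdsValidationError(f"{rec_id}: no usable sense codons")
        return None
    return CodingSequence(
        id=rec_id,
        codons=tuple(codons),
        source_length_nt=len(sequence),
        positions=tuple(positions),
    )


def read_cds_fasta(
    path: str | Path,
    policy: Policy = "strict",
    frame_offset: int = 0,
    label: str | None = None,
) -> Transcriptome:
    """Read a (possibly gzip-compressed) multi-record CDS FASTA.

    Under ``strict`` any invalid record raises :class:`CdsValidationError`
    naming it; under ``lenient`` defective records are repaired or skipped
    with a counted warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CDS FASTA not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[CodingSequence] = []
    skipped = 0
    with opener(path, "rt") as fh:  # type: ignore[operator]
        for rec in SeqIO.parse(fh, "fasta"):
            cds = _validate_record(rec.id, str(rec.seq), policy, frame_offset)
            if cds is None:
                skipped += 1
            else:
                records.append(cds)
    if skipped:
        logger.warning("%s: skipped %d unusable record(s)", path, skipped)
    if not records:
        raise CdsValidationError(f"{path}: no usable CDS records")
    return Transcriptome(records=tuple(records), label=label or path.stem)


def write_cds_fasta(
    transcriptome: Transcriptome,
    path: str | Path,
    alphabet: Literal["RNA", "DNA"] = "RNA",
    add_stop: bool = False,
) -> None:
    """Write a transcriptome back to FASTA (one record per CDS)."""
    seq_records = []
    for cds in transcriptome:
        seq = cds.to_rna() + ("UAA" if add_stop else "")
        if alphabet == "DNA":
            seq = seq.replace("U", "T")
        seq_records.append(
            SeqRecord(Seq(seq), id=cds.id, description=cds.description)
        )
    with open(path, "wt") as fh:
        SeqIO.write(seq_records, fh, "fasta")
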