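"""Synthetic transcriptomes and dicodon-spiked POIs with known structure.

Backgrounds are drawn codon-by-codon i.i.d. from a configurable
distribution over the 61 sense codons (uniform transcript levels by
construction), which emulates the estimation conditions of the E-factor
model while deliberately ignoring real-transcriptome features such as
amino-acid composition bias, codon autocorrelation and length/expression
coupling.  POIs are spiked *constructively*: the exact number of target
dicodon occurrences needed for a requested enrichment is computed and the
occurrences are placed as isolated blocks, so the achievable enrichment is
a design parameter and recovery of it is a meaningful test of the whole
pipeline.

The module also packages a deterministic "viral-like" 10-segment fixture
whose designated rare dicodon occurs exactly four times — twice in one
NS3-like record and once in each of two others — mirroring the structure
of a small segmented viral transcriptome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .cds_io import CodingSequence, Transcriptome, write_cds_fasta
from .decoding import CodonAssignment, IsoacceptorSet, TrnaPair, parse_isoacceptor_table
from .dicodon_stats import PairFrequencies
from .genetic_code import SENSE_CODONS

#: fixed stream for the packaged viral-like fixture
_FIXTURE_SEED = 20130820
#: the fixture's designated rare dicodon (isoleucine AUA:AUA)
FIXTURE_TARGET_DICODON = ("AUA", "AUA")


def packaged_isoacceptor_set() -> IsoacceptorSet:
    """The packaged synthetic mammalian-like 48-isoacceptor decoding set."""
    text = (
        resources.files("dicomps").joinpath("data/synthetic_mammalian_trna.tsv").read_text()
    )
    return parse_isoacceptor_table(text, species_label="synthetic-mammalian-like")


@dataclass(frozen=True)
class Spike:
    """A planted dicodon at a target enrichment over the background."""

    dicodon: tuple[str, str]
    e_true: float

    def __post_init__(self) -> None:
        if self.e_true <= 0:
            raise ValueError("target enrichment must be positive")
        for c in self.dicodon:
            if c not in SENSE_CODONS:
                raise ValueError(f"spike codon {c!r} is not a sense codon")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic transcriptome / POI generator.

    ``length_codons`` is either a fixed integer or an inclusive (lo, hi)
    range sampled uniformly per record.  ``codon_weights`` is a probability
    mapping over sense codons (uniform when omitted); stop codons can never
    be emitted.
    """

    seed: int
    n_transcripts: int = 1
    length_codons: int | tuple[int, int] = 300
    codon_weights: Mapping[str, float] | None = None
    spike: Spike | None = None
    alphabet: Literal["RNA", "DNA"] = "RNA"
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        lo = self.length_codons if isinstance(self.length_codons, int) else self.length_codons[0]
        if lo < 1:
            raise ValueError("length_codons must be >= 1")
        if self.codon_weights is not None:
            bad = set(self.codon_weights) - set(SENSE_CODONS)
            if bad:
                raise ValueError(f"weights for non-sense codons: {sorted(bad)}")
            if not any(w > 0 for w in self.codon_weights.values()):
                raise ValueError("degenerate codon weights: no positive mass on sense codons")

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_transcripts": self.n_transcripts,
            "length_codons": self.length_codons,
            "codon_weights": dict(self.codon_weights) if self.codon_weights else None,
            "spike": (
                {"dicodon": list(self.spike.dicodon), "e_true": self.spike.e_true}
                if self.spike
                else None
            ),
            "alphabet": self.alphabet,
            "label": self.label,
        }


def _weight_vector(
    weights: Mapping[str, float] | None, exclude: frozenset[str] = frozenset()
) -> tuple[np.ndarray, list[str]]:
    codons = [c for c in SENSE_CODONS if c not in exclude]
    if not codons:
        raise ValueError("codon exclusion leaves no sense codons to sample")
    if weights is None:
        w = np.ones(len(codons))
    else:
        w = np.array([weights.get(c, 0.0) for c in codons], dtype=float)
    if w.sum() <= 0:
        raise ValueError("codon weights have no positive mass after exclusions")
    return w / w.sum(), codons


def _sample_length(rng: np.random.Generator, spec: int | tuple[int, int]) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def generate_background(
    cfg: SyntheticConfig, fasta_path: str | Path | None = None
) -> Transcriptome:
    """Draw a synthetic transcriptome, fully reproducible from ``cfg.seed``.

    Optionally writes standard FASTA (``cfg.alphabet``) plus a JSON sidecar
    of the generating configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    probs, codons = _weight_vector(cfg.codon_weights)
    codon_arr = np.array(codons)
    records = []
    for i in range(cfg.n_transcripts):
        n = _sample_length(rng, cfg.length_codons)
        draw = codon_arr[rng.choice(len(codons), size=n, p=probs)]
        records.append(
            CodingSequence(
                id=f"{cfg.label}_{i:04d}",
                codons=tuple(draw.tolist()),
                source_length_nt=3 * n,
                description=f"seed={cfg.seed}",
            )
        )
    transcriptome = Transcriptome(records=tuple(records), label=cfg.label)
    if fasta_path is not None:
        write_cds_fasta(transcriptome, fasta_path, alphabet=cfg.alphabet)
        Path(str(fasta_path) + ".json").write_text(json.dumps(cfg.to_json_dict(), indent=2))
    return transcriptome


def _plant_blocks(
    rng: np.random.Generator,
    length: int,
    blocks: Sequence[Sequence[str]],
    filler_codons: list[str],
    filler_probs: np.ndarray,
) -> list[str]:
    """Place isolated ``blocks`` in a filler sequence of total ``length``.

    Blocks are separated by at least one filler codon so no extra block
    dicodons arise at the seams; filler positions are randomized by
    distributing the filler mass over the gaps between blocks.
    """
    n_blocks = len(blocks)
    n_filler = length - sum(len(b) for b in blocks)
    min_internal = max(n_blocks - 1, 0)
    if n_filler < min_internal:
        raise ValueError(
            f"cannot place {n_blocks} spike blocks in {length} codons; "
            f"minimum length is {length - n_filler + min_internal}"
        )
    gaps = np.ones(n_blocks + 1, dtype=int)
    gaps[0] = gaps[-1] = 0
    spare = n_filler - gaps.sum()
    if spare:
        gaps += rng.multinomial(spare, np.full(n_blocks + 1, 1.0 / (n_blocks + 1)))
    filler = iter(
        np.array(filler_codons)[
            rng.choice(len(filler_codons), size=n_filler, p=filler_probs)
        ].tolist()
        if n_filler
        else []
    )
    out: list[str] = []
    for i, block in enumerate(blocks):
        out.extend(next(filler) for _ in range(gaps[i]))
        out.extend(block)
    out.extend(next(filler) for _ in range(gaps[-1]))
    return out


def _spike_blocks(c1: str, c2: str, m: int, length: int) -> list[list[str]]:
    """Blocks realizing exactly ``m`` occurrences of the dicodon (c1, c2).

    Heterotypic dicodons need ``m`` isolated 2-codon blocks (overlap would
    create reverse-order dicodons of the same unordered pair).  Homotypic
    occurrences may merge into runs — a run of k+1 identical codons holds k
    occurrences — which is what permits saturation up to f_poi = 1.
    """
    if c1 != c2:
        if length < 3 * m - 1:
            raise ValueError(
                f"cannot realize {m} occurrences of {c1}:{c2} in {length} codons; "
                f"minimum length is {3 * m - 1}"
            )
        return [[c1, c2] for _ in range(m)]
    n_runs = min(m, (length + 1 - m) // 2)
    if n_runs < 1:
        raise ValueError(
            f"cannot realize {m} occurrences of {c1}:{c2} in {length} codons; "
            f"minimum length is {m + 1}"
        )
    base, extra = divmod(m, n_runs)
    occ = [base + 1] * extra + [base] * (n_runs - extra)
    return [[c1] * (k + 1) for k in occ]


@dataclass(frozen=True)
class SpikedPoi:
    """A constructed POI together with the enrichment it actually realizes."""

    cds: CodingSequence
    target_pair: TrnaPair
    occurrences: int
    requested_efactor: float
    achievable_efactor: float


def generate_spiked_poi(
    cfg: SyntheticConfig,
    bg: PairFrequencies,
    assignment: CodonAssignment,
) -> SpikedPoi:
    """Construct a POI whose target-pair frequency realizes a requested E-factor.

    The needed occurrence count m = round(E_true * f_bg * (L - 1)) of the
    spike dicodon is placed as isolated blocks; filler codons exclude every
    codon decoded by either target isoacceptor (and unassignable codons),
    so the realized target-pair frequency is exactly m / (L - 1) and the
    achievable E-factor — reported back — differs from E_true only by the
    rounding of m.
    """
    if cfg.spike is None:
        raise ValueError("config has no spike")
    if not isinstance(cfg.length_codons, int):
        raise ValueError("spiked POI requires a fixed length_codons")
    c1, c2 = cfg.spike.dicodon
    a1, a2 = assignment.get(c1), assignment.get(c2)
    if a1 is None or a2 is None:
        raise ValueError(f"spike dicodon {c1}:{c2} contains an unassignable codon")
    pair = TrnaPair.of(a1, a2)
    f_bg = bg.get(pair)
    if f_bg == 0:
        raise ValueError(f"target pair {pair.id} has zero background frequency")

    length = cfg.length_codons
    n_dicodons = length - 1
    m = round(cfg.spike.e_true * float(f_bg) * n_dicodons)
    if m < 1:
        raise ValueError(
            f"target enrichment {cfg.spike.e_true} needs less than one occurrence "
            f"at length {length}; increase length_codons"
        )
    blocks = _spike_blocks(c1, c2, m, length)
    excluded = frozenset(
        c for c in SENSE_CODONS if assignment.get(c) in (a1, a2, None)
    )
    rng = np.random.default_rng(cfg.seed)
    if sum(len(b) for b in blocks) == length:
        codons = [c for b in blocks for c in b]  # saturated: no filler needed
    else:
        filler_probs, filler_codons = _weight_vector(cfg.codon_weights, exclude=excluded)
        codons = _plant_blocks(rng, length, blocks, filler_codons, filler_probs)
    cds = CodingSequence(
        id=f"{cfg.label}_poi",
        codons=tuple(codons),
        source_length_nt=3 * length,
        description=f"seed={cfg.seed} spike={c1}:{c2} m={m}",
    )
    achievable = float(Fraction(m, n_dicodons) / f_bg)
    return SpikedPoi(
        cds=cds, target_pair=pair, occurrences=m,
        requested_efactor=cfg.spike.e_true, achievable_efactor=achievable,
    )


#: (record name, length in codons, planted AUA:AUA blocks)
_FIXTURE_SEGMENTS: tuple[tuple[str, int, int], ...] = (
    ("VP1-like", 1300, 1),
    ("VP2-like", 980, 0),
    ("VP3-like", 900, 0),
    ("VP4-like", 640, 0),
    ("NS1-like", 550, 1),
    ("VP5-like", 520, 0),
    ("NS2-like", 410, 0),
    ("VP7-like", 350, 0),
    ("VP6-like", 330, 0),
    ("NS3-like", 229, 2),
)


def viral_like_fixture() -> Transcriptome:
    """Deterministic 10-segment viral-like transcriptome (synthetic).

    The designated rare dicodon AUA:AUA occurs exactly 4 times in total —
    twice in the NS3-like record and once in each of the VP1-like and
    NS1-like records — while the AUA codon itself appears throughout at
    roughly uniform usage as isolated (never mutually adjacent) singles,
    so only the dicodon, not the codon, is rare.  Regeneration is
    byte-identical.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    target = FIXTURE_TARGET_DICODON
    probs, codons = _weight_vector(None, exclude=frozenset({target[0]}))
    records = []
    for name, length, n_blocks in _FIXTURE_SEGMENTS:
        blocks = [list(target)] * n_blocks + [[target[0]]] * (length // 60)
        order = rng.permutation(len(blocks))
        seq = _plant_blocks(rng, length, [blocks[i] for i in order], codons, probs)
        records.append(
            CodingSequence(
                id=name,
                codons=tuple(seq),
                source_length_nt=3 * length,
                description="synthetic viral-like fixture",
            )
        )
    return Transcriptome(records=tuple(records), label="viral-like-fixture")
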