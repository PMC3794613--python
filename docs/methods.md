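# Methods

## Model

A dicodon is an ordered pair of adjacent codons in a CDS. During the
elongation cycle its two codons occupy the ribosome's P and A sites, so
the two decoding tRNA isoacceptors sit side by side; if one carries a FRET
donor and the other an acceptor, a signal is emitted. The identity of a
candidate reporter is therefore the *unordered* pair of isoacceptors — a
dicodon and its reverse contribute to the same pair.

For a species decoding set of *n* isoacceptors there are
(n² − n)/2 + n distinct unordered pairs (homotypic pairs included); the
packaged 48-member set yields 1176.

Pair frequencies are estimated from overlapping dicodon counts (window
width 2, step 1, never spanning transcript boundaries) under two
simplifying assumptions: all transcripts are present at equal levels and
all are translated at equal rates. The enrichment factor of a pair is

    E = f_pair(POI) / f_pair(background)

with f the pair's share of usable dicodons. High-E pairs give FRET signal
attributable mostly to POI synthesis; pairs with f_POI = 0 but high
background frequency are negative-control candidates.

## Codon → isoacceptor assignment

The decoding model assigns each of the 61 sense codons to exactly one
isoacceptor:

- a candidate must carry the codon's amino acid *and* read it: anticodon
  positions 35/36 pair Watson–Crick with codon positions 2/1, and the
  wobble position 34 reads the codon's third base per a configurable
  matrix (defaults: G34 → {C, U}, U34 → {A, G}, C34 → {G}, A34 treated as
  inosine → {U, C, A}). The amino-acid constraint is essential — without
  it U34 wobble would hand AUG to an isoleucine tRNA;
- priority: explicit per-codon override > exact Watson–Crick > wobble;
  remaining ties broken by higher gene count, then lexicographic
  anticodon. The result is deterministic and serializes identically across
  runs;
- codons no set member can read are reported `unassignable`; dicodons
  touching them are counted as `dropped` so that pair counts + dropped
  always equal the dicodon total;
- initiator-Met and selenocysteine rows of species tables are excluded
  from the elongation set by default (initiators can optionally be merged
  into elongator Met).

Real decoding is shaped by base modifications and tissue-specific tRNA
abundance; this assignment is a declared convention, fully overridable via
the rule set, not a kinetic model.

## Frequencies and the zero-background policy

Frequencies are held as exact rationals (`fractions.Fraction`) from
counting through E-factor division, so normalization sums are exactly 1
and oracle comparisons are bit-reproducible; decimals appear only in
exported TSV (6 significant digits).

The background is either **pooled** (default: one dicodon population over
all records — every dicodon weighs the same, so long transcripts weigh
more) or a **per-transcript mean** (equal weight per record). Both
readings of "average frequency over the transcriptome" are defensible
under the uniform-levels assumption; the mode is stamped into every
output.

A pair present in the POI but absent from the background gets an explicit
+∞ sentinel by default — never a silent division error. An optional
add-α pseudocount (α = 1 by default) on background counts produces finite
values instead; affected records carry `pseudocounted` flags. Background
rarity ranks use competition ranking (ties share the minimum rank,
1 = rarest).

The survey scores each transcript against the full background *including
itself* (no leave-one-out): leading E-factors of a self-surveyed pool are
therefore ≥ 1, and a homogeneous pool scores exactly 1. Threshold
fractions use strict `>` at 100, non-strict `≥` at 20 and strict `<` at
10.

## Synthetic data

The generator emulates the estimation conditions, not real biology:
codons are drawn i.i.d. from a configurable distribution over the 61
sense codons (uniform by default; stop codons never emitted), one seeded
generator per invocation. It does **not** model amino-acid composition,
codon autocorrelation, GC gradients, length–expression coupling or
isoform structure — so passing tests demonstrate correctness of the
estimator under its own assumptions, not robustness to real-transcriptome
structure.

Spiking is constructive rather than rejection-based: to realize a target
enrichment E_true for a dicodon whose background frequency is f_bg, the
generator computes the needed occurrence count m = round(E_true · f_bg ·
(L − 1)) and places the occurrences as isolated blocks separated by at
least one filler codon. Filler excludes every codon decoded by either
target isoacceptor, so the realized pair frequency is exactly m/(L − 1)
and the reported *achievable* E differs from E_true only through the
rounding of m. Homotypic occurrences may merge into runs (a run of k + 1
identical codons holds k occurrences), which permits saturation up to
f_POI = 1; heterotypic spikes must stay isolated because overlapping
blocks would create reverse-order dicodons of the same unordered pair.

Default study conditions: backgrounds of 500 transcripts × 300 codons;
spiked POIs of 4000 codons. The POI length is chosen so that the rounding
of m alone keeps the achievable E within ~5% of E_true even at E_true =
10 (m ≈ 11 under a uniform background), making the 10% recovery tolerance
a test of the pipeline rather than of integer rounding. Recovery is
checked at E_true ∈ {10, 50, 100} and as a 20-seed median at E_true = 50.

The viral-like fixture is a deterministic 10-segment transcriptome
(segment lengths modelled on a segmented dsRNA virus, 229–1300 codons) in
which the designated rare dicodon AUA·AUA occurs exactly four times —
twice in the NS3-like segment and once each in VP1-like and NS1-like —
while single, never mutually adjacent AUA codons are sprinkled throughout
at roughly uniform usage. Only the dicodon is rare, not the codon, which
is the situation the method exploits.

The packaged isoacceptor table is a *synthetic* mammalian-like set: the
45 anticodons common to mammalian gtRNAdb tables plus three rare but
attested ones (Ile-GAU, Ala-GGC, Val-GAC) to reach the 48 typical of such
tables; gene counts are plausible placeholders. It exists so the package
is exercisable end to end without downloads; real analyses should supply
a real species table.

## Codon-usage comparison

Relative usage of a codon is its share of all sense codons pooled over a
set (or of its synonymous family, selectable). Enrichment between two
sets is tested on the 2×2 table (codon vs rest, set A vs set B) with a
two-sided Fisher's exact test — exact and assumption-free at small counts
— with a G-test alternative. The test suite checks Fisher p-values
against an independent exhaustive hypergeometric tail summation in exact
rational arithmetic: exhaustively for all tables with row margins ≤ 15
(and a reduced ≤ 12 grid inside the acceptance script) plus a seeded
random sweep of tables with margins up to 60; a full enumeration to
margin 60 (~3.6 M tables) adds no new behaviour while costing ~25 minutes
per run at scipy's per-table cost.

## Numerical and degenerate-input choices

- Codon positions are 1-based in reports; `codonize` takes a 0-based
  frame offset.
- Codons containing ambiguity letters are dropped (lenient policy) and
  both overlapping dicodon windows are suppressed via original-position
  bookkeeping; strict policy errors, naming the record.
- Internal stops: strict errors; lenient truncates at the first stop.
  Terminal stops are always stripped. AUG is included in dicodon
  statistics (it occupies the P site during the first elongation cycle).
- A POI with < 2 codons, an empty isoacceptor table, a transcriptome with
  zero usable dicodons, a wobble matrix missing a Watson–Crick partner,
  or an override naming an unknown isoacceptor all raise informative
  errors.
- `leading_pair` tie-breaks: higher E, then lower f_bg, then
  lexicographic pair id; +∞ outranks all finite values; an all-zero table
  returns its first record flagged `no_signal`.

## Known limitations

- Uniform transcript/translation levels are a strong simplification; the
  data model would admit expression weighting but none is implemented.
- The decoding convention (one isoacceptor per codon) ignores competition
  between near-equal decoders and tRNA modifications.
- Codon-pair-bias statistics (CPS/CPB), tAI-style weights and longer
  windows are out of scope.
- External headline analyses of real viral/host data depend on
  database-version-specific sequence sets and are documented as
  non-reproducible reference points rather than machine-checked results;
  one printed background-frequency claim for a control pair (0.00186
  described as ~4× the average dicodon frequency) is arithmetically
  inconsistent with a uniform 1/1176 average and is not reproduced.
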