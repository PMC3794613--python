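# dicomps

Dicodon-based selection of fluorescent tRNA pairs for monitoring the
synthesis of a specific protein in single cells.

## The problem

Translation can be watched in live cells by transfecting fluorescently
labelled tRNAs: when a FRET donor-labelled tRNA and an acceptor-labelled
tRNA occupy the adjacent P and A sites of an elongating ribosome, a FRET
signal is emitted. Labelling *specific isoacceptors* instead of bulk tRNA
makes the signal sequence-specific — the pair reports on every ribosome
currently reading a *dicodon* (two adjacent codons) decoded by those two
isoacceptors. To attribute that signal to one protein of interest (POI),
one must pick a pair whose cognate dicodon is heavily enriched in the POI's
mRNA relative to everything else the cell translates.

`dicomps` implements that selection computation. Given CDS FASTA files for
the POI and the host background transcriptome plus a species tRNA
isoacceptor table (gtRNAdb style), it:

1. assigns a decoding isoacceptor to each of the 61 sense codons under
   configurable wobble rules (Watson–Crick beats wobble; gene count, then
   anticodon, break ties; explicit overrides win outright);
2. counts overlapping dicodons and folds them into unordered
   isoacceptor-pair frequencies — for an *n*-isoacceptor set there are
   (n² − n)/2 + n distinct pairs (48 isoacceptors → 1176 pairs);
3. scores each pair by its **enrichment factor**,

   E = f_pair(POI) / f_pair(background),

   where frequencies are estimated under uniform transcript and
   translation levels (background pooled over all CDSs by default, or
   averaged per transcript);
4. ranks pairs, proposes negative controls (pairs absent from the POI but
   common in the background), runs a transcriptome-wide *leading pair*
   survey, and tests codon-usage enrichment between two sequence sets with
   a two-sided Fisher's exact test.

A first-class synthetic-data module generates seeded background
transcriptomes and POIs with a dicodon planted at a known target
enrichment, so the whole pipeline is testable without external downloads.

## Worked example

```python
import dicomps as d

iso = d.packaged_isoacceptor_set()        # synthetic mammalian-like, 48 members
assignment = d.build_codon_assignment(iso)
universe = d.enumerate_pairs(iso)
print(f"{len(iso)} isoacceptors -> {len(universe)} distinct tRNA pairs")

virus = d.viral_like_fixture()            # deterministic 10-segment fixture
bg = d.pooled_background_frequencies(virus, assignment)
poi = d.poi_frequencies(virus["NS3-like"], assignment)
table = d.compute_efactors(poi, bg, universe)

pair = d.TrnaPair.of("Ile-UAU", "Ile-UAU")
rec = table[pair]
print(f"{pair.id}: f_poi={float(rec.f_poi):.5f} f_bg={float(rec.f_bg):.5f} "
      f"E={float(rec.efactor):.2f} (background rarity rank {rec.bg_rank_rarity} of {len(table)})")

controls = d.select_control_pair(poi, bg, universe)
print(f"best negative control: {controls[0].id} "
      f"(f_bg={float(bg.get(controls[0])):.5f}, absent from POI)")
```

prints

```
48 isoacceptors -> 1176 distinct tRNA pairs
Ile-UAU:Ile-UAU: f_poi=0.00877 f_bg=0.00065 E=13.59 (background rarity rank 420 of 1176)
best negative control: Arg-ACG:Tyr-GUA (f_bg=0.00323, absent from POI)
```

The fixture's NS3-like segment carries two isolated AUA·AUA dicodons (four
exist in the whole 10-segment set), so the homotypic Ile-UAU pair is
13.6-fold enriched over the self-inclusive pooled background: FRET from a
labelled Ile-UAU/Ile-UAU pair would be dominated by synthesis of that one
protein. The proposed control pair's dicodons never occur in the POI but
are ~4× more common than the uniform pair frequency in the background.

The same pipeline is available from the shell:

```sh
dicomps efactor --poi poi.fasta --background host_cds.fasta --trna-table trna.tsv --out results/
dicomps survey  --targets host_cds.fasta --out results/
dicomps simulate --seed 7 --spike AUA,AUA,50 --out sim/
```

Every run writes its outputs as TSV/JSON plus a `run_log.json` recording
the resolved configuration.

## Scope notes

The packaged isoacceptor table and the viral-like fixture are synthetic
stand-ins constructed to mirror the size and structure of real mammalian
decoding sets and segmented viral transcriptomes; analyses of real species
should supply their own CDS FASTA and gtRNAdb table. See
`docs/methods.md` for the model's assumptions, parameter choices and
limitations.
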