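"""E-factor computation, ranking, control selection and the survey."""

from __future__ import annotations

import math
import random
from fractions import Fraction

import pytest

from dicomps import (
    CodingSequence,
    Transcriptome,
    TrnaPair,
    ZeroPolicy,
    compute_efactors,
    enumerate_pairs,
    leading_pair,
    poi_frequencies,
    pooled_background_frequencies,
    select_control_pair,
    survey_transcriptome,
)
from dicomps.dicodon_stats import PairFrequencies
from dicomps.genetic_code import SENSE_CODONS

from oracles import brute_efactors, brute_pair_frequencies, brute_rarity_ranks


def cds(*codons, id="x"):
    return CodingSequence(id, tuple(codons), 3 * len(codons))


def freqs(mapping, label=""):
    total = sum(mapping.values())
    support = max(f.denominator for f in mapping.values()) if mapping else 0
    assert total == 1
    return PairFrequencies(freqs=mapping, support_total=support, label=label)


PA = TrnaPair.of("Ile-UAU", "Ile-UAU")
PB = TrnaPair.of("Gly-CCC", "Pro-AGG")
PC = TrnaPair.of("Gly-CCC", "Gly-CCC")
UNIV3 = sorted([PA, PB, PC])


class TestComputeEfactors:
    def test_poi_identical_to_background_gives_unit_efactors(self, assignment, universe):
        rec = cds("AUG", "AUA", "GGG", "CCU", "AUA", id="self")
        bg = pooled_background_frequencies(Transcriptome((rec,)), assignment)
        poi = poi_frequencies(rec, assignment)
        table = compute_efactors(poi, bg, universe)
        for r in table.records:
            if r.f_bg > 0:
                assert r.efactor == 1

    def test_zero_numerator_gives_zero(self):
        poi = freqs({PA: Fraction(1)})
        bg = freqs({PA: Fraction(1, 2), PB: Fraction(1, 2)})
        table = compute_efactors(poi, bg, UNIV3)
        assert table[PB].efactor == 0
        assert table[PC].efactor == 0  # absent from both

    def test_known_ratio(self):
        poi = freqs({PA: Fraction(3, 10), PB: Fraction(7, 10)})
        bg = freqs({PA: Fraction(1, 100), PB: Fraction(99, 100)})
        table = compute_efactors(poi, bg, UNIV3)
        assert table[PA].efactor == Fraction(30)
        assert table[PB].efactor == Fraction(7, 10) / Fraction(99, 100)

    def test_zero_background_sentinel_and_flag(self):
        poi = freqs({PA: Fraction(1, 2), PC: Fraction(1, 2)})
        bg = freqs({PA: Fraction(1)})
        table = compute_efactors(poi, bg, UNIV3)
        assert table[PC].efactor == math.inf
        assert "zero_background" in table[PC].flags

    def test_pseudocount_policy_is_finite_and_flagged(self):
        poi = freqs({PA: Fraction(1, 2), PC: Fraction(1, 2)})
        bg = PairFrequencies(freqs={PA: Fraction(1)}, support_total=10)
        table = compute_efactors(poi, bg, UNIV3, ZeroPolicy("pseudocount", alpha=1.0))
        r = table[PC]
        assert r.efactor == Fraction(1, 2) / (Fraction(1) / 13)  # (0+1)/(10+3)
        assert {"zero_background", "pseudocounted"} <= r.flags

    def test_scale_invariance_of_background_counts(self, assignment, universe):
        rng = random.Random(3)
        recs = tuple(
            cds(*rng.choices(SENSE_CODONS, k=25), id=f"r{i}") for i in range(4)
        )
        poi = poi_frequencies(recs[0], assignment)
        bg1 = pooled_background_frequencies(Transcriptome(recs), assignment)
        tripled = Transcriptome(
            tuple(
                cds(*r.codons, id=f"r{i}_{k}") for k in range(3) for i, r in enumerate(recs)
            )
        )
        bg3 = pooled_background_frequencies(tripled, assignment)
        t1 = compute_efactors(poi, bg1, universe)
        t3 = compute_efactors(poi, bg3, universe)
        assert [(r.pair, r.efactor) for r in t1.records] == [
            (r.pair, r.efactor) for r in t3.records
        ]

    def test_enriching_the_target_strictly_increases_its_efactor(self, assignment, universe):
        # swap one non-target dicodon occurrence for the target, length fixed
        base = ["AUA", "AUA"] + ["GGG", "CCU"] * 10
        more = ["AUA", "AUA", "AUA"] + ["GGG", "CCU"] * 9 + ["GGG"]
        bg = pooled_background_frequencies(
            Transcriptome((cds(*base, id="b"), cds(*["GCU"] * 30, id="f"))), assignment
        )
        e_base = compute_efactors(
            poi_frequencies(cds(*base), assignment), bg, universe
        )[PA].efactor
        e_more = compute_efactors(
            poi_frequencies(cds(*more), assignment), bg, universe
        )[PA].efactor
        assert e_more > e_base

    def test_mismatched_universe_errors(self):
        poi = freqs({PA: Fraction(1)})
        bg = freqs({PB: Fraction(1)})
        with pytest.raises(ValueError, match="outside the universe"):
            compute_efactors(poi, bg, [PA])

    def test_matches_brute_force_on_random_micro_transcriptomes(self, assignment, universe):
        rng = random.Random(42)
        table_map = dict(assignment.table)
        tuple_universe = [(p.first_id, p.second_id) for p in universe]
        for _ in range(25):
            n_rec = rng.randint(1, 6)
            lists = [
                [rng.choice(SENSE_CODONS) for _ in range(rng.randint(2, 30))]
                for _ in range(n_rec)
            ]
            bg_expect, bg_total, _ = brute_pair_frequencies(lists, table_map)
            poi_expect, poi_total, _ = brute_pair_frequencies([lists[0]], table_map)
            if bg_total == 0 or poi_total == 0:
                continue
            t = Transcriptome(tuple(cds(*c, id=f"r{i}") for i, c in enumerate(lists)))
            table = compute_efactors(
                poi_frequencies(t.records[0], assignment),
                pooled_background_frequencies(t, assignment),
                universe,
            )
            expect_e = brute_efactors(poi_expect, bg_expect, tuple_universe)
            expect_rank = brute_rarity_ranks(bg_expect, tuple_universe)
            for r in table.records:
                key = (r.pair.first_id, r.pair.second_id)
                if r.efactor == math.inf:
                    assert expect_e[key] == math.inf
                else:
                    assert abs(float(r.efactor) - float(expect_e[key])) <= 1e-12
                assert r.bg_rank_rarity == expect_rank[key]


class TestLeadingPair:
    def test_unique_maximum(self):
        poi = freqs({PA: Fraction(3, 4), PB: Fraction(1, 4)})
        bg = freqs({PA: Fraction(1, 100), PB: Fraction(99, 100)})
        top = leading_pair(compute_efactors(poi, bg, UNIV3))
        assert top.pair == PA and top.efactor == 75

    def test_efactor_tie_broken_by_lower_background(self):
        # two pairs with identical E; PB has the lower background frequency
        poi = freqs({PA: Fraction(2, 3), PB: Fraction(1, 3)})
        bg = freqs({PA: Fraction(2, 3), PB: Fraction(1, 3)})
        top = leading_pair(compute_efactors(poi, bg, UNIV3))
        assert top.pair == PB and top.efactor == 1

    def test_infinite_outranks_finite(self):
        poi = freqs({PA: Fraction(99, 100), PC: Fraction(1, 100)})
        bg = freqs({PA: Fraction(1, 100), PB: Fraction(99, 100)})
        top = leading_pair(compute_efactors(poi, bg, UNIV3))
        assert top.pair == PC and top.efactor == math.inf

    def test_all_zero_flagged_no_signal(self):
        # a POI with no usable signal: empty frequency vector, zero support
        poi = PairFrequencies(freqs={}, support_total=0, label="empty")
        bg = freqs({PB: Fraction(1)})
        top = leading_pair(compute_efactors(poi, bg, UNIV3))
        assert top.efactor == 0 and "no_signal" in top.flags

    def test_agrees_with_brute_force_max_ordering(self):
        rng = random.Random(5)
        ids = [f"Xaa-A{i}U" for i in range(6)]
        univ = sorted({TrnaPair.of(a, b) for a in ids for b in ids})
        for _ in range(50):
            k = len(univ)
            poi_w = [rng.randint(0, 3) for _ in range(k)]
            bg_w = [rng.randint(0, 3) for _ in range(k)]
            if sum(poi_w) == 0 or sum(bg_w) == 0:
                continue
            poi = freqs({p: Fraction(w, sum(poi_w)) for p, w in zip(univ, poi_w) if w})
            bg = freqs({p: Fraction(w, sum(bg_w)) for p, w in zip(univ, bg_w) if w})
            table = compute_efactors(poi, bg, univ)
            top = leading_pair(table)
            key = lambda r: (
                r.efactor if r.efactor != math.inf else Fraction(10**30),
                -r.f_bg,
                [-ord(ch) for ch in r.pair.id],
            )
            best = max(table.records, key=key)
            assert top.pair == best.pair and top.efactor == best.efactor


class TestControlPair:
    def test_poi_using_every_pair_yields_empty_list(self):
        poi = freqs({PA: Fraction(1)})
        bg = freqs({PA: Fraction(1)})
        assert select_control_pair(poi, bg, [PA]) == []

    def test_single_admissible_control_found(self):
        # PB absent from POI and common in background (above the floor
        # 2/|universe| = 2/3); PC also absent but too rare to qualify
        poi = freqs({PA: Fraction(1)})
        bg = freqs({PA: Fraction(1, 10), PB: Fraction(8, 10), PC: Fraction(1, 10)})
        hits = select_control_pair(poi, bg, UNIV3, min_bg_multiple=2.0)
        assert hits == [PB]

    def test_sorted_by_descending_background(self):
        poi = freqs({PA: Fraction(1)})
        bg = freqs({PB: Fraction(1, 3), PC: Fraction(2, 3)})
        assert select_control_pair(poi, bg, UNIV3, min_bg_multiple=0.5) == [PC, PB]

    def test_control_pair_on_viral_like_fixture(self, assignment, universe):
        # the fixture's target dicodon pair must never qualify as a control
        from dicomps import viral_like_fixture

        fx = viral_like_fixture()
        bg = pooled_background_frequencies(fx, assignment)
        poi = poi_frequencies(fx["NS3-like"], assignment)
        hits = select_control_pair(poi, bg, universe)
        assert PA not in hits
        assert all(poi.get(p) == 0 for p in hits)


class TestSurvey:
    def test_homogeneous_self_survey(self, assignment, universe):
        rec = ("AUG", "GCU", "AAA", "GGG", "UUU") * 8
        t = Transcriptome(tuple(cds(*rec, id=f"r{i}") for i in range(6)))
        bg = pooled_background_frequencies(t, assignment)
        s = survey_transcriptome(t, bg, assignment, universe)
        assert s.n_transcripts == 6
        assert all(e == 1.0 for _, e in s.leading.values())
        assert s.fraction_above[100] == 0.0
        assert s.fraction_below[10] == 1.0

    def test_self_background_leading_is_at_least_one(self, assignment, universe):
        rng = random.Random(11)
        t = Transcriptome(
            tuple(
                cds(*rng.choices(SENSE_CODONS, k=rng.randint(10, 40)), id=f"r{i}")
                for i in range(8)
            )
        )
        bg = pooled_background_frequencies(t, assignment)
        s = survey_transcriptome(t, bg, assignment, universe)
        assert all(e >= 1.0 for _, e in s.leading.values())

    def test_planted_fraction_above_threshold(self, assignment, universe):
        # 2 of 250 equal-length transcripts carry one AUA:AUA occurrence that
        # never appears in the filler, so with self-inclusive pooling their
        # leading E-factor is exactly N/k = 250/2 = 125 > 100 by construction
        filler = ["GGG", "CCU"] * 60
        spiked = ["AUA", "AUA"] + ["GGG", "CCU"] * 59
        recs = [cds(*spiked, id="s1"), cds(*spiked, id="s2")]
        recs += [cds(*filler, id=f"f{i}") for i in range(248)]
        t = Transcriptome(tuple(recs))
        bg = pooled_background_frequencies(t, assignment)
        table = compute_efactors(poi_frequencies(recs[0], assignment), bg, universe)
        assert table[PA].efactor == 125  # construction sanity
        s = survey_transcriptome(t, bg, assignment, universe)
        assert s.fraction_above[100] == pytest.approx(2 / 250)
        assert s.fraction_above[20] >= s.fraction_above[100]
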