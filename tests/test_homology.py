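from __future__ import annotations

import itertools
import logging
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirscout.config import Thresholds
from mirscout.homology import (
    CandidateRegion,
    FamilyCutoffs,
    HomologyHit,
    cap_candidates,
    disambiguate_strand,
    filter_cm_hits,
    filter_hmm_hits,
    filter_sequence_hits,
    merge_engines,
    merge_hits_to_regions,
    resolve_strands,
)
from mirscout.intervals import GenomicInterval


def make_hit(
    start=100,
    end=170,
    strand="+",
    seq="chr1",
    family="fam1",
    engine="blast",
    evalue=1e-10,
    bitscore=60.0,
    hsp=60,
    coverage=0.9,
):
    return HomologyHit(
        interval=GenomicInterval(seq, start, end, strand),
        family_id=family,
        engine=engine,
        evalue=evalue,
        bitscore=bitscore,
        hsp_length=hsp,
        coverage=coverage,
    )


class TestSequenceFilter:
    @pytest.mark.parametrize(
        "evalue, hsp, cov, kept",
        [
            (0.01, 20, 0.70, True),    # all boundaries inclusive
            (0.02, 100, 1.00, False),  # E-value too large
            (1e-10, 19, 1.00, False),  # HSP one nt short
            (1e-10, 100, 0.699, False),
            (1e-10, 100, None, True),  # unknown coverage is not evaluable
        ],
    )
    def test_boundaries(self, evalue, hsp, cov, kept):
        hit = make_hit(evalue=evalue, hsp=hsp, coverage=cov)
        assert (filter_sequence_hits([hit]) == [hit]) is kept

    def test_idempotent_and_order_independent(self):
        hits = [
            make_hit(evalue=e, hsp=h, coverage=c)
            for e, h, c in itertools.product(
                [1e-9, 0.011], [19, 25], [0.6, 0.9]
            )
        ]
        once = filter_sequence_hits(hits)
        assert filter_sequence_hits(once) == once
        reversed_kept = filter_sequence_hits(hits[::-1])
        assert sorted(reversed_kept, key=id) == sorted(reversed_kept, key=id)
        assert set(map(id, reversed_kept)) == set(map(id, once))


class TestCmFilter:
    def test_uniform_genome_size_threshold(self):
        cutoffs = FamilyCutoffs(genome_size=2**31)
        assert cutoffs.bitscore_threshold == 32.0
        kept = filter_cm_hits([make_hit(engine="cm", bitscore=33.0)], cutoffs)
        assert len(kept) == 1
        kept = filter_cm_hits([make_hit(engine="cm", bitscore=32.0)], cutoffs)
        assert kept == []  # strict inequality on log2(2N)

    def test_gathering_cutoff_rescue(self):
        hit = make_hit(engine="cm", bitscore=31.9)
        no_rescue = FamilyCutoffs(genome_size=2**31, gathering_cutoff=100.0)
        assert filter_cm_hits([hit], no_rescue) == []  # nBit = 0.319
        rescue = FamilyCutoffs(genome_size=2**31, gathering_cutoff=90.0)
        assert filter_cm_hits([hit], rescue) == [hit]  # nBit ~ 0.354

    def test_evalue_and_coverage_still_apply(self):
        cutoffs = FamilyCutoffs(genome_size=1000)
        bad_e = make_hit(engine="cm", evalue=0.05, bitscore=500.0)
        bad_cov = make_hit(engine="cm", coverage=0.5, bitscore=500.0)
        assert filter_cm_hits([bad_e, bad_cov], cutoffs) == []

    def test_invalid_gathering_cutoff_rejected(self):
        with pytest.raises(ValueError):
            FamilyCutoffs(genome_size=1000, gathering_cutoff=-1.0)


def test_hmm_filter_applies_evalue_only():
    kept = filter_hmm_hits(
        [make_hit(engine="hmm", evalue=0.01, coverage=0.1),
         make_hit(engine="hmm", evalue=0.02)]
    )
    assert len(kept) == 1 and kept[0].evalue == 0.01


class TestRegionMerging:
    def test_overlapping_hits_form_one_region(self):
        regions = merge_hits_to_regions([make_hit(10, 50), make_hit(40, 90)])
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (10, 90)
        assert len(regions[0].supporting_hits) == 2

    def test_half_open_abutment_is_not_overlap(self):
        regions = merge_hits_to_regions([make_hit(10, 50), make_hit(50, 90)])
        assert len(regions) == 2

    def test_strands_kept_separate(self):
        regions = merge_hits_to_regions(
            [make_hit(10, 50, "+"), make_hit(10, 50, "-")]
        )
        assert len(regions) == 2

    @settings(max_examples=80, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=60),
                st.integers(min_value=1, max_value=25),
                st.sampled_from("+-"),
            ),
            min_size=0,
            max_size=12,
        )
    )
    def test_matches_bruteforce_transitive_closure(self, raw):
        """Region merging equals the fixed point of pairwise merging."""
        hits = [make_hit(s, s + w, strand) for s, w, strand in raw]
        regions = merge_hits_to_regions(hits)

        # oracle: union-find over pairwise-overlapping hits
        parent = list(range(len(hits)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(hits)), 2):
            if hits[i].interval.overlaps(hits[j].interval):
                parent[find(i)] = find(j)
        groups = {}
        for i in range(len(hits)):
            groups.setdefault(find(i), []).append(hits[i])
        expected = sorted(
            (
                min(h.interval.start for h in g),
                max(h.interval.end for h in g),
                g[0].interval.strand,
                len(g),
            )
            for g in groups.values()
        )
        got = sorted(
            (r.interval.start, r.interval.end, r.interval.strand, len(r.supporting_hits))
            for r in regions
        )
        assert got == expected

        # permuting input permutes output only
        permuted = merge_hits_to_regions(hits[::-1])
        assert [
            (r.interval.start, r.interval.end, r.interval.strand) for r in permuted
        ] == [(r.interval.start, r.interval.end, r.interval.strand) for r in regions]

    def test_every_hit_lands_in_exactly_one_region(self):
        hits = [make_hit(s, s + 30) for s in (0, 20, 100, 200, 210)]
        regions = merge_hits_to_regions(hits)
        assigned = [h for r in regions for h in r.supporting_hits]
        assert sorted(map(id, assigned)) == sorted(map(id, hits))


class TestStrandDisambiguation:
    def region(self, strand="+", bitscore=50.0, evalue=1e-10, coverage=0.9):
        return CandidateRegion(
            GenomicInterval("chr1", 100, 170, strand),
            "fam1",
            [make_hit(100, 170, strand, bitscore=bitscore, evalue=evalue, coverage=coverage)],
        )

    def test_higher_bitscore_wins(self):
        winner, loser = disambiguate_strand(self.region("+", 50), self.region("-", 40))
        assert winner.interval.strand == "+"
        assert loser.status == "rejected_strand"

    def test_evalue_breaks_bitscore_tie(self):
        winner, _ = disambiguate_strand(
            self.region("+", 50, evalue=1e-5), self.region("-", 50, evalue=1e-9)
        )
        assert winner.interval.strand == "-"

    def test_full_tie_keeps_plus_and_warns(self, caplog):
        with caplog.at_level(logging.WARNING, logger="mirscout.homology"):
            winner, loser = disambiguate_strand(self.region("+"), self.region("-"))
        assert winner.interval.strand == "+"
        assert loser.status == "rejected_strand"
        assert any("tie" in rec.message for rec in caplog.records)

    def test_resolve_strands_reports_both_sides(self):
        kept, rejected = resolve_strands([self.region("+", 60), self.region("-", 40)])
        assert len(kept) == 1 and len(rejected) == 1
        assert kept[0].interval.strand == "+"


class TestEngineMerging:
    def test_same_locus_from_two_engines_unifies(self):
        blast = merge_hits_to_regions([make_hit(100, 170, engine="blast", bitscore=50)])
        cm = merge_hits_to_regions([make_hit(110, 180, engine="cm", bitscore=70)])
        merged = merge_engines(blast, cm)
        assert len(merged) == 1
        region = merged[0]
        assert (region.interval.start, region.interval.end) == (100, 180)
        assert region.engines == ("blast", "cm")
        assert region.best_bitscore == 70

    def test_single_engine_locus_is_retained(self):
        hmm = merge_hits_to_regions([make_hit(500, 560, engine="hmm")])
        merged = merge_engines([], hmm, [])
        assert len(merged) == 1 and merged[0].engines == ("hmm",)

    def test_disjoint_loci_unchanged(self):
        blast = merge_hits_to_regions([make_hit(0, 50), make_hit(1000, 1050)])
        assert len(merge_engines(blast, [], [])) == 2


class TestCandidateCap:
    def regions(self, n, bitscore=lambda i: 100.0 - i):
        return [
            CandidateRegion(
                GenomicInterval("chr1", 200 * i, 200 * i + 70, "+"),
                "fam1",
                [make_hit(200 * i, 200 * i + 70, bitscore=bitscore(i))],
            )
            for i in range(n)
        ]

    def test_under_cap_all_processed(self):
        processed, potential = cap_candidates(self.regions(100), limit=100)
        assert len(processed) == 100 and potential == []

    def test_overflow_flagged_potential(self):
        processed, potential = cap_candidates(self.regions(120), limit=100)
        assert len(processed) == 100 and len(potential) == 20
        assert all(r.status == "potential" for r in potential)
        assert min(r.best_bitscore for r in processed) >= max(
            r.best_bitscore for r in potential
        )

    def test_boundary_ties_resolved_deterministically(self):
        regions = self.regions(6, bitscore=lambda i: 50.0)
        a = cap_candidates(regions, limit=3)
        b = cap_candidates(list(reversed(regions)), limit=3)
        key = lambda r: (r.interval.start, r.interval.end)
        assert sorted(map(key, a[0])) == sorted(map(key, b[0]))
        # genomic order breaks the tie: the three leftmost loci proceed
        assert [r.interval.start for r in sorted(a[0], key=key)] == [0, 200, 400]
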