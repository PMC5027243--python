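"""Filter rules, reciprocal pairing and survey summaries."""

from __future__ import annotations

import random

import numpy as np
import pytest

from radsig import inversion_screen as isc
from radsig import synthetic_cohort as sc
from radsig.records import RearrangementCall, TumourCatalogue, ValidationError


def make_call(call_id, low, high, orient="head_head", support=12, chrom="chr1",
              chrom_high=None, sample_id="s1"):
    return RearrangementCall(
        call_id=call_id, chrom_low=chrom, chrom_high=chrom_high or chrom,
        low_ival=low, high_ival=high, orient=orient, read_support=support,
        sample_id=sample_id,
    )


def call_with(support, size, orient="head_head"):
    return make_call(f"c_{support}_{size}", (1000, 1000), (1000 + size, 1000 + size),
                     orient=orient, support=support)


class TestFilter:
    @pytest.mark.parametrize(
        "support,size,kept",
        [
            (6, 3000, True),    # passes both strict thresholds
            (6, 2000, False),   # too small, support not high-confidence
            (11, 800, True),    # high-confidence support waives size
            (10, 800, False),   # boundary: strictly greater than 10 required
            (5, 3000, False),   # boundary: strictly greater than 5 required
            (6, 2500, False),   # boundary: strictly greater than 2500 required
        ],
    )
    def test_rule_boundaries(self, support, size, kept):
        result = isc.filter_inversion_calls([call_with(support, size)])
        assert bool(result) is kept

    def test_non_inverted_and_interchromosomal_excluded(self):
        calls = [
            make_call("other", (1000, 1000), (9000, 9000), orient="other", support=50),
            make_call("tra", (1000, 1000), (9000, 9000), support=50, chrom_high="chr2"),
        ]
        assert isc.filter_inversion_calls(calls) == []

    def test_raising_thresholds_never_keeps_more(self):
        rng = random.Random(5)
        calls = [
            call_with(rng.randrange(0, 30), rng.randrange(100, 10000))
            for _ in range(200)
        ]
        base = len(isc.filter_inversion_calls(calls, isc.ScreenConfig()))
        for config in (
            isc.ScreenConfig(min_reads=8),
            isc.ScreenConfig(min_size_bp=5000),
            isc.ScreenConfig(high_conf_reads=15),
            isc.ScreenConfig(min_reads=8, min_size_bp=5000, high_conf_reads=15),
        ):
            assert len(isc.filter_inversion_calls(calls, config)) <= base


class TestPairing:
    def test_reciprocal_pair_and_size(self):
        head = make_call("h1", (1000, 1010), (50000, 50010))
        tail = make_call("t1", (1004, 1014), (50003, 50013), orient="tail_tail")
        inversions, unpaired = isc.pair_balanced_inversions([head, tail])
        assert len(inversions) == 1 and not unpaired
        inv = inversions[0]
        assert (inv.head_call_id, inv.tail_call_id) == ("h1", "t1")
        assert inv.size == pytest.approx(49000, abs=1)

    def test_non_overlapping_low_ends_stay_unpaired(self):
        head = make_call("h1", (1000, 1010), (50000, 50010))
        tail = make_call("t1", (2000, 2010), (50003, 50013), orient="tail_tail")
        inversions, unpaired = isc.pair_balanced_inversions([head, tail])
        assert inversions == [] and len(unpaired) == 2

    def test_nearest_mate_wins_vs_bruteforce(self):
        # three heads all overlap the one tail; closest summed distance wins
        heads = [
            make_call("h1", (1000, 1400), (50000, 50400)),
            make_call("h2", (1100, 1500), (50100, 50500)),
            make_call("h3", (1050, 1450), (50020, 50420)),
        ]
        tail = make_call("t1", (1040, 1440), (50030, 50430), orient="tail_tail")
        inversions, _ = isc.pair_balanced_inversions(heads + [tail])
        assert len(inversions) == 1
        best = min(
            heads,
            key=lambda h: abs(h.low_mid - tail.low_mid) + abs(h.high_mid - tail.high_mid),
        )
        assert inversions[0].head_call_id == best.call_id

    def test_point_breakpoints_get_slop(self):
        head = make_call("h1", (1000, 1000), (50000, 50000))
        tail = make_call("t1", (1300, 1300), (50300, 50300), orient="tail_tail")
        inversions, _ = isc.pair_balanced_inversions([head, tail], isc.ScreenConfig())
        assert len(inversions) == 1
        none, _ = isc.pair_balanced_inversions([head, tail], isc.ScreenConfig(slop_bp=100))
        assert none == []

    def test_pairing_invariant_under_shuffling(self):
        rng = np.random.default_rng(17)
        calls, _ = sc.simulate_rearrangements(
            sc.RearrangementParams(balanced_mean=6, unbalanced_mean=3, artefact_mean=0),
            {"chr1": 5_000_000, "chr2": 5_000_000}, "s1", rng,
        )
        reference, _ = isc.pair_balanced_inversions(calls)
        ref_pairs = {(i.head_call_id, i.tail_call_id) for i in reference}
        shuffled = calls[:]
        for seed in (1, 2, 3):
            random.Random(seed).shuffle(shuffled)
            inversions, _ = isc.pair_balanced_inversions(shuffled)
            assert {(i.head_call_id, i.tail_call_id) for i in inversions} == ref_pairs

    def test_implanted_pairs_recovered(self):
        rng = np.random.default_rng(23)
        params = sc.RearrangementParams(
            balanced_mean=5, unbalanced_mean=0, artefact_mean=0, interchrom_mean=0,
            jitter_bp=100,
        )
        for _ in range(10):
            calls, truth = sc.simulate_rearrangements(
                params, {"chr1": 5_000_000}, "s1", rng
            )
            inversions, _ = isc.screen_catalogue(calls)
            found = {frozenset((i.head_call_id, i.tail_call_id)) for i in inversions}
            implanted = {frozenset(pair) for pair in truth["balanced_pairs"]}
            assert found == implanted


class TestGeneAnnotation:
    def test_breakpoint_hits_and_fraction(self):
        head = make_call("h1", (140, 160), (240, 260))
        tail = make_call("t1", (150, 170), (250, 270), orient="tail_tail")
        inversions, _ = isc.pair_balanced_inversions([head, tail])
        genes = {"chr1": [(100, 200, "GENE1")]}
        table, fraction = isc.annotate_breakpoint_genes(
            inversions, {"h1": head, "t1": tail}, genes
        )
        # low breakpoints (midpoints 150/160) in the gene; high ones (250/260) out
        assert table.set_index(["call_id", "end"])["in_gene"].to_dict() == {
            ("h1", "low"): True, ("h1", "high"): False,
            ("t1", "low"): True, ("t1", "high"): False,
        }
        assert fraction == pytest.approx(0.5)


class TestCohortSummary:
    def test_pooling_of_survey_rows(self):
        rows = [
            isc.InversionSummaryRow("naive_breast", 251, 39, 59),
            isc.InversionSummaryRow("naive_osteosarcoma", 35, 4, 7),
        ]
        pooled = isc.pool_summary_rows(rows, label="radiation_naive")
        assert (
            pooled.tumours_screened,
            pooled.tumours_with_inversion,
            pooled.total_inversions,
        ) == (286, 43, 66)

    def test_empty_group_and_multi_inversion_tumour(self):
        calls = []
        for i, start in enumerate((100_000, 1_000_000, 3_000_000)):
            calls.append(make_call(f"h{i}", (start, start + 100),
                                   (start + 50_000, start + 50_100), sample_id="s1"))
            calls.append(make_call(f"t{i}", (start + 40, start + 140),
                                   (start + 50_060, start + 50_160),
                                   orient="tail_tail", sample_id="s1"))
        catalogues = [
            TumourCatalogue("s1", "radiation", rearrangements=calls),
            TumourCatalogue("s2", "naive_breast"),
        ]
        rows, _ = isc.inversion_cohort_summary(catalogues)
        by_group = {r.group: r for r in rows}
        assert (
            by_group["radiation"].tumours_screened,
            by_group["radiation"].tumours_with_inversion,
            by_group["radiation"].total_inversions,
        ) == (1, 1, 3)
        assert (
            by_group["naive_breast"].tumours_screened,
            by_group["naive_breast"].tumours_with_inversion,
            by_group["naive_breast"].total_inversions,
        ) == (1, 0, 0)

    def test_unknown_group_label_rejected(self):
        catalogues = [TumourCatalogue("s1", "mystery")]
        with pytest.raises(ValidationError, match="mystery"):
            isc.inversion_cohort_summary(catalogues, known_groups=["radiation"])
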