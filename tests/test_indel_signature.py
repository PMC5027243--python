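"""Microhomology, burdens, spectra and the excess-indel estimate."""

from __future__ import annotations

import numpy as np
import pytest

from radsig import indel_signature as isig
from radsig import synthetic_cohort as sc
from radsig.genome import InMemoryGenome
from radsig.records import IndelRecord, SubstitutionRecord, TumourCatalogue, ValidationError


def deletion_at(chrom, anchor, length, reference, sample_id="s1"):
    ref_allele = reference.fetch(chrom, anchor, anchor + length)
    return IndelRecord(
        chrom=chrom, pos=anchor, ref_allele=ref_allele, alt_allele=ref_allele[0],
        indel_class="deletion", length=length, deleted_seq=ref_allele[1:],
        sample_id=sample_id,
    )


def brute_force_mh(sequence: str, span_start: int, span_end: int) -> int:
    """Exhaustive character-comparison oracle (1-based closed span)."""
    deleted = sequence[span_start - 1 : span_end]
    L = len(deleted)
    right = sequence[span_end : span_end + L]
    left = sequence[max(0, span_start - 1 - L) : span_start - 1]
    best = 0
    for k in range(1, L + 1):
        if deleted[:k] == right[:k]:
            best = max(best, k)
    for k in range(1, L + 1):
        if k <= len(left) and deleted[L - k :] == left[len(left) - k :]:
            best = max(best, k)
    return best


class TestMicrohomology:
    def test_left_flank_beats_right(self, tiny_genome):
        # chrA = AAGTAGTCC, delete TAG (4-6): left AAG shares AG, right TCC shares T
        rec = deletion_at("chrA", 3, 3, tiny_genome)
        assert rec.deleted_seq == "TAG"
        assert isig.compute_microhomology(tiny_genome, rec) == 2

    def test_cap_at_deletion_length(self, tiny_genome):
        # chrB = GCACAT, delete CA (2-3): right flank CAT starts with CA -> cap 2
        rec = deletion_at("chrB", 1, 2, tiny_genome)
        assert rec.deleted_seq == "CA"
        assert isig.compute_microhomology(tiny_genome, rec) == 2

    def test_no_shared_terminal_bases(self):
        genome = InMemoryGenome({"chr1": "GGGTTAAACC"})
        rec = deletion_at("chr1", 3, 2, genome)  # delete TT; flanks GGG / AAA
        assert isig.compute_microhomology(genome, rec) == 0

    def test_matches_bruteforce_on_random_deletions(self):
        rng = np.random.default_rng(99)
        # random sequence with embedded tandem repeats to exercise the cap
        parts = []
        while sum(len(p) for p in parts) < 30_000:
            if rng.random() < 0.3:
                unit = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 5)))
                parts.append(unit * int(rng.integers(2, 6)))
            else:
                parts.append("".join(rng.choice(list("ACGT"), size=50)))
        seq = "".join(parts)
        genome = InMemoryGenome({"chr1": seq})
        for _ in range(300):
            length = int(rng.integers(1, 30))
            anchor = int(rng.integers(1, len(seq) - length - 35))
            rec = deletion_at("chr1", anchor, length, genome)
            assert isig.compute_microhomology(genome, rec) == brute_force_mh(
                seq, rec.del_start, rec.del_end
            )

    def test_invariant_under_left_alignment(self):
        # same tandem-repeat event represented at two anchors
        genome = InMemoryGenome({"chr1": "GGTATATATACC"})
        shifted = deletion_at("chr1", 4, 2, genome)   # delete AT at 5-6
        aligned = deletion_at("chr1", 2, 2, genome)   # delete TA at 3-4
        assert isig.compute_microhomology(genome, shifted) == isig.compute_microhomology(
            genome, aligned
        )

    def test_span_outside_reference_raises(self, tiny_genome):
        rec = IndelRecord("chrB", 4, "CAT", "C", "deletion", 2, deleted_seq="AT")
        rec.pos = 5  # span 6-7 exceeds the 6-bp chromosome
        with pytest.raises(IndexError):
            isig.compute_microhomology(tiny_genome, rec)


def catalogue_with(n_subs, n_del, n_ins, n_complex=0, sample_id="s", group="g"):
    genome_pos = iter(range(1, 10**6))
    cat = TumourCatalogue(sample_id=sample_id, group=group)
    cat.substitutions = [
        SubstitutionRecord("chr1", next(genome_pos), "A", "C", sample_id)
        for _ in range(n_subs)
    ]
    for _ in range(n_del):
        cat.indels.append(IndelRecord("chr1", next(genome_pos), "AT", "A",
                                      "deletion", 1, deleted_seq="T",
                                      sample_id=sample_id))
    for _ in range(n_ins):
        cat.indels.append(IndelRecord("chr1", next(genome_pos), "A", "AT",
                                      "insertion", 1, sample_id=sample_id))
    for _ in range(n_complex):
        cat.indels.append(IndelRecord("chr1", next(genome_pos), "AT", "GC",
                                      "complex", 2, sample_id=sample_id))
    return cat


class TestBurdens:
    def test_ratios(self):
        b = isig.burden_summary(catalogue_with(1000, 90, 30))
        assert b.indel_sub_ratio == pytest.approx(0.12)
        assert b.del_ins_ratio == pytest.approx(3.0)

    def test_zero_insertions_undefined_ratio(self):
        b = isig.burden_summary(catalogue_with(100, 10, 0))
        assert b.del_ins_ratio is None
        assert (b.n_del, b.n_ins) == (10, 0)

    def test_empty_catalogue(self):
        b = isig.burden_summary(catalogue_with(0, 0, 0))
        assert b.indel_sub_ratio is None and b.del_ins_ratio is None
        assert b.n_indels == 0

    def test_complex_excluded_from_del_ins_ratio(self):
        b = isig.burden_summary(catalogue_with(100, 20, 10, n_complex=5))
        assert b.del_ins_ratio == pytest.approx(2.0)
        assert b.n_indels == 35


class TestSizeSpectrum:
    def test_normalized_spectrum_sums_to_one(self):
        spec = isig.size_spectrum([1, 1, 2, 5, 150], normalize=True)
        assert spec.sum() == pytest.approx(1.0)
        assert spec[">100"] == pytest.approx(0.2)

    def test_counts(self):
        spec = isig.size_spectrum([1, 1, 3])
        assert spec["1"] == 2 and spec["3"] == 1 and spec.sum() == 3


class TestKsStatistic:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 1, 1], [2, 2, 2], 1.0),
            ([1, 2, 3, 4], [3, 4, 5, 6], 0.5),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert isig.ks_statistic(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=40), rng.normal(1, 2, size=25)
        assert isig.ks_statistic(a, b) == pytest.approx(isig.ks_statistic(b, a))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            isig.ks_statistic([], [1.0])


class TestExcessIndels:
    def test_excess_against_median_baseline(self):
        naive = [catalogue_with(1000, 50, 50, sample_id=f"n{i}") for i in range(3)]
        radiation = [catalogue_with(1000, 200, 100, sample_id="r0")]
        est = isig.excess_indel_estimate(radiation, naive)
        assert est.baseline_ratio == pytest.approx(0.1)
        assert est.per_sample["excess_indels"].iloc[0] == pytest.approx(200)

    def test_sample_at_baseline_has_zero_excess(self):
        naive = [catalogue_with(1000, 50, 50, sample_id=f"n{i}") for i in range(3)]
        radiation = [catalogue_with(1000, 60, 40, sample_id="r0")]
        est = isig.excess_indel_estimate(radiation, naive)
        assert est.per_sample["excess_indels"].iloc[0] == pytest.approx(0.0)

    def test_median_is_order_statistic(self):
        naive = [catalogue_with(1000, 50, 50, sample_id=f"n{i}") for i in range(3)]
        radiation = [
            catalogue_with(1000, 45, 45, sample_id="r0"),   # excess -10
            catalogue_with(1000, 200, 101, sample_id="r1"),  # excess 201
            catalogue_with(1000, 400, 200, sample_id="r2"),  # excess 500
        ]
        est = isig.excess_indel_estimate(radiation, naive)
        assert est.median_excess == pytest.approx(201)

    def test_empty_naive_group_rejected(self):
        with pytest.raises(ValidationError):
            isig.excess_indel_estimate([catalogue_with(10, 1, 1)], [])


def test_del_ins_ratio_separates_groups_across_replicates():
    """3:1 vs 1:1 deletion odds shifts the group median ratio in every seeded run."""
    from conftest import small_params

    params = small_params(n_radiation=4, n_naive=4, chrom_length=100_000)
    for group in params.groups:
        group.sub_burden_median = 300.0
    wins = 0
    n_reps = 10
    for rep in range(n_reps):
        sim = sc.simulate_cohort(params, seed=500 + rep)
        ratios = {"radiation": [], "naive_breast": []}
        for cat in sim.catalogues:
            b = isig.burden_summary(cat)
            if b.del_ins_ratio is not None:
                ratios[cat.group].append(b.del_ins_ratio)
        wins += np.median(ratios["radiation"]) > np.median(ratios["naive_breast"])
    assert wins >= int(0.95 * n_reps)
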