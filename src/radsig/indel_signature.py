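"""Indel burden, deletion size spectra and junction microhomology.

Microhomology here is the longest identity between the deleted sequence and
the reference immediately flanking the deleted span, on either side, capped at
the deletion length. It measures how much sequence the two junction sides
share — the hallmark of microhomology-mediated / non-homologous end-joining
repair of double-strand breaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSequence
from .records import (
    INDEL_COMPLEX,
    INDEL_DELETION,
    INDEL_INSERTION,
    IndelRecord,
    TumourCatalogue,
    ValidationError,
)


def compute_microhomology(reference: GenomeSequence, deletion: IndelRecord) -> int:
    """Junction microhomology length of a deletion, in bp.

    With deleted sequence D of length L spanning ``s..e``:

    * right microhomology = longest k <= L with ``D[:k]`` equal to the k
      reference bases immediately 3' of the span;
    * left microhomology = longest k <= L with ``D[-k:]`` equal to the k
      bases immediately 5' of the span;

    and the result is ``max(left, right)``, in ``0..L``. Flanks truncated by
    a chromosome end simply cap the attainable k on that side.
    """
    if deletion.indel_class != INDEL_DELETION:
        raise ValidationError("microhomology is defined for deletions only")
    L = deletion.length
    s, e = deletion.del_start, deletion.del_end
    chrom_len = reference.lengths[deletion.chrom]
    if s < 1 or e > chrom_len:
        raise IndexError(
            f"deletion span {deletion.chrom}:{s}-{e} outside reference (len {chrom_len})"
        )
    D = deletion.deleted_seq or reference.fetch(deletion.chrom, s, e)

    right = reference.fetch(deletion.chrom, e + 1, min(e + L, chrom_len)) if e < chrom_len else ""
    mh_right = 0
    for k in range(1, min(L, len(right)) + 1):
        if D[:k] == right[:k]:
            mh_right = k
        else:
            break

    left = reference.fetch(deletion.chrom, max(1, s - L), s - 1) if s > 1 else ""
    mh_left = 0
    for k in range(1, min(L, len(left)) + 1):
        if D[L - k :] == left[len(left) - k :]:
            mh_left = k
        else:
            break

    return max(mh_left, mh_right)


def annotate_microhomology(
    reference: GenomeSequence, indels: Sequence[IndelRecord]
) -> list[IndelRecord]:
    """Fill ``mh_len`` in place for every deletion; returns the same list."""
    for rec in indels:
        if rec.indel_class == INDEL_DELETION:
            rec.mh_len = compute_microhomology(reference, rec)
    return list(indels)


# ---------------------------------------------------------------------------
# Burdens and spectra
# ---------------------------------------------------------------------------

@dataclass
class BurdenSummary:
    sample_id: str
    group: str
    n_subs: int
    n_del: int
    n_ins: int
    n_complex: int

    @property
    def n_indels(self) -> int:
        return self.n_del + self.n_ins + self.n_complex

    @property
    def indel_sub_ratio(self) -> float | None:
        if self.n_subs == 0:
            return None
        return self.n_indels / self.n_subs

    @property
    def del_ins_ratio(self) -> float | None:
        """Deletions over insertions; None (undefined) when no insertions.

        Complex indels are excluded from this ratio: the contrast of interest
        is deletions versus insertions specifically.
        """
        if self.n_ins == 0:
            return None
        return self.n_del / self.n_ins


def burden_summary(catalogue: TumourCatalogue) -> BurdenSummary:
    classes = [r.indel_class for r in catalogue.indels]
    return BurdenSummary(
        sample_id=catalogue.sample_id,
        group=catalogue.group,
        n_subs=len(catalogue.substitutions),
        n_del=classes.count(INDEL_DELETION),
        n_ins=classes.count(INDEL_INSERTION),
        n_complex=classes.count(INDEL_COMPLEX),
    )


def burden_frame(catalogues: Sequence[TumourCatalogue]) -> pd.DataFrame:
    rows = []
    for cat in catalogues:
        b = burden_summary(cat)
        rows.append(
            {
                "sample_id": b.sample_id,
                "group": b.group,
                "n_subs": b.n_subs,
                "n_del": b.n_del,
                "n_ins": b.n_ins,
                "n_complex": b.n_complex,
                "indel_sub_ratio": b.indel_sub_ratio,
                "del_ins_ratio": b.del_ins_ratio,
            }
        )
    return pd.DataFrame(rows)


MAX_SPECTRUM_LENGTH = 100


def size_spectrum(lengths: Sequence[int], normalize: bool = False) -> pd.Series:
    """Histogram of deletion (or insertion) lengths over 1..100 plus ">100"."""
    index = [str(i) for i in range(1, MAX_SPECTRUM_LENGTH + 1)] + [">100"]
    counts = np.zeros(len(index), dtype=float)
    for length in lengths:
        if length < 1:
            raise ValidationError(f"indel length must be >= 1, got {length}")
        counts[min(length, MAX_SPECTRUM_LENGTH + 1) - 1] += 1
    if normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return pd.Series(counts, index=index, name="spectrum")


def ks_statistic(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sample Kolmogorov–Smirnov statistic D = sup |ECDF_a - ECDF_b|."""
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValidationError("KS statistic requires two non-empty samples")
    return float(stats.ks_2samp(np.asarray(values_a), np.asarray(values_b)).statistic)


# ---------------------------------------------------------------------------
# Excess indel burden
# ---------------------------------------------------------------------------

@dataclass
class ExcessIndelEstimate:
    baseline_ratio: float
    per_sample: pd.DataFrame  # sample_id, n_subs, n_indels, expected, excess
    median_excess: float
    sd_excess: float


def excess_indel_estimate(
    radiation_catalogues: Sequence[TumourCatalogue],
    naive_catalogues: Sequence[TumourCatalogue],
) -> ExcessIndelEstimate:
    """Median-baseline estimate of the per-genome excess indel burden.

    The radiation-naive group sets the expected indel:substitution ratio r0
    (its median); each exposed genome's excess is its indel count minus
    r0 times its substitution count.
    """
    if not naive_catalogues:
        raise ValidationError("naive group must be non-empty")
    if not radiation_catalogues:
        raise ValidationError("radiation group must be non-empty")
    naive_ratios = [
        b.indel_sub_ratio
        for b in map(burden_summary, naive_catalogues)
        if b.indel_sub_ratio is not None
    ]
    if not naive_ratios:
        raise ValidationError("no naive sample has a defined indel:substitution ratio")
    r0 = float(np.median(naive_ratios))
    rows = []
    for cat in radiation_catalogues:
        b = burden_summary(cat)
        expected = r0 * b.n_subs
        rows.append(
            {
                "sample_id": b.sample_id,
                "n_subs": b.n_subs,
                "n_indels": b.n_indels,
                "expected_indels": expected,
                "excess_indels": b.n_indels - expected,
            }
        )
    per_sample = pd.DataFrame(rows)
    excesses = per_sample["excess_indels"].to_numpy()
    return ExcessIndelEstimate(
        baseline_ratio=r0,
        per_sample=per_sample,
        median_excess=float(np.median(excesses)),
        sd_excess=float(np.std(excesses, ddof=1)) if len(excesses) > 1 else math.nan,
    )
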