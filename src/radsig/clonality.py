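"""Mutation copy number and clonal/subclonal timing of indels.

A mutation present in every tumour cell (clonal, acquired before the most
recent clonal sweep) sits at mutation copy number ~1 or higher; a mutation
confined to a subclone sits below 1. Radiation exposure predates tumour
expansion, so a radiation-derived deletion excess should be confined to the
clonal compartment — the contrast tested here.

Classification uses a fixed mutation-copy-number threshold (default 0.75,
configurable) rather than mixture-model peak finding; the threshold splits a
clonal peak at ~1 from subclonal peaks below it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import (
    CLONAL,
    INDEL_DELETION,
    SUBCLONAL,
    UNKNOWN,
    IndelRecord,
    TumourCatalogue,
    ValidationError,
)

DEFAULT_CLONAL_THRESHOLD = 0.75


def mutation_copy_number(
    vaf: float, purity: float, tumour_cn: float, normal_cn: float = 2.0
) -> float:
    """Number of tumour chromosome copies carrying the mutation.

    mcn = f * (rho * CN_t + CN_n * (1 - rho)) / rho, where f is the variant
    allele fraction, rho the tumour purity and CN_t / CN_n the local tumour
    and normal total copy numbers.
    """
    if purity <= 0 or purity > 1:
        raise ValidationError(f"purity must be in (0, 1], got {purity}")
    if not (0 <= vaf <= 1):
        raise ValidationError(f"VAF must be in [0, 1], got {vaf}")
    if tumour_cn < 0:
        raise ValidationError(f"tumour copy number must be >= 0, got {tumour_cn}")
    return vaf * (purity * tumour_cn + normal_cn * (1 - purity)) / purity


def classify_clonality(mcn: float, clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD) -> str:
    """Clonal when mcn >= threshold (boundary inclusive), else subclonal."""
    if mcn < 0:
        raise ValidationError(f"mutation copy number must be >= 0, got {mcn}")
    return CLONAL if mcn >= clonal_threshold else SUBCLONAL


def _local_copy_number(
    catalogue: TumourCatalogue, chrom: str, pos: int
) -> float | None:
    if catalogue.copy_number is None:
        return None
    for seg_chrom, start, end, cn in catalogue.copy_number:
        if seg_chrom == chrom and start <= pos <= end:
            return cn
    return None


def call_clonality(
    catalogue: TumourCatalogue, clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD
) -> pd.DataFrame:
    """Assign a clonality class to every indel of a tumour, in place.

    Any missing ingredient (VAF, purity, local copy number) yields class
    ``unknown`` rather than a guess. Returns the per-record table.
    """
    rows = []
    for rec in catalogue.indels:
        cn = _local_copy_number(catalogue, rec.chrom, rec.pos)
        if rec.vaf is None or catalogue.purity is None or cn is None:
            rec.clonality = UNKNOWN
            mcn = None
        else:
            mcn = mutation_copy_number(rec.vaf, catalogue.purity, cn)
            rec.clonality = classify_clonality(mcn, clonal_threshold)
        rows.append(
            {
                "sample_id": catalogue.sample_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "indel_class": rec.indel_class,
                "vaf": rec.vaf,
                "mcn": mcn,
                "clonality": rec.clonality,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher's exact test (built-in hypergeometric enumeration)
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    Returns (odds_ratio, p). The two-sided p sums the probabilities of all
    tables (with the observed margins) no more likely than the observed one.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValidationError("contingency table entries must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValidationError("empty contingency table")
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    if b * c == 0 and a * d == 0:
        odds = np.nan
    return float(odds), min(p, 1.0)


@dataclass
class ClonalDeletionContrast:
    """2x2 deletion-vs-other by clonal-vs-subclonal contrast for one tumour."""

    table: pd.DataFrame  # rows deletion/other, columns clonal/subclonal
    odds_ratio: float | None
    p_value: float | None
    computable: bool


def clonal_deletion_contrast(
    indels: Sequence[IndelRecord] | TumourCatalogue,
) -> ClonalDeletionContrast:
    """Test whether deletions are enriched among clonal versus subclonal indels.

    Rows: {deletion, other indel}; columns: {clonal, subclonal}. Indels with
    unknown clonality are excluded. When either timing class is entirely
    absent the table is still returned with the p-value flagged
    not-computable.
    """
    if isinstance(indels, TumourCatalogue):
        indels = indels.indels
    counts = {(r, c): 0 for r in ("deletion", "other") for c in (CLONAL, SUBCLONAL)}
    for rec in indels:
        if rec.clonality == UNKNOWN:
            continue
        row = "deletion" if rec.indel_class == INDEL_DELETION else "other"
        counts[(row, rec.clonality)] += 1
    table = pd.DataFrame(
        {
            CLONAL: [counts[("deletion", CLONAL)], counts[("other", CLONAL)]],
            SUBCLONAL: [counts[("deletion", SUBCLONAL)], counts[("other", SUBCLONAL)]],
        },
        index=["deletion", "other"],
    )
    col_sums = table.sum(axis=0)
    if (col_sums == 0).any():
        return ClonalDeletionContrast(table, None, None, computable=False)
    odds, p = fisher_exact_2x2(table.to_numpy())
    return ClonalDeletionContrast(table, odds, p, computable=True)
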