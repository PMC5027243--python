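"""Balanced-inversion screen.

A balanced inversion — a reciprocal flip of a chromosomal segment with no net
copy-number change — leaves two junctions in a rearrangement catalogue: one
head-to-head and one tail-to-tail call whose breakpoint ranges overlap at both
ends. The screen first removes small, low-read-support inversion artefacts,
then pairs the surviving inverted calls reciprocally.

Filter rule: an intrachromosomal inverted call is kept when its read support
exceeds ``min_reads`` AND its span exceeds ``min_size_bp``, or when its read
support exceeds ``high_conf_reads`` (in which case no size threshold applies).
All inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import (
    ORIENT_HEAD_HEAD,
    ORIENT_TAIL_TAIL,
    BalancedInversion,
    RearrangementCall,
    TumourCatalogue,
    ValidationError,
)


@dataclass
class ScreenConfig:
    """Thresholds of the inversion screen (all strict inequalities)."""

    min_reads: int = 5
    min_size_bp: int = 2500
    high_conf_reads: int = 10
    #: padding applied to degenerate (point) breakpoint intervals before the
    #: overlap test, so that "overlapping ranges" is meaningful for callers
    #: that emit exact breakpoints
    slop_bp: int = 500

    def __post_init__(self) -> None:
        if min(self.min_reads, self.min_size_bp, self.high_conf_reads, self.slop_bp) < 0:
            raise ValidationError("screen thresholds must be >= 0")
        if self.high_conf_reads < self.min_reads:
            raise ValidationError("high_conf_reads must be >= min_reads")


def filter_inversion_calls(
    calls: Iterable[RearrangementCall], config: ScreenConfig | None = None
) -> list[RearrangementCall]:
    """Apply the artefact filter; keeps input order."""
    config = config or ScreenConfig()
    kept = []
    for call in calls:
        if not call.is_intrachromosomal:
            continue
        if call.orient not in (ORIENT_HEAD_HEAD, ORIENT_TAIL_TAIL):
            continue
        size = call.span
        if (call.read_support > config.min_reads and size > config.min_size_bp) or (
            call.read_support > config.high_conf_reads
        ):
            kept.append(call)
    return kept


def _padded(ival: tuple[int, int], slop: int) -> tuple[int, int]:
    if ival[0] == ival[1]:
        return (ival[0] - slop, ival[1] + slop)
    return ival


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def candidate_mate(
    head: RearrangementCall, tail: RearrangementCall, config: ScreenConfig
) -> bool:
    """True when the two calls could form one balanced inversion."""
    if head.chrom_low != tail.chrom_low:
        return False
    slop = config.slop_bp
    return _overlap(_padded(head.low_ival, slop), _padded(tail.low_ival, slop)) and _overlap(
        _padded(head.high_ival, slop), _padded(tail.high_ival, slop)
    )


def _inversion_size(head: RearrangementCall, tail: RearrangementCall) -> float:
    # mean of the two junction midpoint spans: the distance between the
    # averaged outer breakpoint midpoints
    return (head.span + tail.span) / 2.0


def pair_balanced_inversions(
    filtered_calls: Sequence[RearrangementCall], config: ScreenConfig | None = None
) -> tuple[list[BalancedInversion], list[RearrangementCall]]:
    """Pair head-to-head with tail-to-tail calls into balanced inversions.

    Candidate pairs (same chromosome, both breakpoint ranges overlapping) are
    taken greedily in order of summed midpoint distance, ties broken by the
    lexicographic (head id, tail id) pair, so the outcome does not depend on
    input order. Each call joins at most one inversion.
    """
    config = config or ScreenConfig()
    heads = [c for c in filtered_calls if c.orient == ORIENT_HEAD_HEAD]
    tails = [c for c in filtered_calls if c.orient == ORIENT_TAIL_TAIL]
    candidates = []
    for h in heads:
        for t in tails:
            if candidate_mate(h, t, config):
                dist = abs(h.low_mid - t.low_mid) + abs(h.high_mid - t.high_mid)
                candidates.append((dist, h.call_id, t.call_id, h, t))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used: set[str] = set()
    inversions: list[BalancedInversion] = []
    for _, _, _, h, t in candidates:
        if h.call_id in used or t.call_id in used:
            continue
        used.update((h.call_id, t.call_id))
        inversions.append(
            BalancedInversion(
                head_call_id=h.call_id,
                tail_call_id=t.call_id,
                chrom=h.chrom_low,
                size=_inversion_size(h, t),
                sample_id=h.sample_id or t.sample_id,
            )
        )
    unpaired = [c for c in filtered_calls if c.call_id not in used]
    return inversions, unpaired


def screen_catalogue(
    calls: Iterable[RearrangementCall], config: ScreenConfig | None = None
) -> tuple[list[BalancedInversion], list[RearrangementCall]]:
    """Filter then pair: the full screen for one rearrangement catalogue."""
    config = config or ScreenConfig()
    return pair_balanced_inversions(filter_inversion_calls(calls, config), config)


# ---------------------------------------------------------------------------
# Breakpoint gene annotation
# ---------------------------------------------------------------------------

def annotate_breakpoint_genes(
    inversions: Sequence[BalancedInversion],
    calls_by_id: Mapping[str, RearrangementCall],
    gene_intervals: Mapping[str, Sequence[tuple[int, int, str]]],
) -> tuple[pd.DataFrame, float]:
    """Flag each of the four breakpoints per inversion that fall in a gene.

    A breakpoint hits a gene when its interval midpoint lies inside at least
    one gene interval. Returns the per-breakpoint table and the cohort-level
    fraction of breakpoints in genes.
    """
    rows = []
    n_hit = 0
    n_total = 0
    for inv in inversions:
        for call_id, end in (
            (inv.head_call_id, "low"),
            (inv.head_call_id, "high"),
            (inv.tail_call_id, "low"),
            (inv.tail_call_id, "high"),
        ):
            call = calls_by_id[call_id]
            mid = call.low_mid if end == "low" else call.high_mid
            genes = [
                name
                for (s, e, name) in gene_intervals.get(call.chrom_low, [])
                if s <= mid <= e
            ]
            n_total += 1
            n_hit += bool(genes)
            rows.append(
                {
                    "sample_id": inv.sample_id,
                    "head_call_id": inv.head_call_id,
                    "tail_call_id": inv.tail_call_id,
                    "call_id": call_id,
                    "end": end,
                    "midpoint": mid,
                    "in_gene": bool(genes),
                    "genes": ",".join(genes),
                }
            )
    fraction = n_hit / n_total if n_total else 0.0
    return pd.DataFrame(rows), fraction


# ---------------------------------------------------------------------------
# Cohort summary (survey-table shape)
# ---------------------------------------------------------------------------

@dataclass
class InversionSummaryRow:
    """One survey row: tumours screened / with >=1 inversion / total inversions."""

    group: str
    tumours_screened: int
    tumours_with_inversion: int
    total_inversions: int

    def __post_init__(self) -> None:
        if self.tumours_with_inversion > self.tumours_screened:
            raise ValidationError(
                f"group {self.group}: more tumours with inversions than screened"
            )


def pool_summary_rows(
    rows: Sequence[InversionSummaryRow], label: str = "pooled"
) -> InversionSummaryRow:
    """Pool survey rows over a set of groups by plain addition."""
    return InversionSummaryRow(
        group=label,
        tumours_screened=sum(r.tumours_screened for r in rows),
        tumours_with_inversion=sum(r.tumours_with_inversion for r in rows),
        total_inversions=sum(r.total_inversions for r in rows),
    )


def inversion_cohort_summary(
    catalogues: Sequence[TumourCatalogue],
    config: ScreenConfig | None = None,
    known_groups: Sequence[str] | None = None,
    pooled_sets: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[InversionSummaryRow], dict[str, list[BalancedInversion]]]:
    """Screen every catalogue and summarize per group (plus pooled rows).

    ``pooled_sets`` maps a pooled-row label to the group labels it aggregates,
    e.g. ``{"radiation_naive": ["naive_breast", "naive_osteosarcoma"]}``.
    """
    config = config or ScreenConfig()
    if known_groups is not None:
        for cat in catalogues:
            if cat.group not in known_groups:
                raise ValidationError(
                    f"sample {cat.sample_id}: unknown group label {cat.group!r}"
                )
    per_sample: dict[str, list[BalancedInversion]] = {}
    per_group: dict[str, list[TumourCatalogue]] = {}
    for cat in catalogues:
        inversions, _ = screen_catalogue(cat.rearrangements, config)
        per_sample[cat.sample_id] = inversions
        per_group.setdefault(cat.group, []).append(cat)

    rows = []
    for group, cats in per_group.items():
        counts = [len(per_sample[c.sample_id]) for c in cats]
        rows.append(
            InversionSummaryRow(
                group=group,
                tumours_screened=len(cats),
                tumours_with_inversion=sum(c > 0 for c in counts),
                total_inversions=sum(counts),
            )
        )
    by_group = {r.group: r for r in rows}
    for label, groups in (pooled_sets or {}).items():
        members = [by_group[g] for g in groups if g in by_group]
        rows.append(pool_summary_rows(members, label=label))
    return rows, per_sample


def summary_rows_to_frame(rows: Sequence[InversionSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "tumours_screened": r.tumours_screened,
                "tumours_with_inversion": r.tumours_with_inversion,
                "total_inversions": r.total_inversions,
            }
            for r in rows
        ]
    )
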