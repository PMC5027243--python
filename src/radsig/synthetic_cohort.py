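"""Synthetic tumour cohorts with known ground truth.

The generator builds a mini-genome (default 3 chromosomes x 5 Mb), smooth
feature tracks standing in for replication timing and chromatin state, and
per-tumour variant catalogues carrying the statistical structure the analysis
stages look for:

* group-specific substitution burdens and indel:substitution ratios;
* deletion:insertion odds (radiation-like groups deletion-heavy);
* deletion size spectra (radiation-like groups enriched for >2-3 bp events);
* junction microhomology implanted by *sequence construction*: the k bases
  immediately 3' of a chosen deletion span are copied into the span start
  before the deletion is recorded, so the analysis module measures
  microhomology blind rather than reading a label;
* placement either uniform over callable bases or weighted by the timing
  track (``exp(beta * timing)``), emulating chromatin-coupled mutagenesis;
* clonal/subclonal VAF structure driven by a mutation-copy-number era model;
* rearrangement catalogues mixing reciprocal balanced-inversion junction
  pairs, unbalanced single inverted junctions, small low-read-support
  artefacts and inter-chromosomal noise.

Every stochastic choice flows from one seed; (params, seed) fully determine
all output files byte for byte. Machine-readable ground truth is emitted for
recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import catalogue_io
from .genome import InMemoryGenome, write_fasta
from .records import (
    CLONAL,
    INDEL_DELETION,
    INDEL_INSERTION,
    ORIENT_HEAD_HEAD,
    ORIENT_OTHER,
    ORIENT_TAIL_TAIL,
    SUBCLONAL,
    CallableRegions,
    FeatureTrack,
    IndelRecord,
    RearrangementCall,
    SubstitutionRecord,
    TumourCatalogue,
    ValidationError,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MIN_CHROM_LENGTH = 10_000


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class GenomeParams:
    n_chroms: int = 3
    chrom_length: int = 5_000_000
    gc: float = 0.41
    #: chrom -> list of (start, end) 1-based closed blocks excluded from callable
    masked_blocks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


@dataclass
class TrackParams:
    timing_period: int = 1_000_000
    timing_amplitude: float = 1.0
    tile: int = 1_000  # resolution of the emitted bedGraph intervals
    chromatin_block: int = 250_000
    chromatin_labels: tuple[str, ...] = ("A", "B", "C", "D")


@dataclass
class RearrangementParams:
    #: Poisson mean of balanced inversions per tumour
    balanced_mean: float = 4.33
    unbalanced_mean: float = 3.0
    artefact_mean: float = 8.0
    interchrom_mean: float = 3.0
    jitter_bp: int = 100
    breakpoint_width: int = 100
    min_size: int = 5_000
    max_size: int = 2_000_000
    #: balanced-event read support: 11 + Poisson(mean); always above the
    #: high-confidence threshold so implanted pairs are recoverable
    balanced_support_extra_mean: float = 6.0


@dataclass
class GroupParams:
    name: str
    n_samples: int
    #: per-genome substitution burden: lognormal with this median
    sub_burden_median: float = 4113.0
    sub_burden_sigma: float = 0.3
    indel_sub_ratio: float = 0.0554
    del_ins_odds: float = 1.0
    #: deletion sizes: mixture of a short geometric component and a heavier
    #: shifted-geometric tail, truncated to 1..100 bp
    del_size_tail_weight: float = 0.0
    del_size_geom_p: float = 0.5
    del_size_tail_geom_p: float = 0.08
    #: probability that a deletion gets microhomology implanted
    mh_prob: float = 0.1
    mh_len_geom_p: float = 0.5
    mh_len_max: int = 5
    placement: str = "uniform"  # or "feature_weighted"
    placement_beta: float = 1.0
    clonal_fraction_del: float = 0.5
    clonal_fraction_other: float = 0.5
    purity: float = 0.7
    vaf_concentration: float = 200.0
    subclonal_mcn: float = 0.4
    rearrangements: RearrangementParams = field(default_factory=RearrangementParams)


@dataclass
class SimParams:
    genome: GenomeParams = field(default_factory=GenomeParams)
    tracks: TrackParams = field(default_factory=TrackParams)
    groups: list[GroupParams] = field(default_factory=list)


def default_params() -> SimParams:
    """The default two-group cohort: 6 radiation-like vs 20 naive-like tumours.

    Group-level burdens mirror the exposed-cohort conditions (substitution
    median 4113, exposed indel:substitution ratio 429/4113, naive baseline
    ratio 0.0554 so the implied excess is ~201 indels per genome at the median
    burden, deletion:insertion odds 3:1 vs 1:1, balanced-inversion means
    52/12 vs 66/286) on a 3 x 5 Mb mini-genome.
    """
    radiation = GroupParams(
        name="radiation",
        n_samples=6,
        indel_sub_ratio=429.0 / 4113.0,
        del_ins_odds=3.0,
        del_size_tail_weight=0.65,
        mh_prob=0.5,
        placement="uniform",
        clonal_fraction_del=0.9,
        clonal_fraction_other=0.5,
        rearrangements=RearrangementParams(balanced_mean=52.0 / 12.0),
    )
    naive = GroupParams(
        name="naive_breast",
        n_samples=20,
        indel_sub_ratio=0.0554,
        del_ins_odds=1.0,
        del_size_tail_weight=0.0,
        mh_prob=0.1,
        placement="feature_weighted",
        placement_beta=1.0,
        clonal_fraction_del=0.5,
        clonal_fraction_other=0.5,
        rearrangements=RearrangementParams(balanced_mean=66.0 / 286.0),
    )
    return SimParams(groups=[radiation, naive])


# ---------------------------------------------------------------------------
# Reference and tracks
# ---------------------------------------------------------------------------

class _MutableGenome:
    """Draft genome as uint8 arrays, with per-base locks guarding implants."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = arrays
        self.locks = {c: np.zeros(len(a), dtype=bool) for c, a in arrays.items()}

    def locked(self, chrom: str, start: int, end: int) -> bool:
        return bool(self.locks[chrom][start - 1 : end].any())

    def lock(self, chrom: str, start: int, end: int) -> None:
        self.locks[chrom][start - 1 : end] = True

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.arrays[chrom][start - 1 : end].tobytes().decode("ascii")

    def implant(self, chrom: str, span_start: int, span_end: int, k: int) -> None:
        """Copy the k bases 3' of the span into the span start (mh >= k)."""
        arr = self.arrays[chrom]
        arr[span_start - 1 : span_start - 1 + k] = arr[span_end : span_end + k]

    def freeze(self) -> InMemoryGenome:
        return InMemoryGenome(
            {c: a.tobytes().decode("ascii") for c, a in self.arrays.items()}
        )


def _draft_reference(
    params: GenomeParams, rng: np.random.Generator
) -> tuple[_MutableGenome, CallableRegions]:
    if params.chrom_length < _MIN_CHROM_LENGTH:
        raise ValidationError(
            f"chromosome length must be >= {_MIN_CHROM_LENGTH} bp "
            f"(annotation windows undefined below that), got {params.chrom_length}"
        )
    gc = params.gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arrays: dict[str, np.ndarray] = {}
    callable_ivals: dict[str, list[tuple[int, int]]] = {}
    cum = np.cumsum(probs)
    for i in range(params.n_chroms):
        chrom = f"chr{i + 1}"
        codes = np.searchsorted(cum, rng.random(params.chrom_length), side="right")
        arrays[chrom] = _BASES[np.minimum(codes, 3)]
        ivals = [(1, params.chrom_length)]
        for mask_start, mask_end in sorted(params.masked_blocks.get(chrom, [])):
            new: list[tuple[int, int]] = []
            for s, e in ivals:
                if mask_end < s or mask_start > e:
                    new.append((s, e))
                    continue
                if s < mask_start:
                    new.append((s, mask_start - 1))
                if mask_end < e:
                    new.append((mask_end + 1, e))
            ivals = new
        callable_ivals[chrom] = ivals
    return _MutableGenome(arrays), CallableRegions(callable_ivals)


def generate_reference(
    params: GenomeParams, seed: int | np.random.Generator
) -> tuple[InMemoryGenome, CallableRegions]:
    """I.i.d.-base reference with configurable GC; deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draft, callable_regions = _draft_reference(params, rng)
    return draft.freeze(), callable_regions


def generate_tracks(
    reference: InMemoryGenome | _MutableGenome, params: TrackParams
) -> list[FeatureTrack]:
    """Deterministic stand-in tracks: sinusoid timing, thresholded binary
    peaks, alternating categorical chromatin blocks."""
    if isinstance(reference, _MutableGenome):
        lengths = {c: len(a) for c, a in reference.arrays.items()}
    else:
        lengths = reference.lengths
    timing: dict[str, list[tuple[int, int, float]]] = {}
    peaks: dict[str, list[tuple[int, int, int]]] = {}
    chromatin: dict[str, list[tuple[int, int, str]]] = {}
    labels = params.chromatin_labels
    for chrom, length in lengths.items():
        t_rows, p_rows = [], []
        for start in range(1, length + 1, params.tile):
            end = min(start + params.tile - 1, length)
            mid = (start + end) / 2.0
            value = params.timing_amplitude * np.sin(2 * np.pi * mid / params.timing_period)
            t_rows.append((start, end, float(value)))
            p_rows.append((start, end, int(value > 0)))
        timing[chrom] = t_rows
        peaks[chrom] = p_rows
        c_rows = []
        for j, start in enumerate(range(1, length + 1, params.chromatin_block)):
            end = min(start + params.chromatin_block - 1, length)
            c_rows.append((start, end, labels[j % len(labels)]))
        chromatin[chrom] = c_rows
    return [
        FeatureTrack("timing", "quantitative", timing, 0.0),
        FeatureTrack("in_peak", "binary", peaks, 0),
        FeatureTrack("chromatin", "categorical", chromatin, labels[0], labels=labels),
    ]


# ---------------------------------------------------------------------------
# Variant simulation
# ---------------------------------------------------------------------------

def _sample_positions(
    callable_regions: CallableRegions, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    flat, offsets = callable_regions.cumulative()
    draws = rng.integers(0, int(offsets[-1]), size=n)
    idx = np.searchsorted(offsets, draws, side="right") - 1
    chroms = np.array([flat[i][0] for i in idx], dtype=object)
    positions = np.array([flat[i][1] for i in idx], dtype=np.int64) + (draws - offsets[idx])
    return chroms, positions


def _sample_weighted_positions(
    callable_regions: CallableRegions,
    timing: FeatureTrack,
    beta: float,
    n: int,
    rng: np.random.Generator,
    max_weight: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample positions with weight exp(beta * timing)."""
    chroms_out: list[np.ndarray] = []
    pos_out: list[np.ndarray] = []
    got = 0
    while got < n:
        batch = max(2 * (n - got), 256)
        chroms, positions = _sample_positions(callable_regions, batch, rng)
        accept = np.zeros(batch, dtype=bool)
        u = rng.random(batch)
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            values, _ = timing.values_at(str(chrom), positions[sel])
            w = np.exp(beta * (values.astype(float) - max_weight))
            accept[sel] = u[sel] < w
        chroms_out.append(chroms[accept])
        pos_out.append(positions[accept])
        got += int(accept.sum())
    chroms = np.concatenate(chroms_out)[:n]
    positions = np.concatenate(pos_out)[:n]
    return chroms, positions


def _vaf_for_era(
    era: str, group: GroupParams, rng: np.random.Generator
) -> float:
    """Draw a VAF from the era model (diploid loci, purity-scaled).

    At total copy number 2 a fully clonal single-copy mutation sits at
    VAF = purity / 2; subclonal mutations at ``subclonal_mcn`` times that.
    """
    mcn = 1.0 if era == CLONAL else group.subclonal_mcn
    mean = min(max(mcn * group.purity / 2.0, 1e-3), 1 - 1e-3)
    conc = group.vaf_concentration
    vaf = rng.beta(mean * conc, (1 - mean) * conc)
    return float(round(min(max(vaf, 1e-4), 1.0), 4))


def _sample_del_length(group: GroupParams, rng: np.random.Generator) -> int:
    if rng.random() < group.del_size_tail_weight:
        length = 2 + rng.geometric(group.del_size_tail_geom_p)
    else:
        length = rng.geometric(group.del_size_geom_p)
    return int(min(length, 100))


def simulate_tumour(
    genome: _MutableGenome,
    callable_regions: CallableRegions,
    tracks: list[FeatureTrack],
    group: GroupParams,
    sample_id: str,
    rng: np.random.Generator,
) -> tuple[TumourCatalogue, dict]:
    """Simulate one tumour's substitutions, indels and rearrangements.

    Mutates the shared draft genome when implanting microhomology; implant
    and deletion windows are locked so later events cannot corrupt earlier
    records.
    """
    timing = next(t for t in tracks if t.name == "timing")
    warnings: list[str] = []
    placement = group.placement
    if placement == "feature_weighted":
        amp = max(
            (abs(v) for chrom in timing.chromosomes for _, _, v in timing.intervals(chrom)),
            default=0.0,
        )
        if amp == 0:
            warnings.append("timing track is flat; falling back to uniform placement")
            placement = "uniform"
    else:
        amp = 0.0

    def draw_positions(n: int) -> tuple[np.ndarray, np.ndarray]:
        if placement == "feature_weighted":
            return _sample_weighted_positions(
                callable_regions, timing, group.placement_beta, n, rng, amp
            )
        return _sample_positions(callable_regions, n, rng)

    # indel sites are consumed one at a time; draw them in batches
    pool: dict = {"chroms": None, "pos": None, "i": 0}

    def next_position() -> tuple[str, int]:
        if pool["chroms"] is None or pool["i"] >= len(pool["chroms"]):
            pool["chroms"], pool["pos"] = draw_positions(1024)
            pool["i"] = 0
        i = pool["i"]
        pool["i"] += 1
        return str(pool["chroms"][i]), int(pool["pos"][i])

    cat = TumourCatalogue(sample_id=sample_id, group=group.name, purity=group.purity)
    cat.copy_number = [
        (chrom, 1, len(arr), 2.0) for chrom, arr in genome.arrays.items()
    ]

    # --- substitutions -----------------------------------------------------
    n_subs = int(round(rng.lognormal(np.log(group.sub_burden_median), group.sub_burden_sigma)))
    chroms, positions = draw_positions(n_subs)
    alt_shift = rng.integers(1, 4, size=n_subs)  # ref code + shift mod 4 != ref
    sub_eras = np.where(
        rng.random(n_subs) < group.clonal_fraction_other, CLONAL, SUBCLONAL
    )
    base_to_code = {65: 0, 67: 1, 71: 2, 84: 3}
    code_to_base = "ACGT"
    for i in range(n_subs):
        chrom = str(chroms[i])
        pos = int(positions[i])
        ref = genome.fetch(chrom, pos, pos)
        alt = code_to_base[(base_to_code[ord(ref)] + int(alt_shift[i])) % 4]
        cat.substitutions.append(
            SubstitutionRecord(
                chrom=chrom,
                pos=pos,
                ref_base=ref,
                alt_base=alt,
                vaf=_vaf_for_era(str(sub_eras[i]), group, rng),
                sample_id=sample_id,
            )
        )

    # --- indels ------------------------------------------------------------
    n_indels = int(rng.poisson(group.indel_sub_ratio * n_subs))
    p_del = group.del_ins_odds / (1.0 + group.del_ins_odds)
    is_del = rng.random(n_indels) < p_del
    truth_deletions: list[dict] = []
    n_del = n_ins = 0
    for i in range(n_indels):
        if is_del[i]:
            rec, truth = _simulate_deletion(
                genome, callable_regions, group, sample_id, rng, next_position
            )
            cat.indels.append(rec)
            truth_deletions.append(truth)
            n_del += 1
        else:
            rec = _simulate_insertion(
                genome, callable_regions, group, sample_id, rng, next_position
            )
            cat.indels.append(rec)
            n_ins += 1

    # --- rearrangements ----------------------------------------------------
    lengths = {c: len(a) for c, a in genome.arrays.items()}
    calls, rearr_truth = simulate_rearrangements(
        group.rearrangements, lengths, sample_id, rng
    )
    cat.rearrangements = calls

    truth = {
        "sample_id": sample_id,
        "group": group.name,
        "placement": placement,
        "n_subs": n_subs,
        "n_del": n_del,
        "n_ins": n_ins,
        "deletions": truth_deletions,
        "warnings": warnings,
        **rearr_truth,
    }
    return cat, truth


def _simulate_deletion(
    genome: _MutableGenome,
    callable_regions: CallableRegions,
    group: GroupParams,
    sample_id: str,
    rng: np.random.Generator,
    next_position,
) -> tuple[IndelRecord, dict]:
    length = _sample_del_length(group, rng)
    implant = rng.random() < group.mh_prob
    k = 0
    if implant:
        k = int(min(rng.geometric(group.mh_len_geom_p), group.mh_len_max, length))
    for _ in range(200):
        chrom, anchor = next_position()
        span_start, span_end = anchor + 1, anchor + length
        guard_end = span_end + max(k, 1)
        if anchor < 2 or not callable_regions.span_inside(chrom, anchor, guard_end):
            continue
        if genome.locked(chrom, anchor, guard_end):
            continue
        if k > 0:
            genome.implant(chrom, span_start, span_end, k)
        genome.lock(chrom, anchor, guard_end)
        deleted_seq = genome.fetch(chrom, span_start, span_end)
        ref_allele = genome.fetch(chrom, anchor, span_end)
        era = CLONAL if rng.random() < group.clonal_fraction_del else SUBCLONAL
        rec = IndelRecord(
            chrom=chrom,
            pos=anchor,
            ref_allele=ref_allele,
            alt_allele=ref_allele[0],
            indel_class=INDEL_DELETION,
            length=length,
            deleted_seq=deleted_seq,
            vaf=_vaf_for_era(era, group, rng),
            sample_id=sample_id,
        )
        truth = {
            "chrom": chrom,
            "pos": anchor,
            "length": length,
            "mh_implant": k,
            "era": era,
        }
        return rec, truth
    raise RuntimeError(
        f"could not place a deletion of {length} bp for {sample_id}; "
        "callable space too fragmented or locked"
    )


def _simulate_insertion(
    genome: _MutableGenome,
    callable_regions: CallableRegions,
    group: GroupParams,
    sample_id: str,
    rng: np.random.Generator,
    next_position,
) -> IndelRecord:
    length = int(min(rng.geometric(0.5), 100))
    inserted = "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))
    while True:
        chrom, anchor = next_position()
        if callable_regions.contains(chrom, anchor):
            break
    ref = genome.fetch(chrom, anchor, anchor)
    era = CLONAL if rng.random() < group.clonal_fraction_other else SUBCLONAL
    return IndelRecord(
        chrom=chrom,
        pos=anchor,
        ref_allele=ref,
        alt_allele=ref + inserted,
        indel_class=INDEL_INSERTION,
        length=length,
        vaf=_vaf_for_era(era, group, rng),
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# Rearrangements
# ---------------------------------------------------------------------------

def _breakpoint_interval(center: int, width: int, chrom_len: int) -> tuple[int, int]:
    half = width // 2
    start = max(1, center - half)
    end = min(chrom_len, center + half)
    return start, end


def simulate_rearrangements(
    params: RearrangementParams,
    chrom_lengths: dict[str, int],
    sample_id: str,
    rng: np.random.Generator,
) -> tuple[list[RearrangementCall], dict]:
    """Emit balanced pairs, unbalanced inversions, artefacts and noise.

    Balanced events produce one head_head and one tail_tail junction with
    both breakpoints jittered by at most ``jitter_bp`` between the two calls
    and read support of at least 11, so every implanted pair survives the
    screen's high-confidence rule.
    """
    chroms = list(chrom_lengths)
    calls: list[RearrangementCall] = []
    balanced_pairs: list[tuple[str, str]] = []
    margin = 10_000

    def rand_size(chrom_len: int) -> int:
        hi = min(params.max_size, chrom_len - 2 * margin - 1)
        lo = min(params.min_size, hi)
        return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    n_balanced = int(rng.poisson(params.balanced_mean))
    for i in range(n_balanced):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = chrom_lengths[chrom]
        size = rand_size(clen)
        a = int(rng.integers(margin, clen - margin - size))
        b = a + size
        jit_a = int(rng.integers(-params.jitter_bp, params.jitter_bp + 1))
        jit_b = int(rng.integers(-params.jitter_bp, params.jitter_bp + 1))
        support = lambda: int(11 + rng.poisson(params.balanced_support_extra_mean))
        head_id = f"{sample_id}_bal{i}_hh"
        tail_id = f"{sample_id}_bal{i}_tt"
        calls.append(
            RearrangementCall(
                call_id=head_id,
                chrom_low=chrom,
                chrom_high=chrom,
                low_ival=_breakpoint_interval(a, params.breakpoint_width, clen),
                high_ival=_breakpoint_interval(b, params.breakpoint_width, clen),
                orient=ORIENT_HEAD_HEAD,
                read_support=support(),
                sample_id=sample_id,
            )
        )
        calls.append(
            RearrangementCall(
                call_id=tail_id,
                chrom_low=chrom,
                chrom_high=chrom,
                low_ival=_breakpoint_interval(a + jit_a, params.breakpoint_width, clen),
                high_ival=_breakpoint_interval(b + jit_b, params.breakpoint_width, clen),
                orient=ORIENT_TAIL_TAIL,
                read_support=support(),
                sample_id=sample_id,
            )
        )
        balanced_pairs.append((head_id, tail_id))

    n_unbalanced = int(rng.poisson(params.unbalanced_mean))
    for i in range(n_unbalanced):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = chrom_lengths[chrom]
        size = rand_size(clen)
        a = int(rng.integers(margin, clen - margin - size))
        calls.append(
            RearrangementCall(
                call_id=f"{sample_id}_unb{i}",
                chrom_low=chrom,
                chrom_high=chrom,
                low_ival=_breakpoint_interval(a, params.breakpoint_width, clen),
                high_ival=_breakpoint_interval(a + size, params.breakpoint_width, clen),
                orient=ORIENT_HEAD_HEAD if rng.random() < 0.5 else ORIENT_TAIL_TAIL,
                read_support=int(6 + rng.poisson(8)),
                sample_id=sample_id,
            )
        )

    n_artefact = int(rng.poisson(params.artefact_mean))
    for i in range(n_artefact):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = chrom_lengths[chrom]
        size = int(rng.integers(100, 2000))
        a = int(rng.integers(margin, clen - margin - size))
        calls.append(
            RearrangementCall(
                call_id=f"{sample_id}_art{i}",
                chrom_low=chrom,
                chrom_high=chrom,
                low_ival=_breakpoint_interval(a, params.breakpoint_width, clen),
                high_ival=_breakpoint_interval(a + size, params.breakpoint_width, clen),
                orient=ORIENT_HEAD_HEAD if rng.random() < 0.5 else ORIENT_TAIL_TAIL,
                read_support=int(rng.integers(1, 6)),
                sample_id=sample_id,
            )
        )

    n_inter = int(rng.poisson(params.interchrom_mean)) if len(chroms) > 1 else 0
    for i in range(n_inter):
        c1, c2 = rng.choice(len(chroms), size=2, replace=False)
        chrom1, chrom2 = chroms[int(c1)], chroms[int(c2)]
        a = int(rng.integers(margin, chrom_lengths[chrom1] - margin))
        b = int(rng.integers(margin, chrom_lengths[chrom2] - margin))
        calls.append(
            RearrangementCall(
                call_id=f"{sample_id}_tra{i}",
                chrom_low=chrom1,
                chrom_high=chrom2,
                low_ival=_breakpoint_interval(a, params.breakpoint_width, chrom_lengths[chrom1]),
                high_ival=_breakpoint_interval(b, params.breakpoint_width, chrom_lengths[chrom2]),
                orient=ORIENT_OTHER,
                read_support=int(6 + rng.poisson(8)),
                sample_id=sample_id,
            )
        )

    truth = {
        "balanced_pairs": balanced_pairs,
        "n_balanced": n_balanced,
        "n_unbalanced": n_unbalanced,
        "n_artefacts": n_artefact,
        "n_interchromosomal": n_inter,
    }
    if params.jitter_bp > 500:
        truth.setdefault("warnings", []).append(
            f"jitter {params.jitter_bp} bp exceeds the default screen slop budget (500 bp)"
        )
    return calls, truth


# ---------------------------------------------------------------------------
# Cohort orchestration
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    params: SimParams
    seed: int
    reference: InMemoryGenome
    callable_regions: CallableRegions
    tracks: list[FeatureTrack]
    catalogues: list[TumourCatalogue]
    ground_truth: dict


def simulate_cohort(params: SimParams | None = None, seed: int = 0) -> CohortSim:
    """Simulate the full cohort: reference, tracks, one catalogue per tumour."""
    params = params or default_params()
    if not params.groups:
        raise ValidationError("simulation needs at least one tumour group")
    master = np.random.SeedSequence(seed)
    ref_seed, *sample_seeds = master.spawn(
        1 + sum(g.n_samples for g in params.groups)
    )
    draft, callable_regions = _draft_reference(
        params.genome, np.random.default_rng(ref_seed)
    )
    tracks = generate_tracks(draft, params.tracks)

    catalogues: list[TumourCatalogue] = []
    truth: dict = {"seed": seed, "samples": {}}
    seed_iter = iter(sample_seeds)
    for group in params.groups:
        for j in range(group.n_samples):
            sample_id = f"{group.name}_{j:02d}"
            rng = np.random.default_rng(next(seed_iter))
            cat, sample_truth = simulate_tumour(
                draft, callable_regions, tracks, group, sample_id, rng
            )
            catalogues.append(cat)
            truth["samples"][sample_id] = sample_truth

    return CohortSim(
        params=params,
        seed=seed,
        reference=draft.freeze(),
        callable_regions=callable_regions,
        tracks=tracks,
        catalogues=catalogues,
        ground_truth=truth,
    )


def write_cohort(sim: CohortSim, outdir: str) -> dict[str, str]:
    """Write FASTA, BED/bedGraph tracks, per-sample VCF/BEDPE, manifest and
    ground truth; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    ref_path = os.path.join(outdir, "reference.fa")
    write_fasta(sim.reference, ref_path)
    paths["reference"] = ref_path

    callable_path = os.path.join(outdir, "callable.bed")
    catalogue_io.write_callable_bed(sim.callable_regions, callable_path)
    paths["callable"] = callable_path

    track_files = {}
    for track in sim.tracks:
        ext = "bedgraph" if track.kind == "quantitative" else "bed"
        tpath = os.path.join(outdir, f"{track.name}.{ext}")
        catalogue_io.write_track(track, tpath)
        paths[track.name] = tpath
        entry = {"name": track.name, "kind": track.kind, "path": os.path.basename(tpath)}
        if track.kind == "quantitative":
            entry["default"] = float(track.default_value)
        if track.kind == "categorical":
            entry["labels"] = list(track.labels)
            entry["default"] = track.default_value
        track_files[track.name] = entry
    tracks_yaml = os.path.join(outdir, "tracks.yaml")
    with open(tracks_yaml, "w") as fh:
        yaml.safe_dump(
            {"callable": "callable.bed", "tracks": list(track_files.values())},
            fh,
            sort_keys=False,
        )
    paths["tracks_config"] = tracks_yaml

    contigs = sim.reference.lengths
    manifest_rows = []
    for cat in sim.catalogues:
        sub_vcf = f"{cat.sample_id}.subs.vcf"
        indel_vcf = f"{cat.sample_id}.indels.vcf"
        bedpe = f"{cat.sample_id}.bedpe"
        catalogue_io.write_substitution_vcf(
            cat.substitutions, os.path.join(outdir, sub_vcf), contigs
        )
        catalogue_io.write_indel_vcf(
            cat.indels, os.path.join(outdir, indel_vcf), contigs
        )
        catalogue_io.write_rearrangement_bedpe(
            cat.rearrangements, os.path.join(outdir, bedpe)
        )
        manifest_rows.append(
            {
                "sample_id": cat.sample_id,
                "group": cat.group,
                "purity": cat.purity,
                "sub_vcf": sub_vcf,
                "indel_vcf": indel_vcf,
                "bedpe": bedpe,
            }
        )
    manifest_path = os.path.join(outdir, "manifest.tsv")
    catalogue_io.write_manifest(pd.DataFrame(manifest_rows), manifest_path)
    paths["manifest"] = manifest_path

    truth_path = os.path.join(outdir, "ground_truth.json")
    with open(truth_path, "w") as fh:
        json.dump(sim.ground_truth, fh, indent=1)
    paths["ground_truth"] = truth_path

    params_path = os.path.join(outdir, "params.yaml")
    with open(params_path, "w") as fh:
        yaml.safe_dump(params_to_dict(sim.params), fh, sort_keys=False)
    paths["params"] = params_path
    return paths


def params_to_dict(params: SimParams) -> dict:
    return dataclasses.asdict(params)


def params_from_dict(payload: dict) -> SimParams:
    genome = GenomeParams(**payload.get("genome", {}))
    tracks = TrackParams(**payload.get("tracks", {}))
    if isinstance(tracks.chromatin_labels, list):
        tracks.chromatin_labels = tuple(tracks.chromatin_labels)
    groups = []
    for g in payload.get("groups", []):
        g = dict(g)
        rearr = g.pop("rearrangements", {})
        groups.append(GroupParams(**g, rearrangements=RearrangementParams(**rearr)))
    return SimParams(genome=genome, tracks=tracks, groups=groups)


def simulate_long_count_table(
    group_means: dict[str, dict[str, float]],
    n_per_group: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson long count table for model calibration studies.

    ``group_means`` maps group -> {mutation_type -> mean count}. Used for
    null-calibration and power studies of the interaction model without
    simulating genomes.
    """
    rows = []
    for group, means in group_means.items():
        for j in range(n_per_group):
            sample_id = f"{group}_{j:03d}"
            for mtype, mean in means.items():
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "mutation_type": mtype,
                        "count": int(rng.poisson(mean)),
                    }
                )
    return pd.DataFrame(rows)
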