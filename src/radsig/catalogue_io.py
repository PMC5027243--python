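"""Readers and writers for the standard formats the pipeline touches.

Every reader normalizes to the package's internal convention: 1-based closed
coordinates, left-aligned deletions, explicit orientation labels. BED,
bedGraph and BEDPE are 0-based half-open on disk and are converted here, at
the boundary, only.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
import pysam
import yaml

from .genome import GenomeSequence
from .records import (
    INDEL_COMPLEX,
    INDEL_DELETION,
    INDEL_INSERTION,
    ORIENT_HEAD_HEAD,
    ORIENT_OTHER,
    ORIENT_TAIL_TAIL,
    UNKNOWN,
    CallableRegions,
    FeatureTrack,
    IndelRecord,
    ParseError,
    RearrangementCall,
    SubstitutionRecord,
    TumourCatalogue,
    ValidationError,
)

_STRAND_TO_ORIENT = {
    ("+", "+"): ORIENT_HEAD_HEAD,
    ("-", "-"): ORIENT_TAIL_TAIL,
}
_ORIENT_TO_STRANDS = {
    ORIENT_HEAD_HEAD: ("+", "+"),
    ORIENT_TAIL_TAIL: ("-", "-"),
    ORIENT_OTHER: ("+", "-"),
}

_VCF_HEADER_LINES = [
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">',
    '##INFO=<ID=MH,Number=1,Type=Integer,Description="Deletion junction microhomology length (bp)">',
    '##INFO=<ID=CLN,Number=1,Type=String,Description="Clonality class">',
    '##INFO=<ID=SID,Number=1,Type=String,Description="Sample identifier">',
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _open_vcf(path: str) -> pysam.VariantFile:
    try:
        return pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"could not parse VCF {path}: {exc}") from exc


def _classify_alleles(ref: str, alt: str) -> tuple[str, int]:
    """Classify a REF/ALT pair as deletion / insertion / complex with length."""
    if len(ref) > len(alt) and len(alt) == 1 and ref.startswith(alt):
        return INDEL_DELETION, len(ref) - 1
    if len(alt) > len(ref) and len(ref) == 1 and alt.startswith(ref):
        return INDEL_INSERTION, len(alt) - 1
    # complex: strip the shared prefix, count the larger remaining side
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    return INDEL_COMPLEX, max(len(ref), len(alt)) - k


def _left_align_deletion(
    chrom: str, pos: int, length: int, reference: GenomeSequence
) -> int:
    """Shift a deletion anchor left while the event is ambiguous.

    The deletion of span ``pos+1 .. pos+length`` can be shifted one base left
    whenever the base at the anchor equals the last base of the span.
    """
    while pos >= 1 and reference.fetch(chrom, pos, pos) == reference.fetch(
        chrom, pos + length, pos + length
    ):
        pos -= 1
    return pos


def read_indel_vcf(
    path: str,
    reference: GenomeSequence | None = None,
    sample_id: str | None = None,
) -> list[IndelRecord]:
    """Read Pindel-style anchor-base indel calls.

    Deletions are left-aligned against ``reference`` (when given) so that
    microhomology and size spectra do not depend on caller-specific placement,
    and ``deleted_seq`` is extracted from the reference. REF alleles are
    validated against the reference; mismatches raise :class:`ValidationError`
    naming the offending site.
    """
    records: list[IndelRecord] = []
    with _open_vcf(path) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(
                    f"{path}: record at {rec.chrom}:{rec.pos} lacks a single ALT allele"
                )
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            indel_class, length = _classify_alleles(ref, alt)
            pos = rec.pos
            deleted_seq = None
            if reference is not None:
                fetched = reference.fetch(rec.chrom, pos, pos + len(ref) - 1)
                if fetched != ref:
                    raise ValidationError(
                        f"{path}: REF {ref!r} at {rec.chrom}:{pos} does not match "
                        f"reference {fetched!r}"
                    )
                if indel_class == INDEL_DELETION:
                    pos = _left_align_deletion(rec.chrom, pos, length, reference)
                    deleted_seq = reference.fetch(rec.chrom, pos + 1, pos + length)
                    ref = reference.fetch(rec.chrom, pos, pos + length)
                    alt = ref[0]
            elif indel_class == INDEL_DELETION:
                deleted_seq = ref[1:]
            info = rec.info
            records.append(
                IndelRecord(
                    chrom=rec.chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    indel_class=indel_class,
                    length=length,
                    deleted_seq=deleted_seq,
                    vaf=round(float(info["VAF"]), 6) if "VAF" in info else None,
                    mh_len=int(info["MH"]) if "MH" in info else None,
                    clonality=str(info["CLN"]) if "CLN" in info else UNKNOWN,
                    sample_id=sample_id or (str(info["SID"]) if "SID" in info else ""),
                )
            )
    return records


def read_substitution_vcf(path: str, sample_id: str | None = None) -> list[SubstitutionRecord]:
    records: list[SubstitutionRecord] = []
    with _open_vcf(path) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(
                    f"{path}: record at {rec.chrom}:{rec.pos} lacks a single ALT allele"
                )
            info = rec.info
            records.append(
                SubstitutionRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_base=rec.ref.upper(),
                    alt_base=rec.alts[0].upper(),
                    vaf=round(float(info["VAF"]), 6) if "VAF" in info else None,
                    sample_id=sample_id or (str(info["SID"]) if "SID" in info else ""),
                )
            )
    return records


def _write_vcf_header(fh, contig_lengths: dict[str, int] | None) -> None:
    fh.write("##fileformat=VCFv4.2\n")
    for line in _VCF_HEADER_LINES:
        fh.write(line + "\n")
    for chrom, length in (contig_lengths or {}).items():
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
    fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")


def _info_string(pairs: list[tuple[str, object]]) -> str:
    parts = [f"{key}={val}" for key, val in pairs if val is not None and val != ""]
    return ";".join(parts) if parts else "."


def write_indel_vcf(
    records: Sequence[IndelRecord], path: str, contig_lengths: dict[str, int] | None = None
) -> None:
    with open(path, "w") as fh:
        _write_vcf_header(fh, contig_lengths)
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = _info_string(
                [
                    ("VAF", None if r.vaf is None else f"{r.vaf:.6g}"),
                    ("MH", r.mh_len),
                    ("CLN", None if r.clonality == UNKNOWN else r.clonality),
                    ("SID", r.sample_id),
                ]
            )
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t{info}\n"
            )


def write_substitution_vcf(
    records: Sequence[SubstitutionRecord],
    path: str,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_vcf_header(fh, contig_lengths)
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = _info_string(
                [("VAF", None if r.vaf is None else f"{r.vaf:.6g}"), ("SID", r.sample_id)]
            )
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref_base}\t{r.alt_base}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def read_rearrangement_bedpe(path: str, sample_id: str | None = None) -> list[RearrangementCall]:
    """Read a 10+-column BEDPE of rearrangement junctions.

    Column 8 carries read support, columns 9-10 the two strands. Strand pair
    (+,+) maps to head_head, (-,-) to tail_tail, anything mixed to other.
    0-based half-open intervals become 1-based closed.
    """
    calls: list[RearrangementCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(
                    f"{path}:{lineno}: BEDPE needs >= 10 columns, got {len(fields)}"
                )
            try:
                s1, e1 = int(fields[1]), int(fields[2])
                s2, e2 = int(fields[4]), int(fields[5])
                support = int(fields[7])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate field") from exc
            if min(s1, e1, s2, e2) < 0:
                raise ValidationError(f"{path}:{lineno}: negative coordinate")
            orient = _STRAND_TO_ORIENT.get((fields[8], fields[9]), ORIENT_OTHER)
            calls.append(
                RearrangementCall(
                    call_id=fields[6],
                    chrom_low=fields[0],
                    chrom_high=fields[3],
                    low_ival=(s1 + 1, e1),
                    high_ival=(s2 + 1, e2),
                    orient=orient,
                    read_support=support,
                    sample_id=sample_id or (fields[10] if len(fields) > 10 else ""),
                )
            )
    return calls


def write_rearrangement_bedpe(calls: Sequence[RearrangementCall], path: str) -> None:
    with open(path, "w") as fh:
        for c in calls:
            strands = _ORIENT_TO_STRANDS[c.orient]
            fh.write(
                "\t".join(
                    [
                        c.chrom_low,
                        str(c.low_ival[0] - 1),
                        str(c.low_ival[1]),
                        c.chrom_high,
                        str(c.high_ival[0] - 1),
                        str(c.high_ival[1]),
                        c.call_id,
                        str(c.read_support),
                        strands[0],
                        strands[1],
                        c.sample_id,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED / bedGraph tracks
# ---------------------------------------------------------------------------

def _iter_bed_lines(path: str):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_callable_bed(path: str) -> CallableRegions:
    intervals: dict[str, list[tuple[int, int]]] = {}
    for lineno, fields in _iter_bed_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start < 0:
            raise ValidationError(f"{path}:{lineno}: negative coordinate")
        intervals.setdefault(chrom, []).append((start + 1, end))
    return CallableRegions(intervals)


def read_gene_bed(path: str) -> dict[str, list[tuple[int, int, str]]]:
    """Gene intervals as {chrom: [(start, end, name)]}, 1-based closed."""
    genes: dict[str, list[tuple[int, int, str]]] = {}
    for lineno, fields in _iter_bed_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
        name = fields[3] if len(fields) > 3 else f"gene_{lineno}"
        genes.setdefault(fields[0], []).append((int(fields[1]) + 1, int(fields[2]), name))
    return genes


def read_bedgraph_track(path: str, name: str, default_value: float = 0.0) -> FeatureTrack:
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, fields in _iter_bed_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
        try:
            value = float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric bedGraph value") from exc
        intervals.setdefault(fields[0], []).append((int(fields[1]) + 1, int(fields[2]), value))
    return FeatureTrack(name, "quantitative", intervals, default_value)


def read_categorical_bed_track(
    path: str, name: str, labels: Sequence[str], default_value: str
) -> FeatureTrack:
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    for lineno, fields in _iter_bed_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: categorical BED needs a name column")
        intervals.setdefault(fields[0], []).append((int(fields[1]) + 1, int(fields[2]), fields[3]))
    return FeatureTrack(name, "categorical", intervals, default_value, labels=tuple(labels))


def read_binary_bed_track(path: str, name: str) -> FeatureTrack:
    """BED intervals mark value 1; everywhere else is 0."""
    intervals: dict[str, list[tuple[int, int, int]]] = {}
    for lineno, fields in _iter_bed_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
        intervals.setdefault(fields[0], []).append((int(fields[1]) + 1, int(fields[2]), 1))
    return FeatureTrack(name, "binary", intervals, 0)


def read_tracks_and_regions(config_path: str) -> tuple[CallableRegions, list[FeatureTrack]]:
    """Load callable regions and feature tracks from a YAML sidecar config.

    The config declares each track's kind explicitly; kinds are never guessed
    from file contents::

        callable: callable.bed
        tracks:
          - {name: timing, kind: quantitative, path: timing.bedgraph, default: 0.0}
          - {name: chromatin, kind: categorical, path: chromatin.bed,
             labels: [A, B], default: A}
          - {name: in_peak, kind: binary, path: peaks.bed}
    """
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(config_path))

    def _resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    callable_regions = read_callable_bed(_resolve(config["callable"]))
    tracks: list[FeatureTrack] = []
    for spec in config.get("tracks", []):
        kind = spec["kind"]
        path = _resolve(spec["path"])
        if kind == "quantitative":
            tracks.append(read_bedgraph_track(path, spec["name"], float(spec.get("default", 0.0))))
        elif kind == "categorical":
            tracks.append(
                read_categorical_bed_track(
                    path, spec["name"], spec["labels"], spec.get("default", spec["labels"][0])
                )
            )
        elif kind == "binary":
            tracks.append(read_binary_bed_track(path, spec["name"]))
        else:
            raise ValidationError(f"unknown track kind {kind!r} in {config_path}")
    return callable_regions, tracks


def write_callable_bed(regions: CallableRegions, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in regions.chromosomes:
            for s, e in regions.intervals(chrom):
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")


def write_track(track: FeatureTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            for s, e, v in track.intervals(chrom):
                if track.kind == "binary" and not v:
                    continue
                if track.kind == "quantitative":
                    fh.write(f"{chrom}\t{s - 1}\t{e}\t{v:.6g}\n")
                elif track.kind == "categorical":
                    fh.write(f"{chrom}\t{s - 1}\t{e}\t{v}\n")
                else:
                    fh.write(f"{chrom}\t{s - 1}\t{e}\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["sample_id", "group", "purity", "sub_vcf", "indel_vcf", "bedpe"]


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    missing = [c for c in ("sample_id", "group") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest lacks required columns {missing}")
    return df


def write_manifest(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_catalogue(
    row: pd.Series, reference: GenomeSequence | None = None, base_dir: str = "."
) -> TumourCatalogue:
    """Load one tumour's catalogues from a manifest row."""

    def _resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base_dir, p)

    def _has(col: str) -> bool:
        return col in row and isinstance(row[col], str) and row[col] != ""

    sample_id = str(row["sample_id"])
    purity = None
    if "purity" in row and pd.notna(row["purity"]):
        purity = float(row["purity"])
    cat = TumourCatalogue(sample_id=sample_id, group=str(row["group"]), purity=purity)
    if _has("sub_vcf"):
        path = _resolve(row["sub_vcf"])
        if not os.path.exists(path):
            raise FileNotFoundError(f"sample {sample_id}: substitution VCF missing: {path}")
        cat.substitutions = read_substitution_vcf(path, sample_id=sample_id)
    if _has("indel_vcf"):
        path = _resolve(row["indel_vcf"])
        if not os.path.exists(path):
            raise FileNotFoundError(f"sample {sample_id}: indel VCF missing: {path}")
        cat.indels = read_indel_vcf(path, reference=reference, sample_id=sample_id)
    if _has("bedpe"):
        path = _resolve(row["bedpe"])
        if not os.path.exists(path):
            raise FileNotFoundError(f"sample {sample_id}: BEDPE missing: {path}")
        cat.rearrangements = read_rearrangement_bedpe(path, sample_id=sample_id)
    return cat
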