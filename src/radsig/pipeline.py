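"""End-to-end orchestration: manifest in, report bundle out.

Each stage is auditable: structured logs record counts in/out of every
filter, and every numeric table in the report can be reproduced by calling
the corresponding module function with the recorded seed and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__, catalogue_io, clonality, cohort_stats, genome_distribution
from . import indel_signature, inversion_screen
from .genome import FastaGenome
from .records import INDEL_DELETION, TumourCatalogue

logger = logging.getLogger("radsig")


@dataclass
class GenomeDistSettings:
    n_background: int = 100_000
    window_bp: int = 100
    seed: int = 0


@dataclass
class RunConfig:
    manifest: str
    outdir: str
    reference: str | None = None
    tracks_config: str | None = None
    screen: inversion_screen.ScreenConfig = field(
        default_factory=inversion_screen.ScreenConfig
    )
    genome_dist: GenomeDistSettings = field(default_factory=GenomeDistSettings)
    clonal_threshold: float = clonality.DEFAULT_CLONAL_THRESHOLD
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def _resolve(p):
            if p is None:
                return None
            return p if os.path.isabs(p) else os.path.join(base, p)

        screen = inversion_screen.ScreenConfig(**payload.get("screen", {}))
        gd = GenomeDistSettings(**payload.get("genome_dist", {}))
        return cls(
            manifest=_resolve(payload["manifest"]),
            outdir=_resolve(payload.get("outdir", "radsig_out")),
            reference=_resolve(payload.get("reference")),
            tracks_config=_resolve(payload.get("tracks_config")),
            screen=screen,
            genome_dist=gd,
            clonal_threshold=float(
                payload.get("clonal_threshold", clonality.DEFAULT_CLONAL_THRESHOLD)
            ),
            log_level=payload.get("log_level", "INFO"),
        )

    def validate(self) -> None:
        for name, path in (
            ("manifest", self.manifest),
            ("reference", self.reference),
            ("tracks_config", self.tracks_config),
        ):
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"config path {name} does not exist: {path}")

    def provenance(self) -> dict:
        payload = {
            "version": __version__,
            "screen": vars(self.screen),
            "genome_dist": vars(self.genome_dist),
            "clonal_threshold": self.clonal_threshold,
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {**payload, "config_hash": digest}


def _load_catalogues(config: RunConfig, reference) -> list[TumourCatalogue]:
    manifest = catalogue_io.read_manifest(config.manifest)
    base_dir = os.path.dirname(os.path.abspath(config.manifest))
    return [
        catalogue_io.load_catalogue(row, reference=reference, base_dir=base_dir)
        for _, row in manifest.iterrows()
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage whose inputs are present; returns the report dict.

    The report is also written to ``<outdir>/report.json`` together with
    per-stage TSVs. A stage failure is recorded and does not destroy the
    outputs of other stages.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"provenance": config.provenance(), "stages": {}}

    reference = FastaGenome(config.reference) if config.reference else None
    catalogues = _load_catalogues(config, reference)
    logger.info("loaded %d catalogues from %s", len(catalogues), config.manifest)

    def _stage(name, fn):
        try:
            fn()
            report["stages"][name] = "completed"
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.exception("stage %s failed", name)
            report["stages"][name] = f"failed: {exc}"

    # --- inversion screen --------------------------------------------------
    def stage_screen():
        rows, per_sample = inversion_screen.inversion_cohort_summary(
            catalogues, config.screen
        )
        inv_rows = []
        for sample_id, inversions in per_sample.items():
            n_calls = len(next(c for c in catalogues if c.sample_id == sample_id).rearrangements)
            logger.info(
                "screen %s: %d calls in, %d balanced inversions out",
                sample_id, n_calls, len(inversions),
            )
            for inv in inversions:
                inv_rows.append(
                    {
                        "sample_id": sample_id,
                        "chrom": inv.chrom,
                        "head_call_id": inv.head_call_id,
                        "tail_call_id": inv.tail_call_id,
                        "size": inv.size,
                    }
                )
        pd.DataFrame(
            inv_rows,
            columns=["sample_id", "chrom", "head_call_id", "tail_call_id", "size"],
        ).to_csv(os.path.join(config.outdir, "balanced_inversions.tsv"), sep="\t", index=False)
        summary = inversion_screen.summary_rows_to_frame(rows)
        summary.to_csv(
            os.path.join(config.outdir, "inversion_summary.tsv"), sep="\t", index=False
        )
        report["inversion_summary"] = summary.to_dict(orient="records")
        report["inversions_per_sample"] = {s: len(v) for s, v in per_sample.items()}

    _stage("inversion_screen", stage_screen)

    # --- indel metrics -----------------------------------------------------
    def stage_indels():
        if reference is not None:
            for cat in catalogues:
                indel_signature.annotate_microhomology(reference, cat.indels)
        burdens = indel_signature.burden_frame(catalogues)
        burdens.to_csv(os.path.join(config.outdir, "burdens.tsv"), sep="\t", index=False)
        spectra = {}
        mh_rows = []
        for group, cats in _by_group(catalogues).items():
            lengths = [
                r.length
                for cat in cats
                for r in cat.indels
                if r.indel_class == INDEL_DELETION
            ]
            if lengths:
                spectra[group] = indel_signature.size_spectrum(lengths, normalize=True)
            for cat in cats:
                for r in cat.indels:
                    if r.indel_class == INDEL_DELETION and r.mh_len is not None:
                        mh_rows.append(
                            {"group": group, "sample_id": cat.sample_id,
                             "length": r.length, "mh_len": r.mh_len}
                        )
        if spectra:
            pd.DataFrame(spectra).to_csv(
                os.path.join(config.outdir, "deletion_size_spectra.tsv"), sep="\t"
            )
        pd.DataFrame(mh_rows, columns=["group", "sample_id", "length", "mh_len"]).to_csv(
            os.path.join(config.outdir, "deletion_microhomology.tsv"), sep="\t", index=False
        )
        report["burdens"] = burdens.to_dict(orient="records")

    _stage("indel_metrics", stage_indels)

    # --- genome distribution ----------------------------------------------
    def stage_genome_dist():
        if reference is None or config.tracks_config is None:
            raise FileNotFoundError("genome distribution needs reference and tracks_config")
        callable_regions, tracks = catalogue_io.read_tracks_and_regions(config.tracks_config)
        gd = config.genome_dist
        background = genome_distribution.sample_background(
            callable_regions, gd.n_background, gd.seed
        )
        bg_ann = genome_distribution.annotate_positions(
            background, reference, tracks, gd.window_bp
        )
        kinds = {"gc": "quantitative", "complexity": "quantitative"}
        for t in tracks:
            kinds[t.name] = t.kind
        tables = []
        for group, cats in _by_group(catalogues).items():
            positions = pd.DataFrame(
                [
                    {"chrom": r.chrom, "pos": r.pos}
                    for cat in cats
                    for r in cat.indels
                    if r.indel_class == INDEL_DELETION
                ]
            )
            if positions.empty:
                logger.info("genome-dist: group %s has no deletions; skipped", group)
                continue
            var_ann = genome_distribution.annotate_positions(
                positions, reference, tracks, gd.window_bp
            )
            table = genome_distribution.feature_battery(var_ann, bg_ann, kinds)
            table.insert(0, "group", group)
            tables.append(table)
        result = pd.concat(tables, ignore_index=True)
        result.to_csv(
            os.path.join(config.outdir, "feature_tests.tsv"), sep="\t", index=False
        )
        report["feature_tests"] = result.to_dict(orient="records")

    _stage("genome_distribution", stage_genome_dist)

    # --- clonality ---------------------------------------------------------
    def stage_clonality():
        frames = []
        contrasts = {}
        for cat in catalogues:
            frames.append(clonality.call_clonality(cat, config.clonal_threshold))
            contrast = clonality.clonal_deletion_contrast(cat)
            contrasts[cat.sample_id] = {
                "table": contrast.table.to_dict(),
                "odds_ratio": contrast.odds_ratio,
                "p_value": contrast.p_value,
                "computable": contrast.computable,
            }
        pd.concat(frames, ignore_index=True).to_csv(
            os.path.join(config.outdir, "clonality.tsv"), sep="\t", index=False
        )
        report["clonal_deletion_contrasts"] = contrasts

    _stage("clonality", stage_clonality)

    # --- cohort report -----------------------------------------------------
    def stage_report():
        inv_counts = report.get("inversions_per_sample")
        report["cohort"] = cohort_stats.cohort_report(catalogues, inv_counts)
        groups = {cat.group for cat in catalogues}
        if len(groups) >= 2:
            table = cohort_stats.build_long_count_table(catalogues)
            sizes = table.groupby("group")["sample_id"].nunique()
            if (sizes >= 3).all():
                model = cohort_stats.mixed_interaction_model(table)
                report["interaction_model"] = {
                    "terms": model.terms.to_dict(orient="records"),
                    "joint_wald_chi2": model.joint_wald_chi2,
                    "joint_p": model.joint_p,
                    "reference_group": model.reference_group,
                }
            if inv_counts:
                labels = [cat.group for cat in catalogues]
                counts = [inv_counts.get(cat.sample_id, 0) for cat in catalogues]
                glm = cohort_stats.count_glm(counts, labels)
                report["inversion_glm"] = {
                    "coefficients": glm.coefficients.to_dict(orient="records"),
                    "dispersion": glm.dispersion,
                    "overdispersed": glm.overdispersed,
                    "family": glm.family,
                }

    _stage("cohort_report", stage_report)

    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    return report


def _by_group(catalogues) -> dict[str, list[TumourCatalogue]]:
    groups: dict[str, list[TumourCatalogue]] = {}
    for cat in catalogues:
        groups.setdefault(cat.group, []).append(cat)
    return groups


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
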