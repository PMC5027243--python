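"""Signature-recovery metrics on a simulated cohort.

Runs the full analysis battery on one synthetic cohort and reports whether
each implanted radiation signature is recovered: the deletion x group burden
interaction, the clonal-deletion enrichment, the absence (uniform placement)
versus presence (feature-weighted placement) of mutation-density /
genomic-feature associations, and the balanced-inversion enrichment.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import clonality, cohort_stats, genome_distribution as gd
from . import indel_signature, inversion_screen
from .records import INDEL_DELETION
from .synthetic_cohort import CohortSim

DEFAULT_FEATURE_KINDS = {
    "gc": "quantitative",
    "complexity": "quantitative",
    "timing": "quantitative",
    "in_peak": "binary",
    "chromatin": "categorical",
}


def deletion_positions(catalogues, group: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": r.chrom, "pos": r.pos}
            for cat in catalogues
            if cat.group == group
            for r in cat.indels
            if r.indel_class == INDEL_DELETION
        ]
    )


def cohort_recovery_metrics(
    sim: CohortSim,
    exposed_group: str = "radiation",
    naive_group: str = "naive_breast",
    n_background: int = 5_000,
    background_seed: int = 0,
    screen_config: inversion_screen.ScreenConfig | None = None,
) -> dict:
    """Compute every recovery statistic for one simulated cohort."""
    screen_config = screen_config or inversion_screen.ScreenConfig()
    catalogues = sim.catalogues
    metrics: dict = {}

    # --- balanced-inversion screen vs implanted truth ---------------------
    per_sample: dict[str, int] = {}
    n_truth = n_found = n_recovered = 0
    for cat in catalogues:
        inversions, _ = inversion_screen.screen_catalogue(cat.rearrangements, screen_config)
        per_sample[cat.sample_id] = len(inversions)
        truth_pairs = {
            frozenset(p)
            for p in sim.ground_truth["samples"][cat.sample_id]["balanced_pairs"]
        }
        found = {frozenset((i.head_call_id, i.tail_call_id)) for i in inversions}
        n_truth += len(truth_pairs)
        n_found += len(found)
        n_recovered += len(found & truth_pairs)
    metrics["inversions"] = {
        "implanted": n_truth,
        "detected": n_found,
        "recovered": n_recovered,
        "recall": n_recovered / n_truth if n_truth else None,
    }

    # --- burden interaction model -----------------------------------------
    table = cohort_stats.build_long_count_table(catalogues)
    model = cohort_stats.mixed_interaction_model(table, reference_group=naive_group)
    term = model.term_for("deletion", exposed_group)
    metrics["interaction"] = {
        "deletion_group_coef": float(term["coef"]),
        "deletion_group_p": float(term["p"]),
        "joint_p": model.joint_p,
    }

    # --- inversion count GLM ----------------------------------------------
    glm = cohort_stats.count_glm(
        [per_sample[c.sample_id] for c in catalogues],
        [c.group for c in catalogues],
        reference_group=naive_group,
    )
    gterm = glm.group_term(exposed_group)
    metrics["inversion_glm"] = {
        "log_rate_ratio": float(gterm["coef"]),
        "p": float(gterm["p"]),
        "overdispersed": glm.overdispersed,
    }

    # --- genomic-feature associations per group ---------------------------
    background = gd.sample_background(sim.callable_regions, n_background, background_seed)
    bg_ann = gd.annotate_positions(background, sim.reference, sim.tracks)
    metrics["features"] = {}
    for group in (exposed_group, naive_group):
        positions = deletion_positions(catalogues, group)
        ann = gd.annotate_positions(positions, sim.reference, sim.tracks)
        battery = gd.feature_battery(ann, bg_ann, DEFAULT_FEATURE_KINDS)
        metrics["features"][group] = {
            "n_significant": int(battery["significant"].sum()),
            "significant": battery.loc[battery["significant"], "feature"].tolist(),
            "n_deletions": int(len(positions)),
        }

    # --- clonal-deletion contrast in the exposed group --------------------
    exposed_indels = []
    for cat in catalogues:
        if cat.group != exposed_group:
            continue
        clonality.call_clonality(cat)
        exposed_indels.extend(cat.indels)
    contrast = clonality.clonal_deletion_contrast(exposed_indels)
    metrics["clonal_contrast"] = {
        "p": contrast.p_value,
        "odds_ratio": contrast.odds_ratio,
        "computable": contrast.computable,
    }

    # --- excess indel burden ----------------------------------------------
    est = indel_signature.excess_indel_estimate(
        [c for c in catalogues if c.group == exposed_group],
        [c for c in catalogues if c.group == naive_group],
    )
    metrics["excess_indels"] = {
        "median": est.median_excess,
        "sd": est.sd_excess,
        "baseline_ratio": est.baseline_ratio,
    }
    return metrics


def recovery_flags(metrics: dict, alpha: float = 0.01) -> dict[str, bool]:
    """Boolean recovery verdicts used by the replicate studies."""
    exposed, naive = list(metrics["features"])[:2]
    return {
        "deletion_interaction": metrics["interaction"]["deletion_group_p"] < alpha
        and metrics["interaction"]["deletion_group_coef"] > 0,
        "clonal_enrichment": bool(
            metrics["clonal_contrast"]["computable"]
            and metrics["clonal_contrast"]["p"] < alpha
            and metrics["clonal_contrast"]["odds_ratio"] > 1
        ),
        "uniform_no_features": metrics["features"][exposed]["n_significant"] == 0,
        "correlated_has_features": metrics["features"][naive]["n_significant"] >= 1,
        "inversion_enrichment": metrics["inversion_glm"]["log_rate_ratio"] > 0
        and metrics["inversion_glm"]["p"] < alpha,
        "all_implanted_inversions_recovered": metrics["inversions"]["recall"] in (None, 1.0),
    }
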