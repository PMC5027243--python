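"""Cohort-level models: mutation-type x group interactions and count GLMs.

The central question — does one tumour group carry proportionally more
deletions (or indels) than another, over and above per-sample burden
differences? — is asked with a mixed model: log(count + 1) of each mutation
type per sample, fixed effects for mutation type, tumour group and their
interaction, and a per-sample random intercept absorbing total burden.
Inversion (or deletion) count enrichment between groups uses a log-link count
GLM with an explicit overdispersion diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .indel_signature import burden_frame
from .records import TumourCatalogue, ValidationError

MUTATION_TYPES = ("substitution", "deletion", "insertion")


def build_long_count_table(catalogues: Sequence[TumourCatalogue]) -> pd.DataFrame:
    """One row per (sample, mutation type): sample_id, group, mutation_type, count."""
    burdens = burden_frame(catalogues)
    rows = []
    for _, b in burdens.iterrows():
        for mtype, count in (
            ("substitution", b["n_subs"]),
            ("deletion", b["n_del"]),
            ("insertion", b["n_ins"]),
        ):
            rows.append(
                {
                    "sample_id": b["sample_id"],
                    "group": b["group"],
                    "mutation_type": mtype,
                    "count": int(count),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class InteractionModelResult:
    """Mutation-type x group interaction estimates from the mixed model."""

    terms: pd.DataFrame  # term, coef, se, p (interaction block only)
    joint_wald_chi2: float
    joint_wald_df: int
    joint_p: float
    denominator_df: int
    reference_group: str
    reference_type: str
    fit: object = field(repr=False, default=None)

    def term_for(self, mutation_type: str, group: str) -> pd.Series:
        mask = self.terms["term"].str.contains(
            f"[T.{mutation_type}]", regex=False
        ) & self.terms["term"].str.contains(f"[T.{group}]", regex=False)
        matches = self.terms[mask]
        if len(matches) != 1:
            raise KeyError(f"no unique interaction term for {mutation_type} x {group}")
        return matches.iloc[0]


def mixed_interaction_model(
    table: pd.DataFrame,
    reference_group: str | None = None,
    reference_type: str = "substitution",
) -> InteractionModelResult:
    """Fit log(count+1) ~ type * group with a per-sample random intercept.

    Returns the interaction-term estimates (coefficient, standard error, Wald
    p per term) and a joint Wald test over the whole interaction block. Wald
    statistics are referred to t/F distributions with the between-within
    denominator df of the balanced split-plot layout,
    ``(n_samples - n_groups) * (n_types - 1)``, rather than to their
    asymptotic normal/chi-square limits: with tens of samples the asymptotic
    reference is anti-conservative. Raises on singular designs: a mutation type entirely absent from a group
    (named in the error), fewer than 2 groups/types, or fewer than 3 samples
    per group.
    """
    required = {"sample_id", "group", "mutation_type", "count"}
    if not required.issubset(table.columns):
        raise ValidationError(f"long count table needs columns {sorted(required)}")
    groups = sorted(table["group"].unique())
    types = sorted(table["mutation_type"].unique())
    if len(groups) < 2 or len(types) < 2:
        raise ValidationError("need >= 2 tumour groups and >= 2 mutation types")
    sizes = table.groupby("group")["sample_id"].nunique()
    if (sizes < 3).any():
        small = sizes[sizes < 3].index.tolist()
        raise ValidationError(
            f"random intercept inestimable: groups {small} have < 3 samples"
        )
    cell_totals = table.groupby(["group", "mutation_type"])["count"].sum()
    for (g, t), total in cell_totals.items():
        if total == 0:
            raise ValidationError(
                f"singular design: mutation type {t!r} entirely absent from group {g!r}"
            )
    reference_group = reference_group or groups[0]

    df = table.copy()
    df["log_count"] = np.log(df["count"] + 1.0)
    formula = (
        f"log_count ~ C(mutation_type, Treatment('{reference_type}'))"
        f" * C(group, Treatment('{reference_group}'))"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["sample_id"])
        fit = model.fit(reml=True)

    names = list(fit.fe_params.index)
    inter_idx = [i for i, n in enumerate(names) if ":" in n]
    if not inter_idx:
        raise ValidationError("model has no interaction terms")
    terms = pd.DataFrame(
        {
            "term": [names[i] for i in inter_idx],
            "coef": [float(fit.fe_params.iloc[i]) for i in inter_idx],
            "se": [float(fit.bse_fe.iloc[i]) for i in inter_idx],
        }
    )
    n_samples = df["sample_id"].nunique()
    ddf = (n_samples - len(groups)) * (len(types) - 1)
    terms["p"] = 2 * stats.t.sf(np.abs(terms["coef"] / terms["se"]), ddf)

    beta = fit.fe_params.iloc[inter_idx].to_numpy()
    cov = fit.cov_params().iloc[inter_idx, inter_idx].to_numpy()
    chi2 = float(beta @ np.linalg.solve(cov, beta))
    dof = len(inter_idx)
    joint_p = float(stats.f.sf(chi2 / dof, dof, ddf))
    return InteractionModelResult(
        terms=terms,
        joint_wald_chi2=chi2,
        joint_wald_df=dof,
        joint_p=joint_p,
        denominator_df=ddf,
        reference_group=reference_group,
        reference_type=reference_type,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# Count GLM
# ---------------------------------------------------------------------------

@dataclass
class CountGlmResult:
    coefficients: pd.DataFrame  # term, coef (log rate ratio), se, p
    dispersion: float
    overdispersed: bool
    family: str
    reference_group: str

    def group_term(self, group: str) -> pd.Series:
        mask = self.coefficients["term"].str.contains(f"[T.{group}]", regex=False)
        matches = self.coefficients[mask]
        if len(matches) != 1:
            raise KeyError(f"no unique coefficient for group {group!r}")
        return matches.iloc[0]


def count_glm(
    counts: Sequence[int],
    groups: Sequence[str],
    reference_group: str | None = None,
    overdispersion_threshold: float = 2.0,
) -> CountGlmResult:
    """Log-link count regression of per-sample counts on tumour group.

    Fits a Poisson GLM; the group coefficient is the log rate ratio versus
    the reference group (equal to the log of the group-mean ratio at the
    Poisson MLE). When the Pearson dispersion exceeds the threshold the
    standard errors are rescaled quasi-Poisson style and the result flagged
    overdispersed.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if len(counts) != len(groups):
        raise ValidationError("counts and group labels differ in length")
    if counts.sum() == 0:
        raise ValidationError("all counts are zero; rate ratios undefined")
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups")
    reference_group = reference_group or labels[0]
    df = pd.DataFrame({"count": counts, "group": groups})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(
            f"count ~ C(group, Treatment('{reference_group}'))",
            df,
            family=sm.families.Poisson(),
        )
        fit = model.fit()
        dispersion = float(fit.pearson_chi2 / fit.df_resid) if fit.df_resid > 0 else np.nan
        overdispersed = bool(np.isfinite(dispersion) and dispersion > overdispersion_threshold)
        family = "poisson"
        if overdispersed:
            fit = model.fit(scale="X2")  # quasi-Poisson variance inflation
            family = "quasi-poisson"
    coefs = pd.DataFrame(
        {
            "term": list(fit.params.index),
            "coef": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return CountGlmResult(
        coefficients=coefs,
        dispersion=dispersion,
        overdispersed=overdispersed,
        family=family,
        reference_group=reference_group,
    )


# ---------------------------------------------------------------------------
# Headline cohort report
# ---------------------------------------------------------------------------

def cohort_report(
    catalogues: Sequence[TumourCatalogue],
    inversion_counts: Mapping[str, int] | None = None,
) -> dict:
    """Per-group medians/ranges of burdens plus optional inversion counts.

    Rearrangement breakpoints are counted as two per junction call. The
    output is a plain dict, JSON-serializable, with one entry per group.
    """
    burdens = burden_frame(catalogues)
    breakpoints = {
        cat.sample_id: 2 * len(cat.rearrangements) for cat in catalogues
    }
    report: dict = {"groups": {}, "n_samples": len(catalogues)}
    for group, sub in burdens.groupby("group"):
        n_indels = (sub["n_del"] + sub["n_ins"] + sub["n_complex"]).to_numpy()
        bp = np.array([breakpoints[s] for s in sub["sample_id"]])
        entry = {
            "n_samples": int(len(sub)),
            "substitutions": _median_range(sub["n_subs"].to_numpy()),
            "indels": _median_range(n_indels),
            "rearrangement_breakpoints": _median_range(bp),
        }
        if inversion_counts is not None:
            inv = np.array([inversion_counts.get(s, 0) for s in sub["sample_id"]])
            entry["balanced_inversions"] = {
                "total": int(inv.sum()),
                "tumours_with_inversion": int((inv > 0).sum()),
            }
        report["groups"][group] = entry
    return report


def _median_range(values: np.ndarray) -> dict:
    if len(values) == 0:
        return {"median": None, "min": None, "max": None}
    return {
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
    }
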