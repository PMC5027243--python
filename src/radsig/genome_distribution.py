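"""Association of mutation density with genomic features.

The procedure: annotate every variant position and a large uniform background
sample from the callable genome with the same set of genomic properties
(replication-timing-like tracks, GC content, sequence complexity, chromatin
state, ...), test each property for a variant-vs-background difference with a
test matched to its kind, adjust the raw p-values with Benjamini–Yekutieli
(valid under arbitrary dependence between properties), and call a property
significantly associated only when the adjusted q-value is below 0.01 AND the
group difference is at least 5% in magnitude.

A mutational process that reaches DNA independently of chromatin context —
ionizing radiation being the motivating case — leaves no significant
associations; replication- or chromatin-coupled processes do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .genome import GenomeSequence
from .records import CallableRegions, FeatureTrack, ValidationError

QUANTITATIVE = "quantitative"
BINARY = "binary"
CATEGORICAL = "categorical"


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

def sample_background(
    callable_regions: CallableRegions,
    n: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw ``n`` positions uniformly (with replacement) from callable bases.

    Returns a DataFrame with ``chrom`` and ``pos`` columns; deterministic for
    a fixed seed.
    """
    if n <= 0:
        raise ValidationError(f"background sample size must be positive, got {n}")
    flat, offsets = callable_regions.cumulative()
    total = int(offsets[-1])
    if total == 0:
        raise ValidationError("callable regions are empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.integers(0, total, size=n)
    idx = np.searchsorted(offsets, draws, side="right") - 1
    chroms = np.array([flat[i][0] for i in idx], dtype=object)
    starts = np.array([flat[i][1] for i in idx], dtype=np.int64)
    positions = starts + (draws - offsets[idx])
    return pd.DataFrame({"chrom": chroms, "pos": positions})


# ---------------------------------------------------------------------------
# Position annotation
# ---------------------------------------------------------------------------

def _window_bounds(pos: np.ndarray, half: int, chrom_len: int) -> tuple[np.ndarray, np.ndarray]:
    lo = np.maximum(pos - half, 1)
    hi = np.minimum(pos + half, chrom_len)
    return lo, hi


def annotate_positions(
    positions: pd.DataFrame,
    reference: GenomeSequence,
    tracks: Sequence[FeatureTrack] = (),
    window_bp: int = 100,
) -> pd.DataFrame:
    """Annotate positions with GC, sequence complexity and track values.

    * ``gc``: fraction of G/C in a window of ``+-window_bp/2`` around the
      position (windows truncated at chromosome ends are used as-is and
      flagged in ``window_truncated``);
    * ``complexity``: Shannon entropy of overlapping 3-mers in the same
      window, normalized to [0, 1] by the 6-bit maximum over all 64 3-mers;
    * one column per track, queried at the position itself, plus a
      ``<name>_covered`` flag column (uncovered positions carry the track's
      declared default value).
    """
    half = window_bp // 2
    out = positions.reset_index(drop=True).copy()
    n = len(out)
    gc = np.full(n, np.nan)
    complexity = np.full(n, np.nan)
    truncated = np.zeros(n, dtype=bool)
    track_values: dict[str, np.ndarray] = {}
    track_covered: dict[str, np.ndarray] = {}
    for tr in tracks:
        track_values[tr.name] = np.full(n, tr.default_value)
        track_covered[tr.name] = np.zeros(n, dtype=bool)

    lengths = reference.lengths
    for chrom, group in out.groupby("chrom", sort=False):
        pos = group["pos"].to_numpy(dtype=np.int64)
        rows = group.index.to_numpy()
        chrom_len = lengths[chrom]
        if np.any(pos < 1) or np.any(pos > chrom_len):
            bad = pos[(pos < 1) | (pos > chrom_len)][0]
            raise IndexError(f"position {chrom}:{bad} outside reference")
        codes = reference.base_codes(chrom)
        is_gc = ((codes == 1) | (codes == 2)).astype(np.int64)
        gc_prefix = np.concatenate([[0], np.cumsum(is_gc)])
        lo, hi = _window_bounds(pos, half, chrom_len)
        width = hi - lo + 1
        gc[rows] = (gc_prefix[hi] - gc_prefix[lo - 1]) / width
        truncated[rows] = width < (2 * half + 1)

        # 3-mer codes for the whole chromosome, then per-window entropy
        if chrom_len >= 3:
            kmers = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
        else:
            kmers = np.empty(0, dtype=codes.dtype)
        for row, a, b in zip(rows, lo, hi):
            window_kmers = kmers[a - 1 : b - 2]  # 3-mers fully inside [a, b]
            if len(window_kmers) == 0:
                complexity[row] = 0.0
                continue
            counts = np.bincount(window_kmers, minlength=64)
            p = counts[counts > 0] / len(window_kmers)
            complexity[row] = float(-(p * np.log2(p)).sum() / 6.0)

        for tr in tracks:
            vals, covered = tr.values_at(chrom, pos)
            track_values[tr.name][rows] = vals
            track_covered[tr.name][rows] = covered

    out["gc"] = gc
    out["complexity"] = complexity
    out["window_truncated"] = truncated
    for tr in tracks:
        out[tr.name] = track_values[tr.name]
        out[f"{tr.name}_covered"] = track_covered[tr.name]
    return out


# ---------------------------------------------------------------------------
# Test battery
# ---------------------------------------------------------------------------

@dataclass
class FeatureTestResult:
    feature: str
    kind: str
    statistic: float
    raw_p: float
    group_summary: dict[str, Any] = field(default_factory=dict)
    degenerate: bool = False
    q_value: float | None = None
    magnitude_diff: float | None = None
    significant: bool | None = None


def compare_feature(
    variant_values: Sequence[Any],
    background_values: Sequence[Any],
    kind: str,
    feature: str = "",
) -> FeatureTestResult:
    """Raw-p stage of the battery: one two-sided test matched to the kind.

    binary -> pooled two-proportion z-test; quantitative -> Welch t-test
    (large-sample normal theory); categorical -> chi-square on the label
    contingency table.
    """
    if len(variant_values) == 0 or len(background_values) == 0:
        raise ValidationError(f"feature {feature!r}: both samples must be non-empty")
    if kind == BINARY:
        a = np.asarray(variant_values, dtype=float)
        b = np.asarray(background_values, dtype=float)
        counts = np.array([a.sum(), b.sum()])
        nobs = np.array([len(a), len(b)])
        p1, p2 = counts / nobs
        if p1 == p2:
            stat, p = 0.0, 1.0
        else:
            stat, p = proportions_ztest(counts, nobs)
        return FeatureTestResult(
            feature, kind, float(stat), float(p),
            group_summary={"mean_variant": float(p1), "mean_background": float(p2)},
        )
    if kind == QUANTITATIVE:
        a = np.asarray(variant_values, dtype=float)
        b = np.asarray(background_values, dtype=float)
        if np.array_equal(a, b) or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
        return FeatureTestResult(
            feature, kind, float(stat), float(p),
            group_summary={"mean_variant": float(a.mean()), "mean_background": float(b.mean())},
        )
    if kind == CATEGORICAL:
        labels = sorted(set(variant_values) | set(background_values))
        va = pd.Series(list(variant_values)).value_counts()
        vb = pd.Series(list(background_values)).value_counts()
        table = np.array(
            [[va.get(l, 0) for l in labels], [vb.get(l, 0) for l in labels]], dtype=float
        )
        dist_a = {l: va.get(l, 0) / len(variant_values) for l in labels}
        dist_b = {l: vb.get(l, 0) / len(background_values) for l in labels}
        summary = {"dist_variant": dist_a, "dist_background": dist_b, "labels": labels}
        if len(labels) < 2:
            return FeatureTestResult(
                feature, kind, 0.0, 1.0, group_summary=summary, degenerate=True
            )
        # drop all-zero columns (labels absent from both groups cannot occur here)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return FeatureTestResult(feature, kind, float(chi2), float(p), group_summary=summary)
    raise ValidationError(f"unknown feature kind {kind!r}")


def adjust_benjamini_yekutieli(raw_ps: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli step-up q-values (FDR under arbitrary dependence)."""
    ps = np.asarray(raw_ps, dtype=float)
    if len(ps) == 0:
        return ps
    if np.any((ps < 0) | (ps > 1)) or np.any(np.isnan(ps)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(ps, method="fdr_by")[1]


def _magnitude(result: FeatureTestResult, mode: str) -> float:
    """Difference-in-magnitude between the two group summaries.

    For quantitative/binary features the relative difference of means
    |m1 - m2| / max(|m1|, |m2|) (0 when both are 0); ``mode='absolute'``
    uses |m1 - m2| instead. Categorical features use the total-variation
    distance between label distributions under either mode.
    """
    if result.kind == CATEGORICAL:
        da = result.group_summary["dist_variant"]
        db = result.group_summary["dist_background"]
        labels = result.group_summary["labels"]
        return 0.5 * sum(abs(da[l] - db[l]) for l in labels)
    m1 = result.group_summary["mean_variant"]
    m2 = result.group_summary["mean_background"]
    if mode == "absolute":
        return abs(m1 - m2)
    denom = max(abs(m1), abs(m2))
    if denom == 0:
        return 0.0
    return abs(m1 - m2) / denom


def flag_significant(
    results: Sequence[FeatureTestResult],
    q_threshold: float = 0.01,
    magnitude_threshold: float = 0.05,
    magnitude_mode: str = "relative",
) -> list[FeatureTestResult]:
    """Apply the dual rule: q < 0.01 AND magnitude difference >= 5%."""
    if not results:
        return []
    qs = adjust_benjamini_yekutieli([r.raw_p for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
        r.magnitude_diff = _magnitude(r, magnitude_mode)
        r.significant = (r.q_value < q_threshold) and (
            r.magnitude_diff >= magnitude_threshold
        )
    return list(results)


def feature_battery(
    variant_annotations: pd.DataFrame,
    background_annotations: pd.DataFrame,
    feature_kinds: Mapping[str, str],
    q_threshold: float = 0.01,
    magnitude_threshold: float = 0.05,
    magnitude_mode: str = "relative",
) -> pd.DataFrame:
    """Run the full battery over annotated positions and flag significance."""
    results = [
        compare_feature(
            variant_annotations[name].to_numpy(),
            background_annotations[name].to_numpy(),
            kind,
            feature=name,
        )
        for name, kind in feature_kinds.items()
    ]
    flag_significant(results, q_threshold, magnitude_threshold, magnitude_mode)
    rows = []
    for r in results:
        rows.append(
            {
                "feature": r.feature,
                "kind": r.kind,
                "statistic": r.statistic,
                "raw_p": r.raw_p,
                "q_value": r.q_value,
                "magnitude_diff": r.magnitude_diff,
                "significant": r.significant,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Density ratios and the indel-probability profile
# ---------------------------------------------------------------------------

def density_ratio(
    variant_values: Sequence[float],
    background_values: Sequence[float],
    bins: Sequence[float],
) -> pd.DataFrame:
    """Per-bin ratio of variant density over background density.

    ``ratio_b = (fraction of variants in bin b) / (fraction of background in
    bin b)``; bins with zero background are flagged undefined (NaN ratio).
    """
    a = np.asarray(variant_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    if len(a) == 0:
        raise ValidationError("variant sample is empty")
    if len(b) == 0:
        raise ValidationError("background sample is empty")
    edges = np.asarray(bins, dtype=float)
    ca, _ = np.histogram(a, bins=edges)
    cb, _ = np.histogram(b, bins=edges)
    fa = ca / ca.sum() if ca.sum() else np.zeros_like(ca, dtype=float)
    fb = cb / cb.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fb > 0, fa / np.where(fb > 0, fb, 1.0), np.nan)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "n_variant": ca,
            "n_background": cb,
            "ratio": ratio,
            "defined": cb > 0,
        }
    )


@dataclass
class ProfileFit:
    features: list[str]
    coefficients: np.ndarray
    intercept: float
    penalized_fallback: bool


def indel_probability_profile(
    variant_annotations: pd.DataFrame,
    background_annotations: pd.DataFrame,
    genome_bins: pd.DataFrame,
    features: Sequence[str],
) -> tuple[pd.Series, ProfileFit]:
    """Model relative indel probability across the genome (Fig-1d-style).

    A logistic variant-vs-background contrast is fitted on standardized
    feature annotations; the fitted linear score is evaluated on each genome
    bin's mean features and mapped through the logistic function to a
    relative probability profile normalized to sum to 1 over bins.

    On perfect separation (or non-convergence) the fit falls back to an
    L2-penalized logistic regression and is flagged.
    """
    features = list(features)
    Xa = variant_annotations[features].to_numpy(dtype=float)
    Xb = background_annotations[features].to_numpy(dtype=float)
    X = np.vstack([Xa, Xb])
    y = np.concatenate([np.ones(len(Xa)), np.zeros(len(Xb))])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    import statsmodels.api as sm

    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(y, sm.add_constant(Xs, has_constant="add"))
            fit = model.fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True) or np.any(
                ~np.isfinite(fit.params)
            ):
                raise ValueError("logistic fit did not converge")
            intercept = float(fit.params[0])
            coefs = np.asarray(fit.params[1:], dtype=float)
        except Exception:
            from sklearn.linear_model import LogisticRegression

            fallback = True
            lr = LogisticRegression(C=1.0, max_iter=1000)
            lr.fit(Xs, y)
            intercept = float(lr.intercept_[0])
            coefs = lr.coef_[0].astype(float)

    Zb = (genome_bins[features].to_numpy(dtype=float) - mu) / sd
    score = intercept + Zb @ coefs
    prob = 1.0 / (1.0 + np.exp(-score))
    if prob.sum() == 0:
        profile = np.full(len(prob), 1.0 / len(prob))
    else:
        profile = prob / prob.sum()
    return (
        pd.Series(profile, index=genome_bins.index, name="relative_probability"),
        ProfileFit(features, coefs, intercept, fallback),
    )


def genome_bin_features(
    reference: GenomeSequence,
    tracks: Sequence[FeatureTrack],
    bin_width: int,
    window_bp: int = 100,
    points_per_bin: int = 5,
) -> pd.DataFrame:
    """Mean quantitative/binary feature values per fixed-width genome bin.

    Each bin is summarized by annotating ``points_per_bin`` regularly spaced
    positions inside it and averaging. Categorical tracks are skipped (the
    logistic profile uses numeric features).
    """
    numeric_tracks = [t for t in tracks if t.kind in (QUANTITATIVE, BINARY)]
    rows = []
    meta = []
    for chrom, length in reference.lengths.items():
        for start in range(1, length + 1, bin_width):
            end = min(start + bin_width - 1, length)
            pts = np.linspace(start, end, points_per_bin).astype(np.int64)
            ann = annotate_positions(
                pd.DataFrame({"chrom": chrom, "pos": pts}),
                reference,
                numeric_tracks,
                window_bp=window_bp,
            )
            row = {"gc": ann["gc"].mean(), "complexity": ann["complexity"].mean()}
            for t in numeric_tracks:
                row[t.name] = ann[t.name].astype(float).mean()
            rows.append(row)
            meta.append((chrom, start, end))
    index = pd.MultiIndex.from_tuples(meta, names=["chrom", "bin_start", "bin_end"])
    return pd.DataFrame(rows, index=index)
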