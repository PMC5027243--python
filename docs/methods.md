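# Methods

## Scope and model

`radsig` detects two chromatin-independent mutational imprints of ionizing
radiation in somatic variant catalogues: a genome-wide excess of small
(1–100 bp) deletions with junction microhomology and no correlation with
genomic features, and an excess of balanced inversions. The package operates
downstream of variant calling: its inputs are per-tumour substitution and
indel VCFs, rearrangement BEDPEs with read-support annotation, a reference
FASTA, callable-region BEDs and feature tracks. Read alignment, variant
calling, copy-number segmentation and substitution-signature factorization
are out of scope.

All internal coordinates are 1-based closed (VCF convention); BED, bedGraph
and BEDPE are converted at the I/O boundary only. Deletions are left-aligned
against the reference at read time so that size spectra and microhomology do
not depend on caller-specific placement.

## Balanced-inversion screen

A balanced inversion leaves one head-to-head and one tail-to-tail junction
whose breakpoint ranges overlap at both ends. The screen has two stages:

1. **Artefact filter.** Keep an intrachromosomal inverted junction with read
   support r and midpoint span s iff (r > 5 and s > 2500 bp) or r > 10. All
   inequalities are strict, reading "greater than five/ten reads" literally.
   Small inverted artefacts (low support, short span) are removed without
   losing small high-confidence inversions.
2. **Reciprocal pairing.** Candidate pairs are head/tail calls on the same
   chromosome whose low intervals overlap and whose high intervals overlap.
   Point breakpoints (start == end) are padded by `slop_bp` (default 500 bp)
   before the overlap test, since "overlapping ranges" presupposes nonzero
   ranges. Candidates are consumed greedily in order of summed midpoint
   distance, ties broken lexicographically on call ids, so the pairing is
   deterministic and independent of input order; each call joins at most one
   inversion. Tests verify greedy never exceeds exhaustive maximum matching
   and equals it on conflict-free candidate graphs.

Inversion size is reported as the mean of the two junction midpoint spans
(the distance between the averaged outer breakpoint midpoints); no formula is
canonical, and the mean is symmetric in the two junctions. No nesting
constraint is imposed between the head and tail junction coordinates.

## Indel metrics

Junction microhomology of a deletion with deleted sequence D (length L),
span s..e: the right value is the longest k ≤ L with `D[:k]` equal to the k
reference bases 3' of e; the left value the longest k with `D[-k:]` equal to
the k bases 5' of s; the reported value is the maximum, in 0..L. The cap at
L makes tandem-repeat deletions well defined. Microhomology is invariant
under left-alignment because the junction sequence is.

Burdens report deletion/insertion/complex counts; complex indels are excluded
from the deletion:insertion ratio (the contrast of interest is deletions vs
insertions) but kept in totals. The excess indel burden of an exposed genome
is n_indels − r0·n_subs with r0 the median indel:substitution ratio of the
naive group — a transparent median-baseline estimator; the mixed model below
provides the model-based route to the same contrast.

## Mutation density vs genomic features

Variant positions and n background positions drawn uniformly (with
replacement — collisions are immaterial at genome scale and the sampler stays
O(n)) from the callable regions are annotated identically: GC fraction and
3-mer Shannon entropy (normalized by the 6-bit maximum) in a 100-bp window
centred on the position, plus direct track queries with declared defaults for
uncovered positions. The 100-bp window dwarfs indel lengths while staying
local; windows truncated at chromosome ends are used as-is and flagged.

Per feature, variants vs background are compared with a pooled two-proportion
z-test (binary), Welch t-test (quantitative) or χ² contingency test
(categorical); two-sided p-values receive Benjamini–Yekutieli adjustment
(valid under the arbitrary dependence expected between genomic properties).
A feature is significantly associated iff q < 0.01 **and** the magnitude
difference is ≥ 5%. The magnitude rule is interpreted as *relative*
difference |m1−m2|/max(|m1|,|m2|) (proportion scale for binary features,
total-variation distance for categorical ones), which is scale-free across
heterogeneous features; an absolute mode is available. Note the relative rule
is vacuous for features whose means sit near zero, where significance is
carried by the q-threshold alone.

The relative indel-probability profile across the genome fits a logistic
variant-vs-background contrast on standardized numeric features, evaluates
the linear score on per-bin mean features and normalizes the logistic
probabilities to sum to 1 over bins. Perfect separation (or non-convergence)
falls back to an L2-penalized logistic fit and is flagged.

## Clonality

Mutation copy number m = f·(ρ·CN_t + CN_n·(1−ρ))/ρ from VAF f, purity ρ,
local tumour copy number CN_t and normal copy number CN_n = 2. Classification
is a fixed threshold: clonal iff m ≥ 0.75 (boundary inclusive), subclonal
below; any missing ingredient yields "unknown" rather than a guess. The
threshold replaces mixture-model peak finding: the contrast of interest only
needs a clonal/subclonal split, and 0.75 separates a clonal peak at ~1 from
subclonal peaks under the generator's VAF model. VAFs are taken as given
(split-read corrected upstream where applicable). The deletion-vs-other ×
clonal-vs-subclonal table is tested with a two-sided Fisher exact test
implemented by hypergeometric enumeration (summing all tables no more likely
than the observed one, with scipy's relative tolerance on the boundary).

## Cohort models

**Burden interaction.** log(N + 1) of each mutation-type count per sample is
modelled with fixed effects type, group and type×group and a per-sample
random intercept absorbing total burden (statsmodels MixedLM, REML). The log
response stabilizes the 10²–10⁴ count range; the response choice is
documented and swappable. Wald statistics are referred to t/F distributions
with the between-within denominator df of the balanced split-plot layout,
(n_samples − n_groups)(n_types − 1): with tens of samples the asymptotic
normal/χ² reference is measurably anti-conservative (~7–9% at nominal 5% in
null simulations), while the df-corrected reference sits near nominal. Both
per-term tests and a joint F over the interaction block are reported; the
headline "deletion signature" test is the deletion×group term.

**Count enrichment.** Per-sample balanced-inversion (or deletion) counts are
regressed on group with a Poisson log-link GLM; the group coefficient is the
log rate ratio (equal to the log group-mean ratio at the MLE, which the tests
verify to 1e-8). A Pearson dispersion > 2 triggers quasi-Poisson rescaling of
the standard errors and an overdispersion flag, preventing silent
anti-conservatism.

## Synthetic cohorts

The generator emulates the study conditions on a mini-genome small enough for
seconds-scale runs: 3 chromosomes × 5 Mb of i.i.d. bases (GC 0.41), a
sinusoidal replication-timing stand-in (period 1 Mb), its thresholded binary
"peak" track, and alternating 250-kb categorical chromatin blocks. Group
defaults are the exposed-cohort conditions: substitution burden lognormal
with median 4113 (σ = 0.3, spanning ≈1500–9300), exposed indel:substitution
ratio 429/4113 ≈ 0.104 vs naive 0.0554 (so the implied excess is ~201 indels
per genome at the median burden), deletion:insertion odds 3:1 vs 1:1,
exposed deletion sizes drawn from a mixture with a heavier 2–100 bp tail
(65% weight on 2 + Geometric(0.08), truncated at 100) vs naive
Geometric(0.5), microhomology implant probability 0.5 vs 0.1, uniform vs
timing-weighted (∝ exp(β·timing), β = 1, by rejection sampling) placement,
exposed deletions 90% clonal vs 50% everywhere else, purity 0.7, and
balanced-inversion Poisson means 52/12 vs 66/286 per tumour. The default
cohort is 6 exposed vs 20 naive tumours.

Key constructions:

* **Microhomology is implanted by sequence construction**: the k bases
  immediately 3' of the chosen span are copied into the span start in the
  draft reference *before* the deletion is recorded, guaranteeing mh ≥ k
  while the analysis module measures it blind from the final reference.
  Implant and deletion windows are locked so later events cannot corrupt
  earlier records.
* **VAF era model**: clonal mutations target mutation copy number 1 (VAF
  mean ρ/2 at CN 2), subclonal target 0.4, both Beta-distributed with
  concentration 200; flat CN-2 segments and the purity are emitted so the
  clonality module can classify blind.
* **Rearrangement noise**: balanced events emit reciprocal head/tail pairs
  with breakpoints jittered ≤ 100 bp and support ≥ 11 (always recoverable by
  the screen); unbalanced events emit single inverted junctions; artefacts
  emit short (< 2 kb) junctions with support ≤ 5; inter-chromosomal calls
  exercise orientation filtering.

(params, seed) determine every output byte; ground truth (counts, implanted
pairs, per-deletion implant length and era, placement mode) is emitted as
JSON.

What the generator does **not** emulate: real repeat structure and
mutational hotspots, genuine replication-timing or chromatin maps, copy
number heterogeneity, caller-specific error modes beyond the simple artefact
class. Passing recovery tests therefore demonstrates that the statistical
machinery recovers the modelled contrasts at realistic sizes — not that the
pipeline is robust to every failure mode of real sequencing data.

## Problem sizes and numerical choices

Recovery and calibration studies run on the default cohort with 20 seeded
replicates and 5000 background positions (the background:variant ratio on
the 15-Mb mini-genome matches the intent of 100 000 positions on hg19);
null calibration of the interaction test uses 500 Poisson count-table
replicates at 10 samples/group, and the feature-null study redraws variants
and background on one fixed reference per replicate. Determinism: all
randomness flows from numpy `SeedSequence` spawns of one master seed.
Degenerate inputs are explicit: empty samples, single-label categorical
comparisons (p = 1, flagged), zero-background ratio bins (NaN, flagged),
zero-insertion ratios (undefined marker), missing clonality ingredients
("unknown"), all-zero count GLMs and singular mixed-model designs (errors
naming the offending cell).

## Known limitations

* The inversion size definition (mean junction span) is one of several
  defensible conventions; sizes are comparable within this package only.
* The between-within df correction is exact for the balanced layout; heavily
  unbalanced cohorts would warrant Satterthwaite/Kenward–Roger df, which
  statsmodels does not provide.
* The excess-indel estimator ignores substitution-burden error in the
  baseline ratio; its spread across samples is reported alongside.
* The feature battery treats positions as independent; clustered mutations
  would inflate significance for strongly autocorrelated tracks.
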