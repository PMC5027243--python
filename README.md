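# radsig

Analysis toolkit for the genomic imprints that therapeutic ionizing radiation
leaves in the somatic variant catalogues of second malignancies. Radiation
deposits energy in DNA independently of chromatin context, and its
double-strand breaks are repaired by microhomology-mediated / non-homologous
end-joining. Two tumour-type-independent signatures follow:

1. **an excess of small deletions** (1–100 bp), distributed uniformly across
   the genome — uncorrelated with replication timing, GC content, sequence
   complexity or chromatin state — and frequently carrying junction
   microhomology; and
2. **an excess of balanced inversions**: reciprocal head-to-head plus
   tail-to-tail rearrangement junction pairs with no copy-number change.

The package implements the whole detection pipeline — catalogue I/O, the
balanced-inversion screen, indel/microhomology metrics, the mutation-density
vs genomic-feature battery, clonal/subclonal timing, and cohort-level models —
plus a ground-truthed synthetic-cohort generator, so every stage is
exercisable without controlled-access sequencing data.

## Core statistics

* **Balanced-inversion screen.** Intrachromosomal inverted junctions are kept
  when read support r and span s satisfy (r > 5 and s > 2500 bp) or r > 10;
  surviving head-to-head and tail-to-tail calls whose breakpoint ranges
  overlap at both ends are paired greedily by summed midpoint distance.
* **Burden interaction.** For per-sample counts N_ij of mutation type
  j ∈ {substitution, deletion, insertion}, the mixed model
  log(N_ij + 1) = type_j + group_g(i) + (type×group)_jg(i) + u_i + ε_ij
  with random intercept u_i tests whether deletions are disproportionately
  enriched in the exposed group (Wald t/F with between-within df).
* **Microhomology.** For a deletion of sequence D (length L), mh = max over
  flanks of the longest k ≤ L with D's end identical to the k reference bases
  immediately beyond the junction.
* **Feature battery.** Each genomic property is compared between variant
  positions and uniform background positions (two-proportion z, Welch t, or
  χ² by kind); Benjamini–Yekutieli q-values; a property is associated only if
  q < 0.01 *and* the group difference is ≥ 5% in magnitude.
* **Timing.** Mutation copy number m = f(ρ·CN_t + 2(1−ρ))/ρ from VAF f,
  purity ρ and local copy number; clonal ⇔ m ≥ 0.75; deletion-vs-other ×
  clonal-vs-subclonal contrast by Fisher's exact test.
* **Inversion enrichment.** Poisson GLM (log link) of per-tumour balanced
  inversion counts on group, with an overdispersion diagnostic.

## Worked example

The numbered drivers under `analysis/` run the full story on the default
synthetic cohort (6 radiation-like vs 20 naive-like tumours, 3 × 5 Mb
mini-genome, seed 1) and write tables under `results/`:

```bash
python analysis/02_screen_inversions.py
python analysis/04_genome_distribution.py
python analysis/06_cohort_models.py
```

prints, among other lines:

```
       group  tumours_screened  tumours_with_inversion  total_inversions
   radiation                 6                       6                19
naive_breast                20                       1                 1
implanted 20 balanced inversions, screen detected 20, recovered 20 (100% recall)

radiation: 2139 deletions, 0 significant feature associations (none); profile CV 0.024
naive_breast: 2293 deletions, 3 significant feature associations (timing, in_peak, chromatin); profile CV 0.422

  deletion x radiation: coef 1.014 (rate ratio ~ 2.76), p = 2.62e-26
  log rate ratio 4.15, p = 5.27e-05 (dispersion 1.09, family poisson)
```

Reading: the screen recovers every implanted reciprocal inversion pair while
rejecting the implanted artefacts; uniformly placed (radiation-like)
deletions show **zero** significant feature associations and an essentially
flat probability profile, whereas the chromatin-coupled naive deletions light
up the implanted tracks; the mixed model recovers the implanted ~3× deletion
enrichment; and the inversion GLM recovers the exposed group's higher
inversion rate. `analysis/03_indel_spectra.py` and `analysis/05_clonality.py`
add the size-spectrum/microhomology contrasts and the clonal-timing contrast.

The same stages are available as a CLI over on-disk VCF/BEDPE/BED/bedGraph
inputs (`radsig simulate|screen-inversions|indel-metrics|genome-dist|clonality|cohort-report|run-all`).

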