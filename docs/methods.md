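# Methods

## The assay being modeled

A promiscuous biotin ligase retained in the ER lumen of one genetically
defined cell type biotinylates secretory-pathway clients as they transit
the ER; streptavidin enrichment and multiplexed TMT quantification then
yield, per protein and channel, a reporter-ion intensity. Channels come
in two genotypes: Cre+ (ligase expressed) and Cre− (matched background).
Everything downstream rests on one contrast — a protein genuinely labeled
by the ligase is enriched in Cre+ channels, while endogenously
biotinylated proteins and bead-binding contaminants are not.

The pipeline starts at protein-level quant tables; peptide-spectrum
matching, protein inference and isotope-impurity correction are upstream
of its scope, as are the signal-peptide and unconventional-secretion
predictors themselves (their calls are consumed as annotation columns).

## Generative model of the synthetic data

For protein *i* in channel *c*:

```
E[intensity] = base_i · 2^(enrich_i · [c is Cre+]) · 2^(effect_{i, cond(c)})
observed     = E[intensity] · LogNormal(0, σ),   σ = sqrt(ln(1 + CV²))
```

then entries are masked missing, by default completely at random
(an intensity-dependent option masks low-abundance entries preferentially
at the same mean rate). The log-normal noise has median 1, so the
expected observed log-ratio equals the planted one — this is what makes
parameter-recovery tests exact rather than approximate.

Protein classes partition the proteome deterministically (floor for
secretory, then background, remainder nonspecific):

- **secretory** — enrich_i ~ Normal(3, 0.8) log₂ units; the only class
  eligible for condition effects;
- **background** — endogenously biotinylated; enrich = 0, normal
  abundance; annotated mitochondrial in the derived catalog;
- **nonspecific** — bead floor; enrich = 0, base abundance scaled by
  0.05; annotated cytosolic/nuclear.

Defaults mirror the scale and shape of a real 16-plex tissue experiment:
2,400 proteins (≈ the number identified in an adipose run), 60%
secretory (so the passing fraction lands near the ≈ 63% observed in
practice), base abundances LogNormal(ln 10⁵, 2.3) giving a several-order
dynamic range, three conditions (basal 3+/3−, LPS 3+/2−, fasted 3+/2− =
16 channels), 20% of secretory proteins with a per-condition effect of
|log₂| ~ Normal(1.5, 0.5) and random sign, CV = 0.2, 5% missingness.
Replicate-level variance components are not reported for the real assay,
so the noise defaults are chosen for testability, not fitted. A TMT
ratio-compression knob (shrinkage on planted log₂ effects, default 1.0 =
off) exists because compression is a known isobaric artifact that should
be an explicit assumption, not a hidden one.

What the generator deliberately does **not** emulate: correlated noise
across proteins (co-isolation), batch structure across plexes,
peptide-level aggregation, and annotation errors (the derived catalog is
consistent with the planted classes). Passing tests therefore demonstrate
the pipeline's statistical machinery is correct and calibrated under its
stated model — not that real data meet that model.

## Enrichment filter

Per plex (cutoffs are experiment-specific, never pooled):

1. **Normalization** — `median_center` (default): each channel's log₂
   intensities shifted so channel medians coincide at their grand mean;
   `total_sum` and `none` are alternatives. Missing entries are never
   imputed.
2. **Ratios** — a protein is retained if quantified in ≥ 50% of channels
   within *each* genotype group (default; single-channel artifacts
   otherwise dominate). Ratio = log₂(mean Cre+ / mean Cre−) with both
   means floored at ε = half the smallest positive observed intensity.
   Flooring both means (not only the Cre− mean) keeps a zero Cre+ mean
   finite as well; ε is data-scaled rather than a fixed constant.
3. **Truth sets** — true positives: cellular-component terms
   intersecting {endoplasmic reticulum, Golgi apparatus, extracellular
   region, plasma membrane, lysosome} *or* a predicted signal peptide;
   false positives: non-empty terms disjoint from that list and contained
   in {cytosol, nucleus, mitochondrion}. Secretory membership takes
   precedence for dual-localized proteins — an ER-lumenal ligase labels
   them legitimately. Both vocabularies are arguments, not constants.
4. **ROC** — candidate cutoffs are the distinct labeled ratios in
   descending order; TPR/FPR count labeled proteins at ratio ≥ cutoff;
   AUC by trapezoid anchored at (0,0) and (1,1). The operating point
   maximizes Youden's J = TPR − FPR, ties broken toward the smaller
   cutoff (retain more proteins — the resource-building intent). A
   fixed-FPR operating point is exposed as an alternative since the
   choice of ROC operating rule is a genuine design freedom here.
5. **Filter** — inclusive boundary (ratio ≥ cutoff; the cutoff is itself
   an observed ratio), applied to all quantified proteins, labeled or
   not.

## Differential abundance

Welch's two-sample *t* on log₂ intensities of Cre+ channels, vectorized
across proteins, with Welch–Satterthwaite degrees of freedom. Welch is
used because condition groups in these designs are small and there is no
reason to assume equal variances; variance-moderated (empirical-Bayes)
testing is deliberately out of scope. A protein needs ≥ 2 quantified
values per group; otherwise its record carries an absent p/q and is never
significant. When both groups have zero variance, p is 1 for equal means
and the smallest positive float otherwise (a measurable difference with
no within-group noise).

Significance is the joint gate **raw p < 0.05 and |log₂FC| > log₂ 1.5**,
symmetric in direction. BH q-values are computed within each contrast
over the tested proteins and reported, but do not gate protein-level
calls — term-level enrichment is where FDR gates. Under the null this
joint gate is conservative (the FC gate removes small-effect false
positives), which the calibration test quantifies.

Hierarchical clustering of regulated proteins (significant in ≥ 1
contrast) uses average linkage on Euclidean distances between log₂FC
vectors; rows are sorted by protein ID before linkage so leaf order is a
pure function of the data, and fold changes missing for a contrast are
set to 0 for clustering only and flagged.

## Over-representation

Per term: one-sided Fisher exact test (enrichment direction only;
depletion is not interpreted), computed as the exact hypergeometric upper
tail. Term memberships are intersected with the background first; terms
disjoint from the background are skipped, zero-overlap terms are still
tested. The odds ratio is the sample OR with a Haldane–Anscombe 0.5
correction for zero cells (display only — p stays exact) and is defined
as 1 for the degenerate foreground-equals-background case. BH runs across
tested terms only. The background is an explicit argument: the
experiment-specific quantified-and-passing set by default, a supplied
(e.g. genome-wide) list where that is the intended comparison.

The directional variant splits a differential table at its own
significance gate into up- and down-foregrounds against all tested
proteins, tagging records with a signed −log₁₀(q) display score. It is
an over-representation reading of "direction-aware enrichment"; ranked
GSEA is out of scope.

## Annotation-facing analyses

- **Secretion classes** — mutually exclusive partition by precedence
  signal peptide > unconventional secretion > transmembrane-only >
  intracellular/other (the figure-style summary bar is a partition); the
  raw independent flags are preserved per protein.
- **Concordance** — Pearson r on inner-joined (tissue, plasma) log₂FC
  pairs of the same contrast; r is withheld below 3 shared proteins.
  Fold changes, not intensities: the question is whether responses, not
  abundances, agree.
- **Dynamic-range rank** — descending mean intensity in one condition's
  Cre+ channels, ties broken by protein ID, joined with known absolute
  concentrations in a common unit (pmol/mL; the smallest unit in use, so
  catalog values stay integral-friendly). The bundled mini-catalog spans
  albumin (137,300 pmol/mL) to thrombospondin-4 (0.7 pmol/mL), ~5.3
  orders of magnitude.
- **Disease join** — regulated proteins joined to an external
  association atlas filtered at p_adj ≤ 0.05; odds ratios and p-values
  are inputs from the external cohort resource and are never recomputed.

## Pipeline and determinism

One seed governs every stochastic stage through named `SeedSequence`
substreams, so adding a stage never perturbs earlier draws. All outputs
are TSV with fixed float rendering and deterministic row/column order;
the manifest records config hash, seed, input and output SHA-256 hashes
and per-stage counts. The run log is the only timestamped artifact and
is excluded from hashing. A committed 100-protein golden run is part of
the test suite and must reproduce byte-identically.

## Validation problem sizes

The test suite and reproduction script use deliberately modest sizes —
200 random ROC instances, 5 simulated 16-plexes of 2,400 proteins for
filter recovery, 20 × 1,000-protein null simulations (20,000 tests
pooled) for type-I calibration, exhaustive Fisher tables to N = 60,
500 random BH vectors, 300-protein concordance tables — chosen so the
whole validation runs in seconds while keeping Monte-Carlo error well
inside the asserted margins.

## Known limitations

- The truth standard for ROC construction is itself annotation-derived;
  on real data, annotation errors blur the measured TPR/FPR (the
  synthetic catalog is error-free by construction).
- Single-plex contrasts only: no bridging channels or cross-plex batch
  correction.
- Raw-p protein gates are intentionally faithful to the resource style
  they reproduce; users wanting FDR-gated protein calls can gate on the
  reported q column.
- Missingness handling is filter-based (quantification fractions), not
  model-based imputation.
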