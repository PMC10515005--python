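# Methods

This note documents the statistical models implemented in `thermomethyl`,
the defaults and why they were chosen, and the limits of what the synthetic
benchmarks demonstrate.

## The synthetic co-profiling design

The generator emulates a three-temperature (16/22/28 °C) methylome +
transcriptome experiment on a miniature genome. Defaults: 2 chromosomes ×
200 kb, 60 non-overlapping genes of 2 kb laid out in equal slots with ≥ 2 kb
margins (so every gene keeps a full-length promoter), strands alternating;
2 bisulfite replicates and 3 expression replicates per condition, one
developmental stage. This scale runs the full pipeline in seconds while
leaving ~200,000 cytosine records per sample — enough for the smoothing,
shrinkage and FDR machinery to behave as it would at genome scale.

**Methylome.** Every C (and G, as a minus-strand C) whose trinucleotide fits
on the chromosome becomes a site; context is read 5′→3′ on the site's own
strand (CG, CHG, CHH with H ∈ {A,T,C}). Opposite-strand CG sites are kept
independent, mirroring per-strand cytosine reports; symmetric pooling is
deliberately not applied at simulation time. Each site draws a methylation
probability π once from Beta(mean = context baseline, concentration 30);
the baselines (CG 0.50, CHG 0.17, CHH 0.05) echo the magnitudes typical of
*Brassica* methylomes, and the concentration gives mild site-to-site
heterogeneity without destabilizing window-pooled estimates. The π surface
is shared across conditions — the null is exact by construction — except in
the promoters of the FCG set under the single warm condition, where π is
shifted up by `promoter_hyper_delta` (default +0.2, capped at 1). Per
sample, depth is Poisson(30) (depth-0 sites are emitted, exercising
missing-data handling), the methylated count is beta-binomial with
per-context dispersion φ (CG/CHG 0.05, CHH 0.02) parameterized as
a = π(1−φ)/φ, b = (1−π)(1−φ)/φ so φ→0 degenerates to binomial, and each
truly-unmethylated read reports methylated with probability *r* (default
0.005). Non-conversion applies only to unmethylated reads — methylated
reads never "de-convert" — matching the chemistry of bisulfite conversion.
No estimation procedure for *r* is modeled (no chloroplast/lambda control);
*r* is a user input.

**Expression.** Gene means follow μ_gc = μ_g0 · exp(−β · promMeth_gc) with
β = 5 (so the planted +0.2 promoter shift gives a true fold change of
e^1.0 ≈ 2.7, comfortably above the 1.5 DEG gate but small enough that
detection is non-trivial at n = 3). Counts are Gamma-Poisson with
dispersion 0.05 around μ × size factor, size factors log-uniform in
[0.7, 1.4]. Base means μ_g0 are log-normal (median 200, log-sd 1); FCG base
means are drawn from the upper half of that distribution because the genes
whose suppression this design probes are apex-highly-expressed — planting
FCGs among weakly expressed genes would conflate the generator's choice of
gene identity with the power of the downstream test. β < 0 is rejected:
the suppression direction is a modeling commitment, inverted only by
reconfiguring the planted effect.

**Hyper condition.** The effect is planted in the warmest condition only
(28 °C). This is required by the candidate-selection logic downstream: FCG
candidates are the *non-overlapping* DEGs of the warm contrast, so a design
that perturbed 22 °C and 28 °C identically would by construction have an
empty candidate set.

## Methylation calling and levels

A site is called methylated when P(X ≥ mC) for X ~ Binomial(mC+umC, r) is
small after Benjamini–Hochberg correction (q < 0.05). The upper tail is the
only direction consistent with calling *truly methylated* cytosines against
non-conversion noise; BH is applied per sample across all contexts jointly.
Zero-coverage sites have undefined p and level and are never called.

All region summaries are read-pooled — level = Σ mC / Σ(mC+umC) over the
region's reads — not unweighted means of site levels; the two coincide only
at equal depth. Bins default to 10 kb; empty bins are reported as undefined,
not zero. Metagene profiles use 2-kb flanks in fixed 50-bp bins and a gene
body rescaled to 40 relative bins (site → bin ⌊40·offset/length⌋);
minus-strand genes are flipped into transcription orientation before
pooling, and 40 body bins is a configurable convention chosen to keep flank
and body bins visually comparable.

## DMR detection

The model family is beta-binomial. For each context and site:

1. **Smoothing.** Group means are window-pooled proportions over ±250 bp
   (CG only; CHG/CHH sites are tested individually — they are sparser and
   more locally heterogeneous, and pooling them over fixed windows mixes
   unrelated sites). Replicates pool by summed counts.
2. **Dispersion.** A method-of-moments estimate per site — for each
   replicate observation, E[(p̂−μ)²·n/(μ(1−μ))] = 1+(n−1)φ, with an
   R/(R−1) small-sample correction and an Anscombe-adjusted group mean —
   shrunk toward the information-weighted per-context mean with weight
   w = D/(D + 20·D̄), where D = Σ(n−1) is the site's information and D̄ the
   genome average (a "20 average sites" prior), clamped to [1e−4, 0.5].
   This is a deliberately lighter-weight stand-in for full empirical-Bayes
   penalized likelihood: at these depths the estimator is dominated by the
   prior exactly where the likelihood is weak, which is the property that
   matters.
3. **Wald test.** W = (μ₁−μ₂)/√(V₁+V₂) with V_g the variance of the
   window-pooled proportion: V_g = μ_g(1−μ_g)·Σ n(1+(n−1)φ̂)/N_g², summing
   over the window's replicate observations. With a single-site window this
   is the textbook beta-binomial plug-in, and at φ = 0 it is exactly the
   unpooled two-proportion z-test. Degenerate pooled proportions (0/N, N/N)
   use an Anscombe (+½/+1) adjustment in the variance term only, so
   non-degenerate counts keep the exact plug-in. Sites with an uncovered
   group are skipped and flagged.
4. **Segmentation.** Maximal runs of same-sign sites with p < 1e−5 and
   |Δ| ≥ 0.1; runs break at gaps ≥ 100 bp and same-sign runs closer than
   100 bp merge; kept regions span ≥ 50 bp, contain ≥ 3 sites, with ≥ 50%
   of contained sites significant. These thresholds mirror common DMR-caller
   conventions and are all exposed on the CLI; direction (hyper = warm
   group higher) comes from the pooled raw counts of the region.

DMGs are genes whose body [TSS, TES) or 2-kb strand-aware promoter strictly
overlaps a DMR under half-open semantics — touching is not overlap. A fully
clipped promoter (TSS at position 0) is empty and can carry no association.

## Differential expression

Size factors are median-of-ratios against the geometric-mean reference over
genes nonzero in every sample (a positive-counts fallback is flag-enabled).
The NB Wald test estimates per-gene dispersion by method of moments on
normalized counts, shrinks it toward a fitted a₀ + a₁/μ trend with a prior
weight of 6 pseudo-samples, and tests the log mean ratio with a delta-method
standard error and normal reference. Omitted relative to a full DESeq2: the
Cox–Reid adjustment, LFC shrinkage, independent filtering, and outlier
refitting — the downstream claims depend on direction plus thresholded
calls, which this test reproduces (it tracks pydeseq2's MLE fold changes
and p-values closely on shared fixtures; the suite cross-checks this).
All-zero genes are excluded from testing and from the BH family. "Fold
change ≥ 1.5" is read as the symmetric linear gate (FC ≥ 1.5 or ≤ 1/1.5),
with both the FC and padj ≤ 0.05 boundaries inclusive.

## Integration

FCG candidates are the non-overlapping DEGs of the warm contrast against
the milder contrast, per direction, tagged with the cessation stage and the
evidence stage; evidence from the cessation stage and the preceding stage
is reported separately, never merged. The FP-stage rule compares the mild
contrast against the same-temperature across-stage contrast (FB vs FP at
16 °C) to exclude genes that change with normal development rather than
with cessation. methDEGs are DMG ∩ DEG keyed by gene with one row per
(gene, region, methylation direction); class counts tally unique genes per
hyper/hypo × up/down cell. When a gene carries both promoter and body
associations, both rows are kept, but recovery and tripartite analyses use
promoter rows only — the mechanism under study is promoter-centric. The
tripartite trend uses Spearman correlations (methylation vs temperature
rank, expression vs methylation); a gene is consistent iff ρ_mt > 0 and
ρ_me < 0, and constant inputs are flagged uninformative, never consistent.
Term enrichment is a plain upper-tail hypergeometric test with BH — no
length-bias weighting; term maps are user-supplied.

## Motif scanning

PFMs (JASPAR text format, parsed via Biopython) become log₂-odds matrices
with pseudocount 0.25 per cell against a uniform background (a
genome-derived background is accepted). Every window is scored on both
strands; a hit is relative score ≥ 0.85 — a common scanning default, since
no threshold is universal. N bases contribute 0 (background-equivalent)
rather than disqualifying a window. By default only the DMR intervals of
promoter associations are scanned; a full-promoter mode exists.

## Benchmark problem sizes and what they show

The validation suite and `scripts/acceptance.py` use: 20 × 50,000-site
all-null replicates for caller calibration; 20 identical-π two-group
simulations of the full 2 × 200 kb design for the DMR null; one default-scale
run for planted-effect recovery (12 FCG promoters at Δ = +0.2, 30×, 2
replicates); 5,000-gene null and 100-effect-gene NB simulations for the DE
test; and one full-pipeline run for end-to-end recovery. These sizes were
chosen so the whole battery completes in a few minutes on one CPU while
keeping Monte-Carlo error well below the margins being tested.

Passing these benchmarks shows the *methods* are calibrated and can recover
effects of the planted kind under the stated noise model. It does not show
performance on real bisulfite data, which additionally carries mapping
bias, coverage structure (PCR duplicates, M-bias), non-uniform genome
composition, TE-dense regions, and correlated biological replicate
structure that the generator does not emulate. DMR thresholds unstated by
upstream conventions (p, Δ, lengths) and the smoothing window are exposed
as configuration; conclusions at other settings require re-validation.

## Known limitations

- Two-group DMR comparisons only; no multi-factor designs and no
  replicate-free mode.
- Single-site methylation calls are intermediate outputs, not a deliverable
  DML list.
- The NB test's normal reference is slightly anticonservative at n = 3
  (observed type-I ≈ 0.058 at nominal 0.05 in the calibration benchmark, within
  the accepted band).
- Enrichment ignores gene-length bias; with user-supplied term maps this is
  a documented simplification.
- The qPCR helper averages CTs over replicates before ΔΔCT; no per-replicate
  error propagation.
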