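# Methods

This note documents the statistical procedures, the simulator they are
validated against, the parameter defaults and the numerical choices, in
the package's own terms. Nothing here states a result that the test suite
or `scripts/acceptance.py` does not itself compute.

## DMR calling

The caller tests pooled group counts, not per-replicate methylation
levels. For one contrast (exposed vs control, any number of replicates
per side):

1. **Tiling.** Each chromosome is cut into windows of `window_size` bp
   (default 200) every `window_step` bp (default 200, i.e. non-overlapping;
   a step smaller than the size is supported and the merge stage handles
   the resulting overlaps). A non-empty terminal partial window is kept.
2. **Site filter.** A CpG is retained when its coverage *pooled over
   replicates* reaches `site_min_coverage` (default 20) in **both**
   groups. Pooling is deliberate: at n = 6 replicates of ~10× each, a
   per-replicate 20× rule would discard nearly everything, while the
   pooled rule matches the group-level window counts the test consumes.
3. **Window test.** Methylated/unmethylated reads are summed over retained
   CpGs and replicates per group into a 2×2 table and tested with the
   uncorrected Pearson chi-squared statistic on 1 df (no Yates correction;
   a `yates_correction` flag exists but defaults off — the plain statistic
   is the conventional reading of a chi-squared test on read counts, and
   the counts here are far from the small-sample regime the correction
   targets). Windows with no retained CpG or a zero marginal are
   *untestable*: they carry NaN statistics and never enter the
   multiple-testing correction.
4. **Significance.** BH runs once per contrast over all testable windows
   genome-wide. A window is significant iff `q < max_q` (strict, default
   0.1), `|Δβ| ≥ min_delta` (inclusive, default 0.1), `n_cpgs ≥
   region_min_cpgs` (default 2) and per-group mean pooled coverage over
   its retained CpGs ≥ `region_min_avg_coverage` (default 20; with the
   defaults this is implied by the site filter, but the two are
   independent parameters so either can be relaxed alone).
5. **Merging.** Significant windows whose gap is ≤ `merge_max_gap`
   (default 0, i.e. bookended or overlapping) merge transitively;
   by default only same-direction windows merge, and an
   opposite-direction window between two same-direction ones neither
   bridges nor blocks them. Span-level β, Δβ and CpG counts are
   recomputed from pooled counts over the merged interval. *Hyper* means
   exposed > control.

β is always the pooled ratio methylated/(methylated+unmethylated); Δβ is
a difference of pooled ratios, not a mean of per-replicate β values —
consistent with the pooled test.

Numerical choices: the inclusive |Δβ| comparison uses a 1e-12 slack so a
window at exactly the threshold is not lost to float subtraction
(0.5 − 0.4 < 0.1 in binary floating point). In the rare case that merging
dilutes a span's recomputed |Δβ| below `min_delta`, the span is dropped so
every emitted record satisfies the caller's contract.

**Calibration behaviour.** With pure binomial replicate noise the pooled
chi-squared is slightly conservative at window scale (discreteness); with
beta-binomial overdispersion it is mildly anticonservative, as pooling
implies (the test treats pooled reads as independent). The suite measures
both regimes. Note a structural property of interval-level error: BH
controls the *window*-level FDR at q, but merging collapses several true
windows into one reported region while false windows typically stay
singletons, so the interval-level false discovery proportion runs ~2–3×
the window-level one and is pulled back down only where the |Δβ| filter
bites (CpG-dense windows). At the default simulation conditions the
interval-level FDR sits approximately at the BH level itself; users who
need a clearly sub-q interval FDR should raise `region_min_cpgs` or
`min_delta`.

## Differential counts

A self-contained stand-in for the dedicated count-model packages used in
study-scale analyses (which additionally rely on centralised batch
normalisation and cross-feature dispersion moderation, both outside this
package's scope). The pipeline can equally ingest external tables via
`load_external_differential`, which re-applies the thresholds so
significance semantics stay uniform.

* **Size factors**: median-of-ratios over features with all-positive
  counts; an all-zero-free feature set is required (the error message
  suggests pseudocounting upstream).
* **Test**: with normalised counts y = k/s, per feature: group means m₀,
  m₁; log2FC = log₂((m₁+c)/(m₀+c)) with pseudocount c = 0.5 (configurable;
  avoids log 0); a single method-of-moments overdispersion
  α = max(floor, (pooled within-group variance − pooled mean)/pooled
  mean²), floored at 1e-8; delta-method variance of each group's log₂
  mean Vg = (1/(m_g+c) + α)/(n_g ln²2); z = log2FC/√(V₀+V₁).
* **Reference distribution**: two-sided Student-t with n₀+n₁−2 df. With
  six replicates per group the variance entering z is estimated from ~10
  residual degrees of freedom, so the null z is t-like, not normal; the t
  reference is what keeps null p-values uniform (the suite checks KS
  distance < 0.02 and a p < 0.05 fraction in [0.04, 0.06] on 20k null
  features). Unshrunken per-feature estimates are used throughout —
  cross-feature moderation is deliberately out of scope.
* **Thresholds** (strict on both sides): expression padj < 0.001,
  accessibility padj < 0.01, both with |log2FC| > log₂(1.5). A feature at
  exactly either bound is not significant. Features with all-zero counts
  in both groups are reported untested (NaN p) and excluded from BH.

A direct consequence of honest small-sample calibration: at n = 6 and
dispersion 0.05 the largest attainable |z| for a 2-fold change is
1/√(2α/(n ln²2)) ≈ 5.4 even at infinite counts, while BH at padj < 0.001
over 10⁴ features demands roughly |z| ≈ 9 on t₁₀. Two-fold changes are
therefore essentially undetectable under these thresholds without
borrowing strength across features; the recovery scenarios in the
examples and pipeline use 4-fold planted effects, which are detected with
~0.8–0.95 sensitivity at near-zero FDR.

## Concordance

Matching rules per feature kind: genes by exact id; accessibility regions
by identical coordinates (default; a ≥ k bp overlap mode exists) since
both tables live on one consensus-region space; methylation regions by
≥ 1 bp intersection since independent calls never share boundaries. A
region intersecting several partners contributes one pair per partner;
count-level summaries report distinct features per side alongside pair
counts.

Per comparison: A-only/B-only/shared counts; direction concordance =
fraction of pairs with agreeing effect signs (zero-effect pairs excluded
and counted separately; an empty pair set yields a missing value, never
0); Pearson correlation of shared effect sizes (log2FC for genes/regions
from counts, Δβ for methylation; Spearman available), missing below 3
pairs; and, for key-matched kinds, the upper-tail hypergeometric
probability of the observed sharing. The hypergeometric universe N
defaults to the features *tested* in both tables (only features testable
on both sides can be shared); union and user-supplied universes are
available, and N is always reported next to p. Cross-exposure sharing
counts, per feature, the exposures in which it is significant in any
direction and in the same direction (methylation features are first
clustered by overlap across exposures), binned as 1 / 2 / 3 / >3.

All count definitions are symmetric: swapping the two sides swaps
A-only/B-only and preserves shared counts and the hypergeometric p (a
property the suite asserts).

## The simulator

What it emulates: the study layout (two tissues × two sexes × several
exposures, n = 6 replicates per group), WGBS read-count structure, and
negative-binomial count matrices, each with planted effects recorded in a
ground-truth table keyed identically to called features.

* **CpG landscape**: total density 1/100 bp; 70% of CpGs sit in ~800 bp
  island blocks (~25 bp internal spacing) on a jittered grid, the rest is
  sparse Poisson background — a minimal rendering of the clustered CpG
  landscape of a mammalian genome. `cluster_fraction = 0` gives a uniform
  landscape. Planted DMRs always receive an island so they are callable,
  and alternate between window-aligned and window-straddling starts so
  merging across window boundaries is exercised.
* **Methylation**: baseline β per CpG from a bimodal mixture (25% low
  ~Beta(1.5, 8.5), 75% high ~Beta(8.5, 1.5)); inside planted regions the
  baseline is drawn from a range that leaves room for the full shift
  (hyper: 0.15–0.60, hypo: 0.40–0.85), then shifted by ±Δβ and clipped to
  [0.02, 0.98]. Coverage is Poisson (mean 10 per CpG per sample); counts
  are beta-binomial with ρ = 0.01 — mild replicate overdispersion, enough
  to exercise the pooled test's robustness without drowning the signal.
* **Counts**: baseline means log-normal (heavy right tail); NB dispersion
  0.05; planted features multiply the exposed-group mean by 2^log2FC;
  optional per-sample depth factors exercise normalisation.
* **Cross-structure**: per (sex, exposure), a planted set per first
  tissue; each planted feature carries into the second tissue with
  probability `tissue_sharing` (default 0.05), keeping its sign with
  probability `same_direction` (default 0.62); the second tissue refills
  to the same planted count from features untouched in the first, so
  `tissue_sharing = 0` means strictly disjoint planting. Cross-sex and
  cross-exposure recurrence follow analogous Bernoulli constructions. All
  rates hold in expectation and the exact realisation is recorded in the
  truth table. The scenario's planted effect is 4-fold on well-expressed
  features so that concordance measured on *called* features tracks the
  planted rates rather than caller power.

What it does not emulate: read-level artefacts (mapping, bisulfite
conversion), batch effects beyond per-sample depth, correlated
neighbouring-CpG noise, realistic chromosome sizes, or annotation-driven
feature structure. Passing recovery tests therefore demonstrates the
pipeline's statistical machinery under its stated noise model, not
performance on any particular real dataset.

## Pipeline and scoring

`run_pipeline` executes simulate → call (per tissue/sex/exposure) →
concordance → scoring, writing per-stage TSV/BED/JSON artefacts and a
manifest (seed, version, parameter dump, stage status). All randomness
flows from one seed through `numpy.random.SeedSequence` spawning; two runs
with the same config are byte-identical.

Scoring against truth: for keyed features, sensitivity = planted ∩
significant / planted and FDR = significant \ planted / significant. For
DMRs the scoring is interval-level: a planted region counts as recovered
when a called region of matching direction intersects it by ≥ 1 bp; a
called region intersecting no planted region (any direction) is a false
discovery. Problem sizes in the shipped tests and acceptance script
(1–2 Mb genomes, 10–20k features, 5–10 simulation replicates for
expectation estimates) are desk-scale choices that keep a full validation
run in seconds while leaving every rate measurably stable; all are
configurable upward.

## Known limitations

* The pooled chi-squared DMR test ignores replicate-level variance; with
  strong biological overdispersion its q-values are optimistic. A
  beta-binomial regression caller would be the principled upgrade and is
  deliberately out of scope.
* The NB Wald stand-in is honest but low-powered at small n under strict
  thresholds (see above); it is a pipeline-validation instrument, not a
  replacement for moderated count models on real data.
* Interval-level FDR of merged DMR calls runs at, not below, the BH level
  under the default simulation conditions (see the calibration note).
* Chromosome names are compared as exact strings; inputs mixing naming
  conventions trigger a warning, not a translation.
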