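# Methods

## The synthetic study and its generative model

The generator (`nitrosig.simulate`) emulates a macroarray study of three
wine-yeast strains fermenting synthetic grape juice under a low-nitrogen
(LN, limiting) and a high-nitrogen (HN, replete) regime, sampled at 12,
24 and 96 h (optionally 36 h, the limitation stage of a slow strain)
with two membrane replicates per condition. Expression is additive on
the log2 scale:

    log2 x[g, sample] = baseline_g + G_g(strain) + E_g(stage)
                        + GEI_g(strain, stage) + N_g(regime, stage)
                        + Normal(0, noise_sd_log2)

exported as linear intensities. The additive-log2 choice reflects that
every downstream screen operates on log-ratios or ranks of them.

Planted effect classes (disjoint gene sets, exact counts
`round(frac * n_genes)`):

* **genotype (G)** — one randomly chosen strain shifted by
  `effect_size_log2` (default 2.0) at all stages;
* **environment (E)** — one randomly chosen stage shifted in every
  strain and regime;
* **interaction (GEI)** — a zero-sum product contrast
  `effect * u_s * v_t` over a random strain pair and stage pair. The
  zero row/column sums mean a GEI gene contributes nothing to the
  marginal strain or stage means, so the three ANOVA factors stay
  orthogonal in truth — a single shifted cell would genuinely leak into
  the main effects and make factor-wise false-discovery accounting
  ill-defined;
* **nitrogen-responsive** — a linear fold drawn log-uniformly from
  `nitrogen_fold_range` (default 3–25, the span of a published biomarker
  panel) applied under LN from `nitrogen_onset_h` (default 24 h)
  onwards, emulating genes that react once assimilable nitrogen is
  exhausted; a configurable fraction (default 0.25) is repressed rather
  than induced, stored as fold < 1.

Effect shifts are planted with a positive sign (the affected level is
elevated); replicate noise defaults to 0.25 log2 units — a free
parameter, since within-condition membrane variance is not something
the emulated design pins down. Missingness is completely at random. A
single seed drives independent substreams for flag assignment,
baselines, effect draws, noise and missingness, so changing
`missing_rate` never changes which genes carry effects.

**Phenotypes** (μ in 1/h, Nrate, MFR) are generated once per
strain × regime as monotone linear functions of *planted module
activity* — the mean noise-free expected log2 expression of the
nitrogen-responsive genes in that cell (growth phenotypes read the
module at the onset stage, MFR at the final stage) — plus optional
Gaussian noise. Using expected rather than realised expression keeps
phenotype generation a pure function of (truth, config). Because planted
module activity varies only between regimes (effect classes are
disjoint, so module genes carry no strain effects), phenotypes differ
mainly LN vs HN; real strain-specific phenotype variation is not
emulated.

**What passing tests show, and what they do not.** The generator plants
clean, orthogonal, homoscedastic effects with MCAR missingness. Recovery
and calibration results therefore validate the *statistics and the
plumbing*, not robustness to the pathologies of real macroarray data
(intensity-dependent bias, spatial artifacts, informative missingness,
correlated replicates, heteroscedastic low-intensity noise).

## Preprocessing

Fixed order: global-median normalisation → presence filter → log2 →
KNN imputation (`preprocess.run`).

* **Global median**: each sample's present values are scaled so all
  per-sample medians equal the grand median of present values. Targeting
  the grand median (not 1.0) preserves intensity magnitudes for the
  linear fold changes reported later.
* **Presence filter**: genes with < 75% present values are eliminated;
  exactly 75% is retained (the threshold reads "strictly less than 75%
  eliminated").
* **log2** with flooring at half the smallest positive present value;
  background-subtracted intensities can be near zero and their raw log
  would dominate every screen.
* **KNN imputation** (k = 10): gene-wise neighbours by Euclidean
  distance over pairwise-complete samples, rescaled by
  sqrt(n_total/n_shared) so genes sharing few samples are not spuriously
  close (scikit-learn's `nan_euclidean_distances` implements exactly
  this); the k nearest genes with a value in the target column
  contribute a 1/distance-weighted average; zero-distance neighbours
  take over with equal weights; with no candidate donor the gene's own
  row mean is used and the event logged.

Replicate averaging (one column per strain × regime × stage) feeds only
clustering, correlation screens, fold changes and response matrices;
the ANOVA and Rank Product stages always consume replicate-level data.

## Per-gene two-way ANOVA

Within one regime, the balanced a × b × r decomposition (closed form,
vectorised over genes) with F = MS_factor/MS_error on the classical
degrees of freedom; in a balanced design Type I/II/III coincide, so the
closed form equals a model-comparison fit exactly (tested against
statsmodels OLS to 1e-8). Unbalanced input is a hard error — silently
switching to a Type-III fit would change the semantics of the factor
sums of squares. Degenerate genes: with zero within-cell variance, a
factor with positive sum of squares gets p = 0, one with zero sum of
squares gets F = 0, p = 1 (covering the all-constant gene). BH
adjustment (statsmodels, `fdr_bh`) is applied separately per factor and
regime, mirroring factor-wise gene counting; the two membranes are the
error stratum.

## Phenotype correlation screen

Spearman ρ per gene across the replicate-level samples of one stage
(3 strains × 2 regimes × 2 membranes = 12 points), against the
phenotype value of the sample's strain × regime cell. Replicate-level
columns are used deliberately: with only 6 averaged points, p < 0.05
needs |ρ| ≳ 0.94 and the screen could call almost nothing. Two-sided
p-values are exact for n ≤ 8 (full enumeration of the n! rank
permutations, cached per n; 8! = 40320 is the practical ceiling) and
use the t approximation t = ρ√((n−2)/(1−ρ²)) with tie-corrected ρ
above. Calls: |ρ| > 0.6 and BH q < 0.05. Constant gene rows carry no
rank information and are reported with ρ = NaN, p = 1, direction none.

## Two-class Rank Product

For K compared column pairs, per-gene log-ratios are ranked within each
pair (average ranks on ties); RP = geometric mean of the K ranks,
computed in the log domain. The null is the classical reference
distribution — L draws of K independent uniform-random rank
permutations — pooled over genes: p = (x+1)/(Ln+1) with x the count of
null RP values ≤ observed (the +1 keeps p positive), and
pfp = (x/L)/rank(RP) estimates expected false positives per accepted
gene.

**Pairing.** The all-pairs scheme (K = |A|·|B|) makes the K rank columns
share replicates; they correlate at ~0.5 and the independent-rank null
becomes anticonservative (measured ~3× the nominal rate at α = 0.05 for
3-vs-3 classes). The default therefore pairs the i-th column of A with
the i-th column of B (K = class size): disjoint replicate sets make the
K rankings independent under an i.i.d. null, so the reference
distribution is exact — measured null hit rates sit on the nominal level
(acceptance suite). Class columns are ordered consistently (by strain)
so the positional pairing is meaningful; `pairing="all"` remains
available. An exhaustive mode enumerates all (n!)^K rank matrices for
tiny problems and is tested against independent enumeration.

## The nitrogen-limitation biomarker cascade

Classes: each strain's limitation-stage LN sample (24 h for the fast
strains, 36 h for the slow one when present) pooled against the matching
HN samples. Pipeline for the up direction:

    pooled RP up set (permutation p ≤ 0.05)
      − HN responders (per strain: up at the selected stage vs 12 h
        under HN; union)
      ∩ LN-induced (per strain: up at the selected stage vs 12 h under
        LN; union)
      → candidate panel at linear fold ≥ 3 → final panel at fold ≥ 4

Down direction: RP down set with the reciprocal fold filters only (the
exclusion and intersection steps are defined for induced genes). Fold
changes are ratios of linear normalized group means.

**Cutoff choices.** The primary DE sets use the permutation p at 0.05.
The two auxiliary screens are treated asymmetrically, by their role:

* the HN-responder screen is an *exclusion blacklist* — a false positive
  there erases a genuine biomarker. At a raw p cutoff the union over
  three strains would blacklist ≈ 1 − 0.95³ ≈ 14% of genuinely HN-flat
  genes. It therefore uses the pfp at 0.05 over all-pairs ranks
  (maximal per-gene evidence): under a null the pfp admits almost
  nothing, while genuinely time-responsive genes rank at the top and
  are still caught;
* the LN-induction screen is a *required whitelist* — sensitivity is
  what matters, and its false positives are neutralised by the
  intersection with the pooled RP up set. It keeps the raw p cutoff
  (union across strains; a strict per-strain intersection variant is
  available via `ln_induced_rule="intersection"`).

Under the package's cascade stress scenario (true nitrogen genes vs
HN-responder decoys planted at matched 4–10-fold), this design recovers
~94% of true biomarkers and admits no decoys (acceptance suite); the
residual losses are boundary effects of the fold ≥ 4 filter on genes
whose true fold sits at the threshold.

## Clustering

One engine serves heat-map gene clustering and profile clustering:
Pearson similarity, distance d = 1 − r, UPGMA (size-weighted average
linkage, via scipy; heights are nondecreasing and cophenetic distances
ultrametric). Equal-distance ties follow scipy's deterministic internal
order — on continuous similarities exact ties have probability zero.
Heat-map inputs are replicate-averaged log2 values standardised by each
gene's across-condition mean. Zero-variance profiles make the
correlation undefined and raise rather than propagating NaN.

## Enrichment

Hypergeometric upper tail P(X ≥ k) for a query of n genes from a
universe of N against a category of K universe genes (scipy's
log-space survival function; validated against exact rational
arithmetic to 1e-10 for N ≤ 60). Categories are intersected with the
universe — defined as the genes surviving the presence filter, i.e. the
population actually tested — before testing. Raw p with a 0.001 cutoff
and no multiple-testing correction, matching common annotation-screening
practice. Bundled GMT fixtures are synthetic (planted modules plus
random categories), not curated annotation.

## Numerical and engineering choices

* Zero-variance detection in the ANOVA uses a scale-aware tolerance
  (1e-12 × squared signal scale).
* The RP null is drawn in chunks (~2e6 scratch entries) to bound
  memory; searchsorted against the sorted pooled null gives x.
* Exact Spearman null distributions are cached per n; the exact/
  approximate switch sits at n = 8.
* All randomness flows from a single seed through `SeedSequence`
  substreams; derived seeds stay below 2^31. Two runs with identical
  config and seed produce byte-identical result bundles (tested).
* All artifacts are TSV (missing values as "NA"); floats use shortest
  round-trip representation, so write→read is lossless. Every result
  table carries a `#` header naming the thresholds that produced it.

Problem sizes used by the test and acceptance runs — chosen as the
package's standard desk-scale configuration — are: full-design
simulation at 5764 genes for the headline run; recovery and calibration
at 2000–5000 genes with L = 200–1000 permutations over 10 seeds;
end-to-end determinism at 250 genes.

## Known limitations

* The generator's clean additive model understates real macroarray
  noise structure (see above); headline gene counts from a synthetic
  run are not comparable to counts from any deposited dataset.
* The disjoint-pairing Rank Product discards the cross-replicate
  comparisons of the all-pairs scheme, trading some power for a
  calibrated null.
* Phenotypes vary only between regimes, so phenotype screens mostly
  detect the LN/HN split; strain-level phenotype diversity is not
  modelled.
* The GEO series-matrix reader handles the standard table dialect only
  and performs no normalisation of its own.
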