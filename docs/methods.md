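# Methods

This note records the models, defaults and numerical choices behind each
stage of the pipeline, and what the synthetic-data generator does and does
not emulate.

## Data model

All stages consume a taxa × samples table of non-negative integer counts
(`CountTable`) plus a sample→group map (`SampleMetadata`). Relative
abundances are per-sample proportions (`AbundanceTable`, columns sum
to 1). Presence–absence (`PresenceMatrix`) is `count ≥ min_count` with
`min_count = 1` by default: any detected read counts as presence, since
amplicon pipelines have no natural detection threshold after denoising.
TSV is the canonical table dialect; networks round-trip through GraphML
and node-link JSON (node attributes preserved) or a plain edge TSV
(edges, weights and signs only).

## Alpha diversity

`shannon` reports nats (the Shannon–Wiener convention in ecology). Two
estimators:

- `plugin`: H = −Σ pᵢ ln pᵢ over nonzero proportions.
- `chao_shen`: with f₁ singleton counts out of n reads, sample coverage
  C = 1 − f₁/n, adjusted proportions p̃ᵢ = C pᵢ, and
  H = Σ −p̃ᵢ ln p̃ᵢ / (1 − (1 − p̃ᵢ)ⁿ). The denominator is the probability
  that taxon i appears in a sample of size n (a Horvitz–Thompson
  correction for unseen taxa). A sample whose reads are all singletons has
  zero estimated coverage and is rejected rather than extrapolated.

The plugin estimator is the default; "nonparametric Shannon" in the
amplicon literature is ambiguous, so both are exposed and labeled.

## Beta diversity and ordination

Bray–Curtis is the implemented dissimilarity. UniFrac variants are out of
scope because the pipeline carries no phylogenetic tree; where a study's
methods and figures disagree on which of the two was used, Bray–Curtis is
the reproducible choice since it needs no tree.

`pcoa` performs classical metric scaling: B = −½ J D² J with the centering
matrix J, eigendecomposition of the symmetrized B, coordinates
√λₖ·vₖ for eigenvalues above a relative tolerance of 1e-12. Negative
eigenvalues (Bray–Curtis is non-Euclidean) are counted, reported in a
warning and dropped — no Cailliez/Lingoes correction, which would add an
arbitrary constant without changing the visual ordination. Proportion
explained is relative to the sum of positive eigenvalues only.

## Differential abundance

- `kruskal_wallis`: midrank ties correction, χ² p with k−1 df (scipy).
  All-identical observations short-circuit to H = 0, p = 1.
- `two_group_test`: Welch t by default (group contrasts in this study
  design are conventionally t-tests); Mann–Whitney selectable for
  robustness, exact null when groups are small and tie-free. Direction is
  sign(mean₂ − mean₁). Two zero-variance groups with equal means give
  p = 1, direction 0.
- `lda_effect_size` re-implements the LEfSe idea rather than wrapping the
  original tool: stage 1 retains taxa with Kruskal–Wallis p < α (α = 0.05);
  stage 2 runs 30 class-stratified subsampling rounds (2/3 of each group,
  without replacement), fits a one-vs-rest linear discriminant with
  ridge-regularized pooled covariance (λ = 1e-3 · tr(S)/f, so degenerate
  covariances never crash), and scores each taxon by its mean contribution
  |w_f (μ_class,f − μ_rest,f)| to the projected class separation, with
  abundances expressed per million (the LEfSe convention that makes the
  usual log₁₀ threshold of 2.0 meaningful). Reported score is
  log₁₀(1 + mean effect). Bootstrap count, subsample fraction and
  threshold are the tool's conventional defaults; exact numeric agreement
  with the published tool is not claimed — ordering and detection
  properties are what the tests pin down.
- `classify_response` maps the two pairwise contrasts
  (control vs stress: p_A, d_A; stress vs drug: p_B, d_B) to one of four
  categories: **restored** iff p_A<α ∧ p_B<α ∧ d_B = −d_A;
  **stress_only** iff p_A<α without such a reversal; **drug_only** iff
  p_A≥α ∧ p_B<α; **unchanged** otherwise. A significant drug contrast
  with direction 0 is treated as non-reversal. The function is total: every
  input maps to exactly one category.
- Raw p-values are reported by default (matching how such studies present
  them); Benjamini–Hochberg q-values are available behind a flag.

## Co-occurrence networks

- `prevalence_filter` keeps taxa with nonzero counts in strictly more than
  half the samples (9 of 18 is removed, 10 of 18 kept).
- `c_score` is the mean over unordered taxon pairs of
  (Rᵢ−Sᵢⱼ)(Rⱼ−Sᵢⱼ), computed in integer arithmetic.
- The null model is fixed–fixed (SIM9): both taxon occupancies and sample
  richness are conserved, the field-standard and most conservative
  companion to the C-score. The chain proposes random 2×2 submatrices and
  swaps checkerboards. Defaults: burn-in 10× the number of presences,
  thinning 1× the number of presences between the `n_null = 1000` samples.
  p = (#{null ≥ observed}+1)/(n_null+1) for the upper-tail (segregation)
  test — the add-one rule keeps p in (0, 1]. A matrix admitting no
  checkerboard unit cannot move under SIM9; the test is then reported as
  vacuous (p = 1, SES missing) rather than silently returning a degenerate
  distribution. A zero null standard deviation likewise yields a missing
  SES with p from the count rule.
- `spearman_edges` uses one shared Spearman implementation (midranks;
  exact full-enumeration permutation p for n ≤ 9 samples, t approximation
  above). An edge requires |ρ| strictly > 0.7 **and** p < 0.05. Constant
  taxa are excluded with a log notice. Because ranks are scale-invariant,
  counts and relative abundances give identical ρ.
- Nodes are taxa incident to at least one robust edge; isolated taxa are
  dropped, which is why V varies between group networks built on the same
  prevalence universe. Networks are built per group by default (one
  network per experimental group), with pooling available; at n = 6
  samples per group the exact-p requirement effectively demands
  |ρ| ≥ 0.886, so per-group networks are sparse and honest.
- `network_properties`: density 2E/(V(V−1)), mean degree 2E/V, global
  clustering (transitivity), greedy (CNM) modularity and module count,
  mean shortest path on the largest connected component.
- `er_ensemble_compare` samples G(n=V, M=E) uniformly (E distinct pair
  indices drawn without replacement), computes clustering, largest-
  component path length and CNM modularity per draw (via igraph for
  speed; the observed network's properties come from networkx — both
  modularity routines implement the same greedy CNM agglomeration), and
  reports SES and a two-tailed empirical p (doubled smaller tail, add-one
  rule) per property. Which properties a study compared is usually
  unstated, so all three are reported. The default ensemble size is
  10,000 draws.

## Behavior association

`sucrose_preference` evaluates SP(%) = sucrose/(sucrose+water)×100.
`correlate_behavior` computes pairwise-complete Spearman correlations of
each taxon with each index (SP %, immobility time, open-arm time, center
time), requiring ≥ 4 complete pairs; constant vectors yield missing cells.
Stars follow the universal convention (* p<0.05, ** p<0.01, *** p<0.001)
on raw p-values; BH q-values are per-column and optional.
`correlate_time_course` applies the same machinery to one SP column per
timepoint. Taxon–taxon and taxon–behavior correlations share a single
Spearman implementation, so the two stages can never disagree.

## Synthetic data generator

Per taxon i and sample s the latent log-abundance is

    x_is = m_i + ln(2)·lfc_{i,g(s)} + u_is

with baselines m_i ~ N(0, 1.2²) (optionally offset or pinned per taxon),
group effects given as log₂ fold changes, and

    u ~ amplitude · MVN(0, equicorrelation ρ)   for module taxa
    u ~ N(0, 0.35²)                             otherwise.

Infeasible module correlations (non-positive-definite equicorrelation,
e.g. ρ < −1/(k−1)) raise an error from the Cholesky factorization.
Compositions are softmax(x); counts are Dirichlet-multinomial with
concentration p(1−φ)/φ at a Poisson library size (mean 20,000).
Behavioral indices are standardized linear functions of the linked taxa's
latent abundances (link strength = target correlation) plus Gaussian
noise, affinely mapped into realistic mouse ranges (SP ~ 75 ± 8 %,
clipped to [0, 100]; times clipped at 0 s).

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| groups × samples | 3 × 6 | the emulated study design (18 fecal samples) |
| n_taxa | 40 | a genus-level table after prevalence-style filtering |
| library_size_mean | 20,000 | typical per-sample 16S depth |
| baseline_sigma | 1.2 | genus baselines spanning ~2 orders of magnitude |
| latent_sigma | 0.35 | within-group biological variation ~1.4-fold |
| module_amplitude | 1.5 | co-blooming guilds co-vary several-fold |
| noise (φ) | 0.0003 | mild residual overdispersion beyond the latent layer |

The split matters: biological inter-animal variability lives explicitly
in the latent layer, and the Dirichlet φ models only residual technical
noise. These levels are calibrated so that the planted structure is
recoverable at the pipeline's stated operating points — module edges
(ρ = 0.9, 20 samples) with precision/recall ≥ 0.8, and response
categories (|log₂ fc| = 2, n = 6/group) with accuracy ≥ 0.8. Real 16S
data are usually more dispersed; passing these tests demonstrates the
pipeline's correctness and its behavior under the stated effect sizes,
not guaranteed power on noisier field data (the Mann–Whitney option
exists for that reason).

The `study_preset` scenario plants one up- and one down-shifted taxon per
response category with baselines ln(4) apart, so the mass gained and lost
under each contrast cancel and the group effect does not leak into
unplanted taxa through compositional closure. Planted taxa use pinned
baselines: their abundance is an experimental condition, not a roll of
the seed. `generate_presence_matrix` provides segregation fixtures:
iid Bernoulli(fill), paired mutually-exclusive checkerboard taxa, and a
nested pattern that by construction admits no checkerboard unit (useful
for exercising the vacuous-test path).

Not emulated: phylogenetic signal, sequencing error and chimeras,
rarefaction-depth artifacts, longitudinal autocorrelation, cage effects.

## Calibration scenarios and problem sizes

- The C-score size check uses 12 × 18 iid Bernoulli(0.5) matrices with
  199 null draws per test: (count+1)/200 makes the nominal 0.05 cutoff
  exactly attainable. The power check uses 10 taxa × 18 samples; at 12
  samples the test is genuinely underpowered for perfect checkerboards
  (~94% rejection), which is a property of the statistic, not the chain.
- The stage-1 Kruskal–Wallis calibration runs at 15 samples/group: at
  n = 6/group the χ² approximation to H is conservative (empirical size
  ≈ 0.038), a known small-sample property of the approximation. At the
  study's own size the screen therefore errs on the safe side.
- The Erdős–Rényi ensemble mean transitivity is compared to the edge
  density with an absolute tolerance of 0.01, covering the O(1/M)
  without-replacement correction ((M−2)/(C−2) vs M/C) plus Monte-Carlo
  error.

## Known limitations

- Spearman networks on relative abundances inherit compositional-closure
  artifacts (a blooming module depresses everything else); the package
  reports what the method sees, as the original procedure does, rather
  than applying a compositionally-aware estimator (SparCC/SPIEC-EASI are
  out of scope).
- The LDA effect size is a faithful re-implementation of the idea, not a
  byte-compatible port of the published tool.
- Exact Spearman p-values are enumerated only up to n = 9 (9! = 362,880
  permutations); larger n uses the t approximation.
- The SIM9 chain is a sequential MCMC sampler; samples are thinned, not
  independent, and the usual caveats about mixing on extremely sparse or
  nearly-degenerate matrices apply.
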