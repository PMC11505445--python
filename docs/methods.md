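# Methods

## Data model

A well (target *i*, sample *s*) carries a quantification cycle
Cq ~ N(μ_ig, σ_i²) where *g* is the sample's clinical group. qPCR never
reports a Cq beyond the last cycle *L* = 40: a reaction whose latent Cq
exceeds *L* is a **non-detect**. We model non-detects as right-censored
at *L* — the value exists but is only known to exceed the limit. (The
phenomenon is sometimes loosely called truncation; censoring is the
correct formulation because imputing a value beyond the limit for a
non-detect is meaningful, whereas under truncation the observation
would not exist at all.)

Wells can also fail **technical QC** (amplification score ≤ 1,
Cq confidence ≤ 0.8, Cq < 6). A QC-failed well is *not* censored: the
reaction is unreliable, not informative of low abundance. Throughout
the package these wells are excluded observations — they leave both
the numerator and denominator of detection fractions and the censored
likelihoods entirely.

Groups: CNT (controls), OMA (endometrioma), DIE (deep-infiltrating
endometriosis). END = OMA ∪ DIE is always derived at comparison time.

## Censored-normal estimation

`fit_censored_normal` and `tobit_two_group` maximise the classic tobit
log-likelihood in (β, log σ) with the analytic gradient (L-BFGS-B,
gradient tolerance 1e-10). Initialisation is deterministic: the moment
estimates of the uncensored observations (for the two-group model, the
group means and pooled residual SD), so with zero censoring the start
point is already the exact MLE and the optimiser merely confirms it.
Wald standard errors come from a central finite-difference Hessian of
the analytic gradient; p-values use the normal reference distribution,
adequate at the cohort sizes this package targets (n ≈ 127). A
watchdog restarts heavily censored fits from two alternative fixed
initialisations and keeps the best likelihood. Degenerate cases
(< 2 uncensored values per group, σ → 0) raise informative errors and
surface in result tables as NA rows, never silent drops.

Truncated-normal draws (for imputation) use the inverse-CDF method via
`scipy.stats.truncnorm`, which remains exact arbitrarily far into the
tail — no rejection loops.

## Reference selection

The stability analysis needs a complete matrix, so missing wells are
imputed per target within each of END and CNT (fitting within group
avoids manufacturing spurious between-group homogeneity): censored
wells get draws from the fitted normal truncated to [L, ∞); QC-excluded
wells get draws from the *untruncated* fitted normal. The latter is a
deliberate design choice: forcing a technically failed well beyond the
detection limit would inject Ct ≈ 40 values into abundantly expressed
genes and corrupt every stability score (we observed exactly this
before separating the two missingness kinds). Imputed values exist
only for stability scoring and the TOST screen; they are discarded
("set to missing again") before differential expression, and the test
suite asserts DE never sees them.

Four voters rank each candidate (lower = more stable in all four):

- **geNorm**: M_i = mean over j≠i of SD(Cq_i − Cq_j), with classic
  iterative worst-gene elimination; ranking is the reverse elimination
  order, final pair tied at 1.5. The reported M is the full-panel
  first pass.
- **comparative ΔCt**: the same pairwise-SD mean, single pass — kept
  as an independent implementation (explicit double loop) so the two
  methods are genuinely distinct voters and cross-check each other.
- **BestKeeper**: per-gene Cq SD (n−1), ranked; CV% and the Pearson r
  with the per-sample mean index are reported but not ranked (SD is
  BestKeeper's primary exclusion criterion). Zero-variance genes get
  r = 1 by convention.
- **NormFinder**: per group, two-way (gene × sample) centering yields
  residual variances with the small-panel bias correction
  v̂_ig = k/(k−2) · (z_ig − Σ_l z_lg/(k(k−1))), clipped at 0; gene- and
  group-centred means give biases d_ig, shrunk by
  d̃ = d·γ²/(γ² + v̂/n) with γ² the across-gene bias variance net of
  sampling noise; stability = mean_g |d̃_ig| + mean_g √(v̂_ig/n_g).

Consensus: geometric mean of the four ranks (average ranks on ties),
ties broken by geNorm M. References must additionally be
TOST-equivalent between END and CNT (Welch two one-sided tests,
margin 0.5 Ct ≈ 1.4-fold — no published margin exists for this assay,
so a conventional negligible-effect bound is the default and is fully
configurable) and detected in ≥ 95% of samples. The per-sample
normalization factor is the arithmetic mean of the k = 3 reference
Cqs, observed values only; samples missing a reference post-QC are
dropped with a warning (a 2-of-3 mean would shift the factor), with a
mean-of-available option.

Known behaviour: NormFinder's bias term is gene-centred, so a
zero-effect gene inherits (minus) the panel-average group effect. On
small panels with several planted effects this can let a
near-equivalent gene displace a planted reference; the effect scales
as 1/(panel size) and disappears at the 130–230-candidate scale the
pipeline operates at (full-scale recovery is asserted in the
acceptance suite at ≥ 9/10 seeded runs).

## Differential expression

ΔCt_is = Cq_is − factor_s; because the raw limit is common, the
normalized censor point is per-sample: L_s = 40 − factor_s. Per target
and comparison, `tobit_two_group` fits ΔCt* = β0 + β1·case + ε with
those limits; ΔΔCt = β1, FC = 2^(−β1) (lower Ct = more abundant, hence
the sign). The ≥ 75% detection filter is applied per comparison pair
("either group" is pair-specific). Reference miRNAs are excluded from
testing. Raw p-values drive the significance calls (conventional for
confirmatory qPCR panels); BH q-values are emitted as a column. The
wide summary masks cells with p ≥ 0.1 as "-", mirroring the usual
reporting convention.

## Enrichment

One hypergeometric ORA engine replaces database-specific algorithms:
any collection (GO, KEGG, Reactome, ...) is just a GMT input. The
default universe is every gene reachable through the supplied
validated miRNA→gene map — the space the assay can speak about — not
the union of pathway genes; it is overridable. p = P(X ≥ k) with
X ~ Hypergeom(N, K, n); BH FDR across tested pathways.

## Synthetic cohorts

The generator emulates the study design the package targets: 754
targets; 60 CNT + 40 OMA + 27 DIE samples; detection limit Ct = 40.
Because serum panels detect only a minority of targets, baseline means
are a two-component mixture: an expressed fraction (default 20%) with
μ ~ U(22, 34) and the rest at μ ~ U(38, 50); per-target
σ ~ U(0.5, 2.5). This lands the detected-in-≥75% count in the
~130–230 range out of 754, matching real serum cohorts; a single
uniform μ range cannot reproduce that profile. Planted references have
group-invariant μ ~ U(24, 30) and σ ~ U(0.15, 0.35) — serum reference
miRNAs are empirically far more stable than the panel average, and the
band is chosen once, below the generic σ floor, so that "stable
reference" is a property of the stated world rather than a tuning
knob. Planted group effects (default 20 targets, |ΔCt| ∈ [0.5, 4],
random sign, applied to all END samples) are placed on expressed
targets, since recovery is only defined for quantifiable features; the
effect range spans fold changes ≈ 0.06–16. Hemolysis is simulated by
pushing miR-451a (the red-blood-cell miRNA) *down* until
ΔCq(miR-23a-3p − miR-451a) ∈ [8, 12]; clean samples sit near ΔCq ≈ 4.5.
QC-failing wells keep their Cq but carry a failing covariate, so well
QC, not generation, removes them.

What the generator does **not** emulate: plate/position effects,
inter-assay drift, pre-amplification chemistry, non-normal Ct tails,
and correlated miRNA co-regulation. A green recovery test therefore
establishes that the pipeline inverts its own stated data model — not
that it is robust to artefacts outside that model.

## Numerical and design choices

- Seeds: a single pipeline seed is expanded via
  `SeedSequence.spawn` into per-stage substreams; identical
  config + seed reproduces every output byte for byte.
- geNorm's vectorised pairwise SD is computed from the explicit
  difference tensor (not the covariance identity) to agree with the
  brute-force definition to 1e-12.
- Tobit p-values are Wald by default; the likelihood is exposed for
  LRT-style diagnostics.
- Fold changes follow the standard relative-quantification convention
  FC = 2^(−ΔΔCt) throughout.
- Acceptance-suite Monte-Carlo sizes: estimator bias at 200
  replicates, tobit type-I error and TOST boundary size at 1000
  replicates each, end-to-end recovery at 10 full-scale seeded runs
  (scaled from 100 to fit a single-CPU budget; the success threshold
  stays at 90%).

## Limitations

- No covariate adjustment (age, BMI, menstrual phase) in the tobit
  model; no random effects.
- The TOST margin and the screening order (TOST and detection applied
  at selection time over all filtered candidates) are conventions;
  both are configurable.
- BestKeeper is reduced to its descriptive statistics with SD ranking;
  the original's pairwise correlation matrix is not reproduced.
- ORA assumes exchangeable genes within the universe; no
  expression-level bias correction.
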