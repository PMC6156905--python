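# Methods

This note documents the statistical models, the synthetic cohort generator,
the numerical choices, and the limitations of `famethyl`.

## The testing problem

Each analysis unit is one SNP–CpG pair. For subject *j* in family *i*, both
outcome settings are linear models on log triglycerides with mean

```
E[y_ij] = β0 + βG·G*_ij + βM·M*_ij + βGM·(G*·M*)_ij + βage·age + βsex·sex
          + center dummies [+ βpre·log TG_pre  (Pre/Post setting only)]
```

where `G*` and `M*` are the SNP dosage and CpG methylation standardized
within the replicate, and `y` is log post-treatment TG (Pre/Post) or the
post-minus-pre log difference (Change). The null hypothesis of interest is
`βGM = 0`, tested by a two-sided Wald statistic against the standard normal
(n = 680 subjects; no degrees-of-freedom reference is applied, for any
variant — the BC variants change only the covariance, never the estimate).

## Estimators

**Kinship LME.** `y = Xβ + g + ε`, `g ~ N(0, σ_g²·2Φ)`, `ε ~ N(0, σ_e²I)`,
with Φ the kinship matrix from the pedigree recursion (founders φ(i,i)=½,
φ(i,j)=0; non-founder i with parents f,m: φ(i,j)=½[φ(f,j)+φ(m,j)],
φ(i,i)=½[1+φ(f,m)]). The fit eigendecomposes 2Φ once (shareable across
fits on the same cohort), rotates (y, X), profiles β and σ_e² out of the
REML criterion, and optimizes δ = σ_g²/σ_e² by a 61-point log-grid on
[1e−8, 1e4] followed by bounded Brent refinement (xatol 1e−10 on log δ).
REML is the default (ML available); the rotated likelihood is tested to
1e−6 against a dense multivariate-normal evaluation. The Wald covariance is
the model-based `(XᵀΣ̂⁻¹X)⁻¹`.

**GEE.** Identity link, Gaussian working variance `A_i = φI`, independence
or exchangeable working correlation. β solves the usual weighted estimating
equation by iterated GLS with moment updates: `φ̂ = Σê²/(M−p)` and
`α̂ = Σ_i Σ_{j<k} r_ij r_ik / (½Σn_i(n_i−1) − p)` on Pearson residuals (the
standard Liang–Zeger choices; the source analyses name the structure but
not the estimator). Convergence: max|Δβ| < 1e−8, max 100 iterations;
non-convergence is flagged, not raised. α̂ is clipped into the
positive-definite range for the largest cluster with a logged warning.
Covariances: model-based bread inverse, the robust sandwich `B⁻¹MB⁻¹`, and
the Mancl–DeRouen correction in which each cluster's residual is
premultiplied by `(I − H_i)⁻¹`, `H_i = X_i B⁻¹X_iᵀV_i⁻¹`. The exchangeable
inverse is applied in closed form, with clusters batched by size, so a
680-subject fit costs a few milliseconds.

**QIF.** The inverse exchangeable correlation is expanded over `M₁ = I` and
`M₂ = J − I`, giving extended scores `g_i(β)` of length 2p; β minimizes
`Q_N = N·ḡᵀC_N⁻¹ḡ` with `C_N = N⁻¹Σ g_i g_iᵀ` by the two-step GMM scheme
(freeze C at the current β, exact Newton step — the scores are linear in β —
iterate to the fixed point; tolerance 1e−8). Singleton families contribute a
structurally zero M₂ block and stay in the design with zero padding. The
working scale φ̂ comes from a GEE-independence prefit; the estimator and
both covariances are invariant to it. A near-singular C_N is ridged by
`1e−10·tr(C)/dim` with a logged warning.

**QIF small-sample covariance (QIF-BC).** The plain GMM covariance
`N⁻¹(JᵀC_N⁻¹J)⁻¹` is biased downward at a few hundred families for two
distinct reasons, and the corrected covariance removes both:

1. *residual shrinkage* — as in Mancl–DeRouen, C_N is rebuilt from scores
   computed on `(I − H_i)⁻¹ê_i` (independence-working cluster hat matrix);
2. *estimated weighting matrix* — C_N is a q×q covariance (q = 2p ≈ 18)
   estimated from only N = 164 cluster scores; the inverse of such an
   estimate is biased upward by the usual Wishart-inverse factor, so the
   plug-in covariance is too small by roughly (N−q−1)/N. The corrected
   covariance is rescaled by N/(N−q−1).

With nuclear families the cluster leverages are small and step 1 alone
leaves the QIF Wald test anti-conservative (empirically ~0.078 at nominal
0.05 on 1000 null tests; the plain QIF sits near 0.085–0.09, a level
confirmed by an independent QIF implementation on the same data). Adding
step 2 restores nominal calibration (~0.056). Both adjustments vanish as
N → ∞, so the corrected covariance reduces to the plain one in the
many-cluster limit. Published QIF corrections differ in exactly which of
these terms they target; this combination is the package's choice and is
validated by the null-calibration test rather than by matching any single
reference formula.

## Synthetic cohort generator

The generator emulates a family-based pharmacoepigenetic simulation with
known solutions, so operating characteristics can be recomputed without
restricted data.

* **Pedigree**: 164 nuclear families, 680 subjects. Offspring counts are
  allocated deterministically (140 families with 2 offspring, 24 with 3) so
  the cohort size is exact and runs are reproducible; truncated-Poisson
  sizes are available via `random_family_sizes`. The real study's pedigrees
  are deeper and more variable; see Limitations.
* **Genotypes**: founders Binomial(2, maf) with maf = 0.3 at every site
  (the source SNP set's frequencies are not published); offspring receive
  one allele per parent (Mendelian). Genotypes and methylation are redrawn
  each replicate; pedigree, covariates and effect sizes are fixed, as in a
  study where phenotypes are re-simulated on a fixed cohort.
* **Methylation**: i.i.d. Beta(2, 2) per causal CpG (see Calibration).
  Each noncausal CpG shares fraction f = 0.5 of its latent variance with
  its partner causal CpG (standardized causal signal mixed with Gaussian
  noise, mapped back to the methylation scale, clamped to [0, 1]).
* **Outcome**: on the log scale,
  `post = μ + covariates + Σ_k b_k·G_k·(1−M_k) + g + ε`, with
  `g ~ N(0, σ_f²·2Φ)`, σ_f = 0.3, σ_e = 0.45. The generative interaction is
  linear suppression — full expression at M = 0, full suppression at M = 1 —
  while the analysis models fit a product term; the two parameterizations
  agree exactly here (`b·G·(1−M) = b·G − b·G·M` lies in the span of the
  fitted terms, so the estimand of the standardized product coefficient is
  `−b·σ_G·σ_M`).
* **Baseline**: `pre = μ_pre + a·(covariates + g) + noise`, anchor a = 0.6,
  σ_pre = 0.35. The causal pharmaco-response term is deliberately excluded,
  so baseline adjustment cannot absorb the signal under test.
* **Covariates**: age ~ N(49, 16²) clipped to [18, 95] with slope 0.004 per
  year on log-TG; sex (0/1) with −0.12; three study centers with effects
  (0, 0.05, −0.05), dummy-coded against the first.
* **Effect calibration**: `b = sqrt(h2·V0 / Var(G(1−M)))` in closed form,
  where `V0 = σ_f² + σ_e² + Var(covariates)` is the null-model variance of
  post log-TG and `Var(G(1−M)) = E[G²]E[(1−M)²] − E[G]²E[1−M]²` with G ⟂ M.
  Causal heritabilities are {0.125, 0.10, 0.075, 0.05, 0.025}.
* **Seeding**: one master seed; the pedigree/covariate stream and each
  replicate use distinct `SeedSequence` children, so a replicate is
  bit-reproducible and independent of how many others are drawn.

### Calibration of the heritability → effect-size mapping

The reference study reports per-site power and Type I error but not the
mapping from expected heritability to simulated effect size, the SNP
frequencies, or the methylation distribution. The share of a causal term's
variance that is attributable to the *pure interaction* (the component the
Wald test actually sees after the main effects are adjusted out) is
`Var(G)·Var(M) / Var(G(1−M))`, so it is governed by the methylation
variance. A uniform methylation distribution puts ≈21 % of the causal
variance on the product term and yields interaction power far above the
reported operating characteristics at every heritability. The generator
therefore uses Beta(2, 2) methylation (interaction share ≈15 %), chosen by
an analytic noncentrality calculation and one Monte-Carlo comparison
against the reported kinship-LME power column, and frozen thereafter. With
these defaults a 200-replicate run reproduces the reference pattern
(Pre/Post LME power ≈0.91/0.83/0.69/0.52/0.30 across the five
heritabilities; pooled Type I ≈0.05). The calibration targets the LME
column only; the behaviour of all other variants is emergent.

## What the generator does and does not emulate

Passing tests show that the estimators have the right operating
characteristics **under this generator**: exchangeable-plus-kinship family
correlation, i.i.d. unimodal methylation, exact linear suppression, complete
data, and modest nuclear families. Real cohorts differ in ways that matter:
bimodal methylation, larger multigenerational pedigrees (bigger cluster
leverage, so stronger small-sample corrections), shared environment,
missingness, and LD between test SNPs. In particular the uncorrected
GEE sandwich is only mildly anti-conservative here because nuclear-family
leverage is small; with the real pedigrees its inflation is reported to be
larger.

## Numerical and design choices

* Standardization uses the within-replicate sample SD (ddof = 1); a
  zero-variance SNP or CpG in a replicate skips the site with a logged
  reason.
* Non-converged fits keep their scan row with p = NaN and leave the
  power/Type I denominators (logged); in practice all default-scenario fits
  converge.
* Genome-wide threshold: Bonferroni 0.05/461281 ≈ 1.08e−7, reflecting a
  typical epigenome-wide CpG count; at the simulated effect sizes almost
  nothing survives it, as expected.
* The scan's problem sizes — 200 replicates × 10 sites × 2 settings ×
  5 variants — run in a few minutes on one CPU; examples use 40 replicates
  for quick inspection. These sizes are the study conditions, with
  Monte-Carlo SE ≈ 0.035 on a power of 0.5 at 200 replicates.
* Ties between the two settings' power are possible and allowed for in the
  directional checks (Monte-Carlo slack 0.035–0.045).

## Limitations

* The h²→effect mapping is a reconstruction; per-site power is matched
  approximately (the lowest-heritability site and both Type I errors
  closely; mid-column sites within a few points), not replicated exactly.
* Only exchangeable working structures and the two basis matrices are
  implemented (no AR(1)/unstructured), only Gaussian outcomes, and only
  Wald inference — matching the scope of the evaluation the package
  reproduces.
* X-linked kinship, inbreeding-loop-specific corrections beyond what the
  recursion naturally handles, and identity-by-descent estimation from
  genotypes are out of scope.
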