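# Methods

This note documents the models implemented in `gpselect`, the assumptions of
the synthetic-data generator, the numerical choices, and the limits of what
the test suite demonstrates.

## De-regressed proofs

A progeny-tested bull's EBV blends parent-average (PA) information with
progeny information.  Used directly as a pseudo-phenotype it double-counts
the parents, so the PA contribution is removed and the deviation re-expanded
by its information content:

    α        = (4 − h²)/h²
    EDC(R)   = α·R/(1 − R)               (effective daughter contribution)
    REL_PA   = (REL_sire + REL_dam)/4
    EDC_prog = EDC_EBV − EDC_PA
    DRP      = PA + (EBV − PA)·EDC_EBV/EDC_prog

Records with `EDC_prog ≤ 0` (parent information exceeding own information)
cannot be de-regressed; they are flagged and excluded, never clipped, and the
count is logged.  Missing parent reliabilities are treated as 0
(conservative).  `EDC_prog` is carried to the output as the natural weight
of a DRP; REML is unweighted by default — the large-scale GREML tools this
workflow mirrors do not support record weights — and a weights option
exists for sensitivity analyses.

## Genomic relationship matrices

Off-diagonals are always `(1/N)Σᵢ (x_ij − 2pᵢ)(x_ik − 2pᵢ)/(2pᵢ(1−pᵢ))`.
Two diagonal conventions:

* `yang` (default, the convention of the GREML literature):
  `1 + (1/N)Σᵢ (x_ij² − (1+2pᵢ)x_ij + 2pᵢ²)/(2pᵢ(1−pᵢ))`.
* `crossprod`: exactly `W Wᵀ/N` with `w_ij = (x_ij − 2pᵢ)/√(2pᵢ(1−pᵢ))`.
  PSD by construction; the back-solving identity (below) assumes this form.

Allele frequencies are always recomputed on the analysis sample (per cohort
for cohort-restricted GRMs); variants monomorphic within a cohort are
dropped from that cohort's GRM, since they carry no relationship information
there and their scaling divides by zero.  Missing genotypes are mean-imputed
at load.  GRMs whose smallest eigenvalue falls below `1e−6 × mean(diagonal)`
are bent — eigenvalues floored at that bound and the matrix reassembled —
and every bending event is logged: small selected sets of variants in strong
mutual LD make the yang-diagonal GRM indefinite, and this pathway is part of
the phenomenon under study, not a nuisance.  Positions are 1-based; LD
windows are closed intervals `[bp − w, bp + w]`.

The LD-significance test behind the complementary-set exclusion is the
allelic-correlation statistic `n·r² ~ χ²(1)` on dosages, the standard choice
when the tool chain does not document its test.

## GREML

Average-information REML for `V = Σ_k K_k σ_k² + I σ_e²` (one or two GRMs),
restricted log-likelihood `−½(log|V| + log|XᵀV⁻¹X| + yᵀPy)`.  The first step
is always EM; afterwards AI updates with EM fallback whenever the AI system
is singular, proposes an inadmissible move, or decreases the likelihood.
Components are floored at `1e−6·var(y)` and floor activations are logged.
Convergence is `|Δ logL| < 1e−8` (default, `maxit` 100); non-convergence is
returned as a flag with the last iterate, never an exception.  Standard
errors come from the inverse AI matrix; genomic heritabilities
`σ_k²/Σσ²` carry delta-method SEs.  Everything is dense — at desk scale
(n ≤ a few thousand) factorizing V exactly is cheaper than approximating it.

## Association scan

The null model `y = 1μ + g + e`, `g ~ N(0, K σ_g²)`, is fitted once by REML
on a structure GRM built from the HD-like panel subset; σ² are then fixed
and every variant is tested by GLS under `V`: `b̂ = (x̃ᵀV⁻¹x̃)⁻¹x̃ᵀV⁻¹ỹ`
with intercept projection (estimates are therefore invariant to dosage
centering), Wald `χ²(1)` p-values, `var(b̂) = (x̃ᵀV⁻¹x̃)⁻¹`.  Candidate
markers may sit inside the structure GRM (proximal contamination accepted —
the common practice when the structure GRM is a fixed chip panel); a
leave-one-chromosome-out scan is available as a non-default alternative
(`scan_loco`).  Zero-variance variants
are emitted with p = 1 and a degenerate flag.  P-values that underflow are
reported at the smallest positive double.

## Conditional-and-joint selection

Forward selection on individual-level data under the fixed null covariance:
whitening by the Cholesky factor of `V⁻¹` makes the residual variance
exactly 1 under the null model, so conditional tests are known-variance Wald
tests, identical to the marginal scan statistic at step 0.  Modes:

| mode       | prefilter | entry −log10(p) | r² cap | LD horizon |
|------------|-----------|-----------------|--------|------------|
| COJO3      | 3         | 3               | 0.8    | unlimited  |
| COJO5      | 3         | 5               | 0.8    | unlimited  |
| COJO5LD    | none      | 5               | 0.5    | 100 Mb     |
| COJO_TOPN  | none      | top 100         | 0.5    | 100 Mb     |

Pairs farther apart than the horizon (or on different chromosomes) are
treated as independent.  A candidate is accepted only when its conditional
`−log10(p)` clears the gate **and** the df-adjusted joint residual variance
strictly decreases (tolerance `1e−12·var(y)`); candidates whose whitened
genotype retains less than `1e−16` of its squared norm after projection on
the current design (condition number > 1e8) are rejected as collinear.  All
rejections (LD cap, no-variance-gain, collinearity) are recorded in an audit
table, and ties are broken by ascending (chromosome, bp, id), making the
selection order deterministic.  The exact individual-level fit replaces the
summary-statistic approximation deliberately: at desk scale it is simpler
and better conditioned, and the two coincide when the LD reference is the
analysis sample.  The top-100 mode ranks by conditional significance by
default, with an |effect| option, since either reading of "largest effect"
is defensible.

The complementary set (GRMc) for COJO selections excludes the selected
variants plus everything in significant LD (p < 0.01) within ±2 Mb; plain
p-value selections exclude only the selected variants themselves.

## GBLUP, back-solving and validation

Training on discovery animals only: `ĝ_k = σ_k² K_k V⁻¹(y − 1β̂)` per
component, GLS intercept `β̂` as the scoring mean offset (the reference
tool chain does not document intercept handling; this choice makes training
scores mean-consistent).  Effects are back-solved per component,
`u = (1/N)WᵀK⁺ĝ`, `a_i = u_i/√(2pᵢ(1−pᵢ))`, and validation animals scored
as `Σ aᵢ(x_ij − 2pᵢ) + β̂` with training frequencies; two-component models
sum the per-component scores.  `K⁺` truncates the component GRM's spectrum
at a relative `1e−8`: directions below that bound carry O(1e−8) of the
breeding values but amplify floating-point noise by the inverse eigenvalue,
and with LD the spectrum decays continuously into that zone.  When the
training GRM used the yang diagonal, back-solving substitutes the crossprod
factorization, warns, and reports the maximum training-GEBV reconstruction
discrepancy.

Validation metrics: accuracy = Pearson correlation of DRP and GEBV; bias =
OLS regression of DRP on GEBV (slope < 1 ⇒ over-dispersed predictions).  The
DRP is treated as a noiseless target; no reliability correction is applied.

## The synthetic-data generator

What it emulates:

* **Family structure.** Half-sib pedigrees: tracked sires, unknown dams
  drawn from an effectively infinite unrelated population sharing the
  founder allele frequencies.  The last generation forms the validation
  cohort, so every validation bull's sire is in the discovery data (the real
  analogue: 84% of validation sires in discovery).
* **LD.** Founder haplotypes from a latent Gaussian AR(1) field
  (autocorrelation `ld_rho`, default 0.98) thresholded at per-variant
  frequency quantiles — a first-order Markov chain on the latent scale.
  Adjacent-variant allelic r² is a monotone function of `ld_rho`; the
  default produces the towers of mutually redundant variants around each
  association peak that make threshold selection pathological, the regime
  sequence-level data live in.  The MAF floor is enforced by clipping the
  threshold count, so realized founder MAF ≥ `maf_low` deterministically.
* **Recombination.** Haldane map function on bp-proportional distance,
  default 1 Morgan per 100-Mb chromosome.
* **Trait architecture.** `n_qtl` large-effect QTL (default 50, N(0,1)
  per-allele effects, or equal-variance effects for replicated experiments)
  carrying `qtl_weight` (default 0.4) of the genetic variance, on a dense
  polygenic background over all variants.  Dairy traits are
  majority-polygenic with a handful of large QTL; a pure-QTL trait
  (`qtl_weight=1`) is available for truth-recovery tests.
* **Records.** Per bull `EDC_EBV ~ U(24, 971)` (the printed range of a
  protein-yield evaluation), `REL = EDC/(EDC + α)`; the EBV combines the
  sire-derived PA with an independent progeny-deviation record by Bayesian
  information weighting.  For bulls without parent information this gives
  exactly `EBV = R·T + e`, `var(e) = R(1−R)var(T)`, and for all bulls the
  de-regression round-trips with `cor(DRP, TBV)² ≈ EDC_prog/(EDC_prog+α)`.

What it does not emulate: imputation error, genotyping platforms, selection
of sires on the trait (no selection response), multi-trait national
evaluations (DRP noise is independent across bulls, so there is no shared
evaluation noise between cohorts), and mutation.  Passing tests therefore
show that the algorithms are correct and that the selection-bias mechanism
operates through data reuse and LD alone; they do not calibrate real-data
accuracies.

## The selection-bias experiment

`pipeline.selection_bias_replicate` is the package's scaled-down version of
the central empirical comparison: ~1,525 discovery and 500 validation bulls
(25 sires × 20 sons × 4 generations), 20,000 variants on five 100-Mb
chromosomes, 50 QTL at `qtl_weight` 0.4, trait h² 0.6.  Each replicate runs
the full chain twice — all-variant GRM versus the GRM of variants passing
`−log10(p) > 5` in a discovery-only GWAS — with selection and training
reusing the same discovery data.  Training GRMs use the yang diagonal with
bending (the study's convention; for tower-heavy selected sets the bending
and variance inflation are part of the observed phenomenon) and effects are
back-solved through the crossprod factorization.

At this scale the direction of the effect — preselection costs validation
accuracy and depresses the regression slope — is reproducible across
replicate batches; the accuracy loss is large and extremely stable, while
the slope gap is noisier because REML variance components on a
few-dozen-variant GRM have large sampling error (an effect the full-scale
study, with thousands of selected variants and n = 3,416, does not suffer to
the same degree).  The acceptance suite asserts the joint direction in
≥ 8/10 replicates.

## Problem sizes in the test suite

Replicated suites use: GREML recovery n = 1,000 × m = 5,000 × 20 replicates;
scan calibration n = 500 × m = 5,000; selection oracles n ≤ 1,000 × m ≤ 500
with exhaustive enumeration up to 12 candidates; bias experiment as above ×
10 replicates.  These sizes are the package's desk-scale operating point:
large enough for the asymptotics the assertions rely on, small enough to run
on a single CPU.
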