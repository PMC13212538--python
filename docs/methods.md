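# Methods

This note documents the statistical models implemented in `metstab`, the
conventions chosen where the literature is ambiguous, and what the
synthetic-data validation does and does not establish.

## Data model and scope

The unit of input is a balanced multi-environment trial: `g` genotypes ×
`e` environments × `r` replicates, laid out as a randomized complete
block design within each environment, for one or more numeric traits.
All fixed-effect methods (AMMI, GGE, the parametric indices) operate on
the genotype × environment matrix of cell means `X_ij`; the mixed model
uses replicate-level data.  Incomplete matrices are rejected by these
methods rather than imputed: imputation under crossover G×E needs a model
of its own and would silently change every downstream index.  The
environmental index (environment mean − grand mean) classifies an
environment as favorable when strictly positive; a zero index counts as
unfavorable (no tie rule exists in the conventions we follow, so the
conservative side was chosen).

## Culm mechanics

Derived culm-strength traits treat the basal internode as a hollow oval
tube: section modulus `SM = (π/32)(a₁³b₁ − a₂³b₂)` from the outer (a₁,
b₁) and inner (a₂, b₂) oval diameters in mm, bending stress
`BS = (TR/40)(1000/TN)` from the prostrate-tester reading TR and tiller
number TN, and bending moment at breaking `M = SM·BS`.  Two deliberate
switches exist: `convention="standard"` divides SM by the outer major
radius (the textbook section modulus of a hollow oval), and the
calibration constant 40 in BS is an argument because prostrate-tester
conventions vary between instruments.  The default follows the field
formula as used; no unit conversion is applied to `M` (it is returned in
SM·BS native units).

## AMMI

The means matrix is decomposed as
`X_ij = μ + g_i + e_j + Σ_k λ_k γ_ik δ_jk` with the SVD of the
double-centered matrix.  Conventions:

* `K* = min(g, e) − 1` axes; eigenvector sign fixed by making each
  genotype eigenvector's largest-magnitude element positive (outputs are
  reproducible; all derived statistics are sign-invariant anyway).
* Combined ANOVA from replicate-level data; IPCA k takes Gollob df
  `g + e − 1 − 2k` and SS `r·λ_k²`; F-tests of GEN, GEN:ENV and the
  IPCAs use the pooled residual mean square.  The ENV mean square is
  tested against REP(ENV) — environments are blocks' parents, so the
  replicate-within-environment stratum is its natural error line; the
  table records this convention in its metadata.
* Biplot scores default to symmetric singular-value scaling (`λ^0.5` to
  each side); genotype-metric and environment-metric scalings are
  options.  The number of axes entering axis-limited statistics is set by
  an `axes_rule`: `first`, `f-significant` (consecutive IPCAs passing the
  Gollob-df F-test at α = 0.05) or `all`.  An axes rule that retains no
  axis raises an explicit error rather than silently falling back.

## Stability indices

Parametric measures follow their classical definitions; two points needed
a decision:

* **Superiority (Pi).**  Implemented as Lin–Binns superiority,
  `Pi = Σ_j (X_ij − M_j)²/(2q)` with `M_j` the environment-wise best
  genotype — the form consistent with its verbal description ("distance
  from the best") and with the ordering it is expected to produce (the
  worst genotype scores highest).  A `pi_variant="mean"` option returns
  the plain across-environment mean for comparison.
* **AMMI index family.**  All formulas use `λ_n` = the n-th *singular
  value* of the double-centered matrix and `γ_in` the genotype
  eigenvector entries.  This is the convention under which the advertised
  identities actually hold: with all axes, W(AMMI)/FA `= Σ λ_n²γ_in²`
  reduces exactly to Wricke's ecovalence, and AMGE row sums vanish.
  SIPC's `|λ^0.5 γ|` terms are then precisely the symmetric-scaled
  scores.  Explained proportions `θ_n` enter Z_a/ASI/MASI as fractions
  (0–1); this is a constant factor that leaves every ranking unchanged.
  Axes with zero singular value are masked so that a zero-interaction fit
  yields zero for every statistic (their eigenvectors are arbitrary).
* ASV/ASI/MASI/MASV use the standard Euclidean forms
  (`ASV = √[((SS₁/SS₂)s₁)² + s₂²]` etc.); with two retained axes the
  modified statistics collapse to ASV/ASI exactly.
* Ranks use average ties; GSI can therefore be fractional under ties.
  The Annicchiarico index uses the percent-of-environment-mean scale with
  sample sd (ddof = 1) and `z` at 1 − α, α = 0.25 by default (a commonly
  used 75% confidence level for this index).

## REML and BLUP ("gamem")

The fully random model `Y_ijr = μ + g_i + e_j + rep_r(j) + ge_ij + ε_ijr`
is fitted by REML.  For a balanced trial the five ANOVA strata (GEN, ENV,
REP(ENV), GEN:ENV, residual) are orthogonal eigenspaces of the marginal
covariance, so the restricted likelihood decomposes exactly into
`−2lR = Σ_s [df_s ln θ_s + SS_s/θ_s]` with stratum variances linear in
the five components.  The implementation maximizes this form with the
components bounded at zero (L-BFGS-B from the truncated expected-mean-
squares start).  Consequences: the fit is exact (no large-matrix
likelihood approximation), equals the EMS closed form whenever that
solution is interior, and costs milliseconds — which is what makes the
Monte-Carlo recovery and coverage checks cheap.  Unbalanced data are out
of scope for this module and rejected.  Standard errors come from the
expected Fisher information of the stratum likelihood; they are reported
as NaN for components estimated on the zero boundary, where the
asymptotic approximation fails.

BLUPs solve Henderson's mixed-model equations at the REML estimates
(dense solve; the coefficient matrix is a few hundred rows at trial
sizes).  Genotypic values are `GV_ij = μ̂ + ĝ_i + ê_j + ĝe_ij` with the
environment effect at its BLUP, feeding HMGV (harmonic mean of GV), RPGV
(mean of GV relative to the observed environment mean) and HMRPGV
(harmonic mean of the ratios); all require strictly positive GV.
Likelihood-ratio tests refit with one component pinned to zero and refer
`2Δl` to χ²(1); a boundary-corrected option halves the p-value (50:50
mixture), the plain χ² being the default reporting style.

## WAASB, WAASBY, MTSI

WAASB is the explained-proportion-weighted mean of a genotype's absolute
SVD scores, computed from the BLUP interaction matrix (WAAS uses the
fixed-effect double-centered means instead).  Scores use the same
symmetric scaling as the AMMI biplots.  For WAASBY, mean and WAASB are
first rescaled to 0–100 (100 = best mean under the trait's desired
direction; 100 = lowest WAASB) and blended with weights summing to 100
(default 65/35).  The rescaling step is required for the blend to live on
the 0–100 scale its users expect; a constant column cannot be rescaled
and raises an explicit error.  Quadrants classify genotypes against the
across-genotype average mean and average WAASB (IV = desirable mean,
below-average WAASB).

MTSI runs an exploratory factor analysis on the genotypes × traits
WAASBY matrix: correlation-matrix eigendecomposition, Kaiser retention
(eigenvalue ≥ 1, overridable), varimax rotation (delegated to
statsmodels' factor-rotation routines, with a small fixed pre-rotation to
avoid the symmetric saddle gradient rotation can stall on), and
regression-method scores `F = Z R⁻ L` using the pseudo-inverse so that
exactly collinear traits (noiseless latent structure) remain
well-defined.  The ideotype scores 100 on every trait and is projected
through the same weights; MTSI is the Euclidean distance to it in factor
space.  Selection takes the `ceil(intensity·g/100)` lowest-MTSI genotypes
and includes any genotype tied exactly at the cutpoint, so the selected
set can exceed the nominal count.  Selection differentials report
`Xo, Xs, SD, SD%` per trait and, when heritabilities are supplied,
expected gains `SG = SD·h²`.

## GGE

The site-regression model removes only environment means and SVDs the
rest.  The defaults mirror common practice: environment centering, no
scaling (sd scaling available), environment-metric singular-value
partitioning.  Which-won-where computes the convex hull of genotype
points in the PC1/PC2 plane; sector rays are the outward perpendiculars
of the hull edges through the origin (counterclockwise hull orientation
fixes the outward side), sectors are half-open counterclockwise angle
intervals, an environment belongs to the sector containing its vector's
angle, and the sector winner is the hull vertex maximising the biplot
inner product there.  Winners provably equal the per-environment argmax
of centered means whenever PC1+PC2 carry 100% of the variation; on
full-rank data the 2-D view is an approximation, as in any biplot.  The
average-environment axis (AEA) is the normalized mean of environment
points; mean-vs-stability projects genotypes on it (signed) and reports
the unsigned perpendicular deviation; the ideal point sits on the AEA at
the longest mean projection; discriminativeness is the environment vector
length and representativeness its cosine with the AEA.

## Synthetic generator

`simulate_met` draws from the fitted model family itself:
`Y_ijr = μ + g_i + e_j + b_r(j) + ge_ij + ε_ijr`, all Gaussian.  The
interaction is generated as the exact orthogonal decomposition of an iid
`N(0, σ²ge)` matrix — independent grand/row/column margin draws at their
iid-implied variances plus a double-centered bilinear core
`Σ_k √λ*_k u_ik v_jk` with column-centred orthonormal scores (QR of
centred Gaussians) and a geometric eigenvalue profile (ratio ½) totalling
`(g−1)(e−1)σ²ge`.  This construction serves two masters at once: the
classical expected mean squares hold exactly, so REML recovers the
configured variances without bias; and AMMI/GGE, which see only the
double-centered core, face a *known, distinct* singular-value spectrum,
making which-won-where, IPCA-proportion and WAASB oracles exact.

Multi-trait panels correlate genotype effects through a trait × factor
loading matrix (scores and uniquenesses standard normal), so factor
analysis of generated data has a known target structure.  The default
panel mirrors a rice culm-strength/yield trial: 30 genotypes × 4
environments × 3 replicates, 19 traits in six latent groups (loading
0.85), means and scales at realistic field magnitudes (breaking
resistance ≈ 847 g, grain yield ≈ 528 g/m², section modulus ≈ 17 mm³,
...), and internode length and days-to-flowering marked lower-is-better.
`simulate_elite_panel` plants unambiguously superior genotypes (large
main effect, zero interaction) for selection-recovery experiments.

What the generator does **not** emulate: unbalancedness beyond simple
cell dropout, heteroscedastic residuals across environments, non-Gaussian
traits, spatial field trends, and genetic relatedness among genotypes.
Passing tests therefore establish the correctness of the computations and
the statistical behaviour under the assumed model — not robustness to
real-field artefacts.

## Problem sizes and numerics

The validation suite uses the trial's own dimensions (30 × 4 × 3) for
structural checks, 200 simulated trials for REML recovery (mean estimates
within 10% of truth), 100 for interval coverage, 50 rank-2 trials for the
which-won-where oracle, and 50 replicates of the planted-elite selection
experiment; these sizes give stable Monte-Carlo estimates while keeping
the whole suite in tens of seconds.  Numerical tolerances: SVD
reconstruction and SS conservation at 1e-8 absolute/relative, REML vs EMS
at 1e-6 relative, varimax communality preservation at 1e-8, and the
hand-decomposed toy fixture at 1e-10.  Degenerate inputs (zero
interaction, constant traits, collinear biplot points, non-positive
genotypic values) either produce well-defined zeros or raise typed errors
— never silent NaNs.
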