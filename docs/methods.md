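# Methods

## Model

The core object is a lag-1 vector autoregression over N network time
courses with a contemporaneous covariate term:

    Y_t = M · Y_{t−1} + C · Z_t + b + ε_t,   ε_t ~ N(0, diag(σ²))

`M = A + diag(B)` splits into the off-diagonal signed path coefficients
`A_jk` (the effective-connectivity matrix; entry [target, source]) and the
per-node autoregressive self terms `B_j`. The covariate `Z_t` is part of
the regression rather than being removed beforehand, so its influence is
estimated jointly with the paths. Assumptions: stationarity (spectral
radius of M below 1), linear dynamics at the sampling interval (TR = 2 s),
i.i.d. Gaussian innovations per node, and a single lag — higher orders
produce one coefficient matrix per lag with no agreed group-level reading,
so the order parameter is validated at 1 and not generalized.

Estimation is equation-by-equation OLS on the design
`[Y_{t−1}, Z_t, 1]`, which coincides with multivariate least squares for
an unrestricted VAR. Standard errors come from the per-equation unbiased
residual variance and the inverse design Gram matrix. An intercept is
always included even though the canonical equations omit it: without one,
any nonzero series mean contaminates every coefficient.

Two deliberate conventions:

- **Standardization (default on for group analyses).** Each network time
  course is z-scored per subject before fitting, so path coefficients are
  unitless and comparable across subjects — the implicit assumption of the
  group t tests, and consistent with reported coefficient magnitudes of
  ~0.1–0.2. This is an interpretive choice, not an estimation requirement;
  recovery-versus-truth checks fit with `standardize=False` because
  standardization rescales each coefficient by a ratio of stationary SDs.
- **Diagonal exclusion.** `path_matrix()` replaces the diagonal with NaN;
  self terms never enter edge statistics. The N²−N off-diagonal entries
  form the multiple-testing family (90 edges for ten networks). The
  diagonal also carries the classical autoregressive small-sample bias
  (≈ −0.03 at T = 230 with twelve regressors, vanishing with T), which is
  why estimator-consistency guarantees are stated for the off-diagonal
  path coefficients.

## Group statistics

Within-group: classical one-sample t per edge (t = mean·√n/SD, df = n−1,
two-sided p), Benjamini–Hochberg q values over the 90-edge family. Two
pattern rules are provided because published connectivity tables use
either: uncorrected `p<0.01` (the default for within-group patterns — it
is the rule consistent with the critical values implied by the reference
tables bundled in `effconn.reference`, |t| > 2.728 at df 34 and 2.861 at
df 19) and `fdr_q<0.05`. Edges with zero SD get t = 0 when the mean equals
the null value and ±∞ (p = 0) otherwise.

Across groups: `value ~ group + age + sex` by OLS; the group effect is the
partial F comparing full against group-dropped residual sums of squares,
df = (G−1, n−G−c). Sex is coded 0/1, the group factor as G−1 dummies,
adjusted means are evaluated at covariate grand means, and post hoc
pairwise contrasts of adjusted means are Bonferroni-multiplied by the
number of pairs (3 for three groups). Passing `None` for a covariate drops
it, which reduces the procedure to one-way ANOVA exactly — this identity
is tested.

## Degree metrics

Degrees count edges of the significant pattern: in-degree of x = edges
into x (row of the column-causes-row matrix), out-degree = edges out of x
(column). The in+out spread uses the sample SD (divisor N−1), which is the
convention that reproduces the published summaries (2.88, 2.99; the
population SD gives 2.73). Hubs: in+out ≥ mean + 1·SD, with ≥ because the
stated rule is "at least one SD above". Central sources/targets: maximal
out-/in-degree, ties kept. The rule is applied as stated even where a
published example deviates from it (one control-group node is described as
a hub at in+out 7 with cut 7.28; the implementation follows the rule).
Degenerate cases: an all-equal nonzero profile has SD 0, every node
passes the hub rule, and the profile is flagged `degenerate`; an empty
pattern reports no hubs.

## Extraction from volumes

Cleaning regresses each voxel/network series on `[1, nuisance]` (collinear
nuisance columns are dropped with a warning naming them) and applies a
zero-phase 4th-order Butterworth band-pass, default 0.01–0.10 Hz — the
standard BOLD band. Group reduction: temporal concatenation, SVD-based PCA
to `pca_dims` (default 40). Component count: the classical MDL model-order
estimator on the covariance eigenvalues (sphericity log-likelihood of the
trailing eigenvalues plus 0.5·k(2p−k)·log n), default 25 or `"mdl"` to
estimate. Unmixing: FastICA, parallel (symmetric) fixed-point extraction
with a seeded start — deterministic per seed. Components are ordered by
explained variance and sign-fixed so the largest-|z| voxel is positive,
removing ICA's sign indeterminacy before matching.

Back-reconstruction is **dual regression**: subject time courses are the
least-squares projection of subject data onto the group spatial maps, and
subject maps the projection onto those time courses. This is a documented
divergence from toolbox-specific PCA back-projection variants: dual
regression is closed-form, standard for the purpose, and directly testable
(exact on noiseless data).

Spatial maps are z-scored over in-mask voxels; active voxels satisfy
|z| > 1.5 *strictly*. The per-network activation summary `mean_active_z`
averages |z| over active voxels: the active set is two-tailed, so signed
averaging could fall below the threshold or go negative, inconsistent with
activation summaries that are uniformly positive and above threshold; the
magnitude convention is therefore used and documented as an
interpretation. Template matching is greedy on Pearson spatial correlation
in descending order, each component used at most once; correlations are
reported so users can screen poor matches (what to do when a template's
best match is noise is a screening decision, not an automated one).

## Synthetic cohorts

The generator runs the VAR forward and is the ground truth for every test.
Defaults emulate the three-group study design this package targets: groups
NC (n=35), LA-VCIND (n=32), LA-VaD (n=20); T = 230 retained time points at
TR = 2 s; ten networks; ages ~ N(62.8, 7.0²)/N(64.3, 9.7²)/N(65.7, 8.0²)
and group-specific male fractions matching the published demographics. The
default ground truths share a backbone of ~15 signed paths (magnitudes
0.11–0.16, signs following the control-group pattern: broad negative SVN
and DAN outflow, positive flow into aDMN), self terms of 0.3, innovation
SD 1; four connections take group-specific values equal to the published
group-mean coefficients of the altered edges. `planted_edge_ground_truths`
instead varies exactly one edge for specificity/power studies.

Choices the data model does not dictate, made once:

- Innovations are i.i.d. Gaussian per node and time point — the minimal
  structure matching the VAR residual term, keeping oracles closed-form.
- `Z_t` defaults to a slow sinusoid (120 s period, random phase per
  subject, amplitude 0.1 of the unit signal SD) with loading 0.05: the
  covariate's content is unspecified in the analysis design, so it is a
  configurable knob with a small, slow, nuisance-like default.
- 100 burn-in steps are discarded so retained series are approximately
  stationary.
- Demographic effects on coefficients are off by default (age/sex are
  nuisance covariates); an `age_effect` option injects a linear age slope
  on one edge for ANCOVA power studies.
- Non-stationary ground truths are refused at simulation time; at
  construction time, weights are shrunk uniformly to spectral radius 0.95
  and the factor reported.

Voxel mixing places one Gaussian blob per component (plus k pure-noise
components with independent time courses) on a small grid, adds i.i.d.
voxel noise, and refuses grids too small to keep maps pairwise correlated
below 0.5. This emulates *spatial mixing only*: no hemodynamic response
convolution, scanner drift, head motion, or lesion geometry. Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to real-fMRI artifacts; the preprocessing steps that
handle those artifacts upstream (realignment, normalization, smoothing,
motion regression) are outside this package's scope.

Determinism: every stochastic step takes a seed; the same seed reproduces
cohorts bit-for-bit and the PCA+ICA chain byte-identically on the same
machine.

## Numerical choices and problem sizes

- Rank deficiency in designs is detected via pivoted QR and reported by
  column name; fits refuse rank-deficient designs rather than silently
  regularizing.
- `pca_reduce` errors when the target exceeds the numerical rank, naming
  the achievable maximum; MDL eigenvalues are floored at 1e−12 of the
  largest to guard logs.
- The ICA wrapper raises (with the iteration count) if FastICA fails to
  converge rather than returning a partial result.
- In the bundled pipeline the band-pass is off by default: synthetic VAR
  series are generated directly at the network level, and filtering a
  VAR(1) process distorts its lag-1 coefficients; the filter is exercised
  and validated separately and is intended for real voxel data.
- Test and acceptance runs use scaled problem sizes chosen to exercise
  every code path at stable statistics: 12×12×8 voxel grids, 12–36
  subjects and T = 120–200 for ICA/pipeline runs, 200 subjects at T = 230
  for estimator bias/coverage, 500 replicates for error-control rates.

## Known limitations

- Lag order fixed at 1; no spectral or conditional Granger variants.
- Coefficient signs are reported, not interpreted (no excitatory or
  inhibitory claims).
- The between-subject variability of fitted coefficients in synthetic
  cohorts comes from estimation noise only (subjects within a group share
  one ground truth), so synthetic group SDs are smaller than those of real
  cohorts, where the truth itself varies per subject.
- Dual regression approximates, not replicates, toolbox-specific
  back-projection; absolute map values can differ even where recovered
  time courses agree.
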