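# Methods

## Model and procedure

A weighted network `G = (V, E, W)` with symmetric real `W (n x n)` (edge
weights, typically correlations in [−1, 1]) is scored in three stages.

**Embedding.** The double-centered Gram matrix is `B = s·J W J` with
`J = I − (1/n)𝟙𝟙ᵀ` and scale `s = ½` (the scale only rescales coordinates
and cancels in every comparison; it is kept at ½ for definiteness). `B` is
symmetric and doubly centered; for correlation-type `W` it is close to
positive semidefinite. Coordinates are
`X̃ = diag(√λ₁..√λ_k) · [v₁..v_k]ᵀ` from the k largest eigenvalues, clipped
below at zero. Negative spectral mass (present when `W` is not PSD, e.g.
after edge shuffling or Fisher-z transformation) is discarded, recorded on
the result, and logged when it exceeds 5% of the total absolute mass.
Determinism: eigenvalues sorted descending; each eigenvector's sign is
fixed so its largest-magnitude entry is positive. Distances — the only
quantity the metric consumes — are unaffected by sign or by rotations
within non-degenerate eigenspaces; a k that cuts through a *degenerate*
eigenvalue pair makes distances basis-dependent, which is why oracle
comparisons in the tests avoid (or span) degenerate spectra. A constant
`W` embeds legitimately to n coincident points; a `B` with no positive
eigenvalues and nonzero mass raises a degenerate-embedding error.

**Point pattern.** The observation window is the axis-aligned bounding box
of the embedded points (optionally expanded by `expand_fraction`; default
0). The intensity is `λ̂ = n/|window|`. Ripley's K is estimated with strict
inequality `d_ij < r` and ordered pairs,
`K̂(r) = λ̂⁻¹ (1/n) Σ_i Σ_{j≠i} η_ij 1(d_ij < r)`. Corrections:

- `none`: `η = 1` — used for oracle comparisons.
- `translation` (default, valid for any k ≥ 2):
  `η_ij = |W| / |W ∩ (W + x_j − x_i)|`, closed-form for a box:
  `|W ∩ (W+t)| = Π_a max(0, L_a − |t_a|)`. Pairs whose shift degenerates
  the overlap get weight 0; such pairs lie farther than any admissible
  radius, so they never contribute.
- `isotropic2d` (k = 2 only): reciprocal of the in-window arc fraction of
  the circle of radius `d_ij` centered at `x_i`, via the classical
  side-arc/corner-overlap construction for a rectangle. The fraction is
  floored at 1e−9 before inversion.

The radius grid is 100 equally spaced radii on `(r_max/100, r_max]` with
`r_max` = ¼ of the shorter window side — standard Ripley practice to limit
boundary bias; radii beyond half the window diameter warn rather than
error. `L̂(r) = K̂(r)/c` with `c = 1` by default, and
`Geme = ∫ L̂(r) dr` by the trapezoid rule on the grid, so Geme defaults to
the area under the corrected K curve. The literal cross-entropy
transcription `−(1/n) ΣΣ 1(d_ij<r) log(π r² λ̂)` is exposed as
`cross_entropy_direct` for inspection (plane only); its log factor is
r-dependent, so it is not proportional to K and is not the default path.

Under CSR the translation-corrected estimator satisfies
`E[K̂(r)] = ((n−1)/n) π r²` in the plane; the calibration tests use the
Monte-Carlo standard error of the mean over many uniform patterns, which
comfortably absorbs the O(1/n) factor at n = 200.

## Simulation design

Each simulated subject is `Z (n x T) ~ N(μ, Σ)` with block-diagonal `Σ`:
communities are compound-symmetry blocks `I_a(1−ρ) + J_a ρ` (spectrum
`1+(a−1)ρ` once, `1−ρ` with multiplicity a−1; positive definite for
ρ ∈ [0,1)), remaining nodes independent. The subject network is the
correlation normalization of `U = Z Zᵀ/(T−1)` about the known zero mean
(a `center=True` toggle gives ordinary Pearson correlations for real
data). Defaults: `μ = 0`, `T = 150` time points (a typical resting-state
fMRI volume count), 100 subjects per group. Subject streams derive from
`(spec.seed, subject_index)`, so any subject is reproducible in isolation;
the power simulation spawns disjoint per-replicate, per-group seeds from
one master seed, keeping every estimate exactly reproducible.

What the generator emulates: the group-level statistical design of a
functional-connectivity cohort — community structure, correlation noise,
finite scan length. What it does not: hemodynamics, temporal
autocorrelation, motion artifacts, global-signal effects, inter-subject
anatomical variability. Passing tests therefore demonstrate the metric's
statistical behavior under the idealized design, not performance on real
fMRI data.

## Group analysis

Per-subject Geme scores are compared with Welch's two-sample t-test
(two-sided; the test statistic is not dictated by the design, and unequal
variances are the norm when group structures differ); a Wilcoxon rank-sum
alternative is available. Power is the rejection fraction over replicate
simulated studies with its binomial standard error. Cohort analyses fit
`geme ~ group + sex + age + group:sex` by OLS (statsmodels), report the
coefficient table, and accompany it with stratified by-sex Welch
contrasts, since an interaction is only interpretable through them. No
multiplicity correction is applied. `synthetic_cohort` plants known
coefficients for parameter-recovery testing.

## Numerical and design choices

- Strict inequality `d_ij < r` as defined; coincident points count at
  every r > 0.
- The diagonal of `W` is used as supplied (1 for correlation networks);
  centering makes the constant part irrelevant.
- `c` is genuinely underdetermined in the method's description; `c = 1`
  makes the two printed relations (`L = cK`, `L̂ = c⁻¹K̂`) coincide and
  keeps Geme on the interpretable area-under-K scale. We also examined
  scale-normalized alternatives (unit-volume windows, K self-normalized by
  its saturation value). They trade scale sensitivity for an inverted
  ordering — edge-shuffled random graphs embed to one tight blob and score
  *above* community networks — so they were rejected: a complexity score
  should rank organized networks above marginal-matched random ones, and
  the default path does (Welch t ≈ +7 at the default study conditions).
- Default k = 2: the planar corrections are standard, and the two leading
  eigenvectors carry the community contrasts in the simulated designs;
  k > 2 is supported with the translation correction.
- Known limitation: independent "background" nodes (outside every
  community block) have nearly identical correlation profiles and embed to
  the *tightest* cluster. At fixed correlations, mean Geme therefore
  *decreases* as community blocks grow (fewer background nodes), even
  though detection power for size differences behaves as expected
  (two-sided tests see the magnitude, not the sign). Interpret absolute
  Geme levels across designs with this in mind.
- Known limitation: because the metric is scale-sensitive (area under K in
  embedding units), uniformly lowering within-community correlations moves
  group means through the embedding scale as well as through pattern
  noise. Group differences driven purely by correlation level are
  therefore detected far more often at the default study sizes than a
  "noise-only" reading would suggest; the power grid in the acceptance
  suite reflects this.
- Known limitation: very small communities at low correlations (e.g.
  10-node blocks with ρ ≤ 0.5 at T = 150) have leading eigenvalues near
  the sampling-noise bulk edge of the correlation spectrum, so their
  embedding is noise-dominated; per-subject Geme variance inflates and
  two-group power can drop rather than saturate as the design contrast
  grows. The power-grid tests measure and expose this regime rather than
  smoothing over it.

## Problem sizes used in the test suite

The acceptance-style tests run the power grid at 50 replicates for the six
headline cells and 30 replicates for the remaining grid cells (monotonicity
checks use a z = 2.58 Laplace-smoothed binomial slack to absorb Monte-Carlo
error); permutation invariance uses 100 networks of 60 nodes; CSR
calibration uses 500 patterns of 200 points; oracle equivalence uses 50
random patterns and 20 random PSD matrices; the structure-vs-randomness
contrast uses 50 networks per arm. `scripts/acceptance.py` runs the six
headline cells at the full 100 replicates.
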