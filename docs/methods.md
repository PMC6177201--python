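# Methods

## Generative model

Datasets are drawn from the two-class multilevel Gaussian model

    y_ijk = C_i + S_ij + eps_ijk,   i ∈ {1,2}, j ∈ {1..K}, k ∈ {1..N},

with C_i ~ N(0, σ_C²·I_d), S_ij ~ N(0, σ_S²·I_d) and eps_ijk ~
N(0, σ_W²·I_d), all isotropic and mutually independent. Each class
contributes K·N trials; subclass identifiers are globally unique, so the
nesting invariant (every subclass belongs to one class) holds by
construction and is re-validated whenever a dataset is built or loaded.
Both class centroids are random draws, treating the class component
symmetrically with the subclass component; σ_C = 0 gives exactly identical
class centroids. The RNG draw order is fixed (class centroids, subclass
centroids, trial noise, all in class/subclass/trial order) so a seed fully
determines a dataset.

The intraclass correlation ICC = σ_S²/(σ_S²+σ_W²) summarises how much of
the non-class variance is subclass-borne. `estimate_icc` recovers it from
data by a balanced one-way random-effects decomposition (between- vs
within-subclass mean squares, per class and per dimension, pooled; negative
subclass-variance estimates are clipped to zero). Designs with more than
one nesting level collapse to a single level because Gaussian variances
add: `collapse_levels(σ_a, σ_b) = sqrt(σ_a² + σ_b²)`, and
`generate_dataset_two_level` exists to verify that equivalence empirically.

Default study conditions mirror the simulation design the package is built
around: 120 observations per class, σ_W = 1, σ_C and σ_S swept over
[0, 0.6], d ∈ {10, 100}, K ∈ {2, 10}, linear SVM cost 1, 2-fold CV.

What the generator does *not* emulate: non-Gaussian or anisotropic noise,
temporal autocorrelation within sessions, crossed (non-nested) subclass
designs, and unequal subclass sizes. Passing tests therefore demonstrate
the subclass-bias mechanism and its correction under the idealised
multilevel Gaussian model, not robustness to those real-data features.

## Classifiers and cross-validation

`paper_lda` projects onto the difference of the empirical class means and
thresholds at their midpoint θ = (μ̄+ν̄)/2 — LDA under an isotropic
covariance model. It is implemented from scratch because the analytic
theory below describes exactly this rule. Points landing exactly on θ go
to the first class in sorted label order; this is a measure-zero event for
continuous data and is pinned down only so tests can exercise it. The
linear SVM is scikit-learn's `SVC(kernel="linear")` with cost C (default
1). No feature scaling or other preprocessing is applied.

Trial-wise k-fold CV stratifies by class only (trials of each class are
shuffled and dealt round-robin, so fold class counts differ by at most
one); subclass members deliberately end up on both sides of the split,
because that leakage is precisely the phenomenon under study. A 2-fold
(split-half) default is used: it has the same expected CCR as finer folds
but lower variance, which helps permutation testing. Leave-one-subclass-out
CV pairs the j-th subclass of each class (sorted order) and holds one pair
out per fold; it requires equal subclass counts and at least two subclasses
per class. CCRs are pooled over held-out trials rather than averaged over
folds, so unequal fold sizes cannot distort the rate (with stratified folds
the two coincide).

## Permutation tests

Trial-wise nulls shuffle class labels over trials; the permuted data are
treated as subclass-free (each trial its own block), which is the
independence assumption that scheme encodes. Block (subclass-wise) nulls
reassign whole subclasses into two new classes, each taking exactly K/2
subclasses from each original class, so within-subclass dependence is
preserved while class information is removed. K must be even and equal in
both classes — with unequal subclass counts the two new classes would not
be exchangeable and the procedure is invalid, so it raises.

There are C(K, K/2)²/2 distinct balanced assignments; the ½ removes the
duplicate obtained by swapping the two new labels, realised constructively
by requiring new class 1 to contain a fixed reference subclass (the first
subclass of original class A). When the count fits within `n_perm` the
enumeration is used exhaustively; otherwise assignments are sampled
uniformly *without replacement* (rejection on the canonical form, which
stays uniform). The original labeling assigns all K subclasses of one
class together and is therefore never itself a balanced assignment; its
CCR is the test statistic. Each permutation draw re-runs the full CV with
a fresh fold split seeded from the scheme seed, so fold artefacts cannot
correlate across draws.

P-values: sampled nulls use the add-one estimator
p = (1 + #{null ≥ observed})/(1 + n), which never returns zero and gives
an exact test at level α when α(n+1) is an integer. Exhaustive nulls count
the observed arrangement as one outcome: p = max(#{null ≥ observed}, 1)/n.
The group-level test compares the mean observed CCR across subjects with a
null of `n_resample` means, each formed by drawing one CCR uniformly from
every subject's null.

## Expected-accuracy theory

Along the projection axis, model the K training subclass means of each
class as i.i.d. N(class mean, σ_S²), a test trial as centred on its *own*
training subclass mean with variance σ_W², and the threshold as the
midpoint of the two empirical class means. Writing σ² = σ_S² + σ_W²,
ρ = ICC = σ_S²/σ² and δ for the projected class-mean separation, the trial
score minus threshold (a) and the class-mean difference (b) are jointly
Gaussian with E[a|b] = b/2, and the expected CCR reduces to a
one-dimensional integral over a standard normal q:

    CCR = E_q[ Φ( λ·|q + δ̃| ) ],
    λ² = (ρ/2K) / (1 − ρ/K),      δ̃ = δ / (σ·sqrt(2ρ/K)).

At δ = 0, using E[Φ(c|q|)] = 1/2 + arctan(c)/π, this closed-forms to

    CCR = 1/2 + arctan(λ)/π = 1 − arctan( sqrt(2(K/ICC − 1)) )/π,

depending only on K and the ICC: exactly 0.5 at ICC = 0, strictly
increasing in ICC, strictly decreasing in K. At ρ = 0 the integral
degenerates to Φ(δ/2σ) (the plain midpoint-classifier accuracy), handled
analytically since λ and δ̃ are undefined there. Quadrature uses scipy's
adaptive `quad` on a finite window covering both the normal mass and the
kink at q = −δ̃ (the integrand is φ(q) times a bounded factor, so the
truncation error at |q| = 12 is far below the 1e−8 tolerance), with the
kink as an explicit breakpoint.

Three routes must agree and are tested against each other: the closed form,
the quadrature (agreement to 1e−6 at δ = 0), and a Monte-Carlo oracle that
generates datasets and classifies them with `paper_lda` under 2-fold CV
(agreement within max(2 pp, 3 standard errors) on a (K, ICC) grid). The
oracle defaults to d = 1 and N = 100 because the theory describes the
projected coordinate with the subclass-mean sampling noise σ_W²/N
neglected. In higher dimensions the subclass effect accumulates across
dimensions and the simulated chance CCR exceeds the one-dimensional
theory — the simulated d = 100 surfaces show a markedly larger bias than
d = 10 at matched (K, ICC), which is why even ICC ≈ 0.1 can shift
high-dimensional accuracies by ~10 percentage points while the closed form
predicts ~5 at K = 2.

## Experiments and default scales

`run_ccr_surface` sweeps (σ_C, σ_S) grids at fixed (K, d) and reports mean
and SD of the CCR per cell. `run_theory_validation` tabulates closed form
vs Monte Carlo over ICC grids for several total subclass counts.
`run_significance_bias` reports the proportion of significant datasets per
cell and the significance bias SB = P(σ_S) − P(σ_S = 0), which is zero by
construction in the σ_S = 0 column; SB > 0 flags a liberal test. Two null
modes are supported: `per_dataset` (default) runs the actual permutation
test on every simulated dataset — the procedure available on real data —
while `population` pools CCRs of independent null datasets (σ_C = 0,
matched σ_S for the block scheme; σ_S = 0 for the trial scheme) into one
reference null, the protocol used for large simulation studies of the
schemes. Trial-wise testing on subclassed data is liberal; block-wise
testing holds the nominal level at σ_C = 0 and turns slightly conservative
when σ_S is large relative to σ_C, because the block null absorbs part of
the combined effect.

Desk-scale defaults (500 repetitions per cell, 200 permutations) keep the
sweeps in the minutes range while leaving all trend checks well outside
Monte-Carlo error; the full-scale protocols (5000 repetitions, 1000
permutations) are configuration values away. The test suite and the
acceptance script use, as their own problem sizes: 500 datasets for
chance-level calibration, 2000 repetitions per cell for the
theory-consistency grid, 200 datasets × 99 permutations for the
scheme-contrast study, and 500 repetitions per cell for the trend surfaces.

## Known limitations

- Two balanced classes only; multiclass schemes and unbalanced designs are
  out of scope (unequal subclass counts are rejected rather than
  approximated).
- The closed form models the projected coordinate, not the full
  d-dimensional classifier; it is a lower anchor for the bias in high
  dimensions, not a d-dependent prediction.
- The block permutation p-value is granular at 1/count for small K; K = 6
  (200 assignments) is the smallest design supporting p ≤ 0.01, and the
  group-level null is the recommended fallback below that.
- Sampled block nulls assume the balanced-assignment space is large
  relative to n_perm; when it is not, the code switches to exhaustive
  enumeration automatically.
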