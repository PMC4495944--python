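# Methods

## Model and procedure

The package infers the *type* (activating vs inhibitory) of an already
known regulatory interaction from the joint distribution of the two
genes' expression levels. The underlying assumption is purely
co-expressional: similar profiles indicate activation, mirrored profiles
inhibition. Direction of regulation is deliberately not inferred — the
score is symmetric in its two arguments — and the method cannot sign an
edge whose genes show no expression variation.

Scoring an edge proceeds in four steps:

1. **Soft discretization.** Each profile is min–max scaled onto the knot
   domain [0, B−k+1] and evaluated against the B B-spline basis functions
   of order k on the open-uniform knot vector (k-fold repeated boundary
   knots, unit interior spacing). Each sample thus receives non-negative
   membership weights over up to k adjacent bins that sum to exactly 1,
   so samples near bin boundaries are not forced into a single bin. With
   k = 1 this reduces to ordinary equal-width histogram binning, a
   reduction the tests verify against an independent histogram oracle.
   Basis evaluation is delegated to
   `scipy.interpolate.BSpline.design_matrix`; the test suite checks it
   cell-by-cell against a hand-written Cox–de Boor recursion.
2. **Joint estimation.** The bins×bins joint grid is the average outer
   product of the two membership rows; marginals are its row/column sums
   (conserved to 1e-9 by construction).
3. **Rescaling.** A bins×bins weight matrix W converts the non-negative
   co-occurrence metric into a signed one (below).
4. **Expectation.** The score is the expected value of the rescaled
   metric under the joint grid; its sign, after thresholding, is the
   predicted interaction type.

## Rescaling matrices

Bins are indexed by ascending expression. At the canonical B = 10 the
grid splits into four 5×5 quadrants at index 5: same-side quadrants
(low-low, high-high) are positive, mixed quadrants negative, and the
central 4×4 block (indices 3–6 on both axes) — where neither gene
deviates informatively from its median — is zero. This is the unique
simple geometry giving the 42/42/16 positive/negative/zero cell split
that all four variants share.

* **M1** grades magnitudes additively: 1 at the two corner-diagonal cells
  of each quadrant, decreasing by 1/6 ≈ 0.166667 per Chebyshev step
  toward the positive/negative border. Within a 21-cell quadrant the
  distance reaches 3, so four distinct levels (1, 5/6, 2/3, 1/2) occur.
* **M2** keeps M1's positive cells and uniformly rescales the negative
  cells so the matrix sums to zero. Because the reconstructed geometry is
  mirror-symmetric, M1 already balances exactly and the rescaling factor
  is 1 — M2 coincides with M1 while still satisfying its defining
  zero-sum property. A variant of M1 with an unbalanced diagonal would
  make M2 distinct; the available structural constraints (cell counts,
  grading step, symmetry) do not pin such a layout down, so the symmetric
  construction is used for all four variants.
* **M3** is the pure sign pattern, entries in {−1, 0, +1}. It is the
  shipped default: the graded variants add assumptions about *how much*
  less informative off-corner cells are without improving sign recovery
  on the benchmarks generated here.
* **M4** keeps M1's negative cells and grades positive cells
  multiplicatively with ratio (1/6)^(1/5) per step, chosen so that five
  steps reach M1's smallest level 1/6. The ratio is a package choice; it
  preserves the magnitude range [1/6, 1].

All four are transpose-symmetric; the shared sign pattern is
antisymmetric under reversal of one bin axis, which makes the S1–S3
scores exactly antisymmetric under mirroring one profile
(x → max+min−x). S4 is the exception: mirroring flips both its numerator
and denominator, so the ratio is mirror-*invariant*. This is a property
of the NRMI functional form, not an implementation artifact; the property
tests assert invariance for S4 and antisymmetry for the others.

## Scoring functions

With p = p(x,y), PMI = log(p / p(x)p(y)) and NPMI = PMI / (−log p):

* S1 = Σ p·W·PMI (weighted mutual information; default),
* S2 = Σ p·W·NPMI,
* S3 = Σ p·W (expected rescaling weight, bounded in [−1, 1]),
* S4 = (Σ p·W·PMI) / (−Σ p·W·log p) (normalized rescaled MI).

Zero-mass cells contribute 0 throughout (0·log 0 convention); an NPMI
cell holding all the mass takes the perfect-association limit 1; a zero
S4 denominator yields 0 with a warning. With W ≡ +1, S1 reduces exactly
to mutual information and S4 to normalized MI. S1 spans a wider empirical
range than S2 on the clique benchmark and is the default.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `num_bins` | 10 | bins per profile; performance is insensitive within a reasonable range |
| `spline_order` | 3 | B-spline order; 1 = hard binning, >3 adds cost without benefit |
| `scoring_function` | S1 | see above |
| `rescaling_matrix_id` | M3 | see above |
| `log_base` | 10 | scales all PMI-based scores (see below) |
| `threshold` | 0.158 | minimum \|score\| to sign an edge |

**Log base.** Scores scale by 1/log(base), so the base and the signing
threshold are coupled. The package standardizes on base 10 because under
it the permutation-null ceiling of the default score at the reference
sample size (171 samples) sits near 0.10 over 10⁴–10⁵ draws — safely
below, and of the same magnitude as, the 0.158 operating threshold. Under
base 2 or e the same null ensemble exceeds 0.158 routinely, which would
make the default threshold meaningless. Signs, and hence all accuracy
results, are base-independent.

**Threshold calibration.** `permutation_null_threshold` shuffles two
randomly chosen genes' profiles independently across samples (breaking
all dependence while preserving marginals), scores the pair, and returns
the maximum |score| over `n_draws` draws — the smallest τ at which no
null pair is signed. The default 10⁴ draws is a desk-scale choice of the
same estimator one would run at 10⁶; shuffled profiles only permute
membership rows, so memberships are computed once per gene and permuted
per draw. A score exactly equal to ±τ is signed (inclusive boundary
convention).

## Synthetic benchmark

`make_insilico_clique` emulates a benchmark built from disease-progression
expression data: two groups of genes (defaults 9 "up" and 6 "down", 171
samples) follow a shared monotone latent ramp and its negation
respectively, each gene with a random amplitude in [0.5, 1.5], a random
baseline offset, and additive Gaussian noise (default sd 0.25 relative to
the unit-amplitude ramp — enough to perturb scores without flipping
signs; a 4-level step trajectory mimicking discrete disease stages is
available). Every gene pair is an edge: positive within a group, negative
between groups (105 edges, 51/54 at the defaults). At zero noise the
default pipeline recovers all 105 signs at τ = 0; mean accuracy decays
monotonically with noise.

What the generator does *not* emulate: realistic microarray noise
(intensity-dependent variance, batch effects), indirect co-expression
without regulation, feedback dynamics, or the hub-dominated topology of
real GRNs. Passing the synthetic benchmarks therefore demonstrates the
correctness of the machinery and its behavior under idealized co- and
anti-regulation, not field performance on experimental compendia.

## Evaluation conventions

Accuracy counts only edges that received a sign *and* carry a reference
sign: accuracy = (PTP+NTN)/(PTP+NTN+NFP+PFN), reported as NaN when that
denominator is empty. Retrieval is n_signed/n_total over all edges,
including degenerate ones. Accuracy–retrieval curves re-threshold the
stored scores (20 thresholds over [0, 1] by default); retrieval is
monotone non-increasing in τ. The "most fluctuated genes" filter ranks by
cross-sample variance (coefficient of variation behind a flag), breaking
ties by gene identifier, and keeps the top ⌈fraction·n⌉.

## Numerical and degenerate-input choices

* Constant profiles raise a typed error at the discretization layer; the
  network layer converts it to an unsigned edge (NaN score) with a
  warning.
* The right endpoint of the knot domain is assigned to the final basis
  function (value 1), preserving partition of unity at the boundary.
* Missing expression values are a hard error by default; with
  `missing='allow'` edges are scored on pairwise-complete samples
  (fewer than 3 complete samples leaves the edge unsigned).
* Duplicate network rows are merged (undirected); conflicting reference
  signs keep the first with a warning; self-loops are dropped.
* Bin counts other than 10 generalize the rescaling geometry (quadrant
  split at ⌊B/2⌋, zero block spanning [⌈0.3B⌉, B−1−⌈0.3B⌉]) with a
  logged warning; 10 bins is canonical.

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on generated data: the
15-gene/105-edge clique at 171 samples; permutation nulls of 10⁴ draws
(three seeds); and one completion check signing a 2,687-edge network over
a 1,419-gene × 907-sample matrix, which verifies that compendium-scale
inputs are handled in one pass.

## Known limitations

* Signs only; no direction, no p-values per edge (the global null
  threshold is the only significance device).
* The plug-in MI estimator is biased upward at small sample counts; no
  bias correction is applied, which is why the null-calibrated threshold,
  not the raw score magnitude, should gate decisions.
* The graded matrices M1/M2/M4 are structural reconstructions from count
  and step constraints; M2 degenerates to M1 under the symmetric
  geometry (see above). M3, the default, is fully determined.
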