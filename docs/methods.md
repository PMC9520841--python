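# Methods

`fleagm` implements a dual-evidence identification workflow for
morphologically similar dog fleas (*Ctenocephalides canis* vs
*C. orientis*): head-shape geometric morphometrics cross-validated against
cox1 DNA barcoding, plus the descriptive statistics of the underlying
host survey. This note records the models, conventions and numerical
choices, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Landmark scheme and TPS input

Each specimen is digitised as 5 fixed landmarks on the head plus one
open curve along the head outline. The curve is resampled into 10
semilandmarks equally spaced by cumulative arc length (piecewise-linear
interpolation; first and last points are the curve endpoints). Curve
endpoints that fall within a merge tolerance of a fixed landmark are
merged onto it (the fixed landmark is kept), so the default scheme yields
`5 + 10 − 2 = 13` points. The merge tolerance defaults to 1e-6 times the
configuration diameter; an unexpected merge count is an error unless
forced, because it almost always indicates a digitisation problem.
Semilandmarks are treated as ordinary landmarks afterwards — no sliding —
matching how curve points are imported into the standard MorphoJ-style
workflow.

TPS files are parsed in the tpsUtil/tpsDig dialect (`LM=`, `CURVES=`,
`POINTS=`, `IMAGE=`, `ID=`, `SCALE=`). Coordinates pass through
untransformed; `SCALE=` is applied only on request and `flip_y` negates y
for image-row-convention files. Generalized Procrustes analysis is
invariant to both, but raw exports must match the input dialect.
Written coordinates use shortest exact round-trip decimal formatting, so
read(write(x)) is the identity.

## Procrustes superimposition

Configurations are centered and fixed at unit centroid size (square root
of summed squared deviations from the centroid), then iteratively rotated
to the running consensus; the consensus is the coordinate-wise mean
renormalised to unit size. This is the "Procrustes fit" convention of
MorphoJ: no per-iteration rescaling by cos ρ, i.e. partial-Procrustes
alignment of unit-size pre-shapes. Reflections are never applied
(rotation determinant +1). Convergence is declared when the consensus
moves less than 1e-10 (root sum of squares), with a cap of 100 iterations
(`converged=False` plus a logged warning past the cap); the initial
reference is the first specimen after centering and scaling. On the
study-scale datasets the iteration converges in 3–5 rounds.

Distances between shapes are full Procrustes distances. Pairwise values
use the planar complex-coordinate closed form
`d = sqrt(1 − |<z, w>|²)` for unit-norm centered pre-shapes, evaluated
through the rotated-residual identity `|r|² = 2 − 2|g|` to avoid the
catastrophic cancellation of `1 − |g|²` for near-identical shapes.

Tangent coordinates are the orthogonal projection of the aligned
pre-shapes at the consensus: `t = x − (x·c)c` on flattened coordinates.
Because aligned shapes are centered, unit-size and rotationally aligned,
the tangent matrix has rank at most `2p − 4` (22 for the 13-landmark
scheme); all downstream covariance work therefore happens in the
principal subspace of the relevant covariance with eigenvalues above
1e-9 of the largest.

## Procrustes ANOVA

The sex × species factorial ANOVA uses the Goodall-style isotropic model:
sums of squares are computed coordinate-wise from nested least-squares
fits and summed over all 2p tangent coordinates. SS are sequential
(Type I) in the order sex, species, sex × species — the order is the
biologically sensible nesting for this design and is configurable by
permuting the design columns. Degrees of freedom multiply the univariate
effect df by the shape dimension `2p − 4`: each effect has df 22 and the
residual `(n − 4) × 22` (3542 at n = 165). F is MS(effect)/MS(residual)
with the parametric upper-tail F p-value; a zero residual variance yields
NaN with a warning rather than an error.

## CVA, DFA, permutation tests, leave-one-out

Canonical variates solve the between/within generalized eigenproblem
after projection onto the pooled within-group covariance subspace
(divisor n − g); axes are scaled to unit within-group variance, so
canonical-space distances are Mahalanobis distances. With four groups
there are exactly `min(g − 1, rank) = 3` variates and their eigenvalue
percentages sum to 100 by construction.

Pairwise group-separation p-values are two-sample permutation tests:
for each pair, the specimens of those two groups are pooled and their
labels reassigned at random `n_perm` times (the pair-restricted
convention of MorphoJ; the pooled within-group covariance is re-estimated
and re-reduced for every relabelling so the statistic is defined for
every permutation). Two statistics are offered: the Mahalanobis distance
between group means, and the mean-shape ("Procrustes") distance, i.e. the
Euclidean distance between mean tangent vectors. P-values use
`(b + 1)/(n_perm + 1)`, counting ties as extreme, so the smallest
attainable value is `1/(n_perm + 1)` and the null distribution is exactly
uniform on the attainable lattice. All permutation machinery runs off a
single seeded `numpy` generator recorded in the result objects.

A caveat worth knowing: with the study's smallest cell (8 males) pooled
against 26, the Mahalanobis statistic in 22 dimensions rests on ~32
residual df and loses power — on some simulated datasets that male–male
pair does not reach p < 0.001 under the Mahalanobis test while the
mean-shape statistic finds it comfortably. Both are reported.

Two-group discriminant analysis uses the classical axis `W⁻¹(μ₁ − μ₂)`
in the reduced subspace; specimens are classified by their score against
the midpoint of the two group mean scores (no prior-odds term — the
MorphoJ-style rule; a Mahalanobis-to-centroid rule would differ only for
very unbalanced groups and is easy to add). Leave-one-out
cross-validation refits the entire pipeline — subspace reduction, axis,
cutoff — on the n − 1 retained specimens for every held-out specimen;
rank failures are counted and the specimen marked unclassifiable rather
than silently dropped. Default permutation rounds are 10,000 and always
configurable.

Observer-vs-classifier comparison: per-class misclassification is
wrong/total over specimens fully identified by both methods (an
"indeterminate" assignment is excluded from the denominator), rounded to
whole percent; the fold improvement is the ratio of the rounded
percentages to one decimal (31%/6% → 5.2), matching how such rates are
reported in practice. A zero post-rate is flagged infinite.

## cox1 barcoding

Amplicons are protein-coding cox1 fragments (550–650 bp) with no indels
expected, so alignment is simple end-trimming: sequences are assumed to
share their 5′ start and length differences beyond 60 bases are an error.
Haplotypes are defined by exact identity over the common overlap
(one sequence contained in the other, ≥ 400 positions; `full_length`
mode requires strict equality). Ids are assigned in decreasing count
order, then first appearance. A haplotype whose members span two known
species is an integrity error. Reference-panel matching uses the same
identity-over-overlap rule; several distinct matches raise an ambiguity
error and an overlap under 400 positions is a logged no-call.

Kimura-2-parameter distances delete sites pairwise when either sequence
carries a gap, N or ambiguity code (the MEGA default), then
`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` from the transition and
transversion proportions. Arguments outside the formula's domain raise a
saturation error; matrix construction converts per-pair saturation into
flagged (NaN) entries instead.

Trees: Saitou–Nei neighbor joining with the Studier–Keppler Q-criterion,
deterministic tie-break toward the lowest taxon-index pair, negative
branch lengths clamped to zero. Minimum-evolution refinement re-estimates
branch lengths by ordinary least squares on leaf-pair path distances
(solved via normal equations, negatives clamped) and accepts
nearest-neighbor-interchange moves only while the OLS tree length
strictly decreases — NNI only; subtree pruning is out of scope. Bootstrap
resamples alignment columns with replacement, rebuilds K2P → NJ → ME per
replicate, and reports for each internal bipartition of the point
estimate the percentage of successful replicates containing it
(saturated replicates are skipped and counted). Newick I/O goes through
dendropy, with supports as integer internal-node labels.

## Survey statistics

Binomial proportions use the Wald interval
`p ± 1.959964 · sqrt(p(1 − p)/n)` clamped to [0, 100]% — the interval a
normal-approximation spreadsheet workflow produces, and the one that
reproduces all three printed survey intervals (45–67, 46–72, 17–59);
Wilson and Clopper–Pearson are available behind a flag. Percentages are
rounded to whole percent, half away from zero; sex ratios to two
decimals, round half to even (45/8 = 5.625 → 5.62).

## Synthetic data: what it emulates, and what it does not

The generator exists so every pipeline stage is testable without the
study's deposited images and chromatograms.

*Landmarks.* The template is a 13-point fixture — 5 anchor points plus a
half-circle head-outline arc (the real landmark anatomy is not
reproducible from a published figure, and the analysis is invariant to
the template's exact geometry). Group mean shapes displace the template
along three fixed orthonormal tangent directions (species, sex,
interaction), with sign +/− per factor level, so the between-group mean
separation is twice the effect magnitude. Noise is isotropic Gaussian
per landmark coordinate — the classical Goodall assumption under which
the Procrustes ANOVA is exact. Nuisance rotation, translation and scale
are drawn uniformly per specimen. Defaults are the study conditions:
group sizes (86, 26, 45, 8); σ = 0.01 Procrustes units; effects 0.015
(species), 0.018 (sex, the larger main effect), 0.004 (interaction),
calibrated once so that the species DFA shows single-digit overall LOO
error against an observer confusion of ~31%/57%. Real landmark data
have correlated, landmark-specific error and allometry; none of that is
modelled, so passing tests demonstrate correctness of the estimators
under the isotropic model, not robustness to anisotropic digitisation
error.

*Sequences.* A random 614-bp ancestor seeds one founder per species;
substitution counts are solved exactly from the K2P inversion at
transition/transversion ratio 2 and planted at globally disjoint random
sites, so planted divergences are hit nearly exactly (within rounding).
Default design: 22 *C. canis* haplotypes over 113 sequences and 3
*C. orientis* haplotypes over 53 (multiplicities 56, 20, 7, 2, 2, 1, 1,
7, 1, 1, 2, 1, 1, 1, 1, 1, 1, 2, 1, 2, 1, 1 and 25, 18, 10), within-species
maximum divergences 0.012 and 0.064, between-species 0.12. There is no
site-rate heterogeneity, no indels and no coalescent genealogy; the
stochastic counterpart `evolve_k80` (exact K80 transition probabilities
per site) is what estimator-recovery checks sample from.

*Observer and survey.* Morphological identification is an independent
categorical draw per specimen from a per-true-class confusion row
(defaults: *orientis* females misread as *canis* 31%, males 57%,
indeterminate 10%). The survey is Bernoulli infestation over 77 dogs at
p = 43/77 with zero-truncated geometric flea counts (mean 4.6),
species/sex drawn from the published composition and round-robin regions.

All generators are bit-reproducible given their seeds.

## Problem sizes used by the test suite and acceptance script

Study-scale checks run at the survey's own sizes (165 landmark
specimens, 166 sequences / 25 haplotypes, 77 dogs). Monte-Carlo
properties use 200 null datasets for the permutation type-I error, 200
replicates for the zero-effect leave-one-out calibration, 200 simulated
pairs per divergence level for K2P recovery, and a few hundred bootstrap
replicates on haplotype-scale alignments; permutation counts in tests are
199–1999 (the 1/(B+1) floor is what matters, not B itself). Library
defaults remain 10,000 permutations and 1000 bootstrap replicates.

## Known limitations

- Semilandmarks do not slide; curve information near the merge points is
  slightly over-weighted relative to a sliding-semilandmark treatment.
- Procrustes ANOVA is the isotropic (Goodall) variant; landmark-specific
  covariance would require the full multivariate test.
- DFA is two-group only, by design.
- ME search is NNI-only and can stop in a local optimum for very noisy
  matrices; the NJ start makes this rare at barcoding divergences.
- Alignment by end-trimming assumes co-linear amplicons; sequences from
  other primer pairs need external alignment first.
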