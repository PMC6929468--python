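# Methods

## Residue labeling

A residue is *surface* when its accessible surface area exceeds 16% of the
maximum ASA of its amino-acid type, strictly.  Two maximum-ASA scales are
packaged: Rost–Sander 1994 (default) and the Tien et al. 2013 theoretical
bounds; the choice is a config key (`max_asa_scale`) because published
work is not consistent about the scale and the two differ by up to ~25%.
Note that under Rost–Sander the largest value belongs to arginine, under
Tien 2013 to tryptophan.

Among surface residues, a residue is *interface* when the minimum
Cα–Cα distance to the partner chain is strictly below 12 Å (the 1.2 nm
rule, converted once at config load; PDB coordinates are Å).  The partner
pool is the whole partner chain, not only its surface.  ASA is always
consumed from input (an HSSP accessibility column or a TSV field), never
recomputed from coordinates: reimplementing DSSP is out of scope, and
labels should not depend on a second geometry code.

Nonstandard residues are kept for window geometry (they occupy space) but
are never targets and never surface-classified, since the max-ASA scales
cover only the canonical 20.

## Features

Each residue carries 24 conservation values: the 20-dim amino-acid
frequency profile, Shannon entropy in bits (base is configurable to nats;
relative entropy is base-invariant and the learners standardise columns
anyway), relative entropy H/log₂20 ∈ [0,1], a conservation weight, and an
evolutionary rate.  The conservation weight is passed through from HSSP's
WEIGHT column when present; otherwise 1 − relative entropy is used as a
surrogate — it shares the property of being high at conserved positions,
but it is *our* fallback definition, not HSSP's formula.

The window of a target residue is its 10 spatially closest chain
neighbours by Cα distance, ascending, ties broken by ascending sequence
index (a deterministic convention; "closest 10" alone does not fix an
order).  Blocks are concatenated target-first, giving 11 × 24 = 264
values.  Chains shorter than 11 residues pad the trailing slots.

Standardisation is per-column z-scoring fit on the training data and
frozen before being applied to unlabeled/test rows.  Padded blocks are
kept at zero *after* standardisation: a padded slot should sit at the
origin of the standardised space rather than being pushed to the negative
of the column means, which would inject spurious signal.  Padded blocks
are recognised as all-zero raw blocks, which cannot collide with real data
because a real block's profile sums to 1.

## Supervised SVM core

Kernels: RBF (default, γ = 1/(d·var X), the widely used "scale"
heuristic) or linear.  The soft-margin dual is solved by scipy's SLSQP
under a single QP contract (`solve_svm_dual`); the problems here are small
(at most a few hundred variables; the augmented semi-supervised dual has
only l+2), so an off-the-shelf NLP solver reaches the KKT conditions to
~1e−8 without a bespoke SMO.  The bias is recovered from free support
vectors, or from the KKT interval midpoint when none exist.

## Label-mean S3VM (meanS3VM)

The unlabeled assignment vector d ∈ Δ sends u₊ = (r+u)/2 points to the
positive class mean and u₋ = (u−r)/2 to the negative one.  The balance
parameter r defaults to "auto": r ≈ u·(n₊−n₋)/l from the labeled class
ratio, clipped to [−u, u], with parity adjusted toward zero when (r+u) is
odd (the tie at r = 0 goes to the labeled majority sign).  The equilibrium
constraint Σ sgn f = r is what prevents the degenerate solution of
assigning all unlabeled points to one class.

For fixed d the problem is convex; its dual involves only the l labeled
points plus two virtual mean-instances, with feasible set
Σαᵢỹᵢ = 0, α_{l+1} + α_{l+2} = c₂, 0 ≤ αᵢ ≤ c₁ (i ≤ l),
0 ≤ α_{l+1}, α_{l+2} ≤ c₂.  The augmented kernel is computed purely from
the base Gram matrix (kernel trick), so no explicit feature maps exist
anywhere.

*Alternating solver (iter).*  d is initialised by ranking the supervised
SVM's decision values (the warm start consistent with the ranking
theorem: if f(xᵢ) > f(xⱼ) then dᵢ ≥ dⱼ in some optimal assignment).  Each
generation solves the convex problem and re-ranks d; an update is accepted
only if the objective does not increase, so the objective history is
non-increasing by construction and the loop terminates at a fixed point or
after `max_generations` (default 50).

*Cutting-plane MKL solver (mkl).*  Active d's contribute augmented kernels
combined with simplex weights μ.  The inner min–max is solved by
alternating the α-QP on the combined kernel with exponentiated-gradient
steps on μ (the objective is convex piecewise-linear in μ; a few dozen
steps suffice at this scale).  The most-violated new d is proposed by
ranking the combined decision values — the same rule the alternating
solver uses — rather than an exact violation maximisation; the loop stops
on a duplicate proposal, improvement < tol, or the generation cap.  Final
labels re-rank the combined decision values, so Σ sgn = r holds exactly.

With u = 0 or c₂ = 0 both solvers coincide with the supervised baseline
(checked to 1e−6 in the tests).

## Safe S3VM (S4VM)

The S3VM objective of a candidate separator is
h(f, ŷ) = ½‖f‖² + C₁·(labeled hinge) + C₂·(unlabeled hinge).
Candidates are sampled by local search: a random balanced labeling
(Σ = r) is refined by flipping one (+,−) pair at a time — the pair the
current decision values mark as most misclassified, with a small number of
runner-up pairs tried — keeping a flip only when h strictly decreases.
Pair flips preserve the balance exactly; h is non-increasing along every
trajectory (asserted in tests).  Defaults: 30 restarts (one warm-started
from the supervised ranking), ≤ 50 flips each, up to T = 20 distinct
candidates kept.  Inner refits use scikit-learn's libsvm backend with
sample weights C₂/C₁ on pseudo-labeled points; h is recomputed from the
fitted duals.

Representatives are chosen by k-means (k = 5) on the ±1 labeling vectors
(Euclidean on ±1 coordinates is monotone in Hamming distance), keeping the
lowest-h member per cluster.  The diversity of a labeling set is reported
as the mean squared pairwise agreement fraction (1 = all identical,
0 = complementary); the constant M (default 1e4) and this Ω instantiation
matter only as diagnostics of separator diversity, since sampling, not
explicit Ω-minimisation, provides the diversity.

The final labeling maximises the worst-case gain over the supervised
baseline: y⋆ = argmax_y min_t [gain(y, ŷ_t) − gain(ŷ_svm, ŷ_t)] with
gain(a, b) = #agreements − #disagreements = a·b.  The candidate pool is
the representative labelings plus the baseline itself (exhaustive search
over 2ᵘ labelings is used as an oracle in tests for u ≤ 10); ties go to
the baseline, so the returned worst-case gain is never negative — the
"safety" guarantee that unlabeled data cannot make the worst case worse.

## Evaluation

Confusion counts treat interface (+1) as positive.  Six metrics: accuracy,
sensitivity, precision, specificity, F-measure (harmonic mean of precision
and sensitivity) and MCC.  A metric with a zero denominator is reported as
0 and flagged `undefined` instead of raising, so fold aggregation stays
total.

Cross-validation is stratified k-fold (default 5) with a seeded shuffle.
Because the benchmark this protocol mirrors is fully labeled, unlabeled
samples are created by masking a seeded fraction (default 0.7) of each
*training* split; one exemplar per class always stays labeled so every
learner is well-posed, and the test fold is never touched during training.
Semi-supervised learners predict held-out folds inductively: the
label-mean models evaluate their decision function; S4VM trains a weighted
SVM (C₁ labeled, C₂ pseudo-labeled) on its safe labeling.  Optional
negative undersampling of the training split exists for heavily imbalanced
data but is off by default.  Fold stability is summarised as per-metric
absolute deviations from the cross-fold mean.

## Synthetic data

`make_two_gaussians` draws a 2-D semi-supervised toy from N(±c, σ²I); σ
sweeps 0.1–0.7 in the safety experiments, from cleanly separated to
heavily overlapping.

`make_synthetic_complex` emulates the statistical structure the pipeline
assumes: partner chain B occupies a compact blob; a chosen fraction of
chain A's surface residues is placed strictly inside 11 Å of some B
residue and everything else strictly outside 13 Å — a 1 Å guard band on
each side of the 12 Å cutoff so planted labels are immune to floating
point.  Surface residues draw relative accessibilities in (0.25, 0.8) and
buried ones in (0, 0.12), keeping clear of the 16% threshold for the same
reason.  Conservation signal comes from Dirichlet concentrations:
interface profiles use α = 2·10^(−gap) (peaked, low entropy), others
α = 2.0 (flat); one knob (`conservation_gap`, bits-scaled) controls class
separability, with weight = 1 − relative entropy and
rate = relative entropy + N(0, 0.05).

What this generator does *not* emulate: realistic protein packing, chain
connectivity constraints, alignment-depth effects on profiles, or the
partial correlation between accessibility and conservation seen in real
interfaces.  Consequently, at the default 1-bit gap the classes are far
more separable than in real benchmarks — all learners sit near ceiling in
cross-validation, and the method ordering (s4vm ≥ mkl ≥ supervised) holds
with near-equal accuracies.  Passing tests therefore demonstrate
correctness of the machinery and the qualitative safety/ordering
behaviour, not real-data performance levels; the transductive runs, where
the balance constraint and label masking bite, are the harder and more
informative numbers.

## Problem sizes and numerics

Experiments run at desk scale, chosen so the whole suite exercises every
code path quickly: complexes of 200 + 40 residues (≈160 surface targets),
toys of 40 unlabeled points, 5–10 seeds per experiment.  QPs are jittered
by 1e−10 on the diagonal; duplicate-labeling candidates are deduplicated
exactly; all tie-breaks (ranking, windows, k-means seeding) are
deterministic by ascending index; every random draw flows from an explicit
seed, and CLI outputs embed the config hash and seed.

## Known limitations

* The cutting-plane solver's most-violated-d step uses the ranking rule,
  not exact violation maximisation; on adversarial instances it can stall
  at the same d as the alternating solver.
* The fallback conservation weight is a surrogate, not HSSP's WEIGHT
  formula; with real HSSP files the pass-through is used.
* `estimate_r` transfers the labeled class ratio to the unlabeled pool;
  when the two differ (sampling noise at small l), the equilibrium
  constraint forces a proportional number of errors — visible as the gap
  between transductive and inductive accuracy on the synthetic complexes.
* Only the classic fixed-column HSSP profile block (plus an optional
  trailing ACC column, used by the fixture writer) is parsed.
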