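# Methods

## Problem setting

Protein function annotation is usually available per protein, not per
residue: we may know that a protein binds DNA without knowing which
residues touch the nucleic acid.  `milboost` treats this as
multiple-instance learning (MIL).  Each protein is a *bag* of
*instances* — one feature vector per residue microenvironment — and the
class label (binding / non-binding, encoded ±1) attaches to the bag.
The MIL assumption is the witness rule: a bag is positive if and only
if at least one of its instances is truly positive.  Training uses only
bag labels; the fitted model scores both bags (does this protein bind?)
and instances (which residues are responsible?).

## The boosting reduction

The trainer reduces MIL to importance-weighted classification inside an
AdaBoost-style loop.

**Setup.**  Every negative bag is split into one singleton bag per
instance.  Because all instances of a negative bag are certainly
negative, the split loses no information, while giving each negative
instance its own boosting weight.  A uniform distribution
w_1,i = 1/n is placed over the n reorganized bags.

**Per round t = 1…T:**

1. *Instance table.*  Each bag's weight is split uniformly over its
   instances (w_i/n_i) and every instance inherits its bag's label —
   provisionally labelling all residues of a binding protein as
   binding.
2. *Weak learner.*  A confidence-rated decision tree ĥ_t is grown on
   the weighted table (see below).
3. *Bag vote.*  Instance confidences are squashed to probabilities
   p̂ = 1/(1+exp(−ĥ_t)) and each bag is scored by the
   probability-weighted vote of its instances' signs:

       h_t(X_i) = Σ_j p̂(ĥ_t(x_ij))·sgn[ĥ_t(x_ij)] / Σ_j p̂(ĥ_t(x_ij))  ∈ [−1, 1].

   Instances the tree is confident about dominate the vote, so a single
   strongly-positive residue can flip a protein positive — precisely
   the witness semantics.  For a singleton bag the vote collapses to
   sgn(ĥ_t).
4. *Bag-level AdaBoost.*  ε_t = Σ_{sgn h_t(X_i) ≠ y_i} w_t,i,
   α_t = ½ ln((1−ε_t)/ε_t), and
   w_{t+1,i} ∝ w_t,i · exp(−α_t · sgn[h_t(X_i)] · sgn(y_i)), renormalised.

Outputs: instance score H(x) = Σ_t α_t ĥ_t(x) and bag score
H(X_i) = Σ_t α_t h_t(X_i).

Conventions and edge cases:

- sgn(0) = −1 everywhere: a bag must show strictly positive evidence to
  be called positive.
- ε_t = 0 is floored at `epsilon_clamp` (default 1e-10) so α_t stays
  finite; after two consecutive zero-error rounds training stops, since
  the weight update is then a uniform factor and every later round
  would repeat verbatim.
- ε_t ≥ 0.5 discards the round and stops training.
- Training is fully deterministic: the only randomness in the package
  sits in data generation and fold assignment, both seeded.

**Baseline.**  The standard-AdaBoost comparator treats MIL as
classification with positive-label noise: every instance is labelled
with its bag label and discrete AdaBoost runs at the instance level
(sign error, sign weight update) with the same confidence-rated trees.
At prediction time bags are scored with the same probability-weighted
vote, so bag-level comparisons isolate the training difference.  On a
dataset of singleton bags the two algorithms coincide exactly, round
for round — this reduction is asserted in the test suite to 1e-12.

## The weak learner

A greedy top-down binary tree on the weighted instance table.  Splits
minimise the weighted impurity mass W·G(q) with G(q) = 2√(q(1−q)) and
q the weighted positive fraction — the criterion that directly bounds
the exponential loss of confidence-rated boosting.  Candidate
thresholds are midpoints between consecutive distinct sorted feature
values; ties break to the lowest feature index, then lowest threshold.
Leaves predict the smoothed half log-odds
½ ln((W₊+s)/(W₋+s)), bounded by ½ ln((1+s)/s); s defaults to 1/(2N).

Defaults: `max_depth=8`, `min_leaf_weight=1e-3`, T=100.  The depth is
deliberately larger than typical boosted-tree practice.  The bag vote
can only let one witness flip a bag when leaves are confident (p̂ of
the background instances near 0), which requires deep, nearly pure
leaves; with stumps or depth-3 trees the first round misclassifies
essentially every positive bag at tiny ε (the reorganized negatives
hold almost all of the uniform initial weight), the resulting large α
makes the next round's bag error cross 0.5, and training aborts.  The
`min_leaf_weight` floor of 1e-3 (on a total weight of 1) is what keeps
depth-8 trees from memorising single heavily-weighted instances.

## Residue-microenvironment features

Each residue becomes a 205-dimensional vector of six blocks: one-hot
residue identity (20, alphabetical one-letter order); secondary
structure (3: helix = H/G/I, strand = E/B, coil = everything else,
collapsed from the DSSP 8-state code); structural neighbour counts
(20: residues of each type with minimum heavy-atom distance strictly
below 3.0 Å); the PSI-BLAST PSSM row (20 log-odds, columns reordered
to the alphabetical alphabet); BLOSUM62 rows for sequence offsets
−3…+3 (140; out-of-range offsets and chain boundaries contribute zero
blocks — windows are chain-local); and two physico-chemical properties
(formal side-chain charge D/E = −1, K/R = +1, H = +0.5, others 0; and
relative solvent accessibility = DSSP acc / max-ASA, clipped to
[0, 1.2], with the Sander max-ASA table).  The 3-state secondary
structure block and the 205 total are a reconstruction: only the
20-dimensional identity and the 140-dimensional substitution window
have unambiguous published dimensionalities, so the remaining blocks
use the minimal faithful encodings above.

File handling: structures are read with Bio.PDB (first model, heavy
atoms only; MSE→M, SEC→C and common phospho-residues mapped, other
non-canonical residues dropped with a log line); DSSP output files with
Bio.PDB's DSSP-file parser, keyed by chain and author residue number;
substitution matrices via Bio.Align (BLOSUM62 by default, NCBI-format
files accepted); the PSI-BLAST ASCII PSSM parser is local to the
package.  The PSSM sequence must match the structure-derived sequence
exactly; mismatching positions are reported.  A missing profile is
accepted only with `allow_missing_profile=True` (block zeroed).

Out of scope by design: running PSI-BLAST/DSSP/CD-HIT, fetching
structures, and sequence-identity redundancy filtering — inputs are
assumed pre-computed and pre-filtered.

## Synthetic witness-model data

The generator draws background instances from spherical Gaussian noise
(sd `noise_sd`) around the origin and witnesses from the same noise
around a mean at distance `separation × noise_sd` along a seeded random
direction.  Positive bags draw each instance as a witness with
probability `witness_rate` (at least one forced); negative bags contain
none.  Bag labels always equal the witness rule applied to the true
instance labels, and those true labels ride along in metadata for
evaluation only.  Defaults — 30 positive vs 120 negative bags (the
1:4 imbalance of curated nucleic-acid-binding benchmarks), sizes
uniform on {5..20}, witness rate 0.2, separation 3, d = 20 — define
the package's standard benchmark conditions.  A scaled Student-t
(df = 3) noise option stresses the trees with heavy tails.

What the generator does *not* emulate: the discreteness and
block structure of real residue features (one-hot blocks, integer
PSSMs), spatial autocorrelation between neighbouring residues, and
bag-size/label correlations.  Passing recovery tests on this model
therefore demonstrates the learning machinery, not protein-level
performance.

Under the default conditions the benchmark is genuinely hard: the
witness displacement lies along a random oblique direction, so no
single feature separates witnesses, and the Bayes-optimal bag-level
AUC (exact likelihood ratio under the generative model) is ≈ 0.98,
with a max-projection oracle along the true direction at ≈ 0.965.

## Evaluation

AUC is the Mann-Whitney rank statistic (ties half credit), identical
to the area under the threshold-sweep ROC curve; the test suite pins
it to a brute-force concordant-pair count to 1e-12.  Operating points
are conservative: sensitivity at a given specificity is the best TPR
among curve points with FPR ≤ 1 − specificity, with no interpolation.

Cross-validation is bag-stratified: bags are partitioned into k folds
per class (deterministic given the seed), so all residues of a protein
share its fold.  Held-out scores are pooled across folds and reported
in three regimes: `protein` (bag scores), `residue_all` (instance
scores over every instance), and `residue_posonly` (instances of
positive bags only — among a binding protein's residues, are the truly
binding ones ranked first?).  Instance-level regimes require true
instance labels, which are never shown to training; negative-bag
instances default to −1 under the MIL assumption.  Per-fold AUCs are
reported alongside the pooled numbers.  Per-residue-type precision and
recall (over positive-bag instances, default threshold: ensemble score
> 0) support the analysis of which residue types carry the signal;
types with no predicted positives get undefined (NaN) precision rather
than zero.

## Problem sizes

The standard benchmark (150 bags, ≈ 1,900 instances, d = 20) with
T = 150 rounds of depth-8 trees cross-validates in about two minutes
per algorithm on a single core; the weight-conservation run uses 200
rounds on a 60-bag dataset; ROC exactness checks 1,000 random vectors
of up to 200 scores.

## Known limitations

- Axis-parallel trees approximate the oblique witness direction of the
  synthetic benchmark slowly; held-out bag AUC saturates a few points
  below the ≈ 0.98 Bayes ceiling at these sample sizes.
- The bag vote treats instances independently; correlated residues
  (e.g., a contiguous binding patch) are not modelled beyond what the
  neighbour features encode.
- Reorganization makes the initial distribution extremely
  negative-heavy on realistic bag ratios; the first rounds are spent
  re-weighting toward positive bags, which is visible in the training
  log as a small ε_1 followed by much larger ε_2.
- The pooled CV AUC concatenates scores from models whose α-scales
  differ across folds; per-fold AUCs are reported for comparison.
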