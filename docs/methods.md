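# Methods

## Model and procedure

`confscreen` implements a two-round iterative screening policy driven by
set-valued conformal predictions and a linear gain–cost account.

**Splits.** A campaign starts with a simple random draw of 20% of the
library (`SplitPlan.initial_fraction`). The draw is deliberately *not*
stratified: conformal validity rests on exchangeability between the
calibration data and the compounds being predicted, and a random sample is
the only selection that preserves it. A stratified option exists for tiny
benchmark libraries and is documented as breaking the guarantee. Within
any model-building subset, 70% becomes proper training and the remainder
calibration (`floor(0.7·n)`, remainder to calibration, so calibration is
nonempty for n ≥ 2).

**Nonconformity.** The underlying model is a scikit-learn random forest
(default 500 trees, otherwise default parameters). The conformity score of
a compound for a class is the ensemble vote fraction for that class. Two
readings of "vote fraction" are provided:

* `soft` (default): per-tree class probabilities averaged over trees;
  scores for the two classes sum to one.
* `hard`: one vote per tree for its leaf's strict-majority class; a tied
  leaf abstains, so scores may sum to less than one.

The default is `soft` because it is what scikit-learn's ensemble
probability machinery natively produces and it yields finer-grained
scores; `hard` exists because abstaining trees are a real phenomenon in
deployed screening models and the package should be able to reproduce
that behavior.

**p-values.** For a new compound, each class score is placed into that
class's ascending calibration score list and the fraction of the augmented
list strictly below it is the conformal p-value:

    p = #{c in calibration : c < s} / (n_calibration + 1)

A class is included in the prediction set iff `p ≥ ε` (boundary
inclusive). Calibration is **Mondrian** (label-conditional): a calibration
compound's true-class score enters only its own class's list. This is what
makes per-class error control hold for minority actives at 0.3–12%
hit rates; an unconditional pooled mode is available behind
`mondrian=False` for comparison.

**Tie handling.** The strict-lower rule is the package default. Vote
fractions are discrete (atoms at multiples of 1/n_trees, and a large atom
at 1.0 for confidently classified compounds), and ignoring ties makes the
p-value smaller than the rank-randomised version by the tie mass, i.e. the
default is *anti-conservative* by up to a few percent of coverage on
well-separated data. `smooth_ties=True` counts each tie as one half
(deterministic mid-rank), which restores the exact finite-sample coverage
guarantee up to discreteness; the coverage tests in this package use the
smoothed variant for precisely that reason, while the default remains the
strict rule that reproduces the 8/10 = 0.80 worked example. Whether a tied
calibration value should rank above or below the new compound is genuinely
underdetermined; strict-lower was chosen and is not asserted to be the
only defensible reading.

**Aggregation (ACP).** The proper/calibration split is resampled
`n_iterations` times (default 100; tests scale this down) and per-compound
p-values are medians across iterations (even count: mean of the two
central order statistics). For *external* prediction every iteration
re-splits the full training set. For *internal validation* every iteration
first leaves out a random 20% of the training compounds, fits on the
remaining 80%, and predicts only the left-out part; a compound's medians
are taken over exactly the iterations that left it out — the only reading
that keeps internal p-values out-of-sample. Contribution counts are
reported; a compound never left out keeps NaN p-values and is excluded
from every downstream rate estimate rather than imputed. Median
aggregation forfeits the exact finite-sample guarantee of a single ICP;
per-class validity is asserted empirically with binomial tolerance
instead.

**Seeds.** All randomness flows from explicit integer seeds. Iteration
`i` of an ACP uses `seed + i` (retries after a degenerate split shift by
a large constant), so any single iteration can be reproduced in isolation
and the aggregate is independent of iteration order.

## Gain–cost scan and decision

The account is linear: each screened compound costs `screen_cost`
(defaults scanned over 6/10/14, representing assay complexity) and each
confirmed hit earns `hit_gain` (default 400, set so an unguided full
screen at typical hit rates lands near break-even). For each significance
level in the grid (default ε ∈ {0.1, 0.2, 0.3, 0.4}) the internal
validation selection — compounds predicted exactly {active} — yields a
selected fraction and a hit fraction; both are scaled proportionally to
the remaining library size to produce an estimated test-side gain.
Proportional scaling is the assumption-free choice; it treats the
training compounds as a uniform sample of the library, which the random
initial split makes true by construction. Two baselines complete the
candidate set: screening everything remaining (priced at the initial
screen's observed hit rate) and stopping (gain 0).

The decision is the gain-maximising candidate; the campaign stops iff no
candidate has positive estimated test-side gain. Exact ties break toward
the lower significance level (higher confidence), then toward fewer
screened compounds, so a conformal selection beats screen-all at equal
gain. The training-screen terms are sunk at decision time — they are
excluded from the comparison but included in all reported totals. When
the cost already spent on the initial screen exceeds five times the best
indicated subset gain, the decision carries a low-expected-gain warning:
empirically such campaigns rarely end in overall profit even when the
subset screen itself is marginally profitable.

In benchmark mode the package evaluates every candidate policy on the
true test labels (`oracle_best_gain`) and reports regret as
`100·(oracle − realized)/|total gain at oracle|`; when that total is not
positive a percentage is meaningless and the report falls back to the
absolute difference, flagged as such.

## Synthetic libraries

`synthlib` generates labelled libraries with the statistical shape of
large public bioassay screens: binary labels at hit rates 0.3–12.5%,
fingerprint-like sparse binary features (default density 0.02, width
4096) or descriptor-like standard-normal features (width 97), and sizes
from thousands upward. Labels follow a logistic model on a linear score
over `n_informative` leading features, weighted `effect_size/√n_informative`
so the score's scale is independent of how many features carry signal;
the intercept is solved numerically (Brent) so the marginal active rate
equals the requested hit rate, and labels are then flipped with
probability `label_noise`. Rows are i.i.d., hence exchangeable — the
regime where conformal validity is provable.

What the generator does *not* emulate: scaffold clusters and activity
cliffs (which violate exchangeability locally), assay noise structure,
plate effects, or any real chemistry. Passing tests on these libraries
demonstrate the statistical machinery — coverage, transfer of internal
estimates, decision quality — under the method's stated assumptions; they
do not certify performance on a particular real screening collection.

## Featurization

SMILES input is turned into either a 97-descriptor physicochemical block
or a folded binary Morgan fingerprint (default radius 2, 4096 bits). The
fold maps every raw 32-bit fingerprint index `i` to bit `i mod n_bits`;
the result is binary, so pre-fold multiplicities are discarded. The
97-name descriptor list shipped as the default covers bulk properties,
topological indices, atom/ring counts and the SlogP/SMR/PEOE/EState
surface-area partitions; the particular membership is a package choice
(the width matches descriptor sets used in published HTS models) and is
fully overridable via `DescriptorConfig`. A compound for which any
descriptor fails or returns a non-finite value is excluded and reported,
never silently imputed — imputed feature rows would contaminate the
calibration lists. Structure standardization is out of scope; a
`standardize_hook` lets callers apply their own before featurization.

## Problem sizes used in the test suite

The automated tests scale the procedure down to keep the suite fast while
preserving the quantities that drive behavior — calibration-list sizes
and per-class counts:

* coverage: one ICP with ≥150 calibration compounds per class, 2000
  held-out compounds;
* internal/external transfer: 16 000 compounds, 12% hit rate, 25
  aggregation iterations, 200 trees;
* decision recovery: twelve libraries spanning hit rates 0.3–12.5%, each
  sized so the initial screen contains on the order of 60 actives
  (capped at 100 000 compounds), with 32-wide feature vectors, 15
  iterations and 100 trees, evaluated at all three cost levels.

The sizing rule for the benchmark libraries mirrors, proportionally, the
fact that even the most imbalanced real screens contribute a three-digit
number of actives to their training split; with materially fewer actives
the internal gain estimates degrade into noise and the level scan's
argmax becomes arbitrary — a genuine small-sample limitation of the
method, not an implementation artifact.

## Known limitations

* The gain model is linear and uniform; no per-compound costs, budget
  caps, or diminishing returns for redundant chemotypes.
* Exactly two rounds; no lookahead to further iterations.
* Median-aggregated p-values lose the exact finite-sample guarantee;
  coverage statements after aggregation are empirical.
* The decision compares point estimates of gain; no uncertainty band is
  propagated to the decision itself (the level scan output exposes the
  ingredients for one).
* Internal gain estimates are scaled to the remainder proportionally;
  other scalings are conceivable and the choice is logged in the report.
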