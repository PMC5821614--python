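# confscreen

Conformal-prediction-driven iterative high-throughput screening with a
gain–cost decision function.

## The problem

In iterative HTS a fraction of a compound library is screened first and the
results are used to decide what — if anything — to screen next. Classical
enrichment metrics do not answer the operational questions: *how many*
compounds should the next round contain, and is a next round worth its cost
at all? `confscreen` answers both by combining

* an **aggregated Mondrian conformal classifier** built on random-forest
  vote fractions, which turns an initial random screen into per-compound
  prediction sets ({active}, {inactive}, both, or empty) with a
  user-controlled error rate, and
* a **gain–cost function** that prices every screened well and every
  confirmed hit, so candidate screening policies can be compared in a
  single currency.

## The method

An initial random 20% of the library is screened; randomness keeps the
remaining 80% exchangeable with the training data, which is what the
conformal validity guarantee requires. On the screened part:

1. **Conformity scores.** A 500-tree random forest is fitted on a 70%
   "proper training" split; the fraction of trees voting for a class is
   that class's conformity score. The held-out 30% calibration compounds
   contribute their true-class scores to per-class (Mondrian) sorted
   reference lists — label-conditional calibration is what preserves
   per-class validity at hit rates of a fraction of a percent.
2. **Conformal p-values.** A new compound's class-*k* p-value is the
   fraction of the augmented calibration list strictly below its class-*k*
   score, `p_k = #{c < s_k} / (n_cal + 1)`; class *k* enters the prediction
   set iff `p_k ≥ ε`. For example, a score placed at position 9 of a
   ten-element augmented list gives p = 8/10 = 0.80, so at ε = 0.20 the
   compound is assigned that class.
3. **Aggregation.** The proper/calibration split is resampled and the ICP
   refitted (default 100 iterations); per-compound p-values are medians
   across iterations. Internal validation repeats this with a random 20%
   left out per iteration, predicting only the left-out compounds.
4. **Level scan and decision.** For each significance level on a grid
   (default ε ∈ {0.1, 0.2, 0.3, 0.4}, i.e. confidence 90–60%), the
   compounds predicted single-label active in internal validation define a
   candidate selection; its observed screened- and hit-fractions are scaled
   to the unscreened remainder and priced with

   `gain = hit_gain·hits_train − cost·screened_train + hit_gain·hits_test − cost·screened_test`

   (defaults: hit_gain = 400; cost ∈ {6, 10, 14}). Together with the
   screen-everything and screen-nothing baselines, the gain-maximising
   option becomes the decision: **screen_subset**, **screen_all**, or
   **stop**.

In benchmark mode (test labels known) the package also computes the oracle
best — the hindsight-optimal policy — and the regret of the decision
against it.

## Worked example

```bash
confscreen simulate --n 4000 --hit-rate 0.03 --n-features 32 \
    --n-informative 8 --effect-size 8 --seed 11 --out lib.csv
confscreen screen --library lib.csv --seed 11 --iterations 15 \
    --trees 100 --costs 6,10,14 --out run/
```

prints

```
wrote 4000 compounds (126 active, 0.0315) to lib.csv
cost 6: screen_subset at significance 0.2, estimated test gain 20134.6
cost 10: screen_subset at significance 0.2, estimated test gain 17981.7
cost 14: screen_subset at significance 0.2, estimated test gain 15828.9
```

Reading: at a 3% hit rate screening everything remaining would roughly
break even at best, but the conformal selection at 80% confidence — the
430 of 3200 remaining compounds predicted single-label active
(`run/selection_cost10.csv`) — concentrates most of the expected hits in a
small screen, so it wins at every cost level, with the projected gain
shrinking as the assay gets more expensive. `run/levels_cost*.csv` holds
the full scan (validity, efficiency, selection sizes and estimated gains
per level), and `run/decision_cost*.json` the machine-readable decision,
including a low-expected-gain warning when the cost of the already-screened
training set exceeds five times the indicated subset gain.

The same workflow is available as a library call:

```python
import confscreen as cs

lib = cs.generate_library(cs.LibrarySpec(n_compounds=4000, hit_rate=0.03,
                                         n_features=32, n_informative=8,
                                         effect_size=8.0, seed=11))
report = cs.run_iterative_screen(
    lib, cs.SplitPlan(seed=11), cs.AcpConfig(n_iterations=15, seed=11),
    cs.GainCostParams(screen_cost=10), n_trees=100)
print(report.decision.mode, report.decision.significance,
      report.decision.realized_test_gain, report.oracle.gain)
```

## Scope

The package models two screening rounds with fixed per-well cost and
per-hit gain. It does not schedule more rounds, price compounds
individually, or score the chemical novelty of selections; compound
standardization before featurization is left to the caller (a hook is
provided).
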