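# Methods

## The prediction problem

Pathologic stage — organ-confined disease (OCD: pT2 sub-stages with pN0)
versus non-organ-confined disease (NOCD: any pT3 sub-stage or pN1) — is
determined after radical prostatectomy but must be anticipated before it.
The label is derived from AJCC pathologic T and N categories:
`derive_label` returns NOCD iff pT3a/b/c or pN1.  Absence of a recorded
nodal stage is read as pN0.  NOCD is the positive class in every metric
because the clinically costly error is calling extraprostatic disease
confined.

## Predictor encodings

* **PSA** (continuous, ng/mL) is rounded to the nearest integer (ties to
  even), clipped to [0, 511] and written as 9 binary digits, MSB first.
  Nine bits is the smallest width covering the observed maximum
  (440 ng/mL).  Classifier behaviour is invariant to any fixed bit
  permutation, so the MSB-first choice only matters for serialization.
* **Gleason score** is one-hot over the nine ordered categories
  3, 4, 5, 6, 7(3+4), 7(4+3), 8, 9, 10.
* **Clinical T stage** is one-hot over the eight ordered categories
  T1a … T3b.

## Per-feature deep belief networks

Each predictor has its own network of three RBM layers, each as wide as
its input (9/9/8), with logistic units throughout and a two-unit logistic
head.

* **Pretraining**: greedy layer-wise contrastive divergence (CD-1 by
  default; binary-sampled hidden states in the negative phase, mean-field
  visible reconstruction).  Default 100 epochs *per layer*; an
  `epoch_allocation="total"` switch spreads the budget across the stack
  instead.  Layer *k*+1 trains on layer *k*'s hidden activation
  probabilities.
* **Fine-tuning**: 1 000 epochs of mini-batch backpropagation through the
  unrolled network (all layers by default; `freeze_stack` trains only the
  head), minimizing the summed binary cross-entropy of the two head units
  against one-hot targets.
* **Defaults**: learning rates 0.1/0.1, batch size 32, weights
  N(0, 0.01²), zero biases, every RNG seeded.  On a 4 400-patient training
  split the full schedule takes ~12 s per network on one CPU, so no
  reduced schedule is needed anywhere.
* The head outputs are **not** softmax-normalised: the pair
  `(p_OCD, p_NOCD)` is passed on as-is so that the shortfall from 1 can
  act as unassigned belief in the fusion stage.  With near-separable
  training data the two units approximately sum to 1 and the ignorance
  mass is small.
* A practical note on optimisation: with small initial weights the
  three-sigmoid stack starts near a plateau (top-layer activations ≈ 0.5
  regardless of input).  The default 100/1000 schedule at lr 0.1 escapes
  it reliably; much shorter schedules can stall unless the learning rate
  is raised.

Model archives are JSON with float64 values stored as hex strings, so a
save/load round-trip is bit-exact.

## Dempster–Shafer fusion

Frame Θ = {OCD, NOCD}; focal sets {OCD}, {NOCD}, Θ.  A mass function is
built from a score pair by `m(OCD)=p_OCD`, `m(NOCD)=p_NOCD`,
`m(Θ)=1−p_OCD−p_NOCD`.  Two deliberate choices:

* The residual is assigned to **Θ, not the empty set**.  Treating the
  shortfall as mass on ∅ would contradict the axiom m(∅)=0; placing it on
  Θ is the standard reading of unassigned belief as ignorance and leaves
  every downstream formula unchanged.
* If a score pair sums to more than 1 (two confident logistic units), the
  singletons are renormalised and ignorance is 0 — a guard, since the
  mass construction does not otherwise anticipate such pairs.

Combination is Dempster's rule with conflict
`p = m₁(OCD)m₂(NOCD) + m₁(NOCD)m₂(OCD)`; total conflict (p = 1) raises an
explicit error rather than silently falling back.  n sources are folded
left-to-right (the rule is commutative and associative; a property test
checks order-invariance to 1e-9, and an independent power-set
implementation must agree to 1e-12).  Evidential intervals are computed
from the **combined** mass for both hypotheses.  Source unreliability can
be discounted per source (`m_r(A) = (1−r)m(A)` on singletons, remainder to
Θ); the default r = 0 trusts each network fully.  Decisions take the
larger singleton mass; exact ties go to OCD, the majority class — a fixed,
documented rule instead of nondeterminism.  The ROC score of any (single,
pair, or triple) classifier is its combined m(NOCD).

## Evaluation

Confusion-matrix metrics use NOCD as positive.  Zero denominators raise an
error instead of returning a silent 0.  ROC curves sweep the distinct
score values (case called positive at score ≥ threshold) with the (0,0)
and (1,1) endpoints; AUC is the trapezoidal area, which equals the
tie-corrected rank statistic (verified against exhaustive pair
enumeration).  The standard error is the Hanley–McNeil (1982) closed form
and the 95% CI is auc ± 1.96·SE clipped to [0, 1]; these conventions are
fixed here because published AUC tables rarely state theirs, and a seeded
bootstrap check confirms the closed form tracks the resampling SE.

## Synthetic cohort generator

The generator's defaults *are* the published training-set conditions:
prevalence 1561/4039 NOCD; per-class Gleason and clinical-T categorical
distributions proportional to the printed counts (counts, not printed
percentages — some printed percentage columns are not consistent with
their printed group size, and counts are self-consistent); per-class PSA
as a log-normal truncated to the printed [min, max] with the log-mean
solved (Brent root-find on the truncated-mean identity) so the truncated
mean equals the printed class mean.  Only min/mean/max of PSA are
published, so the log-scale spreads (0.55 OCD, 0.75 NOCD) are free
defaults chosen to give right-skewed, clinically plausible PSA
distributions; they are configurable but fixed.

Pathologic sub-stages are emitted as one representative pair per class
(pT2a/pN0 for OCD, pT3a/pN0 for NOCD) since only the binary label feeds
the model.

**What the generator does not emulate**: the three predictors are drawn
independently *given the class* because only marginals are published —
the joint is unidentifiable.  Real cohorts correlate PSA with grade and
stage, typically making the three sources partially redundant.
Consequently accuracies measured on synthetic cohorts characterise the
method under the generator's model, not the registry data, and the
published real-data operating points are deliberately not used as numeric
targets.  What the passing tests do show: the mechanics are correct
(oracle equivalence, algebraic laws), the generator hits its calibration,
the networks learn (toy task), and the fused system lands strictly above
the majority-class rate and at or below the Bayes-oracle bound — the
bracket any sound classifier must occupy under the generating model.

The exact posterior under the generator (prevalence × categorical
likelihoods × truncated-log-normal density) is exposed as
`bayes_predict`; it is invariant to rescaling the counts of a class and
serves as the oracle upper bound in the acceptance checks.

## Numerical and design choices

* Splitting: seeded uniform permutation, first `round(fraction·n)` records
  to training, default fraction 0.70, unstratified.  (For n = 6 345 this
  gives 4 442/1 903; the published 4 039/2 306 split of the same total is
  not an exact 70/30 rounding, so the fraction is configurable rather than
  hard-coded to reproduce it.)
* Category strings are matched case-insensitively after trimming; rows
  failing validation are rejected and counted, not fatal; missing required
  columns are fatal.
* PSA rejection sampling into [min, max] accepts ~90% of draws at the
  default parameters; the calibration solve is cached per class.
* Mass functions are validated to non-negativity and unit sum within 1e-9
  at construction; combination renormalises away float drift before
  validation.
* Problem sizes used in the test and acceptance runs: 10⁴ random mass
  pairs for oracle equivalence, n = 10⁵ draws for generator calibration,
  n = 6 345 with the full 100/1000 epoch schedule for the end-to-end
  bracket — together about a minute on one CPU.

## Known limitations

* Conditional independence given class (above) is the dominant gap between
  synthetic and real cohorts.
* The binary PSA encoding makes the network learn a bit-pattern
  representation of magnitude; single-bit flips at power-of-two boundaries
  are large Hamming moves, so the PSA network needs the full fine-tuning
  schedule to smooth them out.
* The two-class frame is fixed; larger frames exist only in the test
  oracle.  No alternative combination rules (Yager, PCR5) and no
  significance testing between classifiers.
* TRUS volume and age, sometimes recorded alongside these predictors, are
  intentionally out of scope: the model never consumes them.
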