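# Methods

## Problem and data model

A candidate m⁵C site is a cytosine whose methylation status is to be
predicted from local sequence context alone.  The unit of analysis is the
window of `2·flank + 1` nucleotides centred on the site (flank = 20, so
41 nt with the site at position 21, 1-based).  Inputs are a
positive/negative FASTA pair of pre-cut windows (or full sequences plus
site coordinates, cut with `extract_window`) and a k-mer embedding table
in whitespace-separated text.  Sequences are uppercased and T→U
transliterated before validation, since these datasets commonly ship in
the DNA alphabet; by default both labels must have C at the centre
(negative sites are cytosines too), and a flag disables that check for
exploratory inputs.

## Encoding

All k-mer start positions whose span contains the centre are discarded —
the centre is identical across windows and carries no information.  For
41-nt windows and k = 4 that removes starts 18–21, leaving the 34 slots
1–17 and 22–38.  Feature columns are **slot-major** (all `dim`
components of slot 1, then slot 2, …; slots in ascending start order),
giving 34 × 30 = 1020 columns by default.  Slot-major order is a
declared convention — ranking quality is order-invariant, but reported
feature indices depend on it — chosen so a feature's positional
provenance is contiguous.  Every column carries a `FeatureDescriptor`
(slot, start, embedding component, covered positions); the invariants
`slot = ceil(index/dim)` and `emb_dim = (index−1) mod dim + 1` are the
inverse of the layout and are exercised directly in tests.

Missing k-mers at lookup follow a configurable policy: `error` (default;
the curated benchmark data contain no ambiguous bases, so a miss means a
malformed table) or `zero` (substitute a zero vector, for permissive
use on real FASTA).

## mRMR ranking

Each feature column is discretized once into three states around its
mean: below μ − α·σ → −1, above μ + α·σ → +1, else 0, with σ the
population standard deviation and the closed interval mapping to 0; a
constant column is all-zero.  α defaults to 1.0, mirroring the
documented default of the classical mRMR program, and is exposed because
other choices are defensible.  One consequence worth knowing: a
balanced two-valued feature lies entirely within μ ± σ and discretizes
to all zeros at α = 1; tests that need binary features to survive
discretization use α = 0.5.

Mutual information is the plug-in estimate in bits over the empirical
joint distribution, with zero-probability cells contributing nothing.
The base only rescales all scores uniformly; bits are used for
interpretability.  Class labels enter as a discrete ±1 variable and are
never discretized.

Ranking is greedy under the difference (MID) criterion: the first pick
maximizes MI(f, c); each later pick maximizes MI(f, c) minus the mean MI
to the already-ranked features.  Pairwise feature–feature MI values are
computed once per ranked feature (vectorized contingency counting) and
reused, so ranking the top q of m features costs q·m MI evaluations.

Two numerical choices make tie-breaking exactly reproducible:

- MI terms are summed in sorted order, so permutation-equivalent
  contingency tables give bitwise-identical MI.
- Greedy decision scores are compared after rounding to 10 decimals
  (`SCORE_DECIMALS`).  Distinct contingency tables can have *exactly*
  equal MI sums as real numbers while their floating-point evaluations
  differ in the last few ulps; without the tolerance grid such true
  ties would be broken by rounding noise rather than by the declared
  lowest-index rule.

## Metrics

Confusion counts are nonnegative reals, not integers, so rate-scaled
counts are admissible — on a balanced dataset (TP = SN, FN = 1 − SN,
TN = SP, FP = 1 − SP) all six measures are recoverable from SN/SP alone,
which is how published rows are checked without the external data.  Any
measure with a zero denominator (MCC included) is defined as 0; this
convention is unit-tested.  Reports round to 3 decimals; full precision
is kept internally.  Note that recovering a 3-dp MCC from 3-dp-rounded
SN/SP can be off by one unit in the last digit (the underlying integer
counts carry more precision than the rounded rates).

## Cross-validation and IFS

Folds are stratified, shuffled with a single seed (default 1), and
confusion counts are **pooled** over test folds before metric
computation — per-fold MCC on ~24-sample folds is unstable, and pooling
matches the single confusion matrix the metric definitions imply.  When
`n_folds` exceeds the minority class count (e.g., leave-one-out on a
balanced set of 10), stratification is impossible with nonempty test
folds; seeded unstratified K-fold is used instead and a training fold
that loses a class entirely raises an error.

Classifier defaults are pinned explicitly so results are reproducible:
CART decision tree with Gini impurity; kNN with 5 neighbours; random
forest with 100 trees; SVM with RBF kernel, C = 1, `gamma="scale"`.
Distance- and margin-based families (kNN, SVM) get per-fold
standardization fitted on the training part only; tree families consume
raw values.  Stochastic families derive their internal seed from the CV
seed.  All hyperparameters are echoed into result metadata.

IFS evaluates every prefix size 1…N of the ranking (N defaults to the
whole list; `max_size` truncates), always emits the full per-size table,
and selects the optimum by maximum MCC with ties to the smallest prefix.

## Position frequencies

Each selected feature increments the count of each of the k = 4
positions its slot covers by 1 — features are counted, not weighted by
their mRMR scores.  Total mass is therefore 4 × n_selected and the
centre position is identically 0 under the default encoding.  Output is
a (position, count) TSV plus a bar chart; frequencies describe one
(classifier, dataset) pair — no cross-model aggregation rule is imposed,
though profiles from several models can simply be laid side by side.

## Synthetic data

The generator emulates the structure of the curated benchmark sets
(balanced windows, 120+/120− or 97+/97−, 41 nt, centre C) without
modelling realistic genomic background: positions are i.i.d. from a base
composition (uniform by default), motifs (e.g., UCCA at 22, emulating
the type II downstream context; G-rich runs for type I) are planted with
probability `presence_prob` in positives and `background_prob` in
negatives, and the centre is forced to C.  Negatives are the same
background minus the motif signal, so any recoverable class difference
is attributable to the planted motifs — which is what makes end-to-end
recovery a meaningful test.  Passing recovery tests therefore shows the
machinery localizes a planted signal; it says nothing about performance
on real transcriptomic context (no composition bias, conservation, or
redundancy structure is modelled).

Record streams are spawned from a single master seed, so record i is
unchanged when the sample count grows.  Embedding tables cover all 4^k
k-mers; the `near_orthogonal` scheme draws unit vectors and iteratively
pushes violating pairs apart until every pairwise |cos| < 0.5 (default
bound), keeping distinct k-mers separable even with 256 k-mers in 30
dimensions.  Feasibility limit: for n > d(d+1)/2 vectors in d
dimensions, coherence below 1/√d is impossible (orthoplex bound) and the
generator raises rather than loop.

## Problem sizes used in checks

The recovery and null-control checks run 10 replicates of 100+/100−
windows with full 1020-feature encoding; mRMR is truncated to the top 10
(recovery) or 50 (null) ranks and IFS to the same prefix ranges, which
is where the signal, or its absence, is decided.  The mRMR/oracle
equivalence check uses 200 random instances of ≤ 8 features × ≤ 50
samples against a naive fsum-based greedy oracle.

One property of the recovery setting is worth stating: with
`background_prob = 0.05`, negatives that happen to carry the motif are
indistinguishable from positives by construction, so per-replicate MCC
is capped at the value reached when exactly those carriers are the only
errors (≈ 0.95 at the expected 5 carriers per 100 negatives, lower when
the binomial draw gives more).  Observed optima track this ceiling
closely; summaries of recovery MCC should be read against it.

## Known limitations

- Embedding training is out of scope; tables are consumed as text files
  and the synthetic schemes are structural stand-ins, not learned
  vectors.
- Absolute benchmark performance depends on the external datasets and
  the published embedding file and is not reproduced here; the package
  validates the machinery (closed forms, oracle equivalence, planted
  recovery) instead.
- The three-state discretization is a declared reading of the classical
  program's default; other discretizations change rankings.
- No redundancy reduction (CD-HIT-style) is performed; inputs are
  assumed pre-deduplicated.
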