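# Methods

## Model

The package implements the Analytic Hierarchy Process for a fixed
three-level hierarchy: one goal, m categories, and leaf needs under the
categories.  Each internal node with children e_1 … e_n generates one
pairwise-comparison questionnaire and one **judgment matrix**
A ∈ ℝ^{n×n}: a_ij is the responder's judged importance ratio of e_i over
e_j, a_ii = 1 and a_ji = 1/a_ij by construction.  If the responder were
perfectly coherent, a_ij = w_i/w_j for some latent weight vector w, every
column of A would be proportional to w, and Aw = n·w — the transitivity
property a_ij = a_ik·a_kj.

Real judgments are not coherent, so the **local weights** are taken as the
principal eigenvector of A (the eigenvector of the largest eigenvalue
λ_max), normalized to sum 1 — the distributive mode.  Perron–Frobenius
theory guarantees that a strictly positive matrix has a unique dominant
eigenvalue with a strictly positive eigenvector, so the weights are well
defined and power iteration converges to them from any positive start.

**Consistency.**  λ_max ≥ n for every positive reciprocal matrix, with
equality exactly at transitivity, so the excess measures incoherence:
CI = (λ_max − n)/(n − 1) and CR = CI/RI(n), where RI(n) is the tabulated
expected CI of random reciprocal matrices (0, 0, 0.58, 0.90, 1.12, 1.24,
1.32, 1.41, 1.45 for n = 1 … 9).  CR ≤ 0.1 is the conventional acceptance
gate; 0.2 is a documented relaxed option for complex hierarchies where
re-elicitation is impractical.  For n ≤ 2 reciprocity forces consistency
and CR is defined as 0.  A Monte-Carlo re-derivation of RI in the test
suite checks the shipped constants to within ±0.1: published RI estimates
themselves differ by a few hundredths depending on the sampling grid and
scheme, which is why the check is a band and not an equality.

**Aggregation.**  A need's global weight is the product of its local
weight and its category's weight at the goal, GW_i = LW_i · CW.  Since
Σ CW = 1 and Σ LW = 1 within each category, Σ GW = 1; the invariant is
enforced to 1e-9.  This two-level product is the reason tree depth is
fixed: deeper trees would need a different aggregation and are rejected at
load time rather than silently mis-scored.

**Concordance.**  Agreement between two responders' priority profiles is
Spearman's ρ: Pearson correlation of the rank vectors, with tied weights
receiving mid-ranks.  Mid-ranks are not optional — two-decimal elicited
profiles are full of exact ties, and every reproduction check in the test
suite depends on them.  Significance is two-sided against the null of no
association: for n ≤ 8 items the exact permutation distribution of ρ over
all n! orderings is enumerated (cached per n; 8! = 40 320 rows); for
larger n the t approximation t = ρ·√((n−2)/(1−ρ²)) with n−2 df is used,
except that |ρ| = 1 returns the exact enumeration bound 2/n! rather than
the approximation's 0.  Identical (or exactly reversed) rank vectors
short-circuit to ρ = ±1 so that perfect concordance compares equal to 1
without floating-point residue.  Exact-enumeration note: at n = 4 and
ρ = 1 the two-sided p is 2/24 ≈ 0.083 and the one-tailed p is 1/24 ≈
0.0417; software that reports 0.040 for this configuration is using a
different approximation, and this package reports the exact value.

## Elicitation design choices

* **Scale.**  The default vocabulary has nine grades mapping to
  {1/5, 1/4, 1/3, 1/2, 1, 2, 3, 4, 5}.  The five named anchors (much
  less / less / equally / more / much more important) follow the practice
  of giving lay responders a compact scale; the "slightly" (±2, ±1/2) and
  "moderately" (±4, ±1/4) grades carry the in-between judgments.  The
  labels for the in-between grades are this package's convention.  Ratios
  are stored as exact fractions and matrices built so that a_ji is the
  bitwise float reciprocal of a_ij; for the default grid the product
  a_ij·a_ji is exactly 1.0 in IEEE arithmetic.  The classic 1–9 grid is
  available as `SAATY_NINE_SCALE`.
* **Schedules.**  Pairs are emitted by cyclic distance: offset d = 1 …
  ⌊n/2⌋, pair (i, i+d mod n).  This asks every unordered pair once, puts
  each element on the left and right equally often (within one for even
  appearance counts, where exact balance is impossible), is deterministic
  in the node's child order, and reduces to the transitivity-probing cycle
  A–B, B–C, C–A at n = 3.
* **Contradictions.**  A pair answered twice with incompatible grades is
  an error, never averaged: the prescribed remedy for incoherent
  responders is re-answering the questionnaire, and silently averaging
  would hide exactly the signal the CR gate exists to catch.
* **Advisories.**  Nodes with more than 4 elements draw a non-fatal
  advisory (questionnaire length grows as n(n−1)/2 and inconsistency with
  it); 4 is allowed without comment.

## Numerical choices

* Power iteration: uniform start, renormalization to Σw = 1 each step,
  convergence when successive iterates differ by < 1e-12 in max norm,
  budget 10 000 iterations (non-convergence raises — it signals a
  pathological matrix, not a tolerance problem).  λ_max is read off as
  Σ(Aw) at the converged, sum-one w.  The dense eigendecomposition used in
  tests is an independent oracle only, never the implementation path.
* CI uses the (n − 1) denominator.  The RI table and the 0.1 threshold are
  calibrated against that form; a CI "normalized to n" would make the
  shipped RI constants and gate meaningless.
* Tiny negative CI from round-off (|CI| < 1e-12) is floored at zero.
* Ties in need ranking keep hierarchy order (stable sort) and are flagged
  rather than broken arbitrarily.

## Synthetic responders

The simulator is the package's validation instrument.  Each responder
draws a latent category simplex and one latent need simplex per category
from a symmetric Dirichlet (concentration 1 by default — uniform on the
simplex; raise it for near-uniform profiles, lower it for sharply peaked
ones like a safety-dominated emergency profile).  Judgments start from the
true ratios w_i/w_j (transitive by construction, CR = 0) and are degraded
in two controllable, composable ways:

* **Noise:** a_ij ← a_ij·exp(ε), ε ~ N(0, σ²), applied to the upper
  triangle only with the lower triangle forced reciprocal — validity at
  any σ.
* **Quantization:** snapping to the response grid, nearest in log space so
  reciprocal pairs snap consistently — the systematic error a verbal scale
  imposes even on a perfectly coherent responder (latent ratios beyond the
  grid's ceiling of 5 are clipped to it, a real and intended artifact).

Randomness is a single seeded stream per (seed, responder index, node)
triple, so any responder regenerates identically in isolation.  Verbal
response sets are graded off the matrices; when quantization is on the
grading is exact and the CSV round trip is the identity.

What passing simulator tests show: the pipeline inverts its own generative
model — exactly at σ = 0 without quantization (recovery to 1e-8), with
rank fidelity (median recovered-vs-latent ρ ≥ 0.9 at σ = 0.2, quantized,
20 responders), and with L1 error non-decreasing in σ.  What they do not
show: robustness to order effects, fatigue drift, or adversarial
intransitivity, none of which the noise model contains.

## Problem sizes

The property suites run at sizes chosen to exercise the mathematics while
keeping the default test run quick: 1 000 random reciprocal matrices
(n ≤ 9) for the eigen-oracle comparison, 500 seeded replicates per σ level
for the noise-degradation curves, 3 000 Monte-Carlo matrices per dimension
for the RI provenance band.

## Bundled case study

The CT-scanner case ships as the study's printed two-decimal tables
(category weights, local/global need weights, per-questionnaire CRs, and
the published rank-correlation entries) with sha256 integrity checks.
Three reproduction checks run from those printed values: the aggregation
identity |GW − LW·CW| ≤ 0.01 on all 60 cells, the need-level ρ matrix
within ±0.005 of every published entry, and exact recovery of the
published category-level ρ = 1 pairs.  The printed CRs are display data
only: computing a CR needs the raw judgment matrices, which were never
published.  The published correlation tables suppress non-significant
entries as dashes; the reproduction checks compare printed entries only,
and this package itself always reports full matrices plus a significance
mask.  Whether the study's own correlations were computed on rounded or
full-precision weights is unknowable from the tables; the reproduction
uses the printed values, which demonstrably match.

## Known limitations

* Group-consensus aggregation (geometric-mean group matrices, consensus
  indices such as Kendall's W) is out of scope: the concordance module
  measures agreement, it does not manufacture it.
* Alternative weight-extraction methods (geometric mean / log-least
  squares) and ideal-mode normalization are not provided.
* No multiple-testing correction is applied across the pairwise
  concordance matrix; with a handful of responders the matrix is
  descriptive, not confirmatory.
* The RI table covers n ≤ 9; larger nodes require a user-supplied RI and
  draw a design advisory anyway.
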