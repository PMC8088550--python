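# Methods

## Elicitation model

One elicitation is a triplet (low, mode, high) of percentages with
0 ≤ low ≤ mode ≤ high ≤ 100, interpreted as the lowest plausible bound, the
most likely value, and the highest plausible bound for the probability that
a scenario occurs. Triplets violating the ordering or the scale are rejected
at construction with an error naming the offending field; they are never
silently repaired. `low == mode == high` is accepted as a point mass — an
expert may be certain — while a zero-width support with a different mode is
impossible by the ordering invariant.

The fitted density is the PERT (modified beta) distribution: a beta(α, β)
rescaled to [low, high] with

    α = 1 + λ(mode − low)/(high − low),
    β = 1 + λ(high − mode)/(high − low).

The shape weight λ defaults to 4, the canonical PERT convention, and is
exposed as a parameter (`fit_pert(..., shape_lambda=...)`) so a different
modification weight can be reconciled against archived analysis code if
needed. With λ ≥ 0 both shapes are ≥ 1, so the density is finite
everywhere including the edge-mode cases mode = low (α = 1) and
mode = high (β = 1). All computation stays on the percent scale [0, 100];
no internal [0, 1] renormalisation is exposed. Moments and the CDF come
from the exact beta forms (`scipy.stats.beta`); sampling uses beta variates
rescaled to the support, so the contract is seed-determinism and the
correct law, not a particular bit stream.

## Linear opinion pooling

The group opinion for one question is the equal-weight mixture of the
responding experts' PERT densities — "unweighted" is taken literally; no
calibration or performance weighting exists anywhere in the pipeline.
The pool is materialised by Monte Carlo with 50,000 draws per expert
(configurable), concatenated across experts. Experts who skipped the
question are excluded from the pool and from its reported n.

Seeding: one master seed (default 20210501) spawns an independent substream
per expert, keyed by a CRC-32 of the expert identifier rather than by
position. Consequences: expert order cannot change any result, and adding
or removing one expert leaves every other expert's draws untouched.

Summaries are computed two ways. The mean defaults to the analytic mixture
mean (the unweighted average of component means — an exact identity); the
sample mean is available and agrees to Monte-Carlo error. The median
defaults to the empirical median of the pooled draws, matching the
Monte-Carlo pipeline; the analytic alternative solves F(x) = 1/2 on the
mixture CDF by bisection, and where the CDF is flat at 1/2 (disjoint
point-mass components) it returns the midpoint of the median interval — a
documented convention, not a claim of uniqueness.

## HDI and consensus

The reported interval is the 80% highest-density interval taken directly on
the pooled samples: sort the m draws, slide a window of w = ⌈0.80·m⌉
consecutive order statistics, and keep the narrowest window, leftmost on
ties (deterministic and order-stable). This sample-window estimator is the
default because the pipeline pools raw samples and the reporting format is
a single contiguous interval per question. A density-threshold HDI that may
return a union of intervals exists as a diagnostic for multimodal pools
only; it never feeds the reported summaries. Since 0.80 > 0.5, the
empirical median always lies inside the interval.

Bandwidth is upper bound minus lower bound, in percentage points. The
consensus rule is: bandwidth ≤ 50 ⇒ relatively strong consensus, > 50 ⇒
relatively weak (the boundary is inclusive). Both the mass (0.80) and the
threshold (50) are parameters with these defaults.

Display rounding is half-up to one decimal, and a rendered row's bandwidth
is recomputed from the *rounded* bounds so the printed arithmetic is
internally consistent; full precision is kept in memory.

## Kernel density estimation

The pooled density is visualised by a Gaussian KDE with reflection at 0 and
100, because the elicited quantities are probabilities and smoothing mass
outside [0, 100] would be meaningless. Implementation: samples are binned
on the uniform evaluation grid (default 512 points) and smoothed with a
Gaussian filter under reflecting boundary conditions, which keeps the cost
linear in the grid size for pools of ~10⁶ draws and conserves unit mass to
better than 10⁻³. The default bandwidth is Scott's plug-in rule on the
sample spread; it is overridable. The KDE is visualisation and
mode-counting diagnostics only — the reported HDI always comes from the raw
samples, so the smoothing choice cannot move any reported number.

## Ranking tally

Forced rankings of S statements by R representatives: rank r earns
S + 1 − r points, totals are summed across representatives (always
R·S(S+1)/2 in total), and statements are ordered by descending points.
Ties in totals are broken by input statement order (stable) and flagged
explicitly rather than hidden. Incomplete rankings are rejected, not
imputed, since the instrument forces a complete ranking.

## Synthetic panel generator

The generator emulates the statistical structure the pipeline assumes:
18 invited experts by default, bounded three-point answers, asymmetric
spreads, and per-question skipping (default probability 0.10, chosen so the
per-question respondent count lands in the 14–18 range typical of such
surveys). Beliefs follow a per-question Gaussian mixture: cluster means and
weights define the designed group structure, `belief_sd` (default 10) is
the between-expert spread within a cluster, and the elicited bounds sit at
gamma-distributed distances below and above the mode with means
`spread_low` = 10 and `spread_high` = 15 — wider above than below, as
elicited likelihood intervals typically are mid-scale.

Two deliberate design choices:

- **Proportional cluster allocation.** Experts are assigned to clusters by
  largest-remainder allocation on the weights (remainders randomised, then
  a random permutation), not by i.i.d. draws. With 18 experts an i.i.d.
  50/50 draw produces a ≥13/5 split about 10% of the time, which collapses
  the designed bimodality; proportional allocation guarantees the
  configured mixture shape at small panel sizes, which is the property the
  generator exists to provide.
- **Clipping order.** The mode is clipped to [0, 100] first, then the
  bounds, then the ordering is re-enforced. This guarantees validity at the
  cost of slight pile-up at the scale ends; a configuration that
  degenerates more than half of its elicitations to point masses logs a
  warning.

What the generator does *not* model: anchoring, overconfidence, question
order effects, or correlated skipping. Passing recovery tests therefore
show that the pipeline recovers the parameters of this idealised belief
model, not that real expert panels behave this way.

## Validation design

- Exact identities (PERT shapes and means, pool-mean linearity, point
  conservation in the tally) are asserted without tolerance.
- The sample-window HDI is checked for equality against an exhaustive
  O(m²) window enumeration on randomised sample sets (m ≤ 200).
- Distributional contracts use quadrature (unit mass to 10⁻⁶) and
  Dvoretzky–Kiefer–Wolfowitz bands at 50,000 draws.
- Parameter recovery runs the full pipeline at the study conditions —
  18 experts, 50,000 draws per expert, 80% HDI, threshold 50 — over 20
  seeds: a single-cluster panel centred at 60 with belief_sd 5 must return
  a pooled median within ±5 of 60, and a 20/80 split panel must always be
  classified weak. These sizes keep the full suite under a minute.
- The published per-question summary table is used as printed *input*:
  bandwidth arithmetic, median-in-HDI, and the threshold rule's
  strong/weak labels are recomputed from its columns.

## Limitations

- Full numeric reproduction of the original survey's pooled medians
  requires the archived survey responses; the loader accepts such a deposit
  through a column mapping (`read_survey(..., column_map=...)`), but no
  response-level data ships here, so those comparisons are out of desk
  scope.
- The sample-window HDI reports one contiguous interval even for strongly
  multimodal pools; the union-of-intervals diagnostic should be consulted
  whenever the mode count exceeds 1.
- Monte-Carlo summaries carry O(1/√N) noise; at the default 50,000 draws
  per expert the pool median is stable to well under half a percentage
  point, which is below the one-decimal display precision.
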