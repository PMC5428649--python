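# Methods

This note records the models behind `herbconnect`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would want written down. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signature extraction

A treatment is summarized from a probes × samples matrix of normalized,
nonnegative intensities (MAS5-like scale; normalization and array QC are
upstream and out of scope). Replicate columns of a condition are averaged
arithmetically; fold change is the plain ratio of treated to
vehicle-control means on the intensity scale — not log scale — because the
tag thresholds are defined on that ratio. Probes with FC ≥ 2 become up
tags and FC ≤ 0.5 down tags by default; both thresholds are per-run
parameters constrained to `down < 1 < up`. A zero control mean makes a
probe's ratio undefined; such probes are flagged, logged and excluded from
both tag sets rather than propagating infinities. Probe identifiers are
opaque strings throughout: no probe→gene collapsing is attempted, because
a collapse rule (max? mean? MAS5 calls?) would be an additional modelling
choice the rest of the pipeline does not need — reported tag counts are
therefore probe counts. `.grp` files are one identifier per line with no
header; reading tolerates a missing trailing newline and rejects blank or
whitespace-containing lines with the line number.

`FoldChangeVector.from_log2` accepts log2-ratio input and exponentiates at
the boundary so the internal contract stays the plain ratio.

## Connectivity scoring

A reference instance is a total ordering of a probe universe (most induced
first) plus compound/dose/cell/batch metadata. The tag-set statistic is
the signed Kolmogorov–Smirnov-style enrichment given in the README; it
depends only on the tags' ranks. Ties in reference input are broken by
input order and instances must supply a total order. Query tags absent
from an instance's universe are dropped with a logged count by default
(chip universes differ); `on_missing="error"` is available.

Instance scores follow the classic two-sided rule: `raw = ks_up − ks_down`,
forced to 0 when both statistics share a sign (the instance does not
coherently induce or reverse the pattern); an empty tag list contributes 0
on its side, and a signature empty on both sides is an error. Scaling
divides positive raw scores by the collection maximum and negative ones by
the magnitude of the collection minimum, so scores live in [−1, 1], the
best positive instance is exactly 1, and zero raw scores stay zero. These
scaled scores are relative to the queried collection — subsetting the
collection (e.g. to one cell line) rescales them, which is why the query
function takes whatever collection the caller assembles and applies no
default restriction.

Per-compound ("by name") enrichment sorts instances by connectivity
(descending, stable), treats each compound's k positions among N as tag
ranks, and computes the same statistic. Significance is a permutation
test over uniform k-subsets of positions: exact enumeration whenever
C(N, k) ≤ 10 000, otherwise `n_permutations` sampled subsets (default
100 000). Two numerical points matter:

* Sampled tails use the add-one estimator (b + 1)/(m + 1), counting the
  observed statistic as one permutation; without it a sampled p is
  anti-conservative by about 1/m and fails a uniformity check under label
  shuffling. A sampled p is therefore never 0; its floor marks "below the
  permutation resolution". Exact enumeration already contains the observed
  subset.
* Because the tail side is chosen after seeing the statistic's sign, the
  one-sided tail alone doubles the false-positive rate. The default
  reported p doubles the observed-side tail (capped at 1), which restores
  validity: under shuffled compound labels, P(p ≤ α) ≤ α within the
  permutation resolution. The raw one-sided tail remains available
  (`two_sided=False`) for comparison with sources that report it.

A post-hoc filter (`positive_p_filter`) keeps only positively enriched
compounds below a p cutoff, the usual presentation for repositioning
tables.

## Network propagation and synergy

The propagation network comes from a weighted edge list (STRING-style;
0–999 scores are auto-detected and divided by 1000). Edges with confidence
strictly above the threshold (default 0.9) are kept; a target gene whose
every edge falls below the threshold is rescued through its single
maximum-confidence edge, so known targets are not silently lost; self-loops
are dropped; the largest connected component is retained. Propagation is
over the *unweighted* retained graph: P is the column-normalized adjacency
matrix, so each column is a probability distribution and the iteration

    χ(t+1) = (1 − r) P χ(t) + r χ(0)

conserves total mass. The map is a contraction with factor (1 − r), so the
fixed point χ = r (I − (1 − r) P)⁻¹ χ(0) is unique and the iteration
converges from any start; we start at χ(0) and stop when the L1 change
drops below 1e−10 (default), with a 10 000-iteration cap that raises an
error carrying the final residual. At r = 0.3 the residual contracts by
0.7 per step, so convergence takes ~65–70 iterations; the tolerance is far
below any score difference of interest. The restart default r = 0.3
follows common practice for disease-gene propagation: large enough that
seed identity dominates, small enough that multi-hop neighbourhood
structure still matters.

Disease genes seed at strength 1 and drug targets at 0.01, applied
literally per gene with no normalization of the seed vector; effect scores
are raw inner products s = ⟨χ_disease, χ_drug⟩ (a cosine-normalized variant
is available via `effect_score(..., normalized=True)` for scale-free
comparison across networks, since the raw score's scale depends on seed
counts and network size). Drug target sets are differential-expression
gene sets mapped onto network nodes; genes missing from the network are
dropped with a logged count and the reported target number is the
post-intersection count.

The z-score null draws `n_random` (default 1000) uniform node subsets of
the same size from the whole retained network — the count is the only
matched property; degree-matched sampling is behind a flag for sensitivity
analysis, since degree matching is a stricter null that the default does
not assume. Δs_r is the sample (n − 1) standard deviation, making Z
reproducible to the bit from the recorded seed. All null seed vectors
iterate together as columns of one matrix; this is the same update rule
and fixed point as one run per set, vectorized. A degenerate null
(sd = 0, e.g. target count equal to the network size) yields a flagged NaN
Z with a warning rather than an exception.

`synergy_table` scores a mixture plus each component against one shared
disease steady state, network, r and RNG protocol (per-row child seeds
spawned deterministically from the table seed, mixture row first). The
default mixture rule is the union of component target sets — a modelling
choice, labelled as such, appropriate when no separately assayed mixture
signature exists; an explicit mixture gene set is accepted and preferred
when the mixture was profiled directly. Synergy is read as the mixture's Z
exceeding every component's Z, with Z > 3 as the significance convention.

`null_calibration` is a self-diagnostic of the z-score: each repetition
draws one bank of `n_random` counterparts plus several (default 5)
"observed" sets from the same uniform procedure, propagates all of them in
one batch, and standardizes the observed sets against the bank. E[Z] = 0
holds exactly (the observed draw is independent of its bank); scoring
several sets per bank reuses the expensive propagation and tightens the
Monte-Carlo estimate of the mean without changing the null model. The
default diagnostic size (200 repetitions × 5 observed = 1000 z values)
estimates the mean to ±0.03 and the sd to ±0.03 at one standard error.

## Synthetic data

The generators are pure functions of their scenario (same seed ⇒ identical
output) and emit machine-readable ground truth so tests never re-derive it.

*Expression*: a log-normal per-probe baseline (default exp(N(log 100, 1)),
an MAS5-like positive scale) shared across samples; treated replicates
multiply planted up probes by the effect multiplier (default 4) and divide
planted down probes by it; every value then takes log-normal multiplicative
noise (default σ = 0.1, natural log). Two replicates per condition by
default, matching a minimal biological-duplicate design. Not emulated:
probe-level array artifacts (background, saturation), batch effects,
probe–probe correlation — so recovery results bound what the filter does
under idealized noise, not on real arrays.

*Reference collections*: concordant instances place the query's up tags
uniformly in the top decile of the ranking and down tags in the bottom
decile (inverted for discordant; uniform permutations otherwise). The
decile placement makes the planted instance's maximum connectivity a
forced property at the tested sizes rather than a tendency. Real reference
collections have correlated instances, dose ladders and batch structure;
none of that is simulated.

*Networks*: Barabási–Albert preferential attachment (default n = 500,
m = 3) because degree heterogeneity is the property that stresses a
count-matched propagation null; an Erdős–Rényi alternative (bridged to one
component if needed) provides a homogeneous contrast. The disease module
(default 30 nodes) is densified with random intra-module edges to a target
internal density (default 0.3), emulating the clustering of disease genes
in interactomes. Component target sets take their in-module share from
disjoint slices of a shuffled module list — so two components at overlap
0.5 cover complementary halves — and the remainder from off-module nodes,
optionally at a minimum hop distance (negative controls). Edge confidences
are drawn in (0.905, 0.999) so the default 0.9 threshold keeps the planted
structure intact; threshold behaviour itself is tested with hand-built
edge lists. Real interactomes are 20× larger with correlated confidence
scores and study bias; absolute effect-score values here are therefore not
comparable to values computed on a real interactome — the tested claims
are calibration, ordering and recovery properties.

## Problem sizes and determinism

Default verification sizes — 500-node networks, 30-node modules, 1000-probe
matrices, 1000 random counterparts, 100 scenario seeds for the recovery
rate — were chosen so each claim's Monte-Carlo error is small relative to
its margin (e.g. planted mixture Z ≈ 14 against a threshold of 3) while a
full verification run stays in the low minutes on one CPU. Every stochastic
step takes an explicit seed; workflow reports embed the tool version,
config hash and seeds (and deliberately no timestamps), so a rerun of the
same configuration is byte-identical.

## Known limitations

* Scaled connectivity is collection-relative; scores from different
  collections or subsets are not directly comparable.
* The union mixture rule ignores dose and interaction effects between
  components; it models combined target coverage only.
* The uniform null does not condition on degree; hub-heavy target sets can
  earn high Z partly through degree. The degree-matched flag exists for
  exactly this sensitivity check.
* Raw effect scores depend on seed counts and network size; compare them
  only within one table, or use the cosine-normalized variant.
* Probe-level signatures are not collapsed to genes; mapping tags onto
  network nodes is the caller's responsibility when chips and networks use
  different identifier spaces.
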