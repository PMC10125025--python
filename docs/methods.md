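# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `spikeseq`, in the spirit of a methods appendix.

## Data model

A record is one neuron's spike train stored as a series of strictly
positive ISIs in milliseconds (`SpikeRecord`). Spike-time input (seconds
or ms) is converted on read. Records carry a unit id, a structure label
(GPe, STN, GPi) and a state label (normal, MPTP). Analyses operate on the
first 5,000 ISIs of each record (`analysis_window`); shorter records are
excluded — skipped with a warning in batch runs, an `InsufficientDataError`
when analyzed directly. The window length trades detection sensitivity
(longer windows catch repetitions separated in time) against stability and
data availability; the segment-stability analysis (`segment_stability`)
quantifies this trade-off.

Conventions that the summary statistics depend on, chosen because the
field does not fix them and stated here so outputs are interpretable:

* firing rate = `(n_isis + 1) / duration` — counts spikes, not intervals;
* CV of ISIs uses the sample (n−1) standard deviation;
* all medians use numpy's midpoint convention; quartiles (for IQRs) use
  linear interpolation;
* undefined per-cell metrics (e.g. no 2-ISI family) are `nan` and are
  excluded from group statistics.

## Sequence detection

**Tolerance.** A repetition must match its template element-wise within a
fractional tolerance: `|x − t| ≤ tol·t`. The default `tol = 0.01` (1%)
sits between a nearly-silent 0.001 and a nearly-saturating 0.1 (see the
`sweep` analysis). In `absolute_ms` mode a maximal timing error in ms
(1, 2 or 4 ms are typical choices) is divided by the cell's median ISI,
giving a per-cell proportional cutoff with that error at the median. The
criterion is proportional, so it is temporally stricter for short ISIs,
and detection under relative tolerance is invariant to uniform time
rescaling.

**Candidate scan.** For every anchor pair `(i, j)`, `i < j`, the forward
maximal run length is the largest `L` with all elements matching the
template at `i`. Only left-maximal pairs are kept (extending one step
earlier fails), since interior sub-runs are implied. Matching is always
against the earliest occurrence, never chained occurrence-to-occurrence:
the tolerance relation is not transitive, and chaining would let patterns
drift. The scan is a numba-compiled double loop (~25 ms for 5,000 ISIs),
fast enough for 1,000-shuffle nulls per cell in well under a minute.

**Family formation.** Candidates are grouped to their earliest occurrence.
A pair `(i, j)` with run length `L` is suppressed when an already-formed
family of length ≥ `L` lists both `i` and `j` as occurrence starts — the
repetition of a known pattern does not seed a new family — while a
strictly longer pattern starting at a repetition index still can. One
family is emitted per (template, distinct run length); occurrences within
a family are kept disjoint greedily left-to-right (a pattern overlapping
itself in near-constant stretches would otherwise inflate counts).

**Retention.** Families are processed longest-first (ties: more
occurrences, then smaller template start — stable and favouring
more-repeated patterns). An occurrence sharing any ISI index with an
already retained occurrence is discarded; a family left with fewer than
two occurrences is removed and claims nothing. Because full containment
of a shorter sequence inside a longer one is a special case of overlap,
this single pass also implements containment pruning: contained
occurrences of shorter families are discarded, and a shorter family
survives through isolated occurrences only if at least two remain.

An earlier design ran containment pruning as a separate pass judged on
all occurrences of longer families *as found*. Ground-truth testing
exposed a leak: a longer family that later lost the overlap competition
had already deleted the shorter-family occurrences inside it, leaving
genuinely repeating spans uncovered. In the merged pass only retained
occurrences displace shorter ones, which restores the guarantee that a
span covered by some detected repetition stays covered. The standalone
containment relation remains available as `prune_contained`.

The optimized detector is held exactly equal — identical families and
masks — to an independently written brute-force reference implementation
on randomized inputs spanning exponential, jittered-lattice, tie-rich
lattice and high-CV gamma ISI statistics.

**Degenerate inputs.** A constant train collapses to one maximal-length
family with full coverage. Final coverage is provably monotone in the
tolerance at the candidate level; after family competition it is monotone
on all renewal-like trains we generate, but can dip non-monotonically on
adversarial near-lattice inputs where larger tolerances merge candidates
into longer families whose greedy disjointness wastes coverage — a
property of the retention rules, not a bug.

## Shuffle-surrogate null

Chance levels are estimated by rerunning detection and metrics on uniform
random permutations of the cell's ISI order (default 1,000; the test
suite and acceptance script use 100–200 for desk-scale runtime). The
permutation preserves the ISI multiset exactly, so the null shares every
marginal property of the data and differs only in temporal order; the
effective tolerance (median-based in absolute mode) is permutation
invariant. Original values are reported as ratios to the null median.
This null is conservative for motif-rich cells: ISIs that recur in true
sequences inflate the shuffled chance-match rate as well. For an i.i.d.
renewal train the original ordering is exchangeable with its shuffles, so
the original metric falls inside the null's central 95% band with
probability ~0.95 by construction; observed coverage fluctuates
binomially around that (e.g. 17–20 of 20 replicates). One master seed
spawns independent child streams per cell and shuffle, so results are
reproducible and independent of execution order.

## Burst detection

Bursts use the Poisson surprise statistic: `S = −ln P(X ≥ n)` for
`X ~ Poisson(r·T)`, with `n` the burst's spike count, `T` its span from
first to last spike and `r` the cell's mean rate over the analysis
window (internal consistency with the sequence analysis). `S` is
evaluated in log space — a leading-term-times-series expansion in the
right tail, a complement via `log1p` in the bulk — and agrees with a
high-precision tail-sum oracle to better than 1e−9 relative error for
λ ≤ 50, n ≤ 200, including deep tails where naive evaluation underflows.

The search heuristic: seed at runs of ≥ 3 consecutive ISIs shorter than
half the mean ISI, extend the end spike-by-spike while `S` increases,
then trim leading spikes likewise; candidates with `S ≥ 3` are retained,
overlaps resolved in favour of higher surprise. The exact variant of this
classic algorithm differs across published implementations; the seed rule
and the extend-then-trim order used here are exposed as the documented
defaults rather than claimed as canonical. Sequence/burst interaction is
summarized by the fraction of sequence ISIs inside bursts and vice versa,
plus per-group ordinary least-squares regressions of sequence
participation on firing rate and on burst participation.

## Group statistics

Paired comparisons (each cell's original metric vs its own null median)
use the two-sided Wilcoxon signed-rank test; zero differences are
discarded (the "wilcox" convention, configurable to "pratt").
Cross-state comparisons use the two-sided Mann-Whitney U test, exact for
small tie-free samples. Both are computed by scipy behind the module
surface and are verified against independent exact-enumeration oracles
(all group assignments; all sign flips) to 1e−8. Summaries are medians
with IQRs. P-values are reported raw; the output carries the number of
tests performed so users can apply their own multiplicity correction —
none is applied by default since the analysis design reports each metric
and structure separately.

## Synthetic data generator

The generator produces the minimal process matching the two marginal
statistics that characterize the recorded populations: a gamma-renewal
ISI stream with shape `1/CV²` and mean `1000/rate` ms. The six group
presets use the recorded populations' median rate/CV (GPe 66.6/1.13 and
45.7/1.19, STN 22.9/1.46 and 36.8/1.32, GPi 74.4/0.91 and 75.3/1.0 for
normal/MPTP respectively); per-cell values scatter log-normally
(σ = 0.15) around the group medians so that group medians concentrate
near their targets at realistic cell counts.

Planted motifs overwrite disjoint stretches with a fixed ISI pattern,
each element multiplied by `1 + u`, `u ~ U(−jitter, +jitter)`. With
detection tolerance `tol`, the triangle inequality against the template
guarantees recovery of every planted occurrence whenever
`2·jitter ≤ tol·(1 − jitter)`; validation uses `jitter = 0.4·tol`, which
satisfies this bound (a jitter of exactly `tol/2` would not, marginally).
At `jitter = 5·tol` pairwise deviations typically exceed the tolerance
and recovery collapses to the chance rate of the background. Clustered
placement packs occurrences into one block (gaps of 0–2 ISIs), driving
the normalized intersequence-spacing ratio far below 1. Optional burst
epochs divide the ISIs of contiguous stretches by a rate multiplier.

What the generator does *not* emulate: slow nonstationarity of real
recordings, oscillatory modulation, refractory structure beyond the
gamma shape, spike-sorting errors, and cross-neuron correlations. Passing
tests therefore demonstrate correctness of the algorithms under the
stated statistical assumptions, not that real basal ganglia data will
show any particular effect size.

## Problem sizes and numerical choices

The test suite and acceptance script scale simulations to desk size as
the package's own defaults: detector-equivalence on series of ≤ 500 ISIs;
planted-motif recovery on 5,000-ISI trains; null calibration on 2,000-ISI
trains with 200 shuffles; segment stability on 20,000-ISI trains. The
full study configuration (5,000-ISI window, 1,000 shuffles) runs at about
half a minute per cell on one CPU. Tolerance comparisons use `<=` on
float64 throughout; the brute-force reference uses the identical float
arithmetic so equality of outputs is exact. JSON/CSV serialization writes
floats at full `repr` precision, making write/read round trips
bit-identical.

## Known limitations

* Family grouping when a repetition of one pattern coincides with the
  start of a longer different pattern is resolved by explicit rules
  (suppression by occurrence-pair membership; longest-first retention);
  other reasonable conventions exist and would differ on contrived inputs.
* The 2-ISI duration median pools retained occurrences (not unique
  families); occurrence-level durations are the natural unit for
  comparison against shuffled data, but a family-level pooling would give
  slightly different numbers.
* Intersequence gaps are measured end-of-occurrence to start-of-next;
  start-to-start is the noted alternative.
* The surprise algorithm's seed criterion and maximization order follow
  one published variant and are configurable only through the module's
  parameters (cutoff, rate).
* Cross-neuron sequence comparisons (shared motifs between simultaneously
  recorded cells) are out of scope.
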