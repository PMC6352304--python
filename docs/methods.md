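# Methods

## Signal representation

A DNA sequence is mapped residue-by-residue to phases of complex numbers:
A = π/4, C = −3π/4, G = 3π/4, T = −π/4; the partially determined IUPAC
codes lie on the axes (R = π/2, Y = −π/2, S = π, W = 0) and the fully
ambiguous codes (M, K, N, B, D, H, V) at 0.  Two conventions are fixed
here: W is taken as 0 rather than 2π so that all phases lie in (−π, π]
and the running sum acquires no arbitrary 2π jumps; and B/D/H/V, which
the axis projection does not place, are treated like N.  The map is
invertible on A/C/G/T, so no information is lost for unambiguous
sequences.

The cumulated phase is the running sum of the phase signal.  For
A/C/G/T-only prefixes it has the closed form
c_k = π/4·(3(n_G,k − n_C,k) + (n_A,k − n_T,k)); for ambiguity codes the
running-sum definition is used (R/Y/S contribute their phase, all
zero-phase codes contribute nothing), which coincides with the closed
form on unambiguous input.  Every phase is an integer multiple of π/4,
so all running sums are computed in exact int64 units of π/4 and scaled
to radians once at the end.  This makes extremum positions, ties and
comparisons exact — independent of floating-point summation order — which
the canonical rotation below relies on.

## Canonical-start rearrangement

Deposited genome records start at arbitrary positions of the circular
chromosome.  The cumulated phase of a typical bacterial chromosome is
arrow-shaped — rising along one replichore, falling along the other —
with its global minimum at the replication origin, so rotating every
record to start at the signal's true global minimum canonicalizes the
start without annotation.  The rotation is a three-step heuristic:
compute the signal; rotate the sequence to begin at the global maximum
(the stretch after the maximum must contain the true minimum, whereas
the deposited first value may be a false minimum); then rotate to the
global minimum of the rotated record's signal and subtract the minimum
so the signal starts at 0.  Ties in either extremum are broken by first
occurrence.  The final signal is recomputed from the rotated sequence,
so the rearranged genome and everything derived from it depend only on
the circular sequence: two rotations of the same genome yield the
identical result (exactly, thanks to the integer bookkeeping).

The procedure is well-posed when the genome's net phase skew
c_L = π/4·(3(G−C) + (A−T)) is near zero, which real chromosomes
approximate through Chargaff's second parity rule.  A genome with
strongly negative net skew has *no* rotation whose signal stays above
its first value (the signal must end below where it started); the
rotation is still applied, and `is_rearranged` reports whether the
min-at-start contract actually holds.  Near-flat signals (no arrow
shape) are not detected; the rotation is applied regardless.

## The four descriptors

* `diff_p = (1/L)·Σ_{k<L} |p_k − p_{k+1}|`.  The divisor is L although the
  sum has L−1 terms — this matches the definition the worked values
  0.26/1.31 for AAAGGG/AGAGAG are computed from, and the discrepancy
  vanishes at genome scale.
* `tr_0`: count of adjacent pairs with strictly opposite phase signs,
  normalized by L−1.  Zero phases (W, N, …) are neither positive nor
  negative, so pairs involving them never count; on unambiguous input the
  value equals the symbolic fraction of dinucleotides
  {AC, AT, CA, CG, GC, GT, TA, TG}, and the test suite asserts exact
  agreement with brute-force dinucleotide counting.
* `tr_cg`: pairs with both phases in {±3π/4}, normalized by L−1; equals
  the fraction of {CC, CG, GC, GG}.
* `a_cp = (1/N)·Σ_{k≤N} atan(c_i/i)`, i = round(k·i_max/N) clamped to
  [1, i_max], where i_max is the 1-based position of the signal's global
  maximum and N = 10 by default.  Rounding to the nearest integer (numpy
  half-to-even) is chosen so k = N lands exactly on i_max; the
  alternative floor/interpolation readings differ only by one position
  per sample.  The argument of atan mixes radians and base-pair counts;
  the formula is implemented literally, with no rescaling, because the
  descriptor is *defined* by it.  Signals whose maximum lies before
  position N (degenerate tiny inputs) are rejected with advice to lower
  N.  Units are radians, in (−π/2, π/2).

`compute_parameters` applies the rearrangement by default (opt-out flag
for ablation), recomputes the phase signal from the rotated sequence and
derives all four descriptors; results are deterministic for a fixed
input.

## Delineation

For a dataset of N ≥ 2 genomes with unique ids (ordered
lexicographically), each parameter's pairwise absolute difference is
divided by the parameter's range (max − min) over the dataset.  Range
equals the maximum pairwise difference, so the two plausible readings of
"normalize by range" coincide.  If a parameter's range is zero its
normalized distances are defined as 0: identical values carry no
discriminative signal, and this avoids 0/0.  The pair distance d̄ is the
unweighted mean over the chosen subset (presets s2 = {tr_cg, diff_p},
s3 = s2 + tr_0, s4 = all four); similarity is s = 100·(1 − d̄), with 100
on the diagonal.  Similarities are *dataset-dependent by construction*:
adding a range-extending genome rescales existing pairs (a regression
test documents this).  The same-species call uses a strict comparison
s > threshold (default 96%); the boundary convention is not dictated by
the method, strictness is the false-positive-conservative choice, and an
`inclusive` option exposes the alternative.

## Validation

Confusion counts classify every unordered pair: TP/FP are pairs above
the threshold of the same/different species, FN/TN below (or at) the
threshold of the same/different species.  Sensitivity = 100·TP/(TP+FN),
specificity = 100·TN/(TN+FP); when a denominator is empty (e.g. no
intra-species pairs) the value is reported as `None` rather than 0 or
100.  The threshold grid 90–98% in 0.5 steps (17 points) is built by
integer stepping to avoid floating accumulation.  Along an increasing
threshold, sensitivity is non-increasing and specificity non-decreasing
directly from the definitions; the ROC is reported as sensitivity versus
100 − specificity.  `subset_comparison_report` tabulates the sweep for
each single parameter and the s2/s3/s4 combinations.

## Synthetic data

The descriptors are composition and dinucleotide statistics, so
first-order generators suffice to exercise the pipeline:

* i.i.d. genomes from a 4-probability composition;
* first-order Markov genomes with a specified transition matrix, to move
  dinucleotide statistics independently of composition;
* GC-skew-ramp genomes: the two halves are random permutations of exact,
  mirrored base multisets (first half G-rich, second C-rich, A/T
  balanced), so the net phase skew is exactly zero and the arrow-shaped
  signal has a well-posed circular minimum.  i.i.d. halves would leave an
  O(√L) residual net skew that breaks the min-at-start contract about
  half the time regardless of implementation — exact counts emulate the
  Chargaff-parity property of real chromosomes that the rearrangement
  depends on.
* mutation: per-position substitution with probability r to a uniformly
  chosen different base (no indels, recombination or HGT).

The cluster generator builds, per species, one ancestor and
strains_per_species − 1 mutated derivatives, optionally randomly rotated.
Defaults emulate a small multi-species validation set: 7 species ×
5 strains of 200 kb at 1% substitution divergence.  The seven default
compositions are spread deliberately — GC content 0.30–0.66, purine
fraction 0.52–0.70, G-over-C skew 0.02–0.14 — so *every* descriptor has a
non-trivial inter-species range.  This matters because range
normalization amplifies noise in any parameter whose inter-species range
is small: a parameter that barely varies across species would turn tiny
intra-species fluctuations into large normalized distances.  A second
composition set makes species 3 and 4 share GC content (hence expected
tr_cg = g²) while differing in purine fraction and skew, to demonstrate
the specificity gained by averaging all four parameters over using tr_cg
alone.  Species pairs closer than a total-variation margin (default
0.02) trigger a warning that delineation may legitimately fail.

What passing these tests shows — and does not.  The synthetic genomes are
stationary and composition-homogeneous; real genomes carry replichore
structure, repeats, horizontally transferred islands and assembly
artifacts, and real intra-species divergence is not uniform substitution.
Perfect sensitivity/specificity on the synthetic set demonstrates that
the pipeline's machinery (signals, rotation, normalization, sweep) is
correct and that the descriptors separate composition-distinct clusters;
it does not certify the 96% threshold for real taxa, where species
boundaries are set by evolution rather than by construction.

## Problem sizes and numerical choices

The default test-suite experiments use 200-kb cluster genomes, 5–20 kb
rotation fixtures, and a 30-genome × 2-Mbp scale check; these sizes were
chosen so the full pipeline (including 595-pair delineations and
17-point sweeps) exercises every code path while each experiment stays
in the seconds-to-a-minute range on a single CPU.  All generators accept
explicit seeds and the whole fixture→parameters→matrix→ROC chain is
bit-reproducible for a fixed seed.  Floating tolerances: phase values
are exact table lookups; cumulated-phase comparisons use 1e−9; tr_0 and
tr_cg are exact rational counts and are compared exactly against
symbolic dinucleotide counting.

## Known limitations

* Single closed sequence per genome: multi-scaffold assemblies are
  rejected by default (concatenation is possible but order-sensitive and
  explicitly discouraged).
* Genomes violating Chargaff parity (strong net skew) have no rotation
  satisfying the min-at-start contract; descriptors are still computed
  from the best-effort rotation.
* The pairwise calls are not clustered into transitive species groups;
  two calls can be mutually inconsistent (A–B same, B–C same, A–C
  different) and no attempt is made to reconcile them.
* Similarities are only comparable within one dataset, because
  normalization ranges are dataset-wide.
* `a_cp` assumes the rearranged signal rises toward a clear maximum; on
  near-flat signals it degrades to noise around 0.
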