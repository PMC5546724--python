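# Methods

## Model

A binned intra-chromosomal Hi-C contact map is a symmetric matrix `W`
(`n × n`, non-negative, possibly real-valued after balancing) with bin
coverage `c_i = Σ_j W_ij` and total read pairs `N = Σ_i c_i / 2`. A
partition assigns each bin a domain label `σ_i` under the constraint that
every domain is a contiguous run of bins. The quality of a partition is

    Q(σ; γ) = (1 / 2N) Σ_ij (W_ij − γ E_ij) · [σ_i = σ_j]

summed over ordered pairs, diagonal included (configurable). The
resolution parameter γ scales the null expectation: at γ = 1 a domain
must merely beat the background, at larger γ it must beat γ-fold
background, so optima shift toward smaller, more intensely enriched
domains. Because the null reproduces all coverages, the single-domain
partition scores exactly `1 − γ`; this identity is used as a correctness
check throughout the test suite.

## Null model

The expected map factorizes as `E_ij = κ*_i κ*_j f(|i − j|)` subject to
`Σ_j E_ij = c_i` for every bin (hence `Σ_ij E_ij = 2N`). This preserves
the two dominant nuisance structures of Hi-C maps — genomic-distance
decay and per-bin visibility — while containing no domain structure.

**Distance decay.** `f(d)` starts from the raw mean of the `n − d` matrix
elements at distance `d`. Because the decay is close to a steep power law
(`≈ d⁻¹` at intermediate distances) near the diagonal, where the raw
means are already precise, a fixed-width running mean would be badly
biased there: a centered window {1, 2, 3} estimates `f(1)` of a `d⁻¹`
law at 0.61 of its true value, and the resulting systematic positive
near-diagonal residuals `W − E` are strong enough that the exact
optimizer carves dozens of spurious two-bin domains on maps with no
planted structure at all. The smoother therefore uses a centered window
whose half-width grows with distance, `h(d) = min(cap // 2, d // 4)` with
`cap = max(3, round(span · n))` and `span = 0.01` (1% of the distance
points) by default, and averages geometrically whenever all window
entries are positive — unbiased under a pure power law up to curvature
terms — falling back to the arithmetic mean in the sparse far tail where
empty distances occur. `f(0)` is the raw diagonal mean, never blended
into the rest. Windows are truncated symmetrically at the far end of the
series.

**Effective coverages.** The constraint system
`κ_i Σ_j κ_j f(|i − j|) = c_i` is solved by fixed-point iteration with
geometric damping, `κ ← sqrt(κ · c / (F κ))` where `F` is the Toeplitz
matrix of `f`: plain substitution can oscillate in a two-cycle on maps
with heterogeneous coverage, and the geometric mean of the current
iterate and the raw update suppresses exactly that mode. Initialization
is `κ_i = sqrt(c_i / mean(c))`, so the solution is deterministic.
Zero-coverage bins are pinned at `κ = 0` and excluded from all sums.
Convergence is declared when `max_i |Σ_j E_ij − c_i| / max(c_i, 1)` falls
below `tol` (default 1e-6, default cap 2000 iterations; the standard
fixtures converge in well under 200). On the synthetic fixtures the
solved `κ*` correlates with observed coverage at r ≈ 0.96 under a
log-normal visibility spread of 0.5.

## Optimization

**Stochastic heuristic (default).** Each trial starts from singleton
labels and alternates two phases until a full cycle changes nothing:

1. *Endpoint moves.* Bins are visited in a fresh uniformly random order
   each round; a bin that is the left (right) end of its segment may
   adopt the label of the adjacent segment on that side. The best of
   {left, right, stay} is taken when its ΔQ is strictly positive, ties
   broken toward the lower-indexed side. ΔQ is evaluated in O(1) from row
   prefix sums. Only endpoint moves are legal, which provably preserves
   contiguity.
2. *Super-bin merges.* Segments are locked and visited in random order;
   a segment merges with an adjacent segment when that strictly increases
   Q (gains from 2-D prefix sums). After the greedy merge sweeps
   converge, the locked segments are regrouped *optimally* by an exact
   chain dynamic program over the current m segments (O(m³), cheap once
   the bin-level dynamics has coarsened the partition). The regrouping
   can only merge consecutive segments, never split one, so Q is
   monotone. It exists because purely pairwise merges provably stall:
   a small noise-locked segment can make both pairwise merges with its
   neighbors unprofitable while merging all three segments gains Q
   through the interaction of the two outer segments.

Q never decreases within a trial, and every trial's Q is bounded by the
exact optimum (asserted in the tests). The update order is the only
stochastic element; a master seed spawns per-trial child streams through
`numpy`'s `SeedSequence`, making full runs bit-reproducible.

**Consensus.** With `n_trials = 10` (default), the boundary score of each
of the n+1 borders is the fraction of trials in which its two flanking
bins carry different labels; chromosome ends score 1 by convention.
Borders scoring at least the cutoff (default 0.9, i.e. at least 9 of 10
trials) become consensus boundaries; TADs are the maximal runs between
consecutive consensus boundaries. Runs consisting solely of zero-coverage
bins are dropped and zero-coverage bins at run edges are trimmed and left
unassigned.

**Exact optimizer.** `optimal_partition` fills `M[i][j]` — the best Q
attainable on bins `i..j` — in order of increasing length as the maximum
of the whole-segment score (O(1) via 2-D prefix sums) and all binary
splits `M[i][r] + M[r+1][j]`; three nested loops, O(n³) total, with
traceback through stored split points. On exact ties the whole-segment
option wins, so a perfectly flat score landscape (e.g. `W = E`) yields
the single-domain partition. A brute-force enumerator over all `2^(n−1)`
contiguous partitions (boundary bitmasks, n ≤ 16) provides the
independent oracle; DP and enumeration agree to 1e-12 on dozens of random
maps in the test suite. The exact optimizer is practical to a few hundred
bins and is the reference against which the heuristic's consensus is
scored (NMI ≥ 0.977 expected on clean planted maps; the standard 200-bin
fixture reaches 1.0).

## Partition comparison

Normalized mutual information `2 I(X;Y) / (H(X) + H(Y))` over paired bin
labels, natural logarithms, computed from the contingency table with
`I = H(X) + H(Y) − H(X,Y)` so identical partitions score exactly 1. Bins
unassigned in *both* partitions are excluded; bins unassigned in exactly
one are retained as one extra label class of that partition (the
convention for the one-sided case was open; keeping the bins preserves
the penalty for calling domains where the other set calls none). The
implementation is cross-checked in the tests against scikit-learn's
arithmetic-mean NMI.

## Synthetic data

The generator emulates the statistics that make TAD calling nontrivial
on real maps: expectation
`μ_ij = v_i v_j max(|i−j|, 1)^(−α) β^[same domain] β^[same sub-domain]`
with log-normal per-bin visibility `v` (spread `coverage_sigma`),
power-law decay exponent `α` (default 1, the empirical intermediate-range
behavior of mammalian Hi-C), within-domain enrichment `β` (default 2;
sub-domains are enriched `β²`), rescaled so the expected total equals the
requested read depth; counts are Poisson on the upper triangle, mirrored,
diagonal zero (matching balanced maps). Defaults were fixed once at
values typical of published 40-kb-bin analyses. Standard fixtures: `F4`
(a literal 4-bin two-block matrix), `F200` (200 bins, 8 domains,
depth 2·10⁶), `F500` (500 bins, 12 domains, depth 5·10⁶,
`coverage_sigma = 0.5`), `FNEST` (300 bins, 6 domains split into 2–3
sub-domains each, `β = 1.8`).

What the generator does **not** emulate: restriction-fragment structure,
mappability artifacts, translocations/copy-number effects, compartment-
scale checkerboards, or loop-anchor point peaks. Passing tests therefore
demonstrate correctness of the machinery and recoverability under the
stated noise model, not performance on any particular real dataset.

On `FNEST`, γ = 0.75 merges everything into one domain, γ ≈ 1 recovers
approximately the 15 planted sub-domains, and γ ≥ 1.5 saturates at
singletons — the fixture's full dynamic range is narrower than a real
chromosome's, but the count/size monotonicity with γ holds as expected.

## Boundary enrichment

For each boundary coordinate, peaks are assigned by midpoint to 40-kb
offset bins spanning ±600 kb (31 offsets), summed over aligned
boundaries, and divided by the expectation under uniform random placement
on the analyzed chromosome (`n_peaks · covered_length / chrom_length` per
offset bin; windows truncated by chromosome ends contribute only the
covered fraction). The null is per-chromosome; midpoint assignment avoids
biasing toward long peaks.

## Numerical choices and degenerate inputs

- Bins are 0-based; BED output is 0-based half-open; COO text is
  `i j value` with 0-based indices, upper triangle sufficient.
- Matrix symmetry is enforced within a relative 1e-8 and then
  symmetrized exactly; diagonals are kept as provided.
- ICE balancing (optional preprocessing) drives positive-coverage row
  sums to their common mean within `tol`, preserves the total read count
  by rescaling, leaves zero rows untouched, and flags non-convergence.
- A boundary score equal to the cutoff counts as a boundary; the
  comparison includes a 1e-12 guard for the float representation of
  `k / n_trials`.
- `n = 2` maps return the better of {one domain, two domains}; all-zero
  maps are rejected by the solver; non-converged null models are usable
  but flagged and warned about.

## Known limitations

- Modularity maximization overfits noise: on a map with *no* planted
  structure the exact optimum still has Q > 0 with confidently
  reproducible spurious boundaries, because the noise lives in `W` itself
  and is shared by every trial on that map. Boundary scores quantify
  sensitivity to update order, not to data noise; assessing the latter
  requires replicate maps.
- The O(n³) exact optimizer is impractical beyond a few hundred bins
  (use the heuristic, which matches it closely on the fixtures).
- Inter-chromosomal maps, overlapping domains, and hierarchical
  domain-tree construction across γ values are out of scope.
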