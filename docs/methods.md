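# Methods

This note documents the models implemented in `pnampkit`, the parameter
choices that matter, and what the synthetic data do and do not emulate.

## Replication simulator

`simulate_replication` models one S phase per cell. Each origin fires with
probability equal to its `efficiency`, at a time drawn from a normal law
truncated at zero (`firing_time_mean`, `firing_time_sd`; arbitrary time
units). Fired origins emit two forks moving outward at `fork_speed`
(bp per time unit; default 1000). Every 100-bp bin is assigned to the
first-arriving fork — this includes passive replication of non-firing
origins and makes fork annihilation implicit, since the first-arrival
boundary between two converging forks is exactly their meeting point. Cells
in which no origin fired are re-drawn, so the genome is always replicated;
requesting a simulation in which no origin *can* fire is an error.

The truncated-normal firing law is a modeling choice: two parameters are
enough to express early/late and efficient/inefficient origins, and a
distributive initiation zone can be composed from many low-efficiency
origins spread over a window. No claim is made that real firing-time
distributions are normal.

Direction determines polymerase: a rightward fork synthesizes the Watson
strand continuously (Pol ε, leading) and the Crick strand discontinuously
(Pol δ, lagging); a leftward fork reverses the assignment. The per-bin
fraction of cells replicated rightward (`rightward_fraction`) is therefore
simultaneously the Pol ε usage truth on Watson, and its complement the
Pol ε truth on Crick — the `ForkField` container asserts this identity.

## Pu-seq count sampling

`simulate_puseq_counts` draws independent Poisson counts per strain, strand
and bin. The expected mutant count is
`depth × bias(x) × P(strand at x synthesized by that mutant polymerase)`;
the wild-type-polymerase control has expectation `depth × bias(x)`. The
optional multiplicative `bias_profile` is shared by all strains, which is
the reason the analysis divides normalized mutant data by normalized
control data: shared library bias cancels in the ratio (a property test
verifies flatness under a 2× bias spike).

Defaults used by the tests and the acceptance script: `depth = 200` reads
per strand per bin, `n_cells = 2000`, chromosome length 30–50 kb. These are
deliberately modest problem sizes chosen as the package's own test
conditions; per-bin count noise at depth 200 (CV ≈ 7 %) is comparable to a
well-covered real library binned at 100 bp.

What the simulator does **not** emulate: mappability structure, GC bias
differing between strains, ribonucleotide-removal leakage, incomplete
mutant penetrance, replication-timing covariance between neighboring cells,
and chromosome-end effects. Passing tests therefore show the analysis chain
is correct under its statistical assumptions, not that those assumptions
hold in any particular library.

## Usage, initiation index, RFD

The chain follows the standard Pu-seq computation:

1. total-count normalization per track over unmasked bins;
2. mutant/control ratio per bin (control-zero bins masked);
3. centered moving average of `2m+1` bins with `m = 3`;
4. forward differential `Δf(x) = f(x+1) − f(x)`, stored at `x` — the
   half-bin ambiguity of the assignment is absorbed by the ±2-bin tolerance
   used in origin-recovery checks;
5. the differentials smoothed again with `m = 3`;
6. `Ini(x) = ΔE_w − ΔE_c − ΔD_w + ΔD_c` where all four signs match the
   initiation pattern (`ΔE_w>0, ΔE_c<0, ΔD_w<0, ΔD_c>0`) or all four match
   the reversed merging pattern; all other bins are set to 0 but recorded
   as undefined in `defined_mask`, so Z statistics and peak calling operate
   on a full-length series;
7. division by the standard deviation of the resulting series (zeros
   included, masked bins excluded). This is the literal effect of Z
   normalization followed by subtraction of Z(0), and preserves signs.

Smoothing semantics: windows average over the *available unmasked* members,
so they shrink at chromosome ends and around masked bins; masked bins stay
masked with value 0, and every derived track inherits the union of its
inputs' masks. Window sums accumulate in ascending coordinate order with an
explicit loop, making results bit-reproducible and directly comparable with
a straightforward reference implementation; windows hold at most `2m+1 = 7`
values, so the cost is negligible.

RFD is computed from the smoothed usage tracks as
`(E_w − E_c − D_w + D_c)/(E_w + E_c + D_w + D_c)`, which is algebraically
bounded in [−1, 1] for non-negative usage. An alternative form replacing
the Pol δ terms by their differentials is available behind `use_delta=True`
for comparison; it is not bounded and is not the default because it
contradicts the defining notion of a rightward-minus-leftward signal over
their sum.

One calibration caveat, verified in testing: per-strand total-count
normalization rescales the Watson and Crick tracks by `1/mean(rf)` and
`1/mean(1−rf)` respectively, where `rf` is the genome-mean rightward
fraction. When `mean(rf) ≠ 0.5` (asymmetric origin placement), RFD becomes
a monotone, sign-preserving distortion of `2·rf − 1` rather than equal to
it; the ±0.1 agreement with fork truth holds on symmetric designs such as a
single central origin. Real whole-genome data have `mean(rf) ≈ 0.5` by
construction.

Peak calling (`call_origin_peaks`) selects local maxima of the normalized
index at height ≥ 1.0 Z, greedily by height, suppressing maxima within 10
bins of an accepted peak. Both thresholds are exposed in `AnalysisParams`.
The threshold works because the sign-condition gate zeroes most noise bins
(all four independent differentials must agree), leaving genuine initiation
zones to dominate the series SD.

## Tandem-duplication detection

`maximal_exact_matches` finds all maximal exact matches ≥ k between a read
and the reference unit by k-mer seeding: an exact match of length L yields
L−k+1 consecutive hits on one dot-plot diagonal, so merging consecutive
per-diagonal hits reconstructs the maximal matches exactly. Matches are
chained greedily into collinear runs (read and unit offsets both advancing,
gaps ≤ `max_gap`, overlaps up to k tolerated); a match restarting at a
lower unit coordinate — the next tandem copy — necessarily starts a new
run. A run covering ≥ 50 % of the unit counts as one copy
(`require_full_span=True` raises this to 95 %); partial terminal runs stay
visible in `chain_spans`. Reverse-complement reads are handled by scoring
both orientations and reporting the one with more matched bases.

Defaults `k = 15`, `max_gap = 200` bp, query coverage 0.8: with a 2 %
substitution rate the expected error-free stretch is 50 bp, so 15-mer seeds
occur densely (P(clean 15-mer) ≈ 0.74) and inter-seed gaps rarely approach
200 bp. These defaults target error-free to ~2 %-error reads; raw reads
with higher error rates would need smaller k or gapped seeding, which is
out of scope.

Junction-spanning reads are those on which two ~1-kb flanking queries are
both located (chained seed coverage ≥ 80 % of the query) in the correct
order. On an unduplicated haplotype, reads shorter than the segment cannot
contain both queries, which the false-positive test exercises with 1000
simulated reads.

Read simulation (`simulate_tandem_reads`) concatenates
`flank + unit×copies + flank`, samples read start/length (fixed or
truncated-normal length law), guarantees a configurable fraction of reads
spanning the whole array plus a flank margin, and encodes the truth in read
names. Substitution errors are uniform; indels are not modeled, consistent
with the exact-seed detector's scope. Unit and flank sizes in tests (1.5 kb
and 2–2.5 kb) are scaled-down stand-ins for the multi-kilobase segments of
real experiments; the detector's logic is length-independent given
proportionally scaled `max_gap`.

## Coverage-based copy number

`normalized_read_count` divides per-base counts by the genome-wide unmasked
mean; `segment_mean` averages the normalized values over a region, masked
positions excluded from numerator and denominator. Because the duplicated
bases themselves inflate the genome mean, a c-copy segment occupying a
fraction f of the genome normalizes to `c/(1 + (c−1)f)`, slightly below c —
about 6 % low for c = 4 at f = 0.02, within the 10 % calibration band the
tests assert. `simulate_coverage` draws per-base Poisson counts at
`depth × local copy number`, emulating mapped coverage of a clone whose
extra tandem copies pile onto the single reference copy.

## Assay statistics

The reconstitution rate of a two-plate assay is
`n_selective / (ratio × n_complete)` with `ratio` the CFU multiple plated
on selective medium (default 10). A zero selective count yields the
detection limit `1/(ratio × n_complete)` flagged as an upper bound; fold
changes against an upper-bound denominator are flagged as lower bounds and
printed as ">x-fold". Proportions carry Wilson 95 % intervals
(via statsmodels). `expected_copies_after_cycles(n)` returns `2^n`, the
copy number after perfect iterated duplication; the stochastic counterpart
`simulate_iterative_pnamp` doubles with probability `p_dup` per cycle and,
with probability `p_del`, collapses the array to a uniform copy number in
[1, current−1]. The uniform collapse is an acknowledged stand-in: deletions
between tandem repeats certainly occur, but no rate law is available, and
none of the package's conclusions depend on its shape.

The colony simulator assumes every plated CFU forms a colony on complete
medium (no plating-efficiency term) — the estimator calibration tests
quantify only sampling error, not plating losses.

## Degenerate inputs and numerical conventions

Coordinates are 0-based half-open internally; wig output is 1-based
(fixedStep), bedgraph 0-based. A chromosome length not divisible by the bin
size leaves a truncated final bin, flagged but included in totals. Masked
bins are excluded from every sum, mean, normalization and SD. All-zero or
all-masked tracks are rejected by normalization ("empty dataset"); tracks
shorter than `2m+2` bins are rejected by the initiation index. Ties in peak
calling resolve to the lower bin index; equal best/second-best alignment
scores mark a read ambiguous and exclude it. Every simulator consumes a
`SimConfig.seed` through per-stage generator streams, so identical seeds
give bit-identical outputs while stages remain statistically independent.
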