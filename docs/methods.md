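# Methods

This note records the model as implemented, the conventions chosen where
more than one reading was defensible, and what the synthetic benchmark does
and does not demonstrate.

## Model and measures

Fragments restricted to n heterozygous SNP loci form an m x n matrix over
`{0, 1, -}`. For alleles a, b the *conflict* score c(a,b) is 1 iff both are
called and differ; the *pair weight* d(a,b) is −1 for a called match, +1
for a called mismatch, 0 if either is a gap.

A bipartition P of the fragments is judged by:

* `sc(P, M)` — errors corrected, computed column-wise: at column j, with
  N[g,v] the number of group-g fragments calling allele v, the column
  contributes min(N11+N20, N10+N21). This is the number of calls to flip so
  every fragment matches its own group's haplotype, minimised over the
  induced haplotype, and it is the quantity the dynamic program updates
  incrementally. A related measure lets each fragment instead match
  whichever induced haplotype it prefers (`errors_corrected(H, M)`, the
  per-fragment minimum); it lower-bounds the column-wise measure, with
  equality at any optimal partition — reassigning every fragment to its
  preferred haplotype and re-deriving the votes can only reduce the
  column-wise count. The two coincide on all optima returned by the
  solvers; they differ on deliberately bad partitions (both of {"00","11"}
  in one group scores 2 column-wise but 0 per-fragment). Tests exercise the
  inequality and the equality-at-optimum separately.
* `sd(P, M)` — fragments cut: the sum of Σ_j d(·,·) over fragment pairs
  crossing the cut.
* `sp = sc − w·sd` — the combined objective, minimised.

The induced haplotype sets H1[j] = 0 iff N11+N20 ≤ N10+N21 (ties
deterministically take the ≤ branch). A **tied vote means the fragments
cannot orient the site**, so tied columns — like uncovered columns and
singleton blocks — are flagged unphased. This matters empirically: ties
become more frequent as the sequencing error rate grows, which is why the
mean phased length at m=140, l=3 drops by about 1.2 SNPs between e=0.005
and e=0.05 while the block structure is unchanged. Unphased sites still
carry alleles (from the same rule) so scoring stays total.

## Exact score arithmetic

`sc` and `sd` are integers; `w` is held as an exact `fractions.Fraction`
(floats are converted through their decimal string, so 0.1 becomes 1/10).
All score comparisons use the integer key `den·sc − num·sd`, never floats,
so ties break identically on every platform. Ties among equal keys go to
the earlier-inserted beam entry; the brute-force enumerator breaks ties by
the smallest binary encoding of the partition.

## The beam sweep

Fragments are sorted stably by (first called column l, last called column
r). The active set R(i) is the set of rows ≤ i spanning column l(i); rows
that have fallen out of the active set can never again call a column the
sweep will visit (their r lies strictly left), which makes two things
exact:

* projection: extensions agreeing on the carried-over rows are
  interchangeable, so duplicates are merged keeping the best score;
* the incremental updates: `delta_ec` recomputes the column minority votes
  over carried rows before and after adding the new row, `delta_fc` adds
  ±1 per cross-group co-called column. An audit hook (`inspect=`) lets
  tests recompute every surviving entry's (sc, sd) from scratch at every
  step; they match exactly.

The beam is a bounded binary max-heap over the score key with one entry per
canonical active partition (smallest active row pinned to group 0 —
complement symmetry halves the state space). When full, a new entry
replaces the root only if strictly better. With k ≥ 2^(k2−1) every state
survives and the sweep equals exhaustive enumeration; the tests assert this
on noisy random instances, and also that widening the beam never worsens
the final score (an empirical regularity of this DP, not a theorem of beam
search in general).

Solving is per connected component by default. Components share no
fragments, so per-block scores add exactly to the whole-matrix score; a
whole-matrix mode exists behind a flag and handles the empty-overlap
boundary by collapsing the beam to its best entry (exact for the same
reason). Elementary-operation counters (children generated, heap inserts,
inner-loop cell visits) provide a machine-independent effort measure that
grows linearly in k, mirroring the O(m·k·k1·k2) bound without asserting
wall-clock time.

## Synthetic data generator

One seeded `numpy` generator drives everything, in a fixed order: the
haplotype; then per fragment its length, start, flips left-to-right,
interior deletions left-to-right. Conventions:

* h1 is uniform over {0,1}^n; h2 is its complement (all loci heterozygous).
* ⌈m/2⌉ fragments come from h1 and ⌊m/2⌋ from h2 (odd m is allowed; the
  benchmark grids use odd fragment counts).
* Fragment length is round(Normal(l, 1)) **redrawn until it lands in
  [2, n]** — truncation by rejection, not clamping. Rejection gives
  E[len] ≈ 3.1507 at l=3 and hence mean call coverage
  1.4·(0.9·E[len] + 0.2) ≈ 4.25 at (n=100, m=140, g=0.1), matching the
  coverage the benchmark protocol reports; clamping would give ≈ 4.15.
  Observed mean coverage in the acceptance run is 4.24.
* Start is uniform over the feasible window [1, n − len + 1] (length must
  therefore be drawn first).
* Every allele flips with probability e; every *interior* allele is then
  deleted with probability g (ends are kept, so every fragment calls ≥ 2
  sites and no resampling is needed in practice; the guard exists anyway).

What the generator does **not** emulate: base-quality variation (qualities
are parsed from HapCUT-style files but never weighted), non-uniform
fragment starts, paired-end insert structure, multi-allelic or indel
sites, and genotyping error in the truth itself. Passing the simulated
benchmarks therefore demonstrates correctness of the combinatorial solver
under the stated noise model, not robustness to real-library artefacts.

## Evaluation conventions

* Switch errors are counted per block over *phased* sites only; agreement
  is relative (complementing truth or reconstruction leaves the count
  unchanged); no comparison crosses a block boundary.
* Phased length counts phased sites in blocks of ≥ 2 sites.
* QAN50: blocks are cut at switch errors into clean segments; a segment's
  span is inclusive (coords(last) − coords(first) + 1, so a one-SNP
  segment spans 1); the adjusted span multiplies by phased sites over *all*
  sites whose coordinate falls in the segment's extent; segments are
  walked in decreasing adjusted span and the answer is the adjusted span of
  the segment at which cumulative phased sites first strictly exceed half
  of all sites in the evaluated input. For simulated data the site index
  serves as the coordinate; a monotone site→bp map plugs in for real data.

## Problem sizes

The default test suite runs in well under a minute on one CPU: oracle
cross-checks use 100 random instances with m ≤ 8, n ≤ 10 (where 2^(m−1)
enumeration is instant), and the benchmark reproduction uses the printed
protocol unchanged — 100 replicates per cell at n=100 (cells up to m=351
fragments), which is already desk scale.

## Known limitations

* The brute-force solvers refuse (rather than truncate) instances beyond
  m, n = 20; they exist as oracles, not as production solvers.
* Real fosmid-scale datasets (millions of SNPs) are out of the benchmark's
  scope here, though the fragment reader accepts the HapCUT-style files
  such pipelines produce.
* No finite w is claimed to make the blended model exactly equivalent to
  pure max-cut; w is simply exposed.
* Whole-matrix mode reports the same optima as per-block mode but is
  quadratically slower on long disconnected inputs; per-block is the
  default for a reason.
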