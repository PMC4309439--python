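# Methods

## Signal model

The unit of analysis is one (chromosome, strand) pair.  Its data are two
replicate tracks of per-probe log2(condition/control) expression ratios on
a shared probe grid.  The model behind the caller is piecewise-constant:
the genome is mostly silent (ratio ≈ 0) with contiguous *domains* in which
transcription changed — a positive shift (activation) or a negative one
(repression) — plus probe-level noise.  The two strands are processed as
fully independent datasets throughout; nothing joins them before the
summary tables.

Coordinates are 0-based half-open everywhere, including BED outputs.  A
domain's genomic span runs from its first member probe's start to its last
member probe's start plus the probe length.

## Domain calling

**Seeding.** For each direction independently, a window of `seed_window`
(12) consecutive probes qualifies when at least `seed_min_hits` (10) of its
probes lie strictly beyond ±`seed_threshold` (0.35 in log2 units, i.e. a
~1.27-fold change; values exactly at the threshold do not count).  A seed
is the union of probes covered by a maximal run of consecutive qualifying
window start positions — the only reading of "a domain begins and spreads
while the next window qualifies" that is order-independent.  The window
must have its full 12 probes, so no seed ever spans fewer than 12 probes;
with 25-bp probe spacing this sets the ~300-bp resolution floor of the
method.  A candidate whose overall mean contradicts its direction (possible
only under extreme noise, when a few large-magnitude outliers of the
opposite sign sit inside the run) is not a credible call and is dropped.

**Extension.** Each side of a seed advances one probe at a time while the
mean of the `extend_window` (50) probes immediately beyond the edge keeps
the seed's sign (fewer probes near the chromosome end are averaged as
available).  The stopping edges depend only on the track, so the
production path precomputes the failing positions once per track and
binary-searches them; a property test pins this to the literal
probe-by-probe walk.

**Replicate consensus.** Same-direction domains are merged within each
replicate (probe ranges overlapping or touching; the union's mean is
recomputed from the track).  Domains of replicate 1 are then kept only if
they share at least one probe with a same-direction domain of every other
replicate.  Replicate 1's coordinates are retained; the asymmetry is
deliberate and cheap, because boundaries are re-derived next on the
virtual track.

**Boundary refinement.** On the *virtual track* (probe-wise mean of the
replicates), the domain average is computed once on entry and frozen.  For
each side independently, a `2 × refine_flank`-probe window (30) is placed
with `refine_flank` probes outside the boundary and `refine_flank` inside
(including the boundary probe), mirrored between the left and right edges
so both behave identically on a crisp domain.  For activation the boundary
moves outward while the window mean exceeds `refine_factor` (0.5) times
the frozen domain average, and inward otherwise; repression is mirrored.
A side stops at the first reversal of its decision or at the chromosome
end — with a moving average the procedure could oscillate, and the frozen
average plus reversal-stop guarantees termination and determinism.  A
domain that would shrink below 2 probes is discarded with a warning, as is
one whose virtual-track mean is zero or contradicts its direction.  A
final merge resolves overlaps created by refinement.

On noiseless planted domains this pipeline recovers edges exactly for
domains of roughly 56 probes and longer.  Shorter domains overshoot
symmetrically by up to 4 probes: the entry seed includes 2 silent probes
per side, which dilutes the frozen average, and the half-average stationary
point then sits slightly outside the true edge.  This is a property of the
half-average rule itself, not of the implementation, and is why recovery
tests assert exactness only for long domains.

## Randomization significance

The test statistic for a domain is `n_probes × |mean virtual ratio|` —
the absolute probe sum, which rewards both long and strong domains.  For
each of `n_randomizations` rounds, every replicate track is independently
randomized, the full segmentation is re-run, and the maximum domain score
per direction (0 if nothing is called) is recorded.  A domain's empirical
P is `(1 + #{null maxima ≥ score}) / (1 + n_randomizations)` — the +1
correction bounds P ≥ 1/(n+1) and avoids zero P-values.  Using the
per-direction *maximum* gives family-wise control across the track, which
is why a single reporting threshold (P < 0.025, strict) is applied with no
further multiplicity correction.  Note the floor: with n randomizations
the smallest attainable P is 1/(n+1), so at least 40 rounds are needed for
anything to pass 0.025; the default is 199.

The default randomization is an i.i.d. shuffle of each track's values.
The quantity being tested is *contiguity* — could a run this long and this
consistent arise from the same value distribution without positional
structure? — and the shuffle destroys exactly that.  A circular rotation
(`method="rotate"`) is also provided; it preserves local autocorrelation,
but it also preserves real contiguous signal, merely relocating it.  When
genuine domains cover an appreciable fraction of the track, independently
rotated replicates produce chance same-direction overlaps that re-segment
into high-scoring null domains, and the test loses essentially all power
against small true domains.  On data where real signal is sparse the two
schemes agree; where it is not, the shuffle is the meaningful null.

Calibration is checked by Monte Carlo: on pure-noise replicate pairs the
P-value of the top activated call is uniform (chi-square goodness of fit
over 200 independent runs).  The check uses 6,000-probe tracks with noise
sd 3.0 — large relative to the 0.35 threshold, so that spurious calls
occur in nearly every run and the rank-based P has almost no atom at 1;
runs with no call contribute P = 1, consistent with a max-score of 0.

## Classification

Overlap is measured against whole gene spans (pre-mRNA, not exons) with a
≥ 1-bp threshold.  A domain is *sense* to genes it overlaps on its own
strand, *antisense* to genes on the opposite strand, *intergenic* if
neither.  The vlinc rule counts only same-strand gene spans as "annotated"
coverage: a domain qualifies as a vlincRNA when ≥ `vlinc_min_unannotated`
(50,000) bp of its span is free of same-strand annotation.  Opposite-strand
annotation must not count, otherwise antisense vlincRNAs — a substantial
and biologically central part of the class — would be defined away.

The domain summary counts per direction × category (Total, Intergenic,
Genes, Sense, Antisense, Vlincs); a domain overlapping genes on both
strands counts in both Sense and Antisense, so Genes ≤ Sense + Antisense.
The gene-level summary marks each gene sense-hit/antisense-hit per
direction; a gene hit by both directions on a strand counts once in each
direction row, preserving per-direction additivity.  The antisense
concordance partition splits antisense-hit genes into antisense-only
(no sense change), concordant (sense and antisense share one direction)
and opposite (directions differ; genes carrying both directions on one
strand are counted as opposite, the conservative reading).

Percentages are computed against the full catalogue size and rounded
half-to-even to one decimal using exact decimal arithmetic.

## Activation-bias test

For a category with `a` activated of `t` total calls against a global rate
`A/T`, the expected activated count is `t·A/T` (optionally floored or
rounded to an integer when comparing against printed integer
expectations — `expected_rounding` is an explicit argument, default
`none`), the expected repressed count is `t` minus that, and a Pearson
goodness-of-fit statistic `Σ(obs−exp)²/exp` with `cells−1` degrees of
freedom gives the upper-tail P.  Equal observed/expected totals are not
enforced because flooring perturbs them.  The statistic is computed
directly and the tail comes from `scipy.stats.chi2`.

## The synthetic benchmark

The generator emulates the *normalized output* of a strand-specific tiling
array, not the array itself: a uniform probe grid (default spacing 25 bp,
chosen so the 12-probe seed window spans ~300 bp), planted non-overlapping
domains each covering ≥ 12 probes, and per-probe i.i.d. Gaussian noise,
independent across replicates.  The reference benchmark
(`standard_simulation`) is one 5-Mb chromosome (200,000 probes), 20
planted domains of 2–100 kb, effect magnitudes uniform in [0.5, 0.8] with
equal activation/repression probability, noise sd 0.2 and two replicates.
Gene catalogues draw exponential gene lengths (mean 50 kb, clipped at
200 bp) placed uniformly, forbidding same-strand overlap only — opposite
strand overlap is allowed deliberately, since antisense configurations are
what the classifier must see.  All generators are bit-reproducible given
their arguments and a single integer seed.

What the simulation does *not* emulate: probe-sequence and GC effects,
spatially autocorrelated noise, cross-hybridization, jittered probe
spacing, expression-level-dependent variance, or the upstream
normalization pipeline.  Passing the recovery benchmark therefore shows
that the algorithmic machinery is correct under its own signal model, not
that real-array accuracy will match; on real data the effective noise is
heavier-tailed and locally correlated, and boundaries should be read with
correspondingly more caution.  The absolute published census counts
(1,141 transfrags, 71 vlincRNAs, and so on) depend on the original raw
arrays, their normalization, and the hg18 RefSeq annotation, and are
inputs to — not outputs of — this package's summary statistics.

## Problem sizes and runtime

The test suite and the acceptance script are sized for a single CPU: the
full benchmark (200,000 probes × 2 replicates × 199 randomizations) runs
in a few seconds because null rounds on shuffled tracks rarely seed, and
the calibration study (200 runs × 20 segmentations of 6,000 probes) takes
under half a minute.

## Known limitations

- Exactly two replicates is the designed case; k > 2 replicates intersect
  replicate 1 against every other, which is asymmetric in the reference
  replicate.
- The refinement reversal-stop rule is one of several defensible
  termination rules; all agree within about a flank of each other, and
  boundary uncertainty at that scale (~375 bp) should be assumed.
- The caller has no notion of expression level, only of ratio shifts; a
  domain is a region of coherent *change*, not a transcript model.
- P-values are per-(chromosome, strand) family-wise; no correction is
  applied across units beyond the max-statistic construction.
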