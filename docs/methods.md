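# Methods

## The simulation model

The simulator is a fixed-timestep kinetic Monte Carlo model of loop
extrusion on a 1-D lattice.  One chromosome of length `L` (default
300 kb) is divided into bins of `bin_size_bp` (default 2 kb).  An
extruder occupies two bins — its left and right legs — and each leg
attempts one outward step per time step.  A step fails if the target
bin is occupied by any other leg (no bypass, no stacking) or lies off
the chromosome.  Loading places a fresh two-bin extruder on a vacant
adjacent bin pair with probability `loading_rate` per pair per step;
unloading releases an extruder with probability `unloading_prob` per
step, so `1/unloading_prob` is the mean residence time and
`loading_rate · (n_bins − 1) / unloading_prob` the nominal steady-state
occupancy.  A fixed-timestep scheme (rather than an event-driven one)
is sufficient because every analysis consumes steady-state occupancy
statistics, not waiting-time distributions; one time step is simply
the time in which a free leg translocates one bin.

A finite **extruder pool** (`extruder_pool`, default 10) caps the
number of concurrently bound extruders.  This models the limited
cellular cohesin complement: prolonging residence ten-fold (unloader
depletion) raises bound cohesin roughly three-fold, to the pool limit,
rather than ten-fold into a fully jammed lattice — matching the modest
increase in chromatin-bound cohesin seen when the unloader is removed,
and required for longer residence to translate into longer loops
instead of gridlock.

### Barriers

A barrier lives in one bin and blocks a leg moving in its blocked
direction from entering that bin; entry succeeds with probability
`permeability` per attempt.  Directionality encodes head-on collision
with transcription: a `+` gene carries a barrier at its 3′-end bin
blocking left-moving legs (which meet the polymerase head-on), a `−`
gene the mirror image.  In a convergent pair the two barriers face
inward, so extruders loaded between two convergent sites end with one
leg at each — the configuration that accumulates cohesin between
convergent genes and produces corner dots between adjacent sites.
Centromeres and stalled replication forks block both directions with
permeability 0.

Gene-barrier permeability is `exp(−6.5 · expression_level)`.  At
expression 1 this is ≈1.5 × 10⁻³ per attempt: a wild-type extruder
(residence ≈ 50 steps) pinned at such a barrier crosses it rarely,
while a ten-fold longer-lived extruder usually crosses — which is what
lets unloader depletion extend loops past barriers that are effectively
absolute in the wild type.  Barriers with permeability ≤ 0.005 are
reported as "absolute" (`BarrierSet.absolute_bins`): within one
wild-type residence they are indistinguishable from permeability 0.

### Condition presets

| preset | barriers | rates |
| --- | --- | --- |
| `WT_G2M` | gene 3′ ends + centromere | base |
| `thiolutin` | stress-response genes (induced, absolute) + centromere | base |
| `scc2_depleted` | as WT | loading × 0.05 |
| `wpl1_depleted` | as WT | unloading × 0.1 |
| `HU` | as WT + absolute fork barriers at early origin ± 7.5 kb | base |
| `HU_scc2` / `HU_wpl1` | as HU | loading × 0.05 / unloading × 0.1 |
| `thiolutin_scc2` | as thiolutin | loading × 0.05 |

The fork distance default of 7.5 kb is the midpoint of the 5–10-kb
replicated cassettes mapped around early origins under hydroxyurea
arrest.  The residual rate factors are deliberately non-zero: depletion
of the loader or unloader is substantial but not complete.

### The synthetic genome

`make_genome` packs `n_genes` (default scenario: 40 genes on 300 kb)
in strictly alternating orientation, so every second junction is a
convergent pair with a ~1-kb intergenic gap; the remaining space forms
divergent gaps and telomeric margins.  Expression levels are
log-normal (median 1, σ = 0.4); the narrow spread keeps every
simulated window representative of a yeast chromosome arm, where
strong convergent barriers recur every 10–20 kb.  Stress-response
genes are a rare subset (2%, matching a few dozen induced genes among
~6000 ORFs — about one per 40-gene window) with low basal expression;
under thiolutin they are induced (RNA-pol-II fold enrichment > 4) and
become absolute barriers while all other gene barriers vanish.  One
centromere occupies the divergent gap nearest mid-chromosome; origins
occupy divergent gaps at 30–45-kb spacing, each early-firing with
probability 0.6; LTR-like elements are placed in a few intergenic
positions.

### Contact maps and tracks

Expected contact weight per pixel is

    w · B(i,j)/ΣB + (1 − w) · (F(i,j) + bonus(i,j)) / N_ref

with `B = (1 + |i−j|)^(−α)` (α default 1.5), `F` the per-snapshot
frequency of an extruder having legs exactly at `(i, j)`, a small
within-loop bonus (0.01 per pixel over the five diagonals inside each
loop — intra-loop compaction, kept well below the anchor-contact
weight so it cannot drown the long-range signal), `w` the background
weight (default 0.7) and `N_ref` the base-rate reference occupancy
(capped at the pool).  The background is normalized to unit mass but
the extruder term is scaled by the fixed `N_ref`, never by its own
sum: when loader depletion empties the lattice the loop signal fades
towards pure background instead of being silently renormalized back to
full strength, and when unloader depletion raises occupancy the loop
read share rises.  `read_depth` counts (default 3 × 10⁵) are drawn
multinomially over the unique pixels and mirrored.  Identical
configurations (including the seed) give bit-identical maps.

Tracks: cohesin = time-averaged leg occupancy scaled to genome mean
1.0 (the raw occupancy is exposed via `leg_occupancy` and serves as
ground truth for qPCR-style anchoring); RNA pol II = expression
painted over gene bodies on a background of 1.0; BrdU = a plateau of
fold enrichment 2.0 over `origin ± 7.5 kb` for early origins under HU,
flat 1.0 otherwise.

Simulations default to 20 500 steps (500 burn-in, snapshots every 5
steps).  A contact map is a population average over millions of cells;
a short trajectory contains only a few extruder lifetimes and
under-samples the anchor-pair distribution, biasing slow-turnover
conditions (low unloading) toward artificially few distinct loops.
Twenty thousand steps ≈ 200 wild-type residence times, enough for the
per-condition loop counts to stabilise, while a full simulation still
takes ~1–2 s.

## Analysis conventions and numerical choices

* **Coordinates** are 0-based, half-open everywhere (BED convention);
  bin `k` covers `[k·s, (k+1)·s)`.  1-based inputs must be converted
  before use.
* **Coverage-sqrt normalization** divides by `sqrt(r_i r_j)` of row
  sums; zero-coverage bins yield NaN.  One pass (the default, the
  Hi-C tool convention) halves a multiplicative per-bin bias on the
  log scale; the iterated operator (`iterations≈20`) removes a rank-1
  bias exactly and is what the bias-removal check uses.
* **Insulation** uses a square window (default 40 kb each side, pair
  separation capped at the window), normalized by the mean over valid
  bins — bins within one window of a chromosome end are invalid.
  Boundary calls are local minima deeper than the 30th percentile of
  valid bins.  The commonly quoted "bottom decile" qualifier is
  infeasible at this genome density: ~16–20 absolute-barrier sites
  with 2–3-bin-wide dips necessarily occupy ~35% of the ~110 valid
  bins, so a 10% cut can cover at most half the barriers even when
  every bottom-decile bin lies at a barrier (which it does).
* **APA** piles up `(2w+1)²` submatrices (`w` = 20 bins at 1-kb
  resolution per the standard geometry); strength = central square
  over the top-right corner square, side 11 at `w = 20` and ~`(2w+1)/4`
  at simulator-scale windows.  Pairs at the margins or within `w` of
  the diagonal are skipped and counted.  Note that on a
  distance-decaying map the corner sits at systematically larger
  separations, so even random-pair strengths exceed 1; quantitative
  "random ≈ 1" checks are therefore run on flat-background
  configurations, while decaying maps are compared between conditions.
* **Loop calling** tests each upper-triangle pixel against the mean of
  its donut ring plus lower-left square (peak radius 2, donut radius 5
  at 2-kb bins), converts normalized values to pseudo-counts via the
  map's total read depth, takes Poisson upper tails, applies
  Benjamini–Hochberg (FDR < 0.001), requires observed/expected > 1.75
  (the standard enrichment floor of the donut-filter family), clusters
  significant pixels with 8-connectivity and keeps calls longer than
  10 kb.  Anchor filtering demands both anchors (± one bin slack)
  overlap a cohesin site — AND semantics.
* **Domain calling** scores every candidate interval by the fraction
  of sign-consistent arrowhead pixels in its two corner triangles
  (threshold 0.6), suppresses near-duplicates (Jaccard > 0.7 or both
  boundaries within one bin), and merges resolutions by collapsing
  calls whose boundaries agree within one coarse bin, keeping the
  higher score.
* **Binomial comparisons** are exact two-sided tests of one count
  against the pooled total at p = 0.5, for depth-matched libraries.
  "Per million mapped pairs" is the depth normalization for cis/trans
  and anchored counts; it rescales but never reorders comparisons.
* **Ratio maps** default the pseudocount to the mean pixel mass of the
  two (depth-matched, normalized) inputs.
* **qPCR-anchored scaling** computes, per sample, the mean over common
  anchor sites of (qPCR ratio to reference)/(track ratio to
  reference).  Scaling must be applied before any threshold: peak
  calling on per-sample mean-normalized tracks would hide global
  occupancy loss.  In the synthetic workflow the true leg occupancy at
  the strongest reference sites plays the role of the qPCR
  measurements.
* **Meta-profiles** use the normal-approximation 95% band
  (mean ± 1.96·SE) for determinism.

## What the generator does and does not emulate

The simulator reproduces the *mechanistic* structure of the data:
directional barrier landscapes, occupancy accumulation between
convergent genes, corner dots between adjacent barrier sites,
insulation boundaries at absolute barriers, fork-flanked cassettes
under HU, and the occupancy responses to loader/unloader depletion.
It does not attempt 3-D polymer physics, trans contacts, cohesive
(non-extruding) cohesin, replication progression, nucleosome-scale
detail, GC/mappability coverage bias, or overdispersed sequencing
noise beyond multinomial sampling.  Consequently, passing tests
demonstrate that the analysis stack recovers planted structure under
the model's idealized noise — they bound algorithmic correctness, not
performance on real libraries, where biological and technical variance
is higher and detection thresholds bind sooner.

## Problem sizes used by the tests and the acceptance script

Chosen to keep a full run at desk scale: 300-kb genomes at 2-kb bins
(150 bins), 40 genes, read depth 3 × 10⁵ (5 × 10⁵ for the
planted-anchor recall scenario, which uses 42 uniformly strong genes
on 320 kb → ~20 planted anchor pairs), ten seeds per contrast, 20 500
simulation steps.  The acceptance script completes in well under a
minute; the full test suite in a few minutes.

## Known limitations

* Loop-length distributions under unloader depletion depend on the
  pool size; with an unlimited pool the lattice jams and loops
  shorten, which is a real property of exclusion models, not of
  cohesin biology at physiological density.
* The loop caller's Poisson model is exact for the simulator's
  multinomial noise but anti-conservative on overdispersed real data;
  the enrichment floor partially compensates.
* Domain calling simplifies the full arrowhead scoring stack to
  sign-consistency; scores are comparable within, not across,
  datasets.
* With very few extruders (severe loader depletion) the qPCR anchoring
  falls back to whatever common sites retain non-zero occupancy and
  warns below four sites.
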