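"""Synthetic yeast-like genomes and a 1-D loop-extrusion simulator.

Generates small annotated genomes (strand-aware genes, replication
origins, one centromere, LTRs), derives directional loop-extrusion
barriers from the annotation under a set of experimental condition
presets (G2/M wild type, transcription inhibition by thiolutin,
depletion of the cohesin loader Scc2 or the unloader Wpl1, and
hydroxyurea-arrested early S phase with stalled forks), runs a
fixed-timestep stochastic lattice simulation of two-sided loop
extrusion against those barriers, and renders binned contact maps and
cohesin / RNA-polymerase-II / BrdU fold-enrichment tracks with known
ground truth.

The model is deliberately one-dimensional: the chromosome is a lattice
of bins, an extruder is a pair of leg positions (left <= right), and
contacts arise from a distance-decay background plus the leg-pair
co-occupancy accumulated over simulation snapshots.  No 3-D polymer
physics is attempted.

Barrier semantics
-----------------
A barrier occupies one bin and blocks a leg moving in its blocked
direction from *entering* that bin; entry succeeds with probability
``permeability`` per attempt (0 = absolute block).  A gene contributes
a barrier at its 3'-end bin that blocks only the leg translocating
head-on into the transcription unit: for a ``+`` gene (polymerase
moving rightward) the barrier blocks left-moving legs, for a ``-``
gene right-moving legs.  Centromeres and stalled replication forks
block both directions absolutely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .contact_map import ContactMatrix, PairsTable
from .feature_calling import FoldEnrichmentTrack
import pandas as pd

logger = logging.getLogger("extrudex")

CONDITIONS = (
    "WT_G2M",
    "thiolutin",
    "scc2_depleted",
    "wpl1_depleted",
    "HU",
    "HU_scc2",
    "HU_wpl1",
    "thiolutin_scc2",
)

#: conditions with transcription inhibited (gene barriers removed except
#: induced stress-response genes)
_THIOLUTIN = frozenset({"thiolutin", "thiolutin_scc2"})
#: conditions arrested in early S phase with stalled forks
_HU = frozenset({"HU", "HU_scc2", "HU_wpl1"})
#: loader-depletion conditions: residual loading only
_SCC2 = frozenset({"scc2_depleted", "HU_scc2", "thiolutin_scc2"})
#: unloader-depletion conditions: prolonged residence
_WPL1 = frozenset({"wpl1_depleted", "HU_wpl1"})

SCC2_LOADING_SCALE = 0.05
WPL1_UNLOADING_SCALE = 0.1

#: default distance of a stalled fork from its early origin (bp);
#: midpoint of the 5-10 kb replicated cassette mapped under HU arrest
DEFAULT_FORK_DISTANCE_BP = 7500

#: RNA-pol-II fold enrichment painted on a transcribed gene body is
#: 1 + _POL2_FE_PER_EXPR * expression_level
_POL2_FE_PER_EXPR = 1.5
#: expression level stress-response genes are induced to under thiolutin
STRESS_INDUCED_EXPRESSION = 4.0
#: BrdU fold enrichment over replicated cassettes in HU conditions
_BRDU_PLATEAU_FE = 2.0

#: gene-barrier permeability = exp(-PERMEABILITY_DECAY * expression);
#: at expression 1 this is ~1.5e-3 per attempt, i.e. rarely crossed
#: within a wild-type residence but often crossed within the ~10x
#: longer residence of Wpl1-depleted extruders
PERMEABILITY_DECAY = 6.5


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    start: int
    end: int
    strand: str  # '+' or '-'
    expression_level: float = 1.0
    is_stress_gene: bool = False

    @property
    def three_prime_bp(self) -> int:
        """Last transcribed coordinate (0-based) at the 3' end."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class Origin:
    position: int
    is_early: bool = True


@dataclass
class GenomeAnnotation:
    """One synthetic chromosome with the features that shape extrusion."""

    chrom_length_bp: int
    bin_size_bp: int
    genes: list[Gene]
    origins: list[Origin]
    centromere_bp: int
    ltrs: list[tuple[int, int]] = field(default_factory=list)
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length_bp // self.bin_size_bp)

    @property
    def convergent_sites(self) -> list[int]:
        """Midpoints between the 3' ends of adjacent (+, -) gene pairs."""
        sites = []
        for a, b in zip(self.genes, self.genes[1:]):
            if a.strand == "+" and b.strand == "-":
                sites.append((a.three_prime_bp + b.three_prime_bp) // 2)
        return sites

    def bin_of(self, pos_bp: int) -> int:
        return pos_bp // self.bin_size_bp

    def validate(self) -> None:
        L = self.chrom_length_bp
        if not 0 <= self.centromere_bp < L:
            raise ValueError("centromere outside chromosome")
        prev_end = -1
        for g in self.genes:
            if not (0 <= g.start < g.end <= L):
                raise ValueError(f"gene ({g.start},{g.end}) outside chromosome")
            if g.start < prev_end:
                raise ValueError("genes must be sorted and non-overlapping")
            if g.strand not in "+-":
                raise ValueError(f"bad strand {g.strand!r}")
            if g.expression_level < 0:
                raise ValueError("expression_level must be >= 0")
            prev_end = g.end
        for o in self.origins:
            if not 0 <= o.position < L:
                raise ValueError("origin outside chromosome")
        for s, e in self.ltrs:
            if not 0 <= s < e <= L:
                raise ValueError("LTR outside chromosome")


def make_genome(
    n_genes: int,
    chrom_length_bp: int,
    seed: int,
    bin_size_bp: int = 2000,
    within_pair_gap_bp: int = 1000,
    expression_sigma: float = 0.4,
    expression_mu: float = 0.0,
    stress_fraction: float = 0.02,
    early_origin_fraction: float = 0.6,
) -> GenomeAnnotation:
    """Build a deterministic random genome of convergent gene pairs.

    Genes alternate orientation (+, -, +, -, ...) so every second
    junction is a convergent pair with a short intergenic gap; the
    remaining space is distributed over divergent gaps and telomeric
    margins.  Expression levels are log-normal (median 1); genes with
    expression >= 1 become absolute extrusion barriers in G2/M.
    Stress-response genes (a rare random subset, matching their
    scarcity among ORFs genome-wide) are given low basal expression,
    mimicking induction only under transcription stress.
    One centromere sits in the divergent gap nearest mid-chromosome and
    early origins occupy divergent gaps spaced roughly 30-60 kb apart.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if chrom_length_bp < n_genes * 2000:
        raise ValueError("chromosome too short to pack genes (need >= 2 kb per gene)")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(1500, 2500, size=n_genes)
    n_pairs = n_genes // 2
    n_conv_gaps = n_pairs  # gap inside each (+,-) pair
    n_div_slots = max(n_genes - 1 - n_conv_gaps, 0) + 2  # divergent gaps + margins
    spare = chrom_length_bp - int(lengths.sum()) - n_conv_gaps * within_pair_gap_bp
    if spare < n_div_slots * 400:
        raise ValueError("chromosome too short to pack genes with workable gaps")
    w = rng.uniform(0.7, 1.3, size=n_div_slots)
    div_gaps = np.floor(spare * w / w.sum()).astype(int)

    genes: list[Gene] = []
    div_gap_mids: list[int] = []
    pos = int(div_gaps[0])
    div_i = 1
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        expr = float(rng.lognormal(expression_mu, expression_sigma))
        is_stress = bool(rng.random() < stress_fraction)
        if is_stress:
            expr = float(rng.uniform(0.1, 0.5))  # basal, induced only on stress
        genes.append(Gene(pos, pos + int(lengths[i]), strand, expr, is_stress))
        pos += int(lengths[i])
        if i < n_genes - 1:
            if strand == "+":  # inside a convergent pair
                pos += within_pair_gap_bp
            else:  # divergent junction
                gap = int(div_gaps[div_i]) if div_i < len(div_gaps) else 1000
                div_gap_mids.append(pos + gap // 2)
                pos += gap
                div_i += 1
    if pos > chrom_length_bp:
        raise ValueError("gene packing overflowed the chromosome")

    if not div_gap_mids:
        div_gap_mids = [pos + (chrom_length_bp - pos) // 2]
    mids = np.asarray(div_gap_mids)
    centromere_bp = int(mids[np.argmin(np.abs(mids - chrom_length_bp // 2))])

    origins: list[Origin] = []
    last = -(10**9)
    for m in div_gap_mids:
        if m == centromere_bp:
            continue
        spacing = rng.uniform(28_000, 45_000)
        if m - last >= spacing:
            origins.append(Origin(int(m) + 200, bool(rng.random() < early_origin_fraction)))
            last = m

    ltrs: list[tuple[int, int]] = []
    for m in div_gap_mids[:: max(1, len(div_gap_mids) // max(1, chrom_length_bp // 50_000))]:
        s = int(m) - 900
        if s > 0 and rng.random() < 0.5:
            ltrs.append((s, s + 300))
    # keep LTRs clear of genes
    ltrs = [
        (s, e)
        for s, e in ltrs
        if all(e <= g.start or s >= g.end for g in genes)
    ]

    return GenomeAnnotation(
        chrom_length_bp=chrom_length_bp,
        bin_size_bp=bin_size_bp,
        genes=genes,
        origins=origins,
        centromere_bp=centromere_bp,
        ltrs=ltrs,
    )


# ---------------------------------------------------------------------------
# barriers
# ---------------------------------------------------------------------------

@dataclass
class Barrier:
    bin_index: int
    blocking_direction: str  # 'left', 'right', or 'both'
    permeability: float

    def blocks(self, direction: str) -> bool:
        return self.blocking_direction in (direction, "both")


@dataclass
class BarrierSet:
    barriers: list[Barrier]

    def pass_probabilities(self, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin entry probabilities for left- and right-moving legs.

        Co-located barriers compound multiplicatively.
        """
        p_left = np.ones(n_bins)
        p_right = np.ones(n_bins)
        for b in self.barriers:
            if not 0 <= b.bin_index < n_bins:
                raise ValueError("barrier outside genome")
            if b.blocks("left"):
                p_left[b.bin_index] *= b.permeability
            if b.blocks("right"):
                p_right[b.bin_index] *= b.permeability
        return p_left, p_right

    def absolute_bins(self, threshold: float = 0.005) -> list[int]:
        """Bins holding an (effectively) absolute barrier.

        Permeability at or below ``threshold`` is indistinguishable
        from an absolute block within one wild-type extruder residence
        time; 0.0 selects exact blocks only.
        """
        return sorted({b.bin_index for b in self.barriers if b.permeability <= threshold})


def derive_barriers(
    annotation: GenomeAnnotation,
    condition: str,
    fork_distance_bp: int = DEFAULT_FORK_DISTANCE_BP,
) -> BarrierSet:
    """Translate the annotation into condition-specific extrusion barriers.

    G2/M conditions place a directional barrier at every gene 3' end
    with permeability ``exp(-PERMEABILITY_DECAY * expression_level)``:
    strongly transcribed genes are near-absolute blocks (crossed
    rarely within a wild-type residence time, routinely by the
    long-lived extruders of Wpl1 depletion).  Thiolutin removes gene
    barriers except at induced stress-response genes, which gain
    absolute 3' barriers.  HU arrest adds absolute bidirectional
    barriers at the two stalled forks flanking each early origin.
    Scc2/Wpl1 depletion alters loading/unloading rates, not the
    barrier landscape.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    barriers: list[Barrier] = []
    for g in annotation.genes:
        direction = "left" if g.strand == "+" else "right"
        b = annotation.bin_of(g.three_prime_bp)
        if condition in _THIOLUTIN:
            if g.is_stress_gene:
                barriers.append(Barrier(b, direction, 0.0))
        else:
            perm = float(np.exp(-PERMEABILITY_DECAY * g.expression_level))
            barriers.append(Barrier(b, direction, perm))
    barriers.append(Barrier(annotation.bin_of(annotation.centromere_bp), "both", 0.0))
    if condition in _HU:
        for o in annotation.origins:
            if not o.is_early:
                continue
            for fork in (o.position - fork_distance_bp, o.position + fork_distance_bp):
                fb = min(max(fork, 0), annotation.chrom_length_bp - 1)
                barriers.append(Barrier(annotation.bin_of(fb), "both", 0.0))
    return BarrierSet(barriers)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of one loop-extrusion run.

    Rates are per time step on the bin lattice.  ``loading_rate`` is
    the probability that a vacant adjacent bin pair nucleates a new
    extruder per step; ``unloading_prob`` the per-extruder release
    probability per step (their ratio sets the steady-state extruder
    count, and 1/unloading_prob the mean residence time in steps).
    ``extruder_pool`` caps the number of concurrently bound extruders,
    modelling the finite cellular cohesin complement: prolonged
    residence (unloader depletion) then raises occupancy only until
    the pool is exhausted instead of ten-fold to lattice jamming.
    """

    condition: str = "WT_G2M"
    loading_rate: float = 0.0005
    unloading_prob: float = 0.02
    extruder_pool: int | None = 10
    extrusion_step: int = 1
    n_steps: int = 20_500
    burn_in_steps: int = 500
    snapshot_every: int = 5
    contact_background_exponent: float = 1.5
    background_weight: float = 0.7
    loop_bonus_weight: float = 0.01
    loop_bonus_range_bins: int = 5
    read_depth: int = 300_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.loading_rate < 0 or self.extrusion_step < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.unloading_prob <= 1.0:
            raise ValueError("unloading_prob must be a probability")
        if not 0.0 <= self.background_weight <= 1.0:
            raise ValueError("background_weight must be in [0,1]")
        if self.contact_background_exponent <= 0:
            raise ValueError("background exponent must be > 0")
        if self.burn_in_steps >= self.n_steps:
            raise ValueError("burn_in_steps must be < n_steps")

    @property
    def effective_loading_rate(self) -> float:
        scale = SCC2_LOADING_SCALE if self.condition in _SCC2 else 1.0
        return self.loading_rate * scale

    @property
    def effective_unloading_prob(self) -> float:
        scale = WPL1_UNLOADING_SCALE if self.condition in _WPL1 else 1.0
        return self.unloading_prob * scale


@dataclass
class ExtruderEnsemble:
    """Leg positions of all extruders at one recorded time step."""

    extruders: list[tuple[int, int]]
    time_step: int

    def check_invariants(self, n_bins: int) -> None:
        seen: set[int] = set()
        for l, r in self.extruders:
            if not (0 <= l <= r < n_bins):
                raise AssertionError("leg outside genome or disordered")
            for leg in (l, r):
                if leg in seen:
                    raise AssertionError("two legs occupy one bin (bypass)")
                seen.add(leg)


def simulate_extrusion(
    annotation: GenomeAnnotation,
    barriers: BarrierSet,
    config: SimulationConfig,
    initial_extruders: list[tuple[int, int]] | None = None,
) -> list[ExtruderEnsemble]:
    """Fixed-timestep kinetic Monte Carlo of two-sided loop extrusion.

    Per step: (1) each extruder unloads with probability
    ``unloading_prob``; (2) each leg attempts ``extrusion_step`` outward
    moves, each rejected if the target bin is occupied by another leg,
    off-chromosome, or holds a barrier blocking that direction (passed
    with probability = permeability); (3) every vacant adjacent bin
    pair loads a fresh two-bin extruder with probability
    ``loading_rate``.  Snapshots are recorded every ``snapshot_every``
    steps after burn-in.
    """
    n_bins = annotation.n_bins
    p_left, p_right = barriers.pass_probabilities(n_bins)
    load_p = config.effective_loading_rate
    unload_p = config.effective_unloading_prob
    rng = np.random.default_rng([config.seed, 0])

    occ = np.full(n_bins, -1, dtype=np.int64)
    ex: dict[int, list[int]] = {}
    next_id = 0
    for l, r in initial_extruders or []:
        if not (0 <= l <= r < n_bins) or occ[l] != -1 or occ[r] != -1:
            raise ValueError("invalid initial extruder placement")
        occ[l] = next_id
        occ[r] = next_id
        ex[next_id] = [int(l), int(r)]
        next_id += 1
    snapshots: list[ExtruderEnsemble] = []

    for t in range(config.n_steps):
        # unloading
        if ex and unload_p > 0:
            eids = sorted(ex)
            u = rng.random(len(eids))
            for eid, ui in zip(eids, u):
                if ui < unload_p:
                    l, r = ex.pop(eid)
                    occ[l] = -1
                    occ[r] = -1
        # movement
        for eid in sorted(ex):
            legs = ex[eid]
            for _ in range(config.extrusion_step):
                l = legs[0]
                tgt = l - 1
                if tgt >= 0 and occ[tgt] == -1:
                    p = p_left[tgt]
                    if p >= 1.0 or (p > 0.0 and rng.random() < p):
                        occ[l] = -1
                        occ[tgt] = eid
                        legs[0] = tgt
            for _ in range(config.extrusion_step):
                r = legs[1]
                tgt = r + 1
                if tgt < n_bins and occ[tgt] == -1:
                    p = p_right[tgt]
                    if p >= 1.0 or (p > 0.0 and rng.random() < p):
                        occ[r] = -1
                        occ[tgt] = eid
                        legs[1] = tgt
        # loading
        if load_p > 0:
            pool = config.extruder_pool
            draws = rng.random(n_bins - 1)
            for i in np.flatnonzero(draws < load_p):
                if pool is not None and len(ex) >= pool:
                    break
                if occ[i] == -1 and occ[i + 1] == -1:
                    occ[i] = next_id
                    occ[i + 1] = next_id
                    ex[next_id] = [int(i), int(i) + 1]
                    next_id += 1
        if t >= config.burn_in_steps and (t - config.burn_in_steps) % config.snapshot_every == 0:
            snapshots.append(
                ExtruderEnsemble(
                    extruders=sorted((int(l), int(r)) for l, r in ex.values()),
                    time_step=t,
                )
            )
    return snapshots


# ---------------------------------------------------------------------------
# rendering: contact maps and tracks
# ---------------------------------------------------------------------------

def _expected_contact_weights(
    snapshots: list[ExtruderEnsemble],
    n_bins: int,
    config: SimulationConfig,
) -> np.ndarray:
    """Expected (unnormalized) contact weight per pixel.

    background_weight * powerlaw(|i-j|) + (1-background_weight) *
    (leg-pair frequency + within-loop bonus).  The background is
    normalized to unit total mass; the extruder term is scaled by a
    *fixed* reference occupancy (the steady-state extruder count
    implied by the unscaled base rates), never by its own sum.  The
    extruder read share therefore tracks actual occupancy: loader
    depletion shrinks it towards pure background, unloader depletion
    grows it — sparser extrusion is not silently renormalized back to
    full strength.
    """
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    bg = (1.0 + dist) ** (-config.contact_background_exponent)
    bg /= bg.sum()
    # reference extruder mass: base-rate (condition-unscaled) steady state
    if config.unloading_prob > 0 and config.loading_rate > 0:
        ref_mass = config.loading_rate * (n_bins - 1) / config.unloading_prob
        if config.extruder_pool is not None:
            ref_mass = min(ref_mass, float(config.extruder_pool))
    else:
        ref_mass = 1.0

    n_snap = len(snapshots)
    freq = np.zeros((n_bins, n_bins))
    bonus_diag = np.zeros((config.loop_bonus_range_bins + 1, n_bins))
    for snap in snapshots:
        for l, r in snap.extruders:
            freq[l, r] += 1.0
            for d in range(1, min(config.loop_bonus_range_bins, r - l) + 1):
                bonus_diag[d, l] += 1.0
                if r - d + 1 < n_bins:
                    bonus_diag[d, r - d + 1] -= 1.0
    freq /= n_snap
    loops = freq + freq.T
    for d in range(1, bonus_diag.shape[0]):
        band = np.cumsum(bonus_diag[d])[: n_bins - d] / n_snap
        loops[idx[: n_bins - d], idx[: n_bins - d] + d] += config.loop_bonus_weight * band
        loops[idx[: n_bins - d] + d, idx[: n_bins - d]] += config.loop_bonus_weight * band
    w = config.background_weight
    return w * bg + (1.0 - w) * loops / ref_mass


def render_contact_map(
    snapshots: list[ExtruderEnsemble],
    annotation: GenomeAnnotation,
    config: SimulationConfig,
) -> ContactMatrix:
    """Sample a symmetric binned contact map from the simulated ensemble.

    ``read_depth`` read pairs are drawn multinomially over the unique
    (upper-triangle) pixels of the expected-weight matrix and mirrored,
    so the matrix sum follows the 2x-off-diagonal convention of binned
    pairs.  Bit-identical for identical config (including seed).
    """
    if not snapshots:
        raise RuntimeError("no post-burn-in snapshots to render")
    n_bins = annotation.n_bins
    weights = _expected_contact_weights(snapshots, n_bins, config)
    iu = np.triu_indices(n_bins)
    p = weights[iu]
    p = p / p.sum()
    rng = np.random.default_rng([config.seed, 1])
    counts = rng.multinomial(config.read_depth, p)
    m = np.zeros((n_bins, n_bins))
    m[iu] = counts
    m = m + np.triu(m, 1).T
    return ContactMatrix(
        chrom=annotation.chrom,
        bin_size_bp=annotation.bin_size_bp,
        counts=m,
        normalized=None,
        total_read_pairs=int(config.read_depth),
    )


def sample_pairs(matrix: ContactMatrix, seed: int) -> PairsTable:
    """Expand a raw binned matrix into unbinned pair records.

    Each binned contact becomes a record with positions uniform within
    its two bins — the pairs-level view of the same synthetic library,
    for P(s), cis/trans and anchored-count analyses.
    """
    rng = np.random.default_rng([seed, 2])
    iu = np.triu_indices(matrix.n_bins)
    counts = matrix.counts[iu].astype(np.int64)
    b1 = np.repeat(iu[0], counts)
    b2 = np.repeat(iu[1], counts)
    size = matrix.bin_size_bp
    pos1 = b1 * size + rng.integers(0, size, size=b1.size)
    pos2 = b2 * size + rng.integers(0, size, size=b2.size)
    lo = np.minimum(pos1, pos2)
    hi = np.maximum(pos1, pos2)
    rec = pd.DataFrame(
        {"chrom1": matrix.chrom, "pos1": lo, "chrom2": matrix.chrom, "pos2": hi}
    )
    return PairsTable(rec)


def render_tracks(
    snapshots: list[ExtruderEnsemble],
    annotation: GenomeAnnotation,
    condition: str,
    fork_distance_bp: int = DEFAULT_FORK_DISTANCE_BP,
) -> dict[str, FoldEnrichmentTrack]:
    """Cohesin, RNA-pol-II and BrdU fold-enrichment tracks.

    Cohesin: time-averaged leg occupancy scaled to genome mean 1.0
    (peaks co-locate with convergent gene pairs and other barriers).
    RNA pol II: expression painted over gene bodies on a background of
    1.0; under thiolutin non-stress genes fall to background while
    stress genes are induced.  BrdU: plateau of fold enrichment over
    origin +/- fork_distance for early origins in HU conditions, else
    flat 1.0.
    """
    if not snapshots:
        raise RuntimeError("no snapshots to render tracks from")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n_bins = annotation.n_bins
    size = annotation.bin_size_bp

    occ = leg_occupancy(snapshots, n_bins)
    mean_occ = occ.mean()
    cohesin = occ / mean_occ if mean_occ > 0 else occ

    pol2 = np.ones(n_bins)
    for g in annotation.genes:
        if condition in _THIOLUTIN:
            expr = STRESS_INDUCED_EXPRESSION if g.is_stress_gene else 0.0
        else:
            expr = g.expression_level
        b0, b1 = g.start // size, (g.end - 1) // size
        pol2[b0 : b1 + 1] = np.maximum(pol2[b0 : b1 + 1], 1.0 + _POL2_FE_PER_EXPR * expr)

    brdu = np.ones(n_bins)
    if condition in _HU:
        for o in annotation.origins:
            if not o.is_early:
                continue
            lo = max(o.position - fork_distance_bp, 0) // size
            hi = min(o.position + fork_distance_bp, annotation.chrom_length_bp - 1) // size
            brdu[lo : hi + 1] = _BRDU_PLATEAU_FE

    def track(name: str, values: np.ndarray) -> FoldEnrichmentTrack:
        return FoldEnrichmentTrack(
            chrom=annotation.chrom, bin_size_bp=size, values=values, sample_name=name
        )

    return {
        "cohesin": track(f"Scc1_{condition}", cohesin),
        "rna_pol2": track(f"Rpo21_{condition}", pol2),
        "brdu": track(f"BrdU_{condition}", brdu),
    }


def leg_occupancy(snapshots: list[ExtruderEnsemble], n_bins: int) -> np.ndarray:
    """Mean number of extruder legs per bin per snapshot.

    The absolute occupancy underlying the cohesin fold-enrichment
    track; usable as ground truth for qPCR-style absolute anchoring of
    between-sample scaling factors.
    """
    occ = np.zeros(n_bins)
    for snap in snapshots:
        for l, r in snap.extruders:
            occ[l] += 1.0
            occ[r] += 1.0
    return occ / max(len(snapshots), 1)


def mean_loop_length(snapshots: list[ExtruderEnsemble], bin_size_bp: int) -> float:
    """Mean extruded-loop length in bp over all snapshot extruders."""
    lens = [
        (r - l) * bin_size_bp
        for snap in snapshots
        for l, r in snap.extruders
    ]
    return float(np.mean(lens)) if lens else 0.0


def mean_extruder_count(snapshots: list[ExtruderEnsemble]) -> float:
    """Mean number of bound extruders per snapshot."""
    if not snapshots:
        return 0.0
    return float(np.mean([len(s.extruders) for s in snapshots]))
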