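"""Pile-up and boundary-strength metrics.

Insulation scores (square window, mean-normalized), aggregate peak
analysis (APA) with the central-11x11-over-corner strength statistic,
distance-stratified APA, on-diagonal centromere pile-ups, and averaged
ChIP meta-profiles with confidence bands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact_map import ContactMatrix
from .feature_calling import FoldEnrichmentTrack

logger = logging.getLogger("extrudex")

DEFAULT_WINDOW_BP = 40_000
APA_CENTRAL = 11  # side of the central and corner squares


# ---------------------------------------------------------------------------
# insulation
# ---------------------------------------------------------------------------

@dataclass
class InsulationTrack:
    """Per-bin insulation scores for one chromosome.

    The raw score of bin i totals the contacts formed *across* i by
    locus pairs up to ``window_bp`` away on either side (pair
    separation capped at the window).  Normalized scores divide by the
    mean over valid bins, so boundaries appear as local minima around a
    genome average of 1.
    """

    bin_size_bp: int
    window_bp: int
    raw_scores: np.ndarray
    normalized_scores: np.ndarray
    valid_mask: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.raw_scores.size


def insulation_score(
    matrix: ContactMatrix, window_bp: int = DEFAULT_WINDOW_BP
) -> InsulationTrack:
    """Square-window insulation score of a normalized contact matrix.

    raw[i] = sum of M[a, b] over a in [i-w, i-1], b in [i+1, i+w] with
    b - a <= w (w = window in bins).  Bins within one window of either
    chromosome end are masked invalid; normalization is by the mean
    raw score over valid bins.
    """
    m = matrix.counts
    n = m.shape[0]
    w = window_bp // matrix.bin_size_bp
    raw = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if n < 2 * w + 1:
        warnings.warn("chromosome shorter than twice the insulation window")
        return InsulationTrack(matrix.bin_size_bp, window_bp, raw, raw.copy(), valid)
    offs_a = np.arange(-w, 0)
    offs_b = np.arange(1, w + 1)
    sep_ok = (offs_b[None, :] - offs_a[:, None]) <= w
    for i in range(w, n - w):
        sub = m[np.ix_(i + offs_a, i + offs_b)]
        raw[i] = np.nansum(np.where(sep_ok, sub, 0.0))
        valid[i] = True
    mean = np.nanmean(raw[valid])
    norm = raw / mean if mean > 0 else raw.copy()
    return InsulationTrack(matrix.bin_size_bp, window_bp, raw, norm, valid)


def local_minima(track: InsulationTrack, percentile: float | None = None) -> np.ndarray:
    """Bins that are strict-or-flat local minima of the normalized score.

    With ``percentile`` given, keep only minima deeper than that
    percentile of valid normalized scores (e.g. 10 keeps only minima in
    the lowest decile), the convention used for boundary calls.
    """
    s = track.normalized_scores
    n = s.size
    cand = []
    for i in range(n):
        if not track.valid_mask[i]:
            continue
        left = s[i - 1] if i > 0 and track.valid_mask[i - 1] else np.inf
        right = s[i + 1] if i + 1 < n and track.valid_mask[i + 1] else np.inf
        if s[i] <= left and s[i] <= right:
            cand.append(i)
    cand = np.asarray(cand, dtype=np.intp)
    if percentile is not None and cand.size:
        thr = np.nanpercentile(s[track.valid_mask], percentile)
        cand = cand[s[cand] <= thr]
    return cand


def average_insulation(
    track: InsulationTrack,
    anchor_sites_bp: list[int],
    flank_bp: int = 20_000,
    seed: int = 0,
    with_control: bool = True,
) -> pd.DataFrame:
    """Mean insulation profile over windows centered at anchor sites.

    Anchors whose full window leaves the valid region are dropped (and
    logged).  A random-site control profile with the same number of
    sites is generated from the given seed.  Returns a DataFrame with
    offset_bp, mean, and (optionally) control_mean columns.
    """
    if not anchor_sites_bp:
        raise ValueError("need at least one anchor site")
    f = flank_bp // track.bin_size_bp
    valid_bins = np.flatnonzero(track.valid_mask)

    def collect(centers: list[int]) -> np.ndarray:
        rows = []
        for c in centers:
            b = c // track.bin_size_bp
            if b - f < 0 or b + f >= track.n_bins or not track.valid_mask[b - f] or not track.valid_mask[b + f]:
                logger.info("anchor at %d bp dropped (outside valid region)", c)
                continue
            rows.append(track.normalized_scores[b - f : b + f + 1])
        if not rows:
            raise ValueError("no anchor window lies fully inside the valid region")
        return np.nanmean(np.asarray(rows), axis=0)

    offsets = (np.arange(-f, f + 1)) * track.bin_size_bp
    out = pd.DataFrame({"offset_bp": offsets, "mean": collect(list(anchor_sites_bp))})
    if with_control:
        rng = np.random.default_rng(seed)
        lo, hi = valid_bins[0] + f, valid_bins[-1] - f
        ctrl = (rng.integers(lo, hi + 1, size=len(anchor_sites_bp)) * track.bin_size_bp).tolist()
        out["control_mean"] = collect(ctrl)
    return out


# ---------------------------------------------------------------------------
# aggregate peak analysis
# ---------------------------------------------------------------------------

@dataclass
class ApaResult:
    """Summed pile-up around a list of locus pairs and its loop strength.

    ``strength`` = sum of the central 11x11 square / sum of the
    top-right 11x11 corner of the (2w+1)^2 aggregate — central
    enrichment against a longer-distance background.
    """

    aggregate: np.ndarray
    n_pairs_used: int
    n_pairs_skipped: int
    strength: float


def _apa_strength(aggregate: np.ndarray, central: int = APA_CENTRAL) -> float:
    n = aggregate.shape[0]
    c = n // 2
    h = central // 2
    center = np.nansum(aggregate[c - h : c + h + 1, c - h : c + h + 1])
    corner = np.nansum(aggregate[:central, -central:])
    return float(center / corner) if corner > 0 else float("nan")


def apa(
    matrix: ContactMatrix,
    locus_pairs: list[tuple[int, int]],
    w: int = 20,
    central: int = APA_CENTRAL,
) -> ApaResult:
    """Aggregate peak analysis: sum of (2w+1)^2 submatrices centered at
    each upstream<downstream bin pair.

    Pairs whose submatrix leaves the matrix or that sit within w bins
    of the diagonal are skipped and counted.  Missing (NaN) pixels
    contribute zero to the aggregate.  ``central`` sets the side of
    the central and corner squares of the strength ratio (11 with the
    standard w=20 window; choose ~(2w+1)/4 for smaller windows).
    """
    if central >= 2 * w + 1:
        raise ValueError("central square must be smaller than the window")
    m = matrix.counts
    n = m.shape[0]
    agg = np.zeros((2 * w + 1, 2 * w + 1))
    used = skipped = 0
    for i, j in locus_pairs:
        if i > j:
            i, j = j, i
        if i - w < 0 or j + w >= n or (j - i) <= w:
            skipped += 1
            continue
        agg += np.nan_to_num(m[i - w : i + w + 1, j - w : j + w + 1])
        used += 1
    if used == 0:
        raise ValueError("no usable locus pairs for APA (all skipped)")
    return ApaResult(agg, used, skipped, _apa_strength(agg, central))


def apa_by_distance(
    matrix: ContactMatrix,
    sites_a: list[int],
    sites_b: list[int],
    distance_classes_bp: list[tuple[int, int]],
    w: int = 20,
    central: int = APA_CENTRAL,
) -> list[ApaResult | None]:
    """APA stratified by pair separation.

    All cross pairs between the two site lists (bin units, deduplicated
    after ordering) are assigned to half-open bp distance classes; one
    ApaResult per class, or None for classes with no usable pair.
    """
    for (lo1, hi1), (lo2, hi2) in zip(distance_classes_bp, distance_classes_bp[1:]):
        if hi1 > lo2:
            raise ValueError("distance classes must be disjoint, sorted half-open ranges")
    pairs = {
        (min(a, b), max(a, b))
        for a in sites_a
        for b in sites_b
        if a != b
    }
    out: list[ApaResult | None] = []
    for lo, hi in distance_classes_bp:
        cls = [
            p
            for p in sorted(pairs)
            if lo <= (p[1] - p[0]) * matrix.bin_size_bp < hi
        ]
        if not cls:
            out.append(None)
            continue
        try:
            out.append(apa(matrix, cls, w=w, central=central))
        except ValueError:
            out.append(None)
    return out


def pileup_centromeres(
    matrix: ContactMatrix, centromere_bins: list[int], w: int
) -> np.ndarray:
    """Sum of on-diagonal (2w+1)^2 submatrices centered at centromeres."""
    m = matrix.counts
    n = m.shape[0]
    agg = np.zeros((2 * w + 1, 2 * w + 1))
    used = 0
    for c in centromere_bins:
        if c - w < 0 or c + w >= n:
            logger.info("centromere bin %d skipped (margin)", c)
            continue
        agg += np.nan_to_num(m[c - w : c + w + 1, c - w : c + w + 1])
        used += 1
    if used == 0:
        raise ValueError("no usable centromere for pile-up")
    return agg


def cross_insulation_contrast(aggregate: np.ndarray) -> float:
    """Arm-versus-cross contrast of a centromere pile-up.

    Ratio of mean signal in the two on-diagonal arm quadrants to mean
    signal in the off-diagonal (cross-centromere) quadrants; > 1 means
    the centromere insulates its two flanks from each other.
    """
    n = aggregate.shape[0]
    c = n // 2
    q_arm = np.concatenate(
        [aggregate[:c, :c].ravel(), aggregate[c + 1 :, c + 1 :].ravel()]
    )
    q_cross = np.concatenate(
        [aggregate[:c, c + 1 :].ravel(), aggregate[c + 1 :, :c].ravel()]
    )
    return float(np.nanmean(q_arm) / np.nanmean(q_cross))


# ---------------------------------------------------------------------------
# ChIP meta-profiles
# ---------------------------------------------------------------------------

def meta_profile(
    track: FoldEnrichmentTrack, sites_bp: list[int], flank_bp: int
) -> pd.DataFrame:
    """Averaged fold-enrichment profile around a list of sites.

    Returns offset_bp, mean, and a normal-approximation 95% confidence
    band (mean +/- 1.96 SE across sites).  With a single usable site
    the band is NaN.  Sites too close to either chromosome end are
    dropped.
    """
    f = flank_bp // track.bin_size_bp
    rows = []
    for s in sites_bp:
        b = s // track.bin_size_bp
        if b - f < 0 or b + f >= track.n_bins:
            logger.info("site at %d bp dropped from meta-profile (edge)", s)
            continue
        rows.append(track.values[b - f : b + f + 1])
    if not rows:
        raise ValueError("no usable sites for meta-profile")
    arr = np.asarray(rows)
    mean = arr.mean(axis=0)
    if arr.shape[0] >= 2:
        se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        lo, hi = mean - 1.96 * se, mean + 1.96 * se
    else:
        lo = hi = np.full_like(mean, np.nan)
    offsets = np.arange(-f, f + 1) * track.bin_size_bp
    return pd.DataFrame(
        {"offset_bp": offsets, "mean": mean, "ci_low": lo, "ci_high": hi}
    )
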