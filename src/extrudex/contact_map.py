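"""Contact-record and contact-matrix primitives.

Unbinned Hi-C contact records (pairs), binned cis contact matrices,
coverage-sqrt normalization, log2 ratio maps, contact-probability-vs-distance
curves, cis/trans and feature-anchored interaction counts, and the exact
binomial comparison used for depth-matched count contrasts.

Coordinates are 0-based, half-open throughout (BED convention).  Bin ``k``
covers ``[k * bin_size, (k + 1) * bin_size)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("extrudex")

PAIRS_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PairsTable:
    """Unbinned contact records (cis and trans).

    ``records`` is a DataFrame with columns chrom1, pos1, chrom2, pos2,
    canonicalized so that chrom1 <= chrom2 and, within a chromosome,
    pos1 <= pos2.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = canonicalize_pairs(self.records)

    @property
    def total_pairs(self) -> int:
        return len(self.records)

    def cis_mask(self) -> np.ndarray:
        r = self.records
        return (r["chrom1"] == r["chrom2"]).to_numpy()


def canonicalize_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Order each record so chrom1 <= chrom2 and pos1 <= pos2 within a chrom."""
    r = records.reset_index(drop=True).copy()
    if len(r) == 0:
        return pd.DataFrame(columns=PAIRS_COLUMNS)
    if (r[["pos1", "pos2"]].to_numpy() < 0).any():
        raise ValueError("pair positions must be >= 0")
    c1, c2 = r["chrom1"].astype(str), r["chrom2"].astype(str)
    flip = (c1 > c2) | ((c1 == c2) & (r["pos1"] > r["pos2"]))
    if flip.any():
        f = flip.to_numpy()
        r.loc[f, ["chrom1", "pos1", "chrom2", "pos2"]] = r.loc[
            f, ["chrom2", "pos2", "chrom1", "pos1"]
        ].to_numpy()
    r["pos1"] = r["pos1"].astype(np.int64)
    r["pos2"] = r["pos2"].astype(np.int64)
    return r[PAIRS_COLUMNS]


@dataclass
class ContactMatrix:
    """Symmetric binned cis-contact matrix for one chromosome.

    ``normalized`` is None for raw counts, else the name of the
    normalization applied (e.g. ``"VC_SQRT"``).  ``total_read_pairs``
    carries the sequencing depth the matrix derives from, used for
    Poisson depth scaling in the loop caller.
    """

    chrom: str
    bin_size_bp: int
    counts: np.ndarray
    normalized: str | None = None
    total_read_pairs: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contact matrix must be square")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.counts, initial=0.0) < 0:
                raise ValueError("contact matrix entries must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class AnchoredCount:
    """Feature-anchored cis-interaction count, depth-normalized per million."""

    feature_set_name: str
    count: int
    count_per_million: float
    min_separation_bp: int
    total_pairs: int = 0


# ---------------------------------------------------------------------------
# resampling and binning
# ---------------------------------------------------------------------------

def downsample_pairs(pairs: PairsTable, n_target: int, seed: int) -> PairsTable:
    """Uniform sample of exactly ``n_target`` records without replacement.

    Emulates depth-matching libraries by resampling to the depth of the
    shallowest sample.  Deterministic for a fixed seed.
    """
    if n_target > pairs.total_pairs:
        raise ValueError(
            f"n_target={n_target} exceeds table size {pairs.total_pairs}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(pairs.total_pairs, size=n_target, replace=False)
    idx.sort()
    return PairsTable(pairs.records.iloc[idx].reset_index(drop=True))


def bin_pairs(
    pairs: PairsTable,
    chrom: str,
    bin_size_bp: int,
    chrom_length_bp: int | None = None,
    total_read_pairs: int | None = None,
) -> ContactMatrix:
    """Bin the cis records of one chromosome into a symmetric matrix.

    Bin index is ``floor(pos / bin_size_bp)`` (0-based half-open bins).
    Off-diagonal pairs are mirrored into both triangles, so the matrix sum
    equals 2 x (off-diagonal pairs) + (diagonal pairs).
    """
    if bin_size_bp <= 0:
        raise ValueError("bin_size_bp must be positive")
    r = pairs.records
    sel = r[(r["chrom1"] == chrom) & (r["chrom2"] == chrom)]
    if chrom_length_bp is None:
        top = int(sel[["pos1", "pos2"]].to_numpy().max()) + 1 if len(sel) else bin_size_bp
        chrom_length_bp = top
    n_bins = int(np.ceil(chrom_length_bp / bin_size_bp))
    b1 = (sel["pos1"].to_numpy() // bin_size_bp).astype(np.intp)
    b2 = (sel["pos2"].to_numpy() // bin_size_bp).astype(np.intp)
    m = np.zeros((n_bins, n_bins))
    np.add.at(m, (b1, b2), 1.0)
    np.add.at(m, (b2, b1), (b1 != b2).astype(float))
    return ContactMatrix(
        chrom=chrom,
        bin_size_bp=bin_size_bp,
        counts=m,
        normalized=None,
        total_read_pairs=int(len(sel) if total_read_pairs is None else total_read_pairs),
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def vc_sqrt_normalize(matrix: ContactMatrix, iterations: int = 1) -> ContactMatrix:
    """Coverage (sqrt) normalization: N[i,j] = M[i,j] / sqrt(r_i * r_j).

    ``r_i`` is the row sum (per-bin coverage).  Bins with zero coverage
    yield NaN rows/columns rather than division errors.  A single pass
    (the Hi-C tool convention, and the default) removes most of a
    multiplicative per-bin coverage bias on diagonal-dominant contact
    matrices; each pass halves the bias on the log scale, so the
    operator's fixed point (``iterations`` large, ~20) removes a
    planted rank-1 bias exactly.
    """
    m = matrix.counts
    if np.all(np.nan_to_num(m) == 0):
        warnings.warn("all-zero contact matrix: normalization yields all-NaN")
    for _ in range(iterations):
        r = np.nansum(m, axis=1)
        denom = np.sqrt(np.outer(r, r))
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(denom > 0, m / denom, np.nan)
    return replace(matrix, counts=m, normalized="VC_SQRT")


def ratio_map(
    a: ContactMatrix, b: ContactMatrix, pseudocount: float | None = None
) -> np.ndarray:
    """Per-pixel log2 ratio map between two depth-matched normalized maps.

    ``pseudocount`` defaults to the mean pixel mass of the two matrices
    (total normalized mass / number of pixels), a scale-free regulariser.
    """
    if a.counts.shape != b.counts.shape or a.bin_size_bp != b.bin_size_bp:
        raise ValueError("ratio_map requires same-shape, same-bin-size matrices")
    if pseudocount is None:
        pseudocount = float(
            (np.nansum(a.counts) + np.nansum(b.counts)) / (2 * a.counts.size)
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2((a.counts + pseudocount) / (b.counts + pseudocount))


# ---------------------------------------------------------------------------
# distance and cis/trans quantification
# ---------------------------------------------------------------------------

def contact_probability(
    pairs: PairsTable, chrom: str | None = None, bin_width_bp: int = 1000
) -> pd.DataFrame:
    """Contact probability P(s) versus genomic distance at 1-kb steps.

    Cis pairs are binned by separation into ``bin_width_bp`` classes;
    probability = count / total used pairs / bin width (in units of the
    width), so the curve integrates to 1 over the covered range.  Pairs
    closer than one distance bin (including same-bin diagonal pairs) are
    excluded: distance zero is undefined at 1-kb steps.

    Returns a DataFrame with columns distance_bp (bin left edge) and
    probability.
    """
    r = pairs.records
    cis = r[r["chrom1"] == r["chrom2"]]
    if chrom is not None:
        cis = cis[cis["chrom1"] == chrom]
    sep = (cis["pos2"] - cis["pos1"]).to_numpy()
    sep = sep[sep >= bin_width_bp]
    if sep.size == 0:
        return pd.DataFrame(columns=["distance_bp", "probability"])
    d = (sep // bin_width_bp).astype(np.intp)
    counts = np.bincount(d)
    dist = np.arange(len(counts)) * bin_width_bp
    prob = counts / sep.size / (bin_width_bp / 1000.0)  # per kb
    keep = counts > 0
    return pd.DataFrame({"distance_bp": dist[keep], "probability": prob[keep]})


def cis_trans_counts(pairs: PairsTable) -> tuple[float, float]:
    """Cis and trans pair counts per million total mapped pairs."""
    if pairs.total_pairs == 0:
        warnings.warn("empty pairs table: cis/trans counts are zero")
        return 0.0, 0.0
    cis = int(pairs.cis_mask().sum())
    trans = pairs.total_pairs - cis
    scale = 1e6 / pairs.total_pairs
    return cis * scale, trans * scale


def _overlaps_any(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """True where pos falls inside any half-open [start, end) interval."""
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    # merge to disjoint intervals so searchsorted parity works
    ms, me = [], []
    for s, e in zip(starts, ends):
        if me and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    ms_a, me_a = np.asarray(ms), np.asarray(me)
    idx = np.searchsorted(ms_a, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.shape, dtype=bool)
    out[ok] = pos[ok] < me_a[idx[ok]]
    return out


def anchored_cis_counts(
    pairs: PairsTable,
    features: list[tuple[int, int]] | np.ndarray,
    min_separation_bp: int = 10000,
    feature_set_name: str = "features",
    chrom: str | None = None,
) -> AnchoredCount:
    """Count cis pairs (separation strictly > ``min_separation_bp``) with
    either or both ends inside a feature interval; a pair is counted once.

    Reported both raw and per million total mapped pairs.
    """
    feats = np.asarray(features, dtype=np.int64)
    if feats.size == 0:
        raise ValueError("feature list must be non-empty")
    r = pairs.records
    cis = r[r["chrom1"] == r["chrom2"]]
    if chrom is not None:
        cis = cis[cis["chrom1"] == chrom]
    p1 = cis["pos1"].to_numpy()
    p2 = cis["pos2"].to_numpy()
    far = (p2 - p1) > min_separation_bp
    hit = _overlaps_any(p1, feats[:, 0], feats[:, 1]) | _overlaps_any(
        p2, feats[:, 0], feats[:, 1]
    )
    count = int((far & hit).sum())
    cpm = count / pairs.total_pairs * 1e6 if pairs.total_pairs else 0.0
    return AnchoredCount(
        feature_set_name=feature_set_name,
        count=count,
        count_per_million=cpm,
        min_separation_bp=min_separation_bp,
        total_pairs=pairs.total_pairs,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def binomial_compare(
    count_a: int, count_b: int, expected_fraction: float = 0.5
) -> float:
    """Two-sided exact binomial p-value for count_a successes out of
    count_a + count_b trials at ``expected_fraction``.

    The standard test for comparing depth-matched count pairs (loop
    numbers, anchored interactions) between two conditions.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    n = count_a + count_b
    if n == 0:
        raise ValueError("count_a + count_b must be positive")
    return float(stats.binomtest(count_a, n, expected_fraction).pvalue)
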