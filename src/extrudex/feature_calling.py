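"""Feature classification from ChIP-seq fold-enrichment tracks.

Implements the thresholded rules used to define the study's feature
sets: Scc1 (cohesin) peaks and arm sites, thiolutin-induced
stress-response genes, early-firing replication origins from BrdU
incorporation, and between-sample scaling (qPCR-anchored ChIP-seq
factors and spike-in RNA-seq factors).

All tracks are per-bin fold enrichment (ChIP / input).  Intervals are
0-based half-open; overlap means sharing at least one base pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("extrudex")


@dataclass
class FoldEnrichmentTrack:
    """Per-bin ChIP/input ratio for one sample on one chromosome."""

    chrom: str
    bin_size_bp: int
    values: np.ndarray
    sample_name: str = ""
    scaling_factor: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fold-enrichment values must be finite")
        if (self.values < 0).any():
            raise ValueError("fold-enrichment values must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def scaled(self) -> np.ndarray:
        return self.values * self.scaling_factor

    def mean_over(self, start_bp: int, end_bp: int) -> float:
        """Overlap-length-weighted mean fold enrichment over [start, end)."""
        size = self.bin_size_bp
        b0 = start_bp // size
        b1 = (end_bp - 1) // size
        b1 = min(b1, self.n_bins - 1)
        if b1 < b0:
            return float("nan")
        weights = []
        for b in range(b0, b1 + 1):
            lo = max(start_bp, b * size)
            hi = min(end_bp, (b + 1) * size)
            weights.append(hi - lo)
        w = np.asarray(weights, dtype=float)
        return float(np.average(self.values[b0 : b1 + 1], weights=w))


@dataclass
class FeatureCallConfig:
    """All classification thresholds in one place.

    peak_fe_threshold: minimal ChIP/input enrichment for an Scc1 peak bin.
    stress_fe_high/low: Rpo21 enrichment bounds (treated / control) for
        stress-response genes.
    deg_fdr: RNA-seq differential-expression FDR cut consumed as a flag.
    brdu_fe_threshold: BrdU enrichment defining fired (early) origins.
    pericentromere_halfwidth_bp: half of the 25-kb span excluded around
        each centromere when defining arm features.
    """

    peak_fe_threshold: float = 2.0
    stress_fe_high: float = 4.0
    stress_fe_low: float = 2.0
    deg_fdr: float = 1e-5
    brdu_fe_threshold: float = 1.5
    pericentromere_halfwidth_bp: int = 12_500

    def __post_init__(self) -> None:
        if not self.stress_fe_high > self.stress_fe_low > 0:
            raise ValueError("require stress_fe_high > stress_fe_low > 0")
        if self.peak_fe_threshold <= 0 or self.brdu_fe_threshold <= 0:
            raise ValueError("thresholds must be > 0")


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def call_peaks(
    track: FoldEnrichmentTrack,
    threshold: float = 2.0,
    exclusions: list[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Peaks = maximal runs of consecutive bins with FE > threshold.

    Any peak overlapping an exclusion interval (e.g. LTRs) by >= 1 bp
    is dropped.  Returns bp intervals (0-based half-open).
    """
    above = track.values > threshold
    size = track.bin_size_bp
    peaks: list[tuple[int, int]] = []
    i = 0
    n = track.n_bins
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            peaks.append((i * size, (j + 1) * size))
            i = j + 1
        else:
            i += 1
    if exclusions:
        peaks = [p for p in peaks if not any(_intervals_overlap(p, x) for x in exclusions)]
    return peaks


def arm_sites(
    peaks: list[tuple[int, int]],
    centromere_bp: int,
    halfwidth_bp: int = 12_500,
) -> list[tuple[int, int]]:
    """Drop peaks overlapping the pericentromeric span (cen +/- halfwidth)."""
    peri = (centromere_bp - halfwidth_bp, centromere_bp + halfwidth_bp)
    return [p for p in peaks if not _intervals_overlap(p, peri)]


def classify_stress_genes(
    rpo21_treated: FoldEnrichmentTrack,
    rpo21_control: FoldEnrichmentTrack,
    genes: list[tuple[int, int]],
    deg_up_flags: list[bool],
    config: FeatureCallConfig | None = None,
) -> list[int]:
    """Indices of genes classified as induced stress-response genes.

    A gene passes iff its ORF-mean RNA-pol-II enrichment is above
    ``stress_fe_high`` under treatment AND below ``stress_fe_low`` in
    the control AND it carries the up-regulated differential-expression
    flag — a strict conjunction of all three rules.
    """
    cfg = config or FeatureCallConfig()
    if len(genes) != len(deg_up_flags):
        raise ValueError("genes and deg_up_flags must align")
    if rpo21_treated.bin_size_bp != rpo21_control.bin_size_bp:
        raise ValueError("treated and control tracks must share binning")
    out = []
    for i, ((start, end), up) in enumerate(zip(genes, deg_up_flags)):
        t = rpo21_treated.mean_over(start, end)
        c = rpo21_control.mean_over(start, end)
        if t > cfg.stress_fe_high and c < cfg.stress_fe_low and up:
            out.append(i)
    return out


def call_early_origins(
    origins: list[int],
    brdu_track: FoldEnrichmentTrack,
    threshold: float = 1.5,
    centromere_bp: int | None = None,
    halfwidth_bp: int = 12_500,
) -> list[int]:
    """Indices of origins overlapping a BrdU-incorporation peak (FE > threshold).

    With ``centromere_bp`` given, pericentromeric origins are removed
    (the chromosome-arm variant of the rule).
    """
    peaks = call_peaks(brdu_track, threshold, exclusions=None)
    out = []
    for i, pos in enumerate(origins):
        if centromere_bp is not None and abs(pos - centromere_bp) <= halfwidth_bp:
            continue
        if any(s <= pos < e for s, e in peaks):
            out.append(i)
    return out


def chip_scaling_factors(
    qpcr_table: pd.DataFrame,
    chip_table: pd.DataFrame,
    reference_sample: str,
) -> dict[str, float]:
    """Per-sample ChIP-seq scaling factors anchored to qPCR enrichment.

    Both tables are sample-by-site (rows = samples, columns = common
    qPCR anchor sites).  For each sample the factor is the mean over
    sites of (qPCR ratio to reference) / (ChIP-seq track ratio to
    reference), so that factor-scaled tracks reproduce the qPCR
    relative levels; the reference's factor is 1 by construction.
    Sites with a zero denominator are dropped; fewer than 4 usable
    sites triggers a warning but not an error.
    """
    if reference_sample not in qpcr_table.index:
        raise ValueError(f"reference sample {reference_sample!r} missing from qPCR table")
    common = [c for c in qpcr_table.columns if c in chip_table.columns]
    factors: dict[str, float] = {}
    for sample in qpcr_table.index:
        ratios = []
        for site in common:
            q_ref = qpcr_table.loc[reference_sample, site]
            c_ref = chip_table.loc[reference_sample, site]
            q = qpcr_table.loc[sample, site]
            c = chip_table.loc[sample, site]
            if q_ref == 0 or c == 0 or c_ref == 0:
                continue
            ratios.append((q / q_ref) / (c / c_ref))
        if len(ratios) < 4:
            warnings.warn(
                f"only {len(ratios)} usable qPCR sites for {sample!r} (recommend 4-7)"
            )
        if not ratios:
            raise ValueError(f"no usable qPCR anchor sites for sample {sample!r}")
        factors[sample] = float(np.mean(ratios))
    return factors


def rna_spikein_scale(sample_spike_reads: int, reference_spike_reads: int) -> float:
    """Spike-in RNA-seq scaling factor (equal spike-in input assumed).

    Expression values are multiplied by reference_spike_reads /
    sample_spike_reads, equalizing spike-derived totals across samples.
    """
    if sample_spike_reads <= 0 or reference_spike_reads <= 0:
        raise ValueError("spike-in read counts must be positive")
    return reference_spike_reads / sample_spike_reads
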