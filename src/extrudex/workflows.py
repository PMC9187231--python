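"""Condition-panel workflows: the end-to-end comparisons the analysis
stack exists for.

``condition_panel`` simulates one genome under several experimental
presets, renders contact maps and ChIP-style tracks, derives
per-condition cohesin anchor sites the way the study does — scale the
fold-enrichment tracks onto a common absolute level with qPCR-anchored
factors, then threshold — and counts cohesin-anchored loop calls plus
long-range contact fractions.  Used by the acceptance checks and as a
template for users running the full analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic_data as syn
from .contact_map import PairsTable, anchored_cis_counts, vc_sqrt_normalize, ContactMatrix
from .feature_calling import FoldEnrichmentTrack, call_peaks, chip_scaling_factors
from .loop_domain_calling import call_loops, filter_by_anchors


@dataclass
class ConditionResult:
    condition: str
    raw: ContactMatrix
    norm: ContactMatrix
    tracks: dict[str, FoldEnrichmentTrack]
    occupancy: np.ndarray
    pairs: PairsTable
    mean_extruders: float
    mean_loop_bp: float


def simulate_condition(
    annotation: syn.GenomeAnnotation,
    condition: str,
    seed: int,
    **config_overrides,
) -> ConditionResult:
    """Simulate one condition and render every derived object."""
    barriers = syn.derive_barriers(annotation, condition)
    cfg = syn.SimulationConfig(condition=condition, seed=seed, **config_overrides)
    snaps = syn.simulate_extrusion(annotation, barriers, cfg)
    raw = syn.render_contact_map(snaps, annotation, cfg)
    return ConditionResult(
        condition=condition,
        raw=raw,
        norm=vc_sqrt_normalize(raw),
        tracks=syn.render_tracks(snaps, annotation, condition),
        occupancy=syn.leg_occupancy(snaps, annotation.n_bins),
        pairs=syn.sample_pairs(raw, seed=seed),
        mean_extruders=syn.mean_extruder_count(snaps),
        mean_loop_bp=syn.mean_loop_length(snaps, annotation.bin_size_bp),
    )


def qpcr_scaled_cohesin_peaks(
    results: dict[str, ConditionResult],
    annotation: syn.GenomeAnnotation,
    reference: str,
    n_sites: int = 6,
    peak_threshold: float = 2.0,
) -> dict[str, list[tuple[int, int]]]:
    """Per-condition cohesin peaks on a common absolute scale.

    The true leg occupancy at a handful of strong reference sites
    plays the role of ChIP-qPCR measurements; qPCR-anchored scaling
    factors put every sample's fold-enrichment track on the reference
    scale before thresholding (scaling must precede thresholding),
    so occupancy loss (e.g. loader depletion) translates into lost
    peaks rather than being hidden by per-sample mean normalization.
    """
    conditions = list(results)
    ref_occ = results[reference].occupancy
    order = np.argsort(ref_occ)[::-1]
    sites = [
        int(b) for b in order if all(r.occupancy[b] > 0 for r in results.values())
    ][:n_sites]
    qpcr = pd.DataFrame({s: {c: results[c].occupancy[s] for c in conditions} for s in sites})
    chip = pd.DataFrame(
        {s: {c: results[c].tracks["cohesin"].values[s] for c in conditions} for s in sites}
    )
    factors = chip_scaling_factors(qpcr, chip, reference)
    peaks = {}
    for cond, res in results.items():
        tr = res.tracks["cohesin"]
        scaled = FoldEnrichmentTrack(
            tr.chrom, tr.bin_size_bp, tr.values * factors[cond], tr.sample_name
        )
        peaks[cond] = call_peaks(scaled, peak_threshold, exclusions=annotation.ltrs)
    return peaks


def anchored_loop_counts(
    results: dict[str, ConditionResult],
    annotation: syn.GenomeAnnotation,
    reference: str = "WT_G2M",
    fdr: float = 0.001,
    min_length_bp: int = 10_000,
) -> dict[str, int]:
    """Number of loop calls with both anchors at cohesin sites, per
    condition, using that condition's own scaled cohesin peaks."""
    peaks = qpcr_scaled_cohesin_peaks(results, annotation, reference)
    out = {}
    for cond, res in results.items():
        loops = call_loops(res.norm, fdr=fdr, min_length_bp=min_length_bp)
        loops = filter_by_anchors(loops, peaks[cond], slack_bp=annotation.bin_size_bp)
        out[cond] = sum(c.anchor_filter_passed for c in loops)
    return out


def long_range_fraction(result: ConditionResult, threshold_bp: int = 100_000) -> float:
    """Fraction of cis contacts spanning more than ``threshold_bp``."""
    sep = (result.pairs.records["pos2"] - result.pairs.records["pos1"]).to_numpy()
    return float((sep > threshold_bp).mean())


def origin_anchored_counts(
    result: ConditionResult,
    annotation: syn.GenomeAnnotation,
    halfwidth_bp: int = 10_000,
    min_separation_bp: int = 10_000,
) -> float:
    """Early-origin-anchored cis interactions (> min separation), per million."""
    early = [o.position for o in annotation.origins if o.is_early]
    feats = [(p - halfwidth_bp, p + halfwidth_bp) for p in early]
    return anchored_cis_counts(
        result.pairs, feats, min_separation_bp=min_separation_bp,
        feature_set_name="early_origins",
    ).count_per_million


def condition_panel(
    seed: int,
    conditions: tuple[str, ...],
    genome_kwargs: dict | None = None,
    **config_overrides,
) -> tuple[syn.GenomeAnnotation, dict[str, ConditionResult]]:
    """One genome simulated under several condition presets at one seed."""
    gk = {"n_genes": 40, "chrom_length_bp": 300_000}
    gk.update(genome_kwargs or {})
    annotation = syn.make_genome(seed=seed, **gk)
    results = {
        cond: simulate_condition(annotation, cond, seed, **config_overrides)
        for cond in conditions
    }
    return annotation, results
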