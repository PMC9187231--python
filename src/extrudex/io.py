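"""Readers/writers for the interchange formats, run configuration and
the end-to-end pipeline.

All interchange coordinates are 0-based half-open (BED convention);
1-based inputs must be converted by the caller.  Native contact-matrix
format is dense TSV with a small ``#key=value`` header — yeast-scale
matrices are small enough that a binary format buys nothing.

Readers validate shape (square matrices, fixed column counts, end >
start) so silently truncated files are rejected rather than returned
as partial data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contact_map import (
    ContactMatrix,
    PairsTable,
    anchored_cis_counts,
    cis_trans_counts,
    contact_probability,
    vc_sqrt_normalize,
)
from .feature_calling import FoldEnrichmentTrack, call_peaks, arm_sites
from .aggregate_metrics import insulation_score
from .loop_domain_calling import call_loops, filter_by_anchors
from . import synthetic_data as syn

logger = logging.getLogger("extrudex")

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr (no hidden state, no files)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# pairs
# ---------------------------------------------------------------------------

def read_pairs(path: str | Path, strict: bool = True) -> tuple[PairsTable, int]:
    """Read 4-column pairs TSV (chrom1, pos1, chrom2, pos2; '#' comments).

    Returns (table, n_malformed).  With ``strict`` a malformed line is
    a parse error naming the line; otherwise it is skipped and counted.
    """
    rows = []
    bad = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) != 4:
                    raise ValueError("expected 4 columns")
                rows.append((parts[0], int(parts[1]), parts[2], int(parts[3])))
            except ValueError as e:
                if strict:
                    raise ValueError(f"{path}:{ln}: malformed pairs line ({e})") from None
                bad += 1
    if bad:
        logger.warning("%s: skipped %d malformed pairs lines", path, bad)
    df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])
    return PairsTable(df), bad


def write_pairs(pairs: PairsTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom1\tpos1\tchrom2\tpos2\n")
        pairs.records.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED (3-6 columns) into a DataFrame; strand from column 6."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            start, end = int(p[1]), int(p[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: interval end <= start")
            rows.append(
                {
                    "chrom": p[0],
                    "start": start,
                    "end": end,
                    "name": p[3] if len(p) > 3 else ".",
                    "score": float(p[4]) if len(p) > 4 and p[4] != "." else 0.0,
                    "strand": p[5] if len(p) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(features: pd.DataFrame, path: str | Path) -> None:
    df = features.copy()
    for col, default in [("name", "."), ("score", 0), ("strand", ".")]:
        if col not in df.columns:
            df[col] = default
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> FoldEnrichmentTrack:
    """Read a 4-column bedGraph with uniform bins into a track."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            if len(p) != 4:
                raise ValueError(f"{path}:{ln}: bedGraph needs 4 columns")
            s, e = int(p[1]), int(p[2])
            if e <= s:
                raise ValueError(f"{path}:{ln}: interval end <= start")
            rows.append((p[0], s, e, float(p[3])))
    if not rows:
        raise ValueError(f"{path}: empty bedGraph")
    chrom = rows[0][0]
    sizes = {e - s for _, s, e, _ in rows}
    if len(sizes) != 1:
        raise ValueError(f"{path}: non-uniform bedGraph bins")
    size = sizes.pop()
    n = max(e for _, _, e, _ in rows) // size
    vals = np.zeros(n)
    for _, s, e, v in rows:
        vals[s // size] = v
    return FoldEnrichmentTrack(chrom=chrom, bin_size_bp=size, values=vals)


def write_bedgraph(track: FoldEnrichmentTrack, path: str | Path) -> None:
    size = track.bin_size_bp
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            fh.write(f"{track.chrom}\t{i * size}\t{(i + 1) * size}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# dense matrix TSV
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: ContactMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#chrom={matrix.chrom}\n")
        fh.write(f"#bin_size_bp={matrix.bin_size_bp}\n")
        fh.write(f"#normalized={matrix.normalized or 'raw'}\n")
        fh.write(f"#total_read_pairs={matrix.total_read_pairs}\n")
        np.savetxt(fh, matrix.counts, fmt="%.10g", delimiter="\t")


def read_matrix_tsv(path: str | Path) -> ContactMatrix:
    meta: dict[str, str] = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k] = v
            elif line:
                data_lines.append(line.split("\t"))
    if not data_lines:
        raise ValueError(f"{path}: matrix file has no data rows")
    widths = {len(r) for r in data_lines}
    if len(widths) != 1 or widths.pop() != len(data_lines):
        raise ValueError(f"{path}: matrix not square (truncated file?)")
    counts = np.array([[float(x) for x in row] for row in data_lines])
    norm = meta.get("normalized", "raw")
    return ContactMatrix(
        chrom=meta.get("chrom", "chr?"),
        bin_size_bp=int(meta.get("bin_size_bp", 1)),
        counts=counts,
        normalized=None if norm == "raw" else norm,
        total_read_pairs=int(meta.get("total_read_pairs", 0)),
    )


def write_annotation_beds(ann: syn.GenomeAnnotation, outdir: str | Path) -> dict[str, Path]:
    """Export the synthetic annotation as standard BED files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    genes = pd.DataFrame(
        {
            "chrom": ann.chrom,
            "start": [g.start for g in ann.genes],
            "end": [g.end for g in ann.genes],
            "name": [
                ("stress_gene" if g.is_stress_gene else "gene") + f"_{i}"
                for i, g in enumerate(ann.genes)
            ],
            "score": [g.expression_level for g in ann.genes],
            "strand": [g.strand for g in ann.genes],
        }
    )
    paths["genes"] = outdir / "genes.bed"
    write_bed(genes, paths["genes"])
    origins = pd.DataFrame(
        {
            "chrom": ann.chrom,
            "start": [o.position for o in ann.origins],
            "end": [o.position + 1 for o in ann.origins],
            "name": [f"ARS_{i}" + ("_early" if o.is_early else "") for i, o in enumerate(ann.origins)],
        }
    )
    paths["origins"] = outdir / "origins.bed"
    write_bed(origins, paths["origins"])
    cen = pd.DataFrame(
        {"chrom": [ann.chrom], "start": [ann.centromere_bp], "end": [ann.centromere_bp + 1],
         "name": ["CEN"]}
    )
    paths["centromere"] = outdir / "centromere.bed"
    write_bed(cen, paths["centromere"])
    ltrs = pd.DataFrame(
        {"chrom": ann.chrom, "start": [s for s, _ in ann.ltrs], "end": [e for _, e in ann.ltrs],
         "name": [f"LTR_{i}" for i in range(len(ann.ltrs))]}
    )
    paths["ltrs"] = outdir / "ltrs.bed"
    write_bed(ltrs, paths["ltrs"])
    return paths


# ---------------------------------------------------------------------------
# run configuration / manifest
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "seed", "outdir", "condition", "genome", "simulation", "analysis", "log_level",
}
_GENOME_KEYS = {"n_genes", "chrom_length_bp", "bin_size_bp"}
_SIM_KEYS = {
    "loading_rate", "unloading_prob", "extrusion_step", "n_steps", "burn_in_steps",
    "snapshot_every", "contact_background_exponent", "background_weight",
    "loop_bonus_weight", "loop_bonus_range_bins", "read_depth",
}
_ANALYSIS_KEYS = {
    "window_bp", "fdr", "min_length_bp", "peak_fe_threshold", "anchor_slack_bp",
    "peak_radius_bins", "donut_radius_bins", "min_separation_bp",
}


@dataclass
class RunConfig:
    """Resolved configuration for one reproducible pipeline run."""

    seed: int = 0
    outdir: str = "extrudex_run"
    condition: str = "WT_G2M"
    genome: dict = field(default_factory=lambda: {"n_genes": 40, "chrom_length_bp": 300_000, "bin_size_bp": 2000})
    simulation: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, allowed in [("genome", _GENOME_KEYS), ("simulation", _SIM_KEYS), ("analysis", _ANALYSIS_KEYS)]:
            extra = set(raw.get(key, {})) - allowed
            if extra:
                raise ValueError(f"unknown {key} config keys: {sorted(extra)}")
        cfg = cls(**raw)
        base = cls()
        cfg.genome = {**base.genome, **cfg.genome}
        return cfg


@dataclass
class RunManifest:
    """Record of what a run consumed and produced."""

    tool_version: str
    config: dict
    input_checksums: dict
    counts: dict
    outputs: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """simulate -> render -> normalize -> insulation -> loop calls -> quantify.

    Deterministic per seed; every declared output is written under
    ``config.outdir`` together with a JSON manifest whose counts match
    the emitted files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ana = config.analysis

    ann = syn.make_genome(seed=config.seed, **config.genome)
    bed_paths = write_annotation_beds(ann, outdir)
    barriers = syn.derive_barriers(ann, config.condition)
    sim_cfg = syn.SimulationConfig(condition=config.condition, seed=config.seed, **config.simulation)
    snapshots = syn.simulate_extrusion(ann, barriers, sim_cfg)
    raw = syn.render_contact_map(snapshots, ann, sim_cfg)
    tracks = syn.render_tracks(snapshots, ann, config.condition)
    pairs = syn.sample_pairs(raw, seed=config.seed)

    write_matrix_tsv(raw, outdir / "contacts_raw.tsv")
    norm = vc_sqrt_normalize(raw)
    write_matrix_tsv(norm, outdir / "contacts_vcsqrt.tsv")
    write_pairs(pairs, outdir / "contacts.pairs.tsv")
    for name, track in tracks.items():
        write_bedgraph(track, outdir / f"track_{name}.bedgraph")

    ins = insulation_score(norm, window_bp=ana.get("window_bp", 40_000))
    pd.DataFrame(
        {
            "bin": np.arange(ins.n_bins),
            "start": np.arange(ins.n_bins) * ins.bin_size_bp,
            "raw": ins.raw_scores,
            "normalized": ins.normalized_scores,
            "valid": ins.valid_mask.astype(int),
        }
    ).to_csv(outdir / "insulation.tsv", sep="\t", index=False)

    cohesin_peaks = call_peaks(
        tracks["cohesin"], ana.get("peak_fe_threshold", 2.0), exclusions=ann.ltrs
    )
    arm = arm_sites(cohesin_peaks, ann.centromere_bp)
    loops = call_loops(
        norm,
        peak_radius_bins=ana.get("peak_radius_bins", 2),
        donut_radius_bins=ana.get("donut_radius_bins", 5),
        fdr=ana.get("fdr", 0.001),
        min_length_bp=ana.get("min_length_bp", 10_000),
    )
    loops = filter_by_anchors(loops, cohesin_peaks, slack_bp=ana.get("anchor_slack_bp", ann.bin_size_bp))
    loop_df = pd.DataFrame(
        [
            {
                "chrom1": ann.chrom, "start1": c.anchor_up[0], "end1": c.anchor_up[1],
                "chrom2": ann.chrom, "start2": c.anchor_down[0], "end2": c.anchor_down[1],
                "length_bp": c.length_bp, "enrichment": c.enrichment,
                "q_value": c.q_value, "anchor_filter": int(c.anchor_filter_passed),
            }
            for c in loops
        ]
    )
    loop_df.to_csv(outdir / "loops.tsv", sep="\t", index=False)

    cis, trans = cis_trans_counts(pairs)
    quant = {"cis_per_million": cis, "trans_per_million": trans}
    if ann.convergent_sites:
        feats = [(s - 1000, s + 1000) for s in ann.convergent_sites]
        ac = anchored_cis_counts(
            pairs, feats, min_separation_bp=ana.get("min_separation_bp", 10_000),
            feature_set_name="convergent_sites",
        )
        quant["convergent_anchored_per_million"] = ac.count_per_million
    ps = contact_probability(pairs)
    ps.to_csv(outdir / "contact_probability.tsv", sep="\t", index=False)
    pd.Series(quant).to_csv(outdir / "quantification.tsv", sep="\t", header=False)

    manifest = RunManifest(
        tool_version=__version__,
        config={
            "seed": config.seed, "outdir": str(config.outdir), "condition": config.condition,
            "genome": config.genome, "simulation": config.simulation,
            "analysis": config.analysis,
        },
        input_checksums={},
        counts={
            "n_genes": len(ann.genes),
            "n_convergent_sites": len(ann.convergent_sites),
            "n_barriers": len(barriers.barriers),
            "n_snapshots": len(snapshots),
            "pairs_total": pairs.total_pairs,
            "cohesin_peaks": len(cohesin_peaks),
            "cohesin_arm_sites": len(arm),
            "loops_called": len(loops),
            "loops_anchor_filtered": int(sum(c.anchor_filter_passed for c in loops)),
        },
        outputs={k: str(v) for k, v in bed_paths.items()}
        | {
            "contacts_raw": str(outdir / "contacts_raw.tsv"),
            "contacts_vcsqrt": str(outdir / "contacts_vcsqrt.tsv"),
            "pairs": str(outdir / "contacts.pairs.tsv"),
            "insulation": str(outdir / "insulation.tsv"),
            "loops": str(outdir / "loops.tsv"),
            "contact_probability": str(outdir / "contact_probability.tsv"),
            "quantification": str(outdir / "quantification.tsv"),
        },
    )
    manifest.write(outdir / "manifest.json")
    return manifest
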