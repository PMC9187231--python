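# extrudex

Cohesin extrudes chromatin loops until something stops it.  In budding
yeast the stopping points are made by other machines moving on the same
DNA: RNA polymerases transcribing convergently oriented gene pairs,
centromeres, and — in early S phase — replication forks stalled a few
kilobases from early-firing origins.  `extrudex` is a toolkit for
studying this barrier landscape quantitatively.  It bundles two things:

1. **A 1-D loop-extrusion simulator.**  A chromosome is a lattice of
   bins; an extruder is a pair of leg positions `(l, r)` that step
   outward symmetrically, blocked by other legs and by directional
   barriers derived from a synthetic genome annotation (gene 3′ ends
   with permeability decreasing in expression, an absolute centromere,
   fork barriers at `origin ± 7.5 kb` under hydroxyurea arrest).
   Condition presets mimic the key perturbations: transcription
   inhibition (thiolutin), depletion of the cohesin loader Scc2
   (loading × 0.05) or the unloader Wpl1 (unloading × 0.1), and
   HU-arrested S phase, alone or combined.  The simulator renders
   binned contact maps (distance-decay background plus leg-pair
   co-occupancy, multinomially sampled to a chosen read depth) and
   cohesin / RNA-pol-II / BrdU fold-enrichment tracks with known
   ground truth.

2. **The Hi-C / ChIP-seq analysis stack used to detect barriers.**
   Pairs binning, coverage-sqrt normalization
   (`N[i,j] = M[i,j] / sqrt(r_i r_j)`), log2 ratio maps, contact
   probability `P(s)`, cis/trans and feature-anchored counts with exact
   binomial comparisons; insulation scores (1-kb bins, 40-kb window,
   mean-normalized) and averaged profiles; aggregate peak analysis with
   the central-square / top-right-corner strength ratio; local-background
   (donut) loop calling with Poisson tails, Benjamini–Hochberg FDR
   < 0.001, a > 10-kb length filter and cohesin-site anchor filtering;
   arrowhead-transform domain calling with cross-resolution merging; and
   the ChIP-seq classification rules for Scc1 peaks (FE > 2.0, LTR and
   25-kb pericentromere exclusions), thiolutin-induced stress-response
   genes (Rpo21 FE > 4.0 treated AND < 2.0 control AND differential-
   expression flag), BrdU-defined early origins (FE > 1.5), and
   qPCR-anchored / spike-in scaling factors.

Everything runs on plain-text formats (pairs TSV, dense matrix TSV,
BED, bedGraph, YAML configs); coordinates are 0-based half-open
throughout.

## Worked example

```python
import extrudex as x

ann = x.make_genome(n_genes=40, chrom_length_bp=300_000, seed=1)
wt = x.simulate_condition(ann, "WT_G2M", seed=1)
thio = x.simulate_condition(ann, "thiolutin", seed=1)
counts = x.anchored_loop_counts({"WT_G2M": wt, "thiolutin": thio}, ann)
print(counts, x.long_range_fraction(wt), x.long_range_fraction(thio))
```

prints (condensed):

```
genes: 40  convergent sites: 20  origins: 6  centromere at 153474 bp
WT: 3.3 extruders, mean loop 16.4 kb
thiolutin: 3.4 extruders, mean loop 76.7 kb
cohesin-anchored loops: WT 41, thiolutin 0
contacts >100 kb: WT 1.22%, thiolutin 8.10%
binomial test on depth-matched loop counts: p = 9.09e-13
insulation minima recover 15/17 absolute barriers
```

Read: with transcription on, extruders stall between convergent genes,
producing ~41 loop calls anchored at cohesin sites and short loops
(16 kb).  Removing the gene barriers lets the same number of extruders
run free — loops grow to ~77 kb, focal anchored loops vanish, and the
>100-kb contact fraction rises seven-fold.  The insulation-score minima
of the wild-type map sit at 15 of the 17 analyzable absolute barriers.

The same pipeline is available from the shell:

```bash
extrudex simulate --seed 1 --outdir run_wt --condition WT_G2M
extrudex insulation run_wt/contacts_vcsqrt.tsv -o run_wt/insulation.tsv
extrudex call-loops run_wt/contacts_vcsqrt.tsv --anchors run_wt/genes.bed -o run_wt/loops.tsv
```

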