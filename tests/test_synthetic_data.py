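"""Unit and property tests for the genome generator and loop-extrusion
simulator."""

import numpy as np
import pytest

import extrudex as x
from extrudex.synthetic_data import Gene, Origin


def tiny_annotation(genes, length=40_000, cen=35_000, bin_size=1000):
    return x.GenomeAnnotation(
        chrom_length_bp=length,
        bin_size_bp=bin_size,
        genes=genes,
        origins=[],
        centromere_bp=cen,
    )


class TestMakeGenome:
    def test_single_convergent_pair(self):
        ann = x.make_genome(2, 20_000, seed=0)
        assert [g.strand for g in ann.genes] == ["+", "-"]
        sites = ann.convergent_sites
        assert len(sites) == 1
        assert ann.genes[0].three_prime_bp < sites[0] < ann.genes[1].three_prime_bp

    def test_divergent_pair_has_no_site(self):
        genes = [Gene(1000, 3000, "-", 1.0), Gene(4000, 6000, "+", 1.0)]
        ann = tiny_annotation(genes)
        assert ann.convergent_sites == []

    def test_convergent_count_matches_brute_force_scan(self):
        ann = x.make_genome(40, 300_000, seed=1)
        brute = sum(
            a.strand == "+" and b.strand == "-"
            for a, b in zip(ann.genes, ann.genes[1:])
        )
        assert len(ann.convergent_sites) == brute
        assert brute >= 300 // 15 - 5  # at least ~1 site per ~15 kb

    def test_deterministic_for_fixed_seed(self):
        a = x.make_genome(20, 150_000, seed=9)
        b = x.make_genome(20, 150_000, seed=9)
        assert [(g.start, g.end, g.strand, g.expression_level) for g in a.genes] == [
            (g.start, g.end, g.strand, g.expression_level) for g in b.genes
        ]

    def test_impossible_packing_raises(self):
        with pytest.raises(ValueError):
            x.make_genome(40, 50_000, seed=0)

    def test_invariants_hold(self):
        ann = x.make_genome(30, 250_000, seed=3)
        ends = [g.three_prime_bp for g in ann.genes]
        for s, (a, b) in zip(
            ann.convergent_sites,
            [
                (g1, g2)
                for g1, g2 in zip(ann.genes, ann.genes[1:])
                if g1.strand == "+" and g2.strand == "-"
            ],
        ):
            assert a.three_prime_bp < s < b.three_prime_bp
        assert 0 <= ann.centromere_bp < ann.chrom_length_bp
        assert all(e <= ann.chrom_length_bp for _, e in ann.ltrs)


class TestDeriveBarriers:
    def test_thiolutin_keeps_only_centromere_without_stress_genes(self):
        genes = [Gene(1000, 3000, "+", 2.0), Gene(4000, 6000, "-", 1.0), Gene(8000, 10_000, "+", 0.5)]
        ann = tiny_annotation(genes)
        b = x.derive_barriers(ann, "thiolutin")
        assert len(b.barriers) == 1
        assert b.barriers[0].blocking_direction == "both"
        assert b.barriers[0].bin_index == ann.bin_of(ann.centromere_bp)

    def test_convergent_pair_gives_facing_barriers(self):
        genes = [Gene(1000, 4000, "+", 1.0), Gene(8000, 11_000, "-", 1.0)]
        ann = tiny_annotation(genes)
        b = x.derive_barriers(ann, "WT_G2M")
        gene_bs = [bb for bb in b.barriers if bb.blocking_direction != "both"]
        assert len(gene_bs) == 2
        left, right = sorted(gene_bs, key=lambda bb: bb.bin_index)
        # + gene barrier at its 3' end blocks legs moving head-on (leftward);
        # - gene barrier blocks rightward legs: the pair faces inward
        assert left.bin_index == ann.bin_of(3999) and left.blocking_direction == "left"
        assert right.bin_index == ann.bin_of(8000) and right.blocking_direction == "right"

    def test_permeability_decreases_with_expression(self):
        genes = [Gene(1000, 3000, "+", 0.2), Gene(5000, 7000, "-", 3.0)]
        ann = tiny_annotation(genes)
        b = x.derive_barriers(ann, "WT_G2M")
        weak, strong = (bb for bb in b.barriers if bb.blocking_direction != "both")
        assert weak.permeability > strong.permeability
        assert strong.permeability == pytest.approx(np.exp(-6.5 * 3.0))

    def test_hu_barrier_count_by_enumeration(self):
        genes = [Gene(2000 + 6000 * i, 4000 + 6000 * i, "+-"[i % 2], 1.0) for i in range(5)]
        ann = x.GenomeAnnotation(
            chrom_length_bp=60_000, bin_size_bp=1000, genes=genes,
            origins=[Origin(40_000, True), Origin(52_000, True), Origin(46_000, False)],
            centromere_bp=35_000,
        )
        b = x.derive_barriers(ann, "HU")
        # 5 gene barriers + 1 centromere + 2 forks per early origin
        assert len(b.barriers) == 5 + 1 + 2 * 2
        forks = [bb for bb in b.barriers if bb.blocking_direction == "both"][1:]
        expected = sorted(
            ann.bin_of(p + d)
            for p in (40_000, 52_000)
            for d in (-7500, 7500)
        )
        assert sorted(f.bin_index for f in forks) == expected

    def test_rate_conditions_leave_barriers_unchanged(self):
        ann = x.make_genome(10, 80_000, seed=2)
        wt = x.derive_barriers(ann, "WT_G2M")
        for cond in ("scc2_depleted", "wpl1_depleted"):
            other = x.derive_barriers(ann, cond)
            assert [(b.bin_index, b.blocking_direction, b.permeability) for b in wt.barriers] == [
                (b.bin_index, b.blocking_direction, b.permeability) for b in other.barriers
            ]

    def test_unknown_condition_rejected(self):
        ann = x.make_genome(4, 30_000, seed=0)
        with pytest.raises(ValueError):
            x.derive_barriers(ann, "heat_shock")


class TestSimulateExtrusion:
    def test_zero_loading_gives_empty_snapshots(self):
        ann = x.make_genome(4, 30_000, seed=0, bin_size_bp=1000)
        cfg = x.SimulationConfig(loading_rate=0.0, n_steps=50, burn_in_steps=10, seed=0)
        snaps = x.simulate_extrusion(ann, x.BarrierSet([]), cfg)
        assert snaps and all(s.extruders == [] for s in snaps)

    def test_free_extrusion_is_deterministic(self):
        ann = x.make_genome(4, 30_000, seed=0, bin_size_bp=1000)  # 30 bins
        cfg = x.SimulationConfig(
            loading_rate=0.0, unloading_prob=0.0, n_steps=6, burn_in_steps=0,
            snapshot_every=1, seed=0,
        )
        snaps = x.simulate_extrusion(ann, x.BarrierSet([]), cfg, initial_extruders=[(14, 15)])
        # snapshot k is recorded after k+1 update steps
        for k, snap in enumerate(snaps):
            l, r = snap.extruders[0]
            assert (l, r) == (max(14 - (k + 1), 0), min(15 + (k + 1), 29))

    def test_legs_clip_at_chromosome_ends(self):
        ann = x.make_genome(4, 30_000, seed=0, bin_size_bp=1000)
        cfg = x.SimulationConfig(
            loading_rate=0.0, unloading_prob=0.0, n_steps=100, burn_in_steps=90,
            snapshot_every=1, seed=0,
        )
        snaps = x.simulate_extrusion(ann, x.BarrierSet([]), cfg, initial_extruders=[(14, 15)])
        assert snaps[-1].extruders[0] == (0, 29)

    def test_absolute_barrier_never_crossed(self):
        ann = x.make_genome(4, 30_000, seed=0, bin_size_bp=1000)
        barriers = x.BarrierSet([x.Barrier(20, "right", 0.0)])
        cfg = x.SimulationConfig(
            loading_rate=0.0, unloading_prob=0.0, n_steps=10_000, burn_in_steps=0,
            snapshot_every=1, seed=0,
        )
        snaps = x.simulate_extrusion(ann, barriers, cfg, initial_extruders=[(18, 19)])
        assert all(s.extruders[0][1] < 20 for s in snaps)

    @pytest.mark.parametrize("cond", ["WT_G2M", "thiolutin", "wpl1_depleted", "HU"])
    def test_leg_order_and_no_bypass_along_trajectory(self, cond):
        ann = x.make_genome(20, 150_000, seed=4)
        cfg = x.SimulationConfig(condition=cond, n_steps=2000, burn_in_steps=100, seed=4)
        snaps = x.simulate_extrusion(ann, x.derive_barriers(ann, cond), cfg)
        for s in snaps:
            s.check_invariants(ann.n_bins)

    def test_scc2_depletion_reduces_occupancy_below_ten_percent(self):
        ann = x.make_genome(40, 300_000, seed=0)
        counts = {}
        for cond in ("WT_G2M", "scc2_depleted"):
            cfg = x.SimulationConfig(condition=cond, seed=0)
            snaps = x.simulate_extrusion(ann, x.derive_barriers(ann, cond), cfg)
            counts[cond] = x.mean_extruder_count(snaps)
        assert counts["scc2_depleted"] < 0.1 * counts["WT_G2M"]

    @pytest.mark.parametrize("cond", ["thiolutin", "wpl1_depleted"])
    def test_mean_loop_length_exceeds_wild_type(self, cond):
        # matched seeds and steps, ten replicates
        wins = 0
        for seed in range(10):
            ann = x.make_genome(40, 300_000, seed=seed)
            spans = {}
            for c in ("WT_G2M", cond):
                cfg = x.SimulationConfig(condition=c, seed=seed)
                snaps = x.simulate_extrusion(ann, x.derive_barriers(ann, c), cfg)
                spans[c] = x.mean_loop_length(snaps, ann.bin_size_bp)
            wins += spans[cond] > spans["WT_G2M"]
        assert wins == 10


class TestRenderContactMap:
    def test_pure_background_recovers_exponent(self):
        ann = x.make_genome(40, 300_000, seed=1)
        cfg = x.SimulationConfig(
            seed=1, background_weight=1.0, read_depth=2_000_000,
            n_steps=600, burn_in_steps=500,
        )
        snaps = x.simulate_extrusion(ann, x.derive_barriers(ann, "WT_G2M"), cfg)
        m = x.render_contact_map(snaps, ann, cfg)
        d = np.arange(2, 80)
        mean_diag = np.array([np.mean(np.diagonal(m.counts, k)) for k in d])
        slope = np.polyfit(np.log1p(d), np.log(mean_diag), 1)[0]
        assert slope == pytest.approx(-cfg.contact_background_exponent, abs=0.1)

    def test_single_permanent_extruder_concentrates_contacts(self):
        ann = x.make_genome(4, 30_000, seed=0, bin_size_bp=1000)
        barriers = x.BarrierSet([x.Barrier(5, "left", 0.0), x.Barrier(24, "right", 0.0)])
        cfg = x.SimulationConfig(
            loading_rate=0.0, unloading_prob=0.0, background_weight=0.0,
            loop_bonus_weight=0.0, n_steps=300, burn_in_steps=200,
            snapshot_every=1, read_depth=10_000, seed=0,
        )
        snaps = x.simulate_extrusion(ann, barriers, cfg, initial_extruders=[(14, 15)])
        m = x.render_contact_map(snaps, ann, cfg)
        assert m.counts[6, 23] == m.counts.max()

    def test_seed_contract(self):
        ann = x.make_genome(10, 80_000, seed=2)
        b = x.derive_barriers(ann, "WT_G2M")
        cfg = x.SimulationConfig(seed=11, n_steps=1500, burn_in_steps=200)
        m1 = x.render_contact_map(x.simulate_extrusion(ann, b, cfg), ann, cfg)
        m2 = x.render_contact_map(x.simulate_extrusion(ann, b, cfg), ann, cfg)
        np.testing.assert_array_equal(m1.counts, m2.counts)
        cfg3 = x.SimulationConfig(seed=12, n_steps=1500, burn_in_steps=200)
        m3 = x.render_contact_map(x.simulate_extrusion(ann, b, cfg3), ann, cfg3)
        assert not np.array_equal(m1.counts, m3.counts)

    def test_no_snapshots_rejected(self):
        ann = x.make_genome(4, 30_000, seed=0)
        with pytest.raises(RuntimeError):
            x.render_contact_map([], ann, x.SimulationConfig(seed=0))

    def test_symmetric_with_total_depth(self, wt_bundle):
        m = wt_bundle["raw"]
        np.testing.assert_array_equal(m.counts, m.counts.T)
        assert m.counts.sum() >= m.total_read_pairs  # mirrored off-diagonal counts


class TestSamplePairs:
    def test_positions_fall_inside_their_bins(self, wt_bundle):
        pairs = x.sample_pairs(wt_bundle["raw"], seed=0)
        assert pairs.total_pairs == wt_bundle["raw"].total_read_pairs
        sub = pairs.records.sample(500, random_state=0)
        assert (sub.pos2 >= sub.pos1).all()
        assert (sub.pos2 < wt_bundle["annotation"].chrom_length_bp).all()


class TestRenderTracks:
    def test_cohesin_maxima_colocate_with_convergent_sites(self, wt_bundle):
        ann = wt_bundle["annotation"]
        track = wt_bundle["tracks"]["cohesin"]
        sites = {ann.bin_of(s) for s in ann.convergent_sites}
        top = np.argsort(track.values)[::-1][:15]
        frac = np.mean([any(abs(int(t) - s) <= 1 for s in sites) for t in top])
        assert frac >= 0.7
        assert track.values.mean() == pytest.approx(1.0)

    def test_thiolutin_flattens_pol2_over_non_stress_orfs(self):
        ann = x.make_genome(40, 300_000, seed=0)
        snaps = x.simulate_extrusion(
            ann, x.derive_barriers(ann, "thiolutin"),
            x.SimulationConfig(condition="thiolutin", seed=0, n_steps=1500, burn_in_steps=200),
        )
        thio = x.render_tracks(snaps, ann, "thiolutin")["rna_pol2"]
        wt = x.render_tracks(snaps, ann, "WT_G2M")["rna_pol2"]
        stress_bins = {
            b
            for g in ann.genes
            if g.is_stress_gene
            for b in range(ann.bin_of(g.start), ann.bin_of(g.end - 1) + 1)
        }
        for g in ann.genes:
            bins = [
                b
                for b in range(ann.bin_of(g.start), ann.bin_of(g.end - 1) + 1)
                if b not in stress_bins
            ]
            if g.is_stress_gene:
                assert thio.values[ann.bin_of(g.start)] > 4.0
            elif bins:
                assert thio.values[bins].max() == pytest.approx(1.0)
                assert wt.values[bins].max() > 1.0

    def test_brdu_flat_outside_hu(self, wt_bundle):
        assert np.all(wt_bundle["tracks"]["brdu"].values == 1.0)

    def test_brdu_plateau_under_hu(self):
        ann = x.make_genome(40, 300_000, seed=0, early_origin_fraction=1.0)
        snaps = x.simulate_extrusion(
            ann, x.derive_barriers(ann, "HU"),
            x.SimulationConfig(condition="HU", seed=0, n_steps=1500, burn_in_steps=200),
        )
        brdu = x.render_tracks(snaps, ann, "HU")["brdu"]
        for o in ann.origins:
            assert brdu.values[ann.bin_of(o.position)] > 1.5
        assert brdu.values.min() == 1.0
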