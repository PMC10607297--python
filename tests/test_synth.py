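"""Synthetic-data generator: determinism, programmed-truth fidelity and
round trips through the downstream estimators."""

import io

import numpy as np
import pandas as pd
import pytest

import nucshift as ns
from nucshift.gelquant import lanes_from_table
from nucshift.io import write_fasta
from nucshift.synth import (
    ClusterSpec,
    SyntheticConfig,
    TractRule,
    generate_dyad_tracks,
    generate_fragments,
    generate_gel_tables,
    generate_promoter_genome,
)
from nucshift.tracts import scan_tracts

NO_TRACT_CLUSTERS = (ClusterSpec(name="unchanged", weight=1.0),)
ONE_TRACT_CLUSTERS = (
    ClusterSpec(
        name="unchanged",
        weight=1.0,
        tract_rules=(TractRule(anchor="minus1", side="downstream", sense_base="A", length=15),),
    ),
)


class TestGenome:
    def test_no_tracts_configured_scan_finds_none(self):
        cfg = SyntheticConfig(n_genes=10, clusters=NO_TRACT_CLUSTERS, seed=1)
        genome, _, _ = generate_promoter_genome(cfg)
        assert all(not scan_tracts(seq, 6) for seq in genome.values())

    def test_one_15bp_tract_per_gene(self):
        cfg = SyntheticConfig(n_genes=10, clusters=ONE_TRACT_CLUSTERS, seed=1)
        genome, _, truths = generate_promoter_genome(cfg)
        found = [t for seq in genome.values() for t in scan_tracts(seq, 6)]
        assert len(found) == 10
        assert all(t.length == 15 for t in found)

    def test_programmed_tracts_appear_verbatim(self):
        cfg = SyntheticConfig(n_genes=8, seed=3)
        genome, _, truths = generate_promoter_genome(cfg)
        for t in truths:
            for pos, base, length in t.tract_placements:
                assert genome[t.chrom][pos : pos + length] == base * length

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        paths = []
        for i in range(2):
            cfg = SyntheticConfig(n_genes=6, seed=99)
            genome, _, _ = generate_promoter_genome(cfg)
            p = tmp_path / f"g{i}.fa"
            write_fasta(genome, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_genes=0)
        with pytest.raises(ValueError):
            SyntheticConfig(promoter_span=400)

    def test_colliding_tracts_rejected(self):
        clash = (
            ClusterSpec(
                name="unchanged",
                weight=1.0,
                tract_rules=(
                    TractRule("minus1", "downstream", "A", 15, 0),
                    TractRule("minus1", "downstream", "T", 15, 5),
                ),
            ),
        )
        with pytest.raises(ValueError, match="collide"):
            generate_promoter_genome(SyntheticConfig(n_genes=2, clusters=clash, seed=1))


class TestDyadTracks:
    def test_zero_jitter_shift_definition(self):
        clusters = (ClusterSpec(name="downstream", weight=1.0, minus1_shift=30),)
        cfg = SyntheticConfig(n_genes=4, clusters=clusters, seed=5)
        _, _, truths = generate_promoter_genome(cfg)
        for t in truths:
            if t.strand == "+":
                assert t.minus1_dyad_treated == t.minus1_dyad_sgd + 30
            else:
                assert t.minus1_dyad_treated == t.minus1_dyad_sgd - 30

    def test_jittered_shift_recovered_on_average(self):
        clusters = (ClusterSpec(name="downstream", weight=1.0, minus1_shift=30),)
        cfg = SyntheticConfig(n_genes=1000, clusters=clusters, dyad_jitter_sd=5, seed=6)
        _, _, truths = generate_promoter_genome(cfg)
        da, db = generate_dyad_tracks(truths, cfg)
        # pick the emitted -1 dyads: nearest emitted position to the truth
        errs = []
        for t in truths:
            sign = 1 if t.strand == "+" else -1
            a = da[da.chrom == t.chrom].start.to_numpy()
            b = db[db.chrom == t.chrom].start.to_numpy()
            pa = a[np.argmin(np.abs(a - t.minus1_dyad_sgd))]
            pb = b[np.argmin(np.abs(b - t.minus1_dyad_treated))]
            errs.append(sign * (pb - pa) - 30)
        assert abs(np.mean(errs)) < 1.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            generate_dyad_tracks([], SyntheticConfig(n_genes=1, seed=0))


class TestFragments:
    def test_zero_jitter_midpoints_equal_dyads(self):
        cfg = SyntheticConfig(n_genes=3, seed=7, fragment_count_per_dyad=5)
        _, _, truths = generate_promoter_genome(cfg)
        da, _ = generate_dyad_tracks(truths, cfg)
        frags = generate_fragments(da, cfg)
        mids = (frags.start + frags.end) // 2
        dyads = da.loc[da.index.repeat(5), "start"].reset_index(drop=True)
        assert (mids == dyads).all()
        assert ((frags.end - frags.start) == 147).all()

    def test_caller_recovers_dyads_within_5bp(self):
        clusters = NO_TRACT_CLUSTERS
        cfg = SyntheticConfig(
            n_genes=3, clusters=clusters, seed=8,
            dyad_jitter_sd=10, fragment_count_per_dyad=200,
        )
        _, _, truths = generate_promoter_genome(cfg)
        da, _ = generate_dyad_tracks(
            truths, SyntheticConfig(n_genes=3, clusters=clusters, seed=8)
        )  # dyads without jitter; jitter enters via fragments
        frags = generate_fragments(da, cfg)
        called = ns.call_dyads_from_fragments(frags)
        by_chrom = {}
        for p in called:
            by_chrom.setdefault(p.chrom, []).append(p.pos)
        for t in truths:
            got = np.array(by_chrom[t.chrom])
            for true_pos in (t.minus1_dyad_sgd, t.plus1_dyad_sgd):
                assert np.min(np.abs(got - true_pos)) <= 5

    def test_empty_dyads_give_empty_fragments(self):
        cfg = SyntheticConfig(n_genes=1, seed=0)
        empty = pd.DataFrame(columns=["chrom", "start", "end", "score"])
        assert generate_fragments(empty, cfg).empty


class TestGelTables:
    def test_zero_noise_round_trip(self):
        cfg = SyntheticConfig(n_genes=1, seed=0, intensity_noise_cv=0.0)
        table = generate_gel_tables(
            {
                "sliding": {"p1": 0.30},
                "eviction": {"p1": 0.25},
                "binding": {"p1": 0.40},
                "keq_rel": {"p1": 0.125},
            },
            cfg,
        )
        lanes = {(l.assay_id, l.lane_id): l for l in lanes_from_table(table)}
        assert ns.sliding_extent(lanes[("sliding", "p1")]) == pytest.approx(0.30)
        assert ns.eviction_extent(
            lanes[("eviction", "p1_plus")], lanes[("eviction", "p1_minus")]
        ) == pytest.approx(0.25)
        assert ns.binding_extent(lanes[("binding", "p1")]) == pytest.approx(0.40)
        ref = lanes[("keq", "ref")]
        m = lanes[("keq", "p1")]
        keq = ns.relative_keq(
            ns.ReconstitutionMeasurement("p1", m.band("nucleosomal"), m.band("free_dna")),
            ns.ReconstitutionMeasurement("ref", ref.band("nucleosomal"), ref.band("free_dna")),
        )
        assert keq == pytest.approx(0.125)

    def test_noisy_recovery_unbiased(self):
        """With 5% multiplicative band noise over 100 lanes, the mean
        recovered sliding extent stays within 2 SEM of the truth."""
        cfg = SyntheticConfig(n_genes=1, seed=12, intensity_noise_cv=0.05)
        true = 0.30
        table = generate_gel_tables(
            {"sliding": {f"l{i}": true for i in range(100)}}, cfg
        )
        vals = [
            ns.sliding_extent(l)
            for l in lanes_from_table(table)
            if l.assay_id == "sliding"
        ]
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - true) < 2 * sem + 1e-9

    def test_out_of_range_extent_rejected(self):
        cfg = SyntheticConfig(n_genes=1, seed=0)
        with pytest.raises(ValueError):
            generate_gel_tables({"sliding": {"p": 1.5}}, cfg)
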