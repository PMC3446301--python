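"""The synthetic-data generator: composition, read sampling, determinism."""

import re

import numpy as np
import pytest

from oriseq.features import PWM
from oriseq.synthetic import (
    ORIGIN_CORE,
    SAP1_LIKE_CONSENSUS,
    SyntheticSpec,
    make_genome,
    nucleosome_intensity,
    plant_motifs,
    replication_intensity,
    simulate_dataset,
    simulate_nucleosome_reads,
    simulate_replication_reads,
)

SMALL = dict(
    chromosome_lengths=[400_000],
    n_origins=4,
    s_read_count=60_000,
    g2_read_count=60_000,
    nuc_read_count=60_000,
)


def core_seq(genome, chrom, mu):
    return genome[chrom][mu - ORIGIN_CORE : mu + ORIGIN_CORE]


class TestMakeGenome:
    def test_no_origins_gives_background_only(self):
        spec = SyntheticSpec(**{**SMALL, "n_origins": 0}, seed=2)
        genome, truth = make_genome(spec)
        assert truth.origin_positions == []
        assert len(genome["chr1"]) == 400_000

    def test_polyA_origins_contain_long_AT_runs(self):
        spec = SyntheticSpec(chromosome_lengths=[2_000_000], n_origins=20, seed=2)
        genome, truth = make_genome(spec)
        assert len(truth.origin_positions) == 20
        for chrom, mu in truth.origin_positions:
            assert re.search(r"A{8,}|T{8,}", core_seq(genome, chrom, mu))

    def test_gc_origins_contain_planted_motif_kinds(self):
        spec = SyntheticSpec(
            chromosome_lengths=[2_000_000], n_origins=20, species_mode="GC_motif", seed=2
        )
        genome, truth = make_genome(spec)
        rc_sap1 = SAP1_LIKE_CONSENSUS.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        for chrom, mu in truth.origin_positions:
            s = core_seq(genome, chrom, mu)
            has_polyG = re.search(r"G{9,}|C{9,}", s)
            has_sap1 = SAP1_LIKE_CONSENSUS in s or rc_sap1 in s
            has_repeat = "CTCGCT" * 2 in s
            assert has_polyG and has_sap1 and has_repeat

    def test_origins_separated_by_four_sigma(self):
        spec = SyntheticSpec(chromosome_lengths=[2_000_000], n_origins=15, seed=4)
        _, truth = make_genome(spec)
        pos = sorted(p for _, p in truth.origin_positions)
        assert min(np.diff(pos)) >= 4 * spec.peak_sigma

    def test_origins_land_in_intergenes(self):
        spec = SyntheticSpec(**SMALL, seed=5)
        _, truth = make_genome(spec)
        for chrom, mu in truth.origin_positions:
            assert not any(
                s <= mu < e for c, s, e in truth.gene_intervals if c == chrom
            )

    def test_chromosome_too_short_raises_sizing_error(self):
        spec = SyntheticSpec(chromosome_lengths=[50_000], n_origins=30, s_read_count=0,
                             g2_read_count=0, nuc_read_count=0)
        with pytest.raises(ValueError, match="too short"):
            make_genome(spec)


class TestReplicationReads:
    def test_read_counts_are_exact(self):
        spec = SyntheticSpec(**SMALL, seed=6)
        genome, truth = make_genome(spec)
        s, g2 = simulate_replication_reads(genome, truth, spec)
        assert len(s) == spec.s_read_count and len(g2) == spec.g2_read_count

    def test_no_origin_spec_gives_flat_s_over_g2(self):
        spec = SyntheticSpec(**{**SMALL, "n_origins": 0, "s_read_count": 200_000,
                                "g2_read_count": 200_000}, seed=7)
        genome, truth = make_genome(spec)
        s, g2 = simulate_replication_reads(genome, truth, spec)
        assert truth.replicated_fraction_n == 0.0
        bins = np.arange(0, 400_001, 2000)
        hs, _ = np.histogram(s["start"], bins=bins)
        hg, _ = np.histogram(g2["start"], bins=bins)
        ratio = hs[hg > 0] / hg[hg > 0]
        assert abs(ratio.mean() - 1.0) < 0.05

    def test_single_origin_doubles_coverage_at_center(self):
        spec = SyntheticSpec(
            chromosome_lengths=[400_000],
            n_origins=1,
            origin_efficiency_range=(1.0, 1.0),
            notch_depth=0.0,
            s_read_count=400_000,
            g2_read_count=0,
            nuc_read_count=0,
            seed=8,
        )
        genome, truth = make_genome(spec)
        s, _ = simulate_replication_reads(genome, truth, spec)
        (chrom, mu), = truth.origin_positions
        starts = s["start"].to_numpy()
        at_mu = np.sum(np.abs(starts - mu) < 250) / 500
        far = np.abs(starts - mu) > 5 * spec.peak_sigma
        baseline = far.sum() / (400_000 - 10 * spec.peak_sigma)
        assert at_mu / baseline == pytest.approx(2.0, abs=0.15)

    def test_notch_depresses_center_relative_to_notch_shoulder(self):
        spec = SyntheticSpec(
            chromosome_lengths=[400_000],
            n_origins=1,
            origin_efficiency_range=(1.5, 1.5),
            notch_depth=0.3,
            notch_width=2000,
            s_read_count=800_000,
            g2_read_count=0,
            nuc_read_count=0,
            seed=9,
        )
        genome, truth = make_genome(spec)
        s, _ = simulate_replication_reads(genome, truth, spec)
        (chrom, mu), = truth.origin_positions
        starts = s["start"].to_numpy()
        half = spec.notch_width / 2
        at_center = np.sum(np.abs(starts - mu) < 200)
        at_shoulder = (
            np.sum(np.abs(starts - (mu - half)) < 200)
            + np.sum(np.abs(starts - (mu + half)) < 200)
        ) / 2
        assert at_center < at_shoulder

    def test_empirical_coverage_tracks_generating_intensity(self):
        spec = SyntheticSpec(
            chromosome_lengths=[400_000],
            n_origins=8,
            s_read_count=1_000_000,  # deep enough that Poisson noise is small vs signal
            g2_read_count=0,
            nuc_read_count=0,
            seed=10,
        )
        genome, truth = make_genome(spec)
        s, _ = simulate_replication_reads(genome, truth, spec)
        lam = replication_intensity(spec, truth, "chr1")
        edges = np.arange(0, 400_001, 200)
        counts, _ = np.histogram(s["start"], bins=edges)
        expected = np.add.reduceat(lam, edges[:-1])[: len(counts)]
        r = np.corrcoef(counts, expected)[0, 1]
        assert r > 0.95


class TestNucleosomeReads:
    def test_no_nfrs_gives_flat_binned_occupancy(self):
        spec = SyntheticSpec(**{**SMALL, "n_origins": 0, "nuc_read_count": 400_000}, seed=11)
        genome, truth = make_genome(spec)
        reads = simulate_nucleosome_reads(genome, truth, spec)
        counts, _ = np.histogram(reads["start"], bins=np.arange(0, 400_001, 1000))
        assert counts.std() / counts.mean() < 0.1

    def test_intensity_near_zero_inside_origin_nfrs(self):
        spec = SyntheticSpec(**SMALL, seed=12)
        genome, truth = make_genome(spec)
        lam = nucleosome_intensity(spec, truth, "chr1")
        for (c, s, e), is_origin in zip(truth.nfr_intervals, truth.nfr_is_origin):
            if is_origin:
                assert lam[s:e].mean() < 0.15

    def test_origin_nfrs_deeper_and_broader_than_others(self):
        spec = SyntheticSpec(**SMALL, seed=13)
        genome, truth = make_genome(spec)
        lam = nucleosome_intensity(spec, truth, "chr1")
        ori = [(s, e) for (c, s, e), f in zip(truth.nfr_intervals, truth.nfr_is_origin) if f]
        non = [(s, e) for (c, s, e), f in zip(truth.nfr_intervals, truth.nfr_is_origin) if not f]
        assert non, "fixture should generate non-origin NFRs"
        ori_depth = np.mean([lam[s:e].mean() for s, e in ori])
        non_depth = np.mean([lam[s:e].mean() for s, e in non])
        assert ori_depth < non_depth
        assert np.mean([e - s for s, e in ori]) > np.mean([e - s for s, e in non])


class TestPlantMotifs:
    PWMS = [PWM.from_consensus("m1", "ACGTACGTAC")]

    def test_empty_placement_leaves_genome_unchanged(self):
        genome = {"c": "ACGT" * 1000}
        out, instances = plant_motifs(genome, self.PWMS, [])
        assert out == genome and instances == []

    def test_planted_consensus_is_top_scan_hit(self):
        rng = np.random.default_rng(0)
        genome = {"c": "".join(rng.choice(list("ACGT"), 4000, p=[0.2, 0.3, 0.3, 0.2]))}
        out, instances = plant_motifs(genome, self.PWMS, [("c", 2000, "m1")])
        lo = self.PWMS[0].log_odds()
        w = len(lo)
        scores = [
            sum(lo[i, "ACGT".index(b)] for i, b in enumerate(out["c"][j : j + w]))
            for j in range(len(out["c"]) - w + 1)
        ]
        assert int(np.argmax(scores)) == 2000

    def test_overlapping_placements_listed_in_error(self):
        genome = {"c": "ACGT" * 1000}
        with pytest.raises(ValueError, match="overlapping"):
            plant_motifs(genome, self.PWMS, [("c", 100, "m1"), ("c", 105, "m1")])


class TestDeterminism:
    def test_fixed_seed_reproduces_dataset_bytes(self, tmp_path):
        spec = SyntheticSpec(**{**SMALL, "s_read_count": 5000, "g2_read_count": 5000,
                                "nuc_read_count": 5000})
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(spec, d1)
        simulate_dataset(spec, d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
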