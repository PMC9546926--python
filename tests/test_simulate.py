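"""Generator contracts: non-overlap, determinism, planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gvmine import simulate as sim


@pytest.fixture(scope="module")
def two_genomes():
    g1 = sim.random_genome("gA", "viral", 400_000, seed=1)
    g2 = sim.random_genome("gB", "bacterial", 400_000, seed=2)
    return g1, g2


class TestShredGenome:
    def test_pigeonhole_bound_and_conservation(self, two_genomes):
        g1, _ = two_genomes
        genome = sim.SourceGenome("g", "viral", g1.sequence[:100_000])
        contigs = sim.shred_genome(genome, seed=0)
        assert len(contigs) <= 10  # 100 kb / 10 kb minimum
        assert sum(c.length for c in contigs) <= 100_000
        assert all(
            sim.LengthDistribution().min_len <= c.length <= sim.LengthDistribution().max_len
            for c in contigs
        )

    def test_deterministic_under_seed(self, two_genomes):
        g1, _ = two_genomes
        assert sim.shred_genome(g1, seed=7) == sim.shred_genome(g1, seed=7)

    def test_genome_shorter_than_min_len_warns_empty(self):
        genome = sim.random_genome("tiny", "bacterial", 9_999, seed=0)
        with pytest.warns(UserWarning, match="shorter than"):
            assert sim.shred_genome(genome, seed=0) == []

    def test_intervals_never_overlap(self, two_genomes):
        g1, _ = two_genomes
        for seed in range(5):
            contigs = sim.shred_genome(g1, seed=seed)
            intervals = sorted(
                (s.start, s.end) for c in contigs for s in c.segments
            )
            for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
                assert b1 <= a2

    def test_empirical_family(self, two_genomes):
        g1, _ = two_genomes
        dist = sim.LengthDistribution(
            family="empirical", lengths=(12_000, 15_000), min_len=10_000, max_len=20_000
        )
        contigs = sim.shred_genome(g1, dist, seed=0)
        # the genome tail may truncate the final draw; every other length
        # comes straight from the pool, and all stay within bounds
        assert set(c.length for c in contigs[:-1]) <= {12_000, 15_000}
        assert all(10_000 <= c.length <= 20_000 for c in contigs)


class TestPlantChimeras:
    @pytest.fixture(scope="class")
    def contigs(self, two_genomes):
        g1, g2 = two_genomes
        return sim.shred_genome(g1, seed=3) + sim.shred_genome(g2, seed=4)

    def test_rate_zero_is_identity(self, contigs):
        assert sim.plant_chimeras(contigs, 0.0, seed=0) == contigs
        assert not any(c.is_chimera for c in contigs)

    def test_rate_one_saturates(self, contigs):
        out = sim.plant_chimeras(contigs, 1.0, seed=0)
        for c in out:
            if c.is_chimera:
                assert len(c.source_genome_ids) == 2
        # at rate 1 essentially every contig is replaced
        assert sum(c.is_chimera for c in out) == len(out)

    def test_planted_count_within_binomial_ci(self, two_genomes):
        g1, g2 = two_genomes
        big1 = sim.SourceGenome("gA", "viral", g1.sequence * 40)
        big2 = sim.SourceGenome("gB", "bacterial", g2.sequence * 40)
        contigs = (sim.shred_genome(big1, seed=5) + sim.shred_genome(big2, seed=6))[:1000]
        assert len(contigs) == 1000
        out = sim.plant_chimeras(contigs, 0.05, seed=0)
        lo, hi = stats.binom.interval(0.95, 1000, 0.05)
        assert lo <= sum(c.is_chimera for c in out) <= hi

    def test_length_and_count_preserved(self, contigs):
        out = sim.plant_chimeras(contigs, 0.5, seed=1)
        assert len(out) == len(contigs)
        assert [c.length for c in out] == [c.length for c in contigs]

    def test_labels_recoverable_from_provenance(self, contigs):
        out = sim.plant_chimeras(contigs, 0.3, seed=2)
        for c in out:
            assert c.is_chimera == (len(set(s.genome_id for s in c.segments)) >= 2)

    def test_single_genome_is_an_error(self, two_genomes):
        g1, _ = two_genomes
        contigs = sim.shred_genome(g1, seed=0)
        with pytest.raises(ValueError, match="two source genomes"):
            sim.plant_chimeras(contigs, 0.1, seed=0)

    def test_deterministic(self, contigs):
        a = sim.plant_chimeras(contigs, 0.2, seed=9)
        b = sim.plant_chimeras(contigs, 0.2, seed=9)
        assert a == b


class TestHitCounts:
    @staticmethod
    def fixed_length_contigs(n, length=10_000, label="viral"):
        return [
            sim.SimulatedContig(
                f"c{i}", (sim.Segment("g", i * length, (i + 1) * length),), label, False
            )
            for i in range(n)
        ]

    def test_zero_rate_gives_zero_counts(self):
        contigs = self.fixed_length_contigs(100, label="bacterial")
        model = sim.HitCountModel(
            viral_rate_per_kb={"bacterial": 0.0},
            cellular_rate_per_kb={"bacterial": 2.0},
            seed=0,
        )
        table = sim.simulate_hit_counts(contigs, model)
        assert (table["viral_orf_count"] == 0).all()

    def test_mean_converges_to_rate_times_length(self):
        # law of large numbers: mean of n=10,000 Poisson counts with mean 5
        # is within 3 standard errors of 5
        contigs = self.fixed_length_contigs(10_000)
        model = sim.HitCountModel.well_separated(seed=42)
        table = sim.simulate_hit_counts(contigs, model)
        expected = 0.5 * 10  # rate/kb * kb
        se = np.sqrt(expected / len(contigs))
        assert abs(table["viral_orf_count"].mean() - expected) < 3 * se

    def test_deterministic(self):
        contigs = self.fixed_length_contigs(50)
        model = sim.HitCountModel.well_separated(seed=5)
        pd.testing.assert_frame_equal(
            sim.simulate_hit_counts(contigs, model),
            sim.simulate_hit_counts(contigs, model),
        )

    def test_missing_class_rate_names_the_class(self):
        contigs = self.fixed_length_contigs(5, label="eukaryotic")
        model = sim.HitCountModel(
            viral_rate_per_kb={"viral": 1.0}, cellular_rate_per_kb={"viral": 1.0}
        )
        with pytest.raises(ValueError, match="eukaryotic"):
            sim.simulate_hit_counts(contigs, model)

    def test_overdispersed_counts_have_larger_variance(self):
        contigs = self.fixed_length_contigs(5_000)
        poisson = sim.simulate_hit_counts(
            contigs, sim.HitCountModel.well_separated(seed=1)
        )
        nb = sim.simulate_hit_counts(
            contigs, sim.HitCountModel.well_separated(seed=1, dispersion=0.5)
        )
        assert nb["viral_orf_count"].var() > poisson["viral_orf_count"].var() * 2


class TestAbundanceMatrix:
    def test_default_sample_count_is_eleven(self):
        m = sim.simulate_abundance_matrix(["a", "b", "c"], seed=0)
        assert m.shape == (11, 3)
        assert (m.to_numpy() >= 0).all()

    def test_perfect_association_has_identical_ranks(self):
        m = sim.simulate_abundance_matrix(
            ["v1", "e1", "x"], planted_pairs=[("v1", "e1", 1.0)], seed=3
        )
        assert (m["v1"].rank() == m["e1"].rank()).all()

    def test_null_mean_abs_rho_matches_permutation_oracle(self):
        # 1,000 independent pairs at n=11 vs the permutation-null E|rho|
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(2000)]
        m = sim.simulate_abundance_matrix(taxa, seed=1)
        rhos = [
            stats.spearmanr(m[f"t{2 * i}"], m[f"t{2 * i + 1}"]).statistic
            for i in range(1000)
        ]
        null = [
            stats.spearmanr(np.arange(11), rng.permutation(11)).statistic
            for _ in range(5000)
        ]
        assert abs(np.mean(np.abs(rhos)) - np.mean(np.abs(null))) < 0.02

    def test_duplicate_taxa_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            sim.simulate_abundance_matrix(["a", "a", "b"], seed=0)

    def test_deterministic(self):
        a = sim.simulate_abundance_matrix(["a", "b"], seed=4)
        b = sim.simulate_abundance_matrix(["a", "b"], seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestControlDataset:
    def test_class_balance_and_determinism(self):
        ev1, contigs = sim.simulate_control_dataset(n_per_class=30, seed=2)
        ev2, _ = sim.simulate_control_dataset(n_per_class=30, seed=2)
        assert ev1["truth_class"].value_counts().to_dict() == {
            c: 30 for c in sim.CLASS_LABELS
        }
        pd.testing.assert_frame_equal(ev1, ev2)

    def test_truth_alignments_cover_each_segment(self, two_genomes):
        g1, g2 = two_genomes
        contigs = sim.plant_chimeras(
            sim.shred_genome(g1, seed=1) + sim.shred_genome(g2, seed=2), 0.5, seed=3
        )
        matches = sim.truth_alignments(contigs)
        by_query = {}
        for m in matches:
            by_query.setdefault(m.query_id, []).append(m)
        for c in contigs:
            ms = sorted(by_query[c.contig_id], key=lambda m: m.qstart)
            assert ms[0].qstart == 1
            assert ms[-1].qend == c.length
            assert len(ms) == len(c.segments)


def test_fasta_and_truth_roundtrip(tmp_path, two_genomes):
    g1, g2 = two_genomes
    contigs = sim.shred_genome(g1, seed=0)[:3]
    sim.write_contigs_fasta(contigs, {"gA": g1}, tmp_path / "contigs.fasta")
    from Bio import SeqIO

    records = list(SeqIO.parse(str(tmp_path / "contigs.fasta"), "fasta"))
    assert [r.id for r in records] == [c.contig_id for c in contigs]
    assert [len(r.seq) for r in records] == [c.length for c in contigs]
    seg = contigs[0].segments[0]
    assert str(records[0].seq) == g1.sequence[seg.start : seg.end]

    sim.write_truth_table(contigs, tmp_path / "truth.tsv")
    truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
    assert list(truth["contig_id"]) == [c.contig_id for c in contigs]
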