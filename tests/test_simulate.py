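"""The synthetic-data generator: determinism, read sampling, ground truth."""

import numpy as np
import pytest
from scipy import stats

from probenet.simulate import (MicrobeSpec, SimulationConfig, plant_contaminants,
                               simulate_host, simulate_microbes, simulate_reads,
                               simulate_study, synthetic_reference_collection)


def small_config(**kw):
    defaults = dict(
        rng_seed=11,
        host_cell_count=10.0,
        microbes=[MicrobeSpec("Bacillus simulans", "B1", 0.1, rbpc=2000.0)],
        reads_per_sample=500,
        host_filler_transcripts=5,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_study(self):
        a = simulate_study(small_config())
        b = simulate_study(small_config())
        assert a.host_transcripts == b.host_transcripts
        assert [s.reads for s in a.samples] == [s.reads for s in b.samples]
        assert all(x.truth.equals(y.truth) for x, y in zip(a.samples, b.samples))

    def test_different_seed_changes_reads(self):
        a = simulate_study(small_config())
        b = simulate_study(small_config(rng_seed=12))
        assert a.samples[0].reads != b.samples[0].reads

    def test_config_round_trips_through_yaml(self):
        cfg = small_config(read_error_rate=0.01, sample_count=3)
        restored = SimulationConfig.from_yaml(cfg.to_yaml())
        assert restored == cfg


class TestHostPool:
    def test_zero_host_cells_gives_empty_pool(self):
        rng = np.random.default_rng(0)
        _, pool, _ = simulate_host(small_config(host_cell_count=0.0), rng)
        assert pool == []

    def test_housekeeping_copies_scale_with_cells(self):
        rng = np.random.default_rng(0)
        _, pool, _ = simulate_host(small_config(), rng)
        hk = {e.origin: e.copies for e in pool if e.origin.startswith("housekeeping")}
        assert hk == {"housekeeping:PGK1": 500.0, "housekeeping:NSE": 500.0}

    def test_hk_probes_are_64mers_cut_from_the_transcript(self):
        rng = np.random.default_rng(0)
        transcripts, _, hk_probes = simulate_host(small_config(), rng)
        seqs = dict(transcripts)
        for gene, probes in hk_probes.items():
            for name, probe in probes:
                assert len(probe) == 64
                assert probe in seqs[f"host_{gene}"]


class TestMicrobePool:
    def test_copy_number_is_theta_cells_rbpc(self):
        rng = np.random.default_rng(0)
        cfg = small_config()
        _, pool = simulate_microbes(cfg, rng)
        assert pool[0].copies == pytest.approx(0.1 * 10.0 * 2000.0)

    def test_zero_abundance_organism_contributes_no_reads(self):
        cfg = small_config(microbes=[MicrobeSpec("Absent missing", "B0", 0.0)])
        study = simulate_study(cfg)
        assert not study.samples[0].truth.origin.str.startswith("microbe").any()

    def test_doubling_rbpc_doubles_expected_reads_at_fixed_theta(self):
        # at trace abundance the pool denominator is unchanged, so the
        # expected readcount is proportional to RBPC
        base = simulate_study(small_config(
            microbes=[MicrobeSpec("Bacillus simulans", "B1", 0.001, rbpc=2000.0)]))
        double = simulate_study(small_config(
            microbes=[MicrobeSpec("Bacillus simulans", "B1", 0.001, rbpc=4000.0)]))
        key = "microbe:Bacillus simulans"
        ratio = double.expected_reads[key] / base.expected_reads[key]
        assert ratio == pytest.approx(2.0, rel=0.02)


class TestReads:
    def test_error_free_reads_are_substrings_of_their_source(self):
        study = simulate_study(small_config())
        sources = dict(study.host_transcripts)
        sources.update({f"rRNA_{s.species_name}": s.sequence
                        for s in study.rrna_sources})
        from probenet.aligner import reverse_complement
        sample = study.samples[0]
        truth = sample.truth.set_index("read_id")
        for read_id, seq in sample.reads:
            row = truth.loc[read_id]
            source = sources[row.source]
            if row.strand == "-":
                seq = reverse_complement(seq)
            assert source[row.start:row.start + len(seq)] == seq

    def test_error_rate_perturbs_reads_at_expected_frequency(self):
        from probenet.aligner import reverse_complement
        noisy = simulate_study(small_config(read_error_rate=0.02,
                                            reads_per_sample=1000))
        sources = dict(noisy.host_transcripts)
        sources.update({f"rRNA_{s.species_name}": s.sequence
                        for s in noisy.rrna_sources})
        truth = noisy.samples[0].truth.set_index("read_id")
        diffs = total = 0
        for read_id, seq in noisy.samples[0].reads:
            row = truth.loc[read_id]
            if row.strand == "-":
                seq = reverse_complement(seq)
            original = sources[row.source][row.start:row.start + len(seq)]
            diffs += sum(x != y for x, y in zip(seq, original))
            total += len(seq)
        assert 0.015 < diffs / total < 0.025

    def test_strand_fractions_are_balanced(self):
        study = simulate_study(small_config(reads_per_sample=2000))
        plus = (study.samples[0].truth.strand == "+").sum()
        assert stats.binomtest(plus, 2000, 0.5).pvalue > 1e-4

    def test_read_longer_than_source_is_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        cfg = small_config(read_length=5000)
        _, pool, _ = simulate_host(cfg, rng)
        import logging
        with caplog.at_level(logging.WARNING):
            sample = simulate_reads(pool, cfg, rng)
        assert sample.reads == []
        assert "shorter than read length" in caplog.text

    def test_expected_housekeeping_counts_match_binomial_expectation(self):
        """Mean PGK1-origin read count over replicates is the pool-fraction
        expectation, within 3 sigma of the binomial spread."""
        cfg = small_config(reads_per_sample=1000, sample_count=25)
        study = simulate_study(cfg)
        expected = study.expected_reads["housekeeping:PGK1"]
        counts = [s.truth.origin.eq("housekeeping:PGK1").sum()
                  for s in study.samples]
        n = cfg.reads_per_sample
        p = expected / n
        sigma_of_mean = np.sqrt(n * p * (1 - p) / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * sigma_of_mean


class TestContaminants:
    def test_contaminants_are_identical_across_samples(self):
        cfg = small_config(
            sample_count=3,
            contaminants=[MicrobeSpec("Ralstonia contaminans", "B4", 0.5)])
        rng = np.random.default_rng(cfg.rng_seed)
        _, host_pool, _ = simulate_host(cfg, rng)
        pools = [list(host_pool) for _ in range(3)]
        plant_contaminants(pools, cfg, rng)
        entries = [[(e.name, e.sequence, e.copies) for e in pool
                    if e.origin.startswith("contaminant")] for pool in pools]
        assert entries[0] == entries[1] == entries[2]
        assert entries[0]

    def test_no_contaminants_is_identity(self):
        cfg = small_config()
        rng = np.random.default_rng(0)
        pools = [[]]
        assert plant_contaminants(pools, cfg, rng) == [[]]


class TestSyntheticReferenceCollection:
    def test_collection_size_and_composition(self):
        coll = synthetic_reference_collection(rng_seed=0)
        assert len(coll) == 1017
        assert len(set(p.name for p in coll)) == 1017
        assert all(len(p.sequence) == 64 for p in coll)

    def test_seed_reproducibility(self):
        a = synthetic_reference_collection(rng_seed=5)
        b = synthetic_reference_collection(rng_seed=5)
        assert [(p.name, p.sequence) for p in a] == [(p.name, p.sequence) for p in b]

    def test_small_composition_has_planted_redundancy(self):
        from probenet.probes import compute_redundancy, redundancy_histogram
        coll = synthetic_reference_collection(rng_seed=1, group_sizes=[1] * 5 + [2, 3])
        compute_redundancy(coll)
        assert redundancy_histogram(coll) == \
            {"1": 5, "2": 2, "3-5": 3, "6-19": 0, ">=20": 0}
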