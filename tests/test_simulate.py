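"""Simulator contracts: determinism, conservation, and the divergence law."""

import numpy as np
import pytest

from retrozyme.annotate import count_ltr_mismatches
from retrozyme.seq_io import revcomp
from retrozyme.simulate import (
    GenomeSimConfig,
    ReplicationSimConfig,
    insert_tag,
    simulate_genome,
    simulate_reads,
    simulate_replication,
    TAG_24NT,
)

from conftest import random_dna


class TestGenomeSim:
    def test_same_seed_is_byte_identical(self):
        cfg = GenomeSimConfig(seed=99)
        s1, t1 = simulate_genome(cfg)
        s2, t2 = simulate_genome(GenomeSimConfig(seed=99))
        assert [(a.id, a.seq) for a in s1] == [(b.id, b.seq) for b in s2]
        assert len(t1.loci) == len(t2.loci)

    def test_conservation_of_planted_elements(self, default_sim):
        cfg, _scaffolds, truth = default_sim
        assert len(truth.loci) == cfg.n_full + cfg.n_cr_partial + cfg.n_ltr_fragment
        by_kind = {}
        for l in truth.loci:
            by_kind[l.completeness] = by_kind.get(l.completeness, 0) + 1
        assert by_kind == {
            "full": cfg.n_full,
            "cr_partial": cfg.n_cr_partial,
            "ltr_fragment": cfg.n_ltr_fragment,
        }

    def test_planted_ltr_divergence_is_exact(self, default_sim):
        cfg, scaffolds, truth = default_sim
        seqs = {s.id: s.seq for s in scaffolds}
        for locus in truth.loci:
            if locus.completeness != "full":
                continue
            seq = seqs[locus.scaffold_id]
            d = count_ltr_mismatches(
                seq[locus.ltr5.start : locus.ltr5.end],
                seq[locus.ltr3.start : locus.ltr3.end],
            )
            assert d == locus.ltr_mismatches

    def test_zero_divergence_config(self):
        cfg = GenomeSimConfig(
            n_full=1, n_cr_partial=0, n_ltr_fragment=0,
            full_groups=["Group 1"], ltr_divergence=[0], tandem_loci=[], seed=5,
        )
        scaffolds, truth = simulate_genome(cfg)
        locus = truth.loci[0]
        seq = {s.id: s.seq for s in scaffolds}[locus.scaffold_id]
        assert (
            seq[locus.ltr5.start : locus.ltr5.end]
            == seq[locus.ltr3.start : locus.ltr3.end]
        )

    def test_tsd_planted_as_exact_duplication(self, default_sim):
        _cfg, scaffolds, truth = default_sim
        seqs = {s.id: s.seq for s in scaffolds}
        for locus in truth.loci:
            if locus.completeness != "full":
                continue
            seq = seqs[locus.scaffold_id]
            span = locus.span
            assert locus.tsd == seq[span.start - 4 : span.start] == seq[span.end : span.end + 4]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="ltr_divergence"):
            GenomeSimConfig(n_full=2, full_groups=["Group 1", "Group 1"],
                            ltr_divergence=[1]).validate()


class TestReplicationSim:
    def test_zero_error_rate_preserves_population(self, rng):
        circle = random_dna(rng, 400)
        cfg = ReplicationSimConfig(n_molecules=20, rounds_distribution={10: 1.0},
                                   error_rate=0.0, seed=1)
        population, truth = simulate_replication(circle, cfg)
        assert all(seq == circle for _, seq in population)
        assert all(subs == () for _, subs in truth.molecule_lineages.values())

    def test_degenerate_zero_rounds(self, rng):
        circle = random_dna(rng, 400)
        cfg = ReplicationSimConfig(n_molecules=20, rounds_distribution={0: 1.0},
                                   error_rate=0.01, seed=1)
        population, _ = simulate_replication(circle, cfg)
        assert all(seq == circle for _, seq in population)

    def test_divergence_matches_closed_form(self):
        rng = np.random.default_rng(8)
        circle = random_dna(rng, 800)
        eps, r, n = 0.001, 10, 2000
        cfg = ReplicationSimConfig(n_molecules=n, rounds_distribution={r: 1.0},
                                   error_rate=eps, seed=2)
        population, truth = simulate_replication(circle, cfg)
        divs = np.array([
            len(subs) / len(circle) for _, subs in truth.molecule_lineages.values()
        ])
        expected = 1 - (1 - eps) ** r
        se = divs.std(ddof=1) / np.sqrt(n)
        assert abs(divs.mean() - expected) <= 3 * se

    def test_rounds_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums"):
            ReplicationSimConfig(rounds_distribution={1: 0.6, 2: 0.6}).validate()

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError, match="error_rate"):
            ReplicationSimConfig(error_rate=0.1).validate()


class TestReadSim:
    def test_reads_have_origins_and_match_their_molecule(self, rng):
        circle = random_dna(rng, 500)
        population = [("m1", circle)]
        reads, truth = simulate_reads(population, n_reads=50, read_len=100, seed=3)
        assert len(reads) == len(truth.read_origins) == 50
        doubled = circle + circle
        for read in reads:
            mol, start, strand = truth.read_origins[read.id]
            expected = doubled[start : start + 100]
            if strand == "-":
                expected = revcomp(expected)
            assert read.seq == expected

    def test_zero_reads(self, rng):
        reads, truth = simulate_reads([("m", random_dna(rng, 200))], 0, 100, seed=1)
        assert reads == [] and truth.read_origins == {}

    def test_read_longer_than_molecule_rejected(self, rng):
        with pytest.raises(ValueError, match="read_len"):
            simulate_reads([("m", random_dna(rng, 50))], 1, 100, seed=1)


class TestTag:
    def test_tag_insertion_detected_with_correct_length(self, rng):
        from retrozyme.rna import find_insertion

        monomer = random_dna(rng, 900)
        tagged = insert_tag(monomer, (350, 900))
        found = find_insertion(tagged, monomer)
        assert found is not None
        pos, inserted = found
        assert inserted == TAG_24NT
        assert 350 <= pos <= 900

    def test_untagged_sequence_yields_none(self, rng):
        from retrozyme.rna import find_insertion

        monomer = random_dna(rng, 900)
        assert find_insertion(monomer, monomer) is None
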