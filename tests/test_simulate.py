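"""Simulator: genome/gene placement, insertion library, selection, reads."""

import numpy as np
import pytest
from scipy import stats

from haploscreen import (
    ScreenSimConfig,
    apply_selection,
    generate_genome,
    simulate_insertions,
    synthesize_reads,
)
from haploscreen.simulate import RESTRICTION_MOTIFS, revcomp


class TestGenerateGenome:
    def test_models_within_bounds(self, small_config, small_genome):
        genome, models = small_genome
        assert len(models) == small_config.n_genes
        for m in models:
            assert 0 <= m.start < m.end <= genome.length(m.chromosome)

    def test_seeded_determinism(self, small_config):
        g1, m1 = generate_genome(small_config)
        g2, m2 = generate_genome(small_config)
        assert g1.sequences == g2.sequences
        assert m1 == m2

    def test_exon_structure(self, small_genome):
        _, models = small_genome
        for m in models:
            assert len(m.exons) == 3
            for (s1, e1), (s2, e2) in zip(m.exons, m.exons[1:]):
                assert s1 < e1 <= s2 < e2
                assert s2 - e1 >= 50  # intron floor

    def test_no_overlap_by_default(self, small_genome):
        _, models = small_genome
        by_chrom = {}
        for m in models:
            by_chrom.setdefault(m.chromosome, []).append((m.start, m.end))
        for spans in by_chrom.values():
            spans.sort()
            for (_, e1), (s2, _) in zip(spans, spans[1:]):
                assert s2 >= e1

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            ScreenSimConfig(n_chromosomes=1, chromosome_length=10_000,
                            n_genes=10, gene_span=3_000)

    def test_alphabet(self, small_genome):
        genome, _ = small_genome
        for seq in genome.sequences.values():
            assert set(seq) <= set("ACGT")


class TestSimulateInsertions:
    def test_count_and_bounds(self, small_config, small_genome):
        genome, _ = small_genome
        events = simulate_insertions(genome, small_config)
        assert len(events) == small_config.n_insertions
        for e in events:
            assert 0 <= e.position < genome.length(e.chromosome)

    def test_orientation_balance(self, small_genome):
        """Orientations are a fair coin: exact binomial test at n=10,000."""
        genome, _ = small_genome
        cfg = ScreenSimConfig(n_insertions=10_000, seed=7)
        events = simulate_insertions(genome, cfg)
        n_plus = sum(e.orientation == "+" for e in events)
        p = stats.binomtest(n_plus, len(events), 0.5).pvalue
        assert p > 0.001

    def test_deterministic(self, small_config, small_genome):
        genome, _ = small_genome
        assert simulate_insertions(genome, small_config) == simulate_insertions(
            genome, small_config
        )

    def test_rejects_nonpositive(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError):
            simulate_insertions(genome, ScreenSimConfig(n_insertions=0))


class TestApplySelection:
    def test_degenerate_probabilities(self, small_genome):
        """background=0, resistant=1: survivors are exactly the events that
        inactivate a resistance gene."""
        genome, models = small_genome
        from haploscreen.annotation import classify_insertion, index_models

        target = models[0].gene_id
        cfg = ScreenSimConfig(seed=2, n_insertions=5_000,
                              resistance_genes=frozenset({target}),
                              p_survive_resistant=1.0, p_survive_background=0.0)
        events = simulate_insertions(genome, cfg)
        survivors = apply_selection(events, models, cfg)
        index = index_models(models)
        expected = [
            e for e in events
            if any(g == target and inact for g, inact in
                   classify_insertion(e.chromosome, e.position, e.orientation, index))
        ]
        assert survivors == expected
        assert len(survivors) > 0

    def test_neutral_selection_composition(self, small_genome):
        """Equal survival probabilities: per-chromosome survivor composition
        matches the library (chi-square not rejected at alpha=0.001)."""
        genome, models = small_genome
        cfg = ScreenSimConfig(seed=3, n_insertions=10_000,
                              p_survive_resistant=0.3, p_survive_background=0.3)
        events = simulate_insertions(genome, cfg)
        survivors = apply_selection(events, models, cfg)
        chroms = genome.chromosomes
        lib = np.array([sum(e.chromosome == c for e in events) for c in chroms])
        surv = np.array([sum(e.chromosome == c for e in survivors) for c in chroms])
        expected = lib / lib.sum() * surv.sum()
        p = stats.chisquare(surv, expected).pvalue
        assert p > 0.001

    def test_empty_resistance_zero_background(self, small_genome):
        genome, models = small_genome
        cfg = ScreenSimConfig(seed=4, n_insertions=100, p_survive_background=0.0)
        events = simulate_insertions(genome, cfg)
        assert apply_selection(events, models, cfg) == []

    def test_unknown_resistance_gene(self, small_genome):
        genome, models = small_genome
        cfg = ScreenSimConfig(seed=4, resistance_genes=frozenset({"nope"}))
        events = simulate_insertions(genome, cfg)
        with pytest.raises(ValueError, match="nope"):
            apply_selection(events, models, cfg)

    def test_survivors_subset_of_library(self, small_genome):
        genome, models = small_genome
        cfg = ScreenSimConfig(seed=5, n_insertions=2_000,
                              p_survive_resistant=0.5, p_survive_background=0.05)
        events = simulate_insertions(genome, cfg)
        survivors = apply_selection(events, models, cfg)
        assert set(survivors) <= set(events)


@pytest.fixture(scope="module")
def readset(small_genome):
    genome, models = small_genome
    cfg = ScreenSimConfig(seed=6, n_insertions=500,
                          p_survive_resistant=0.5, p_survive_background=0.5)
    events = simulate_insertions(genome, cfg)
    survivors = apply_selection(events, models, cfg)
    return genome, cfg, survivors, synthesize_reads(survivors, genome, cfg)


class TestSynthesizeReads:
    def test_read_conservation(self, readset):
        _, _, survivors, rs = readset
        assert len(rs.reads) == sum(t.n_reads for t in rs.truth)
        assert len(rs.truth) == len(survivors)
        assert all(t.n_reads >= 1 for t in rs.truth if not t.skipped)

    def test_reads_match_genome(self, readset):
        """Each read is the genomic sequence at its event, in proviral
        orientation, truncated through the first TTAA/CATG."""
        genome, cfg, _, rs = readset
        by_read = rs.truth_by_read()
        for read_id, seq in rs.reads[:200]:
            t = by_read[read_id]
            chrom_seq = genome[t.chromosome]
            if t.orientation == "+":
                ref = chrom_seq[t.position : t.position + cfg.read_length]
            else:
                start = max(0, t.position - cfg.read_length + 1)
                ref = revcomp(chrom_seq[start : t.position + 1])
            assert ref.startswith(seq)
            # truncation rule: any internal motif ends exactly at the read end
            interior = seq[:-1]
            for motif in RESTRICTION_MOTIFS:
                i = interior.find(motif)
                assert i < 0 or i + len(motif) >= len(seq)

    def test_truncation_length(self):
        """A motif beginning 20 bases downstream yields a 24-base read."""
        from haploscreen.simulate import _truncate_at_motif

        seq = "G" * 20 + "TTAA" + "G" * 26
        assert _truncate_at_motif(seq) == "G" * 20 + "TTAA"
        assert len(_truncate_at_motif(seq)) == 24

    def test_near_telomere_event_skipped(self, small_genome):
        genome, _ = small_genome
        from haploscreen.models import InsertionEvent

        cfg = ScreenSimConfig(seed=8)
        events = [InsertionEvent(0, "chr1", 3, "+"),      # 3' end too close? no: + reads right
                  InsertionEvent(1, "chr1", 3, "-")]      # only 4 bases leftward
        with pytest.warns(UserWarning, match="skipped"):
            rs = synthesize_reads(events, genome, cfg)
        skipped = {t.cell_id for t in rs.truth if t.skipped}
        assert skipped == {1}
        assert all(not t.skipped or t.n_reads == 0 for t in rs.truth)
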