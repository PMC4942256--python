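"""Trimming and unique exact-match mapping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploscreen import ScreenSimConfig, map_reads, trim_at_restriction_site
from haploscreen.mapping import import_external_alignments, strip_vector_prefix
from haploscreen.simulate import SyntheticGenome, revcomp

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestTrim:
    @pytest.mark.parametrize(
        "read,expected",
        [
            ("ACGTTTAACCGGTT", "ACGTTTAA"),
            ("CATGACGT", "CATG"),
            ("ACGT" * 12 + "GG", "ACGT" * 12 + "GG"),  # no motif: unchanged
            ("TTAACATG", "TTAA"),                      # leftmost motif wins
            ("GCATGTTAAG", "GCATG"),
        ],
    )
    def test_examples(self, read, expected):
        assert trim_at_restriction_site(read) == expected

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            trim_at_restriction_site("")

    @settings(derandomize=True, max_examples=300)
    @given(dna)
    def test_prefix_and_idempotent(self, read):
        trimmed = trim_at_restriction_site(read)
        assert read.startswith(trimmed)
        assert trim_at_restriction_site(trimmed) == trimmed

    def test_vector_prefix_stripped_before_trimming(self):
        # the vector carries its own CATG; stripping first prevents a bogus trim
        read = "GGCATGCC" + "ACGTTTAACC"
        assert strip_vector_prefix(read, "GGCATGCC") == "ACGTTTAACC"


def _clean_window(genome: SyntheticGenome, chrom: str, length: int = 40) -> tuple[int, str]:
    """First window with no restriction motif on either strand, so trimming
    leaves the read intact."""
    seq = genome[chrom]
    for start in range(len(seq) - length):
        w = seq[start : start + length]
        if all(m not in w and m not in revcomp(w) for m in ("TTAA", "CATG")):
            return start, w
    raise AssertionError("no motif-free window in test genome")


@pytest.fixture(scope="module")
def genome():
    # repeat-free by construction: short random chromosomes
    import numpy as np

    rng = np.random.default_rng(11)
    seqs = {
        c: "".join(rng.choice(list("ACGT"), size=300))
        for c in ("chr1", "chr2")
    }
    return SyntheticGenome(seqs)


class TestMapReads:
    def test_unique_read_recovers_coordinates(self, genome):
        start, seq = _clean_window(genome, "chr1")
        [site] = map_reads([("r1", seq)], genome, min_length=20)
        assert (site.chromosome, site.position, site.orientation) == ("chr1", start, "+")

    def test_reverse_read_reports_junction_base(self, genome):
        # a read sequenced leftward from the window's last base
        start, seq = _clean_window(genome, "chr1")
        [site] = map_reads([("r1", revcomp(seq))], genome, min_length=20)
        assert (site.chromosome, site.position, site.orientation) == (
            "chr1", start + len(seq) - 1, "-",
        )

    def test_repeat_discarded(self, genome):
        _, dup = _clean_window(genome, "chr1")
        two_copy_genome = SyntheticGenome(
            {"chr1": genome["chr1"], "chr2": genome["chr2"][:100] + dup}
        )
        assert map_reads([("r1", dup)], two_copy_genome, min_length=20) == []

    def test_mismatch_discarded(self, genome):
        _, seq = _clean_window(genome, "chr1")
        sub = "A" if seq[5] != "A" else "C"
        mutated = seq[:5] + sub + seq[6:]
        if any(m in mutated or m in revcomp(mutated) for m in ("TTAA", "CATG")):
            mutated = mutated[:20]  # still mismatched at base 5, motif-free prefix
        assert map_reads([("r1", mutated)], genome, min_length=20) == []

    def test_short_read_discarded(self, genome):
        start, seq = _clean_window(genome, "chr1")
        assert map_reads([("r1", seq[:15])], genome, min_length=20) == []

    def test_mapping_soundness_brute_force(self, genome):
        """Every emitted placement matches the genome exactly there and
        nowhere else (brute-force scan over both strands)."""
        reads = [(f"r{i}", genome["chr1"][i : i + 30]) for i in range(0, 200, 7)]
        reads += [(f"m{i}", revcomp(genome["chr2"][i : i + 30])) for i in range(0, 200, 13)]
        sites = map_reads(reads, genome, min_length=20)
        assert sites  # at least some place uniquely
        seq_by_id = dict(reads)
        for s in sites:
            read = trim_at_restriction_site(seq_by_id[s.read_id])
            if s.orientation == "+":
                expected = genome[s.chromosome][s.position : s.position + len(read)]
                assert expected == read
            else:
                left = s.position - len(read) + 1
                expected = genome[s.chromosome][left : s.position + 1]
                assert expected == revcomp(read)
            n_hits = sum(
                chrom_seq.count(read) + (revcomp(read) != read) * chrom_seq.count(revcomp(read))
                for chrom_seq in genome.sequences.values()
            )
            assert n_hits == 1

    def test_pipeline_identity_on_simulator_output(self, small_genome):
        """On a repeat-free synthetic genome, mapping recovers the truth-table
        junction coordinate for every non-skipped read of sufficient length."""
        from haploscreen import simulate_insertions, synthesize_reads

        genome, _ = small_genome
        cfg = ScreenSimConfig(seed=12, n_insertions=300)
        events = simulate_insertions(genome, cfg)
        rs = synthesize_reads(events, genome, cfg)
        by_read = rs.truth_by_read()
        sites = map_reads(rs.reads, genome, min_length=20)
        assert sites
        mapped_ids = set()
        for s in sites:
            t = by_read[s.read_id]
            assert (s.chromosome, s.position, s.orientation) == (
                t.chromosome, t.position, t.orientation,
            )
            mapped_ids.add(s.read_id)
        # unmapped reads must be short fragments, not mapper losses
        for read_id, seq in rs.reads:
            if read_id not in mapped_ids:
                assert len(trim_at_restriction_site(seq)) < 20


class TestImportExternalAlignments:
    HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:1000\n"

    def _write(self, tmp_path, records):
        path = tmp_path / "aln.sam"
        path.write_text(self.HEADER + "".join(records))
        return str(path)

    def test_coordinate_and_strand_conventions(self, tmp_path):
        recs = [
            "r1\t0\tchr1\t101\t30\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n",
            "r2\t16\tchr1\t201\t30\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n",
        ]
        sites = import_external_alignments(self._write(tmp_path, recs))
        assert [(s.read_id, s.position, s.orientation) for s in sites] == [
            ("r1", 100, "+"),
            ("r2", 200, "-"),
        ]

    def test_ambiguous_records_dropped(self, tmp_path):
        recs = [
            "r1\t256\tchr1\t101\t30\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n",  # secondary
            "r2\t2048\tchr1\t111\t30\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n",  # supplementary
            "r3\t0\tchr1\t121\t0\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n",      # MAPQ 0
            "r4\t0\tchr1\t131\t30\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n",
        ]
        sites = import_external_alignments(self._write(tmp_path, recs))
        assert [s.read_id for s in sites] == ["r4"]

    def test_unsorted_input_rejected(self, tmp_path):
        path = tmp_path / "aln.sam"
        path.write_text("@HD\tVN:1.6\tSO:queryname\n@SQ\tSN:chr1\tLN:1000\n")
        with pytest.raises(ValueError, match="sorted"):
            import_external_alignments(str(path))
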