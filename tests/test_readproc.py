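import gzip
import random

import pytest
from Bio.Seq import Seq

from umiamp.readproc import (
    AlignedRead,
    PanelAligner,
    ReadPairRecord,
    filter_alignment,
    ingest_tabular_alignments,
    parse_fastq_pairs,
)


# ---------------------------------------------------------------------------
# independent quadratic-time Gotoh local-alignment oracle
# ---------------------------------------------------------------------------
def gotoh_local_score(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Affine-gap local alignment score by full DP (gap of length L scores
    gap_open + (L-1)*gap_extend)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _fastq(path, records, gz=False):
    op = gzip.open if gz else open
    with op(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


class TestParseFastqPairs:
    def test_parses_matched_pairs(self, tmp_path):
        _fastq(tmp_path / "r1.fq", [("a/1", "ACGT"), ("b/1", "GGCC")])
        _fastq(tmp_path / "r2.fq", [("a/2", "TTTT"), ("b/2", "AAAA")])
        pairs = list(parse_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"))
        assert [p.read_id for p in pairs] == ["a", "b"]
        assert pairs[0].r1_seq == "ACGT" and pairs[0].r2_seq == "TTTT"

    def test_gzipped_input_identical(self, tmp_path):
        recs1 = [("a/1", "ACGTACGT")]
        recs2 = [("a/2", "TGCATGCA")]
        _fastq(tmp_path / "r1.fq", recs1)
        _fastq(tmp_path / "r2.fq", recs2)
        _fastq(tmp_path / "r1.fq.gz", recs1, gz=True)
        _fastq(tmp_path / "r2.fq.gz", recs2, gz=True)
        plain = list(parse_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"))
        zipped = list(parse_fastq_pairs(tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz"))
        assert plain == zipped

    def test_truncated_r2_raises(self, tmp_path):
        _fastq(tmp_path / "r1.fq", [("a/1", "ACGT"), ("b/1", "GGCC")])
        _fastq(tmp_path / "r2.fq", [("a/2", "TTTT")])
        with pytest.raises(ValueError, match="truncated"):
            list(parse_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"))

    def test_mate_name_mismatch_raises(self, tmp_path):
        _fastq(tmp_path / "r1.fq", [("a/1", "ACGT")])
        _fastq(tmp_path / "r2.fq", [("zzz/2", "TTTT")])
        with pytest.raises(ValueError, match="mismatch"):
            list(parse_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"))


class TestAlignRead:
    def test_exact_substring_hits_its_gene_at_full_identity(self, panel, aligner):
        g = panel.genes[0]
        sub = g.cdna_seq[10:160]
        a = aligner.align_read(sub)
        assert a.target == g.name
        assert a.matched_len == 150
        assert a.identity_pct == 100.0
        assert (a.target_start, a.target_end) == (11, 160)

    def test_reverse_complement_symmetric(self, panel, aligner):
        g = panel.genes[0]
        sub = g.cdna_seq[10:160]
        fwd = aligner.align_read(sub)
        rev = aligner.align_read(str(Seq(sub).reverse_complement()))
        assert (rev.target, rev.target_start, rev.target_end) == (
            fwd.target,
            fwd.target_start,
            fwd.target_end,
        )
        assert rev.strand == "-"

    def test_random_sequence_yields_none_matching_oracle(self, panel, aligner):
        rng = random.Random(99)
        seq = "".join(rng.choice("ACGT") for _ in range(150))
        # brute-force oracle over every target and strand
        best = max(
            gotoh_local_score(g.cdna_seq, q)
            for g in panel.genes
            for q in (seq, str(Seq(seq).reverse_complement()))
        )
        assert best < aligner.min_score
        assert aligner.align_read(seq) is None

    def test_score_matches_gotoh_oracle_on_small_instances(self, panel):
        small = PanelAligner(panel, min_score=5)
        rng = random.Random(5)
        g = panel.genes[1]
        for _ in range(15):
            start = rng.randrange(0, len(g.cdna_seq) - 60)
            frag = list(g.cdna_seq[start : start + 50])
            for _ in range(rng.randrange(0, 8)):  # mutate a few bases
                frag[rng.randrange(len(frag))] = rng.choice("ACGT")
            q = "".join(frag)
            a = small.align_read(q)
            oracle = max(
                gotoh_local_score(t.cdna_seq, p)
                for t in panel.genes
                for p in (q, str(Seq(q).reverse_complement()))
            )
            if a is None:
                assert oracle < small.min_score
            else:
                assert a.score == oracle

    def test_sampled_long_substrings_always_identity_100(self, panel, aligner):
        rng = random.Random(7)
        for _ in range(20):
            g = rng.choice(panel.genes)
            length = rng.randrange(90, len(g.cdna_seq) + 1)
            start = rng.randrange(0, len(g.cdna_seq) - length + 1)
            a = aligner.align_read(g.cdna_seq[start : start + length])
            assert a.target == g.name
            assert a.identity_pct == 100.0
            assert a.matched_len == length

    def test_empty_sequence_raises(self, aligner):
        with pytest.raises(ValueError):
            aligner.align_read("")

    def test_base_calls_report_the_read_bases(self, panel, aligner):
        g = panel.genes[0]
        sub = list(g.cdna_seq[:120])
        sub[50] = "A" if sub[50] != "A" else "G"  # one mismatch at target pos 51
        a = aligner.align_read("".join(sub))
        assert a.base_calls[51] == sub[50]
        assert a.base_calls[1] == g.cdna_seq[0]


class TestFilterAlignment:
    @pytest.mark.parametrize(
        "matched,identity,keep",
        [
            (90, 80.0, True),  # both boundaries are kept
            (89, 100.0, False),
            (200, 79.9, False),
            (150, 100.0, True),
        ],
    )
    def test_boundaries(self, matched, identity, keep):
        a = AlignedRead("r", "R1", "G", 1, matched, matched, identity)
        assert filter_alignment(a) is keep

    def test_monotone_in_length_and_identity(self):
        kept = [
            (m, i)
            for m in range(80, 101, 5)
            for i in (70.0, 80.0, 90.0)
            if filter_alignment(AlignedRead("r", "R1", "G", 1, m, m, i))
        ]
        for m, i in kept:  # increasing either argument never flips keep -> drop
            assert filter_alignment(AlignedRead("r", "R1", "G", 1, m + 10, m + 10, i))
            assert filter_alignment(AlignedRead("r", "R1", "G", 1, m, m, min(i + 10, 100.0)))


class TestIngestTabular:
    def _row(self, subject, length, identity):
        return (
            f"q1\t{subject}\t{identity}\t{length}\t2\t0\t1\t{length}\t5\t{4 + length}\t1e-30\t200"
        )

    def test_row_passing_filter(self, panel, tmp_path):
        path = tmp_path / "aln.tsv"
        path.write_text(self._row(panel.genes[0].name, 120, 95.0) + "\n")
        (a,) = list(ingest_tabular_alignments(path, panel))
        assert a.matched_len == 120 and a.identity_pct == 95.0
        assert filter_alignment(a)
        assert a.base_calls is None

    def test_unknown_subject_named_in_error(self, panel, tmp_path):
        path = tmp_path / "aln.tsv"
        path.write_text(self._row("NOT_A_GENE", 120, 95.0) + "\n")
        with pytest.raises(ValueError, match="NOT_A_GENE"):
            list(ingest_tabular_alignments(path, panel))

    def test_short_alignment_fails_filter(self, panel, tmp_path):
        path = tmp_path / "aln.tsv"
        path.write_text(self._row(panel.genes[0].name, 80, 99.0) + "\n")
        (a,) = list(ingest_tabular_alignments(path, panel))
        assert not filter_alignment(a)
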