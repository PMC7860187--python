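"""Paired FASTQ parsing and local alignment to the panel cDNA reference.

Reads are mapped to the panel's custom cDNA reference with an exact
affine-gap local aligner (match +1, mismatch -2, gap open -5, gap extend
-2), trying every target on both strands; the reference is tiny (tens of
kilobases), so full dynamic programming is fast.  A k-mer pre-screen picks
candidate targets per read; when no seed hits, every target is scanned, so
the pre-screen never changes which alignments are reachable.

Alignments are then filtered on the assay's two rules: matched region of
at least 90 nt and identity of at least 80% (reads *shorter* than 90 nt or
*below* 80% identity are removed, so the boundaries are kept).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import Align
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import TargetPanel

__all__ = [
    "ReadPairRecord",
    "AlignedRead",
    "QcTally",
    "parse_fastq_pairs",
    "PanelAligner",
    "filter_alignment",
    "ingest_tabular_alignments",
    "align_pairs",
]

MIN_MATCHED_LEN = 90
MIN_IDENTITY_PCT = 80.0

# floor below which a best local alignment is reported as "no hit"
MIN_ALIGN_SCORE = 30

_SEED_K = 15


@dataclass
class ReadPairRecord:
    read_id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str = ""
    r2_qual: str = ""

    def __post_init__(self) -> None:
        if self.r1_qual and len(self.r1_qual) != len(self.r1_seq):
            raise ValueError(f"{self.read_id}: R1 seq/qual length mismatch")
        if self.r2_qual and len(self.r2_qual) != len(self.r2_seq):
            raise ValueError(f"{self.read_id}: R2 seq/qual length mismatch")


@dataclass
class AlignedRead:
    """Placement of one mate on a target cDNA.

    ``base_calls`` maps 1-based target positions to the read base observed
    there (absent for gapped columns); it is ``None`` for alignments
    ingested from tabular files, which carry no per-base information.
    """

    read_id: str
    mate: str  # "R1" | "R2"
    target: str
    target_start: int  # 1-based closed interval on the cDNA
    target_end: int
    matched_len: int  # aligned (non-gap) columns
    identity_pct: float
    score: float = 0.0
    strand: str = "+"
    base_calls: dict[int, str] | None = field(default=None, repr=False)


@dataclass
class QcTally:
    """Per-library read accounting emitted alongside the counts."""

    pairs_in: int = 0
    r1_aligned: int = 0
    r2_aligned: int = 0
    r1_pass_filter: int = 0
    r2_pass_filter: int = 0
    target_consistent: int = 0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k, v in vars(self).items():
                fh.write(f"{k}\t{v}\n")


def _strip_mate_suffix(name: str) -> str:
    base = name.split()[0]
    if base.endswith("/1") or base.endswith("/2"):
        base = base[:-2]
    return base


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def parse_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPairRecord]:
    """Stream read pairs from matched R1/R2 FASTQ files (optionally gzipped).

    Raises ``ValueError`` on mate-name mismatch or a truncated file.
    """
    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for title1, seq1, qual1 in it1:
            try:
                title2, seq2, qual2 = next(it2)
            except StopIteration:
                raise ValueError(
                    f"R2 file truncated: no mate for {title1.split()[0]!r}"
                ) from None
            id1, id2 = _strip_mate_suffix(title1), _strip_mate_suffix(title2)
            if id1 != id2:
                raise ValueError(f"mate-name mismatch: {id1!r} vs {id2!r}")
            yield ReadPairRecord(id1, seq1.upper(), seq2.upper(), qual1, qual2)
        try:
            next(it2)
        except StopIteration:
            return
        raise ValueError("R1 file truncated: R2 has extra records")


class PanelAligner:
    """Local aligner over every panel target, both strands.

    Scoring: match +1, mismatch -2, gap open -5, gap extend -2 (a gap of
    length L scores -5 - 2(L-1)).  Ties are broken by panel order, then
    plus strand.
    """

    def __init__(self, panel: TargetPanel, min_score: int = MIN_ALIGN_SCORE):
        self.panel = panel
        self.min_score = min_score
        self._aligner = Align.PairwiseAligner(
            mode="local",
            match_score=1,
            mismatch_score=-2,
            open_gap_score=-5,
            extend_gap_score=-2,
        )
        # sequences per (gene index, strand); queries on '-' are reverse
        # complemented instead, so targets are stored plus-strand only
        self._targets = [(i, g.name, g.cdna_seq) for i, g in enumerate(panel.genes)]
        self._seed_index: dict[str, set[tuple[int, str]]] = {}
        for i, _name, seq in self._targets:
            for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
                for j in range(len(s) - _SEED_K + 1):
                    self._seed_index.setdefault(s[j : j + _SEED_K], set()).add((i, strand))

    def _candidates(self, seq: str) -> list[tuple[int, str]]:
        hits: set[tuple[int, str]] = set()
        for j in range(0, max(1, len(seq) - _SEED_K + 1), 7):
            hits |= self._seed_index.get(seq[j : j + _SEED_K], set())
        if not hits:
            return [(i, s) for i, _n, _seq in self._targets for s in ("+", "-")]
        return sorted(hits, key=lambda t: (t[0], t[1] != "+"))

    def align_read(self, seq: str, read_id: str = "", mate: str = "R1") -> AlignedRead | None:
        """Best-scoring local alignment of ``seq`` across all targets/strands.

        Returns ``None`` when no alignment reaches the score floor.
        """
        if not seq:
            raise ValueError("cannot align an empty sequence")
        seq = seq.upper()
        best: AlignedRead | None = None
        for idx, strand in self._candidates(seq):
            _, name, target = self._targets[idx]
            query = seq if strand == "+" else str(Seq(seq).reverse_complement())
            alns = self._aligner.align(target, query)
            score = alns.score
            if score < self.min_score:
                continue
            if best is not None and score <= best.score:
                continue  # strict improvement required: earlier candidate wins ties
            aln = alns[0]
            t_blocks, q_blocks = aln.aligned
            matched = 0
            matches = 0
            calls: dict[int, str] = {}
            for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
                matched += te - ts
                for k in range(te - ts):
                    tb = target[ts + k]
                    qb = query[qs + k]
                    calls[ts + k + 1] = qb
                    if tb == qb:
                        matches += 1
            best = AlignedRead(
                read_id=read_id,
                mate=mate,
                target=name,
                target_start=int(t_blocks[0][0]) + 1,
                target_end=int(t_blocks[-1][1]),
                matched_len=matched,
                identity_pct=100.0 * matches / matched if matched else 0.0,
                score=float(score),
                strand=strand,
                base_calls=calls,
            )
        return best


def filter_alignment(a: AlignedRead) -> bool:
    """Keep an alignment iff matched region >= 90 nt and identity >= 80%."""
    return a.matched_len >= MIN_MATCHED_LEN and a.identity_pct >= MIN_IDENTITY_PCT


def ingest_tabular_alignments(path: str | Path, panel: TargetPanel) -> Iterator[AlignedRead]:
    """Read 12-column tabular alignments (outfmt-6 style) as AlignedReads.

    Per-base calls are unavailable on this path; downstream pileups refuse
    such records.  Unknown subjects and malformed rows raise ``ValueError``.
    """
    known = set(panel.gene_names)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            query, subject = cols[0], cols[1]
            if subject not in known:
                raise ValueError(f"{path}:{lineno}: unknown subject {subject!r}")
            try:
                identity = float(cols[2])
                length = int(cols[3])
                s_start, s_end = int(cols[8]), int(cols[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            strand = "+" if s_start <= s_end else "-"
            lo, hi = sorted((s_start, s_end))
            yield AlignedRead(
                read_id=query,
                mate="R1",
                target=subject,
                target_start=lo,
                target_end=hi,
                matched_len=length,
                identity_pct=identity,
                strand=strand,
                base_calls=None,
            )


def align_pairs(
    pairs: Iterable[ReadPairRecord],
    panel: TargetPanel,
    aligner: PanelAligner | None = None,
    tally: QcTally | None = None,
) -> Iterator[tuple[ReadPairRecord, AlignedRead, AlignedRead]]:
    """Align both mates and keep target-consistent, filter-passing pairs.

    A pair survives only if both mates pass :func:`filter_alignment` and
    agree on the target gene; everything else is dropped and accounted for
    in the tally.
    """
    aligner = aligner or PanelAligner(panel)
    tally = tally if tally is not None else QcTally()
    for pair in pairs:
        tally.pairs_in += 1
        a1 = aligner.align_read(pair.r1_seq, pair.read_id, "R1")
        a2 = aligner.align_read(pair.r2_seq, pair.read_id, "R2")
        if a1 is not None:
            tally.r1_aligned += 1
        if a2 is not None:
            tally.r2_aligned += 1
        ok1 = a1 is not None and filter_alignment(a1)
        ok2 = a2 is not None and filter_alignment(a2)
        if ok1:
            tally.r1_pass_filter += 1
        if ok2:
            tally.r2_pass_filter += 1
        if ok1 and ok2 and a1.target == a2.target:
            tally.target_consistent += 1
            yield pair, a1, a2
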