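"""Per-target counting, expression values and signature scores.

Reads mode counts every filter-passing, target-consistent read pair on its
target; UMIs mode counts surviving UMI groups (one per detected molecule).
Expression is log2 with a 0.5 pseudocount, normalised to the mean of the
panel's control (reference) genes, which makes both expression values and
signature scores invariant to library-size rescaling.  Signature score =
mean expression over member genes (the published clinical signature
weights are proprietary to their source assays; this generic mean-diff
score is a labelled stand-in).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .panel import SignatureDefinition, TargetPanel
from .readproc import AlignedRead, ReadPairRecord
from .umiproc import UmiGroup

__all__ = [
    "CountsTable",
    "ExpressionProfile",
    "SignatureScore",
    "count_reads",
    "count_umis",
    "to_expression",
    "score_signature",
]

PSEUDOCOUNT = 0.5


@dataclass
class CountsTable:
    library_id: str
    mode: str  # "reads" | "umis"
    counts: dict[str, int]
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("reads", "umis"):
            raise ValueError(f"unknown counts mode {self.mode!r}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative count")
        if self.mode == "reads" and self.library_size == 0:
            self.library_size = sum(self.counts.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"gene\t{self.library_id}.{self.mode}\n")
            for g in sorted(self.counts):
                fh.write(f"{g}\t{self.counts[g]}\n")


@dataclass
class ExpressionProfile:
    library_id: str
    expr: dict[str, float]
    reference_mean: float = 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"gene\t{self.library_id}\n")
            for g in sorted(self.expr):
                fh.write(f"{g}\t{self.expr[g]:.6f}\n")


@dataclass
class SignatureScore:
    library_id: str
    signature: str
    score: float
    note: str = "generic mean-difference score (not the published clinical formula)"


def count_reads(
    consistent_pairs: Iterable[tuple[ReadPairRecord, AlignedRead, AlignedRead]],
    panel: TargetPanel,
    library_id: str = "library",
) -> CountsTable:
    """Reads-mode counts: one count per target-consistent filter-passing pair."""
    counts = {g: 0 for g in panel.gene_names}
    for _pair, a1, _a2 in consistent_pairs:
        counts[a1.target] += 1
    return CountsTable(library_id=library_id, mode="reads", counts=counts)


def count_umis(
    filtered_groups: dict[str, list[UmiGroup]],
    panel: TargetPanel,
    library_id: str = "library",
    library_size: int = 0,
) -> CountsTable:
    """UMIs-mode counts: surviving (post-2%-filter) groups per target."""
    counts = {g: 0 for g in panel.gene_names}
    for target, glist in filtered_groups.items():
        counts[target] = len(glist)
    return CountsTable(
        library_id=library_id, mode="umis", counts=counts, library_size=library_size
    )


def to_expression(c: CountsTable, panel: TargetPanel) -> ExpressionProfile:
    """log2(count + 0.5), centred on the mean of the reference genes.

    Zero-count reference genes stay in the mean through the pseudocount,
    keeping the normaliser defined for sparse libraries.
    """
    refs = sorted(panel.reference_genes)
    if not refs:
        raise ValueError("panel defines no reference genes (no signature reference sets)")
    logc = {g: math.log2(c.counts.get(g, 0) + PSEUDOCOUNT) for g in panel.gene_names}
    ref_mean = sum(logc[r] for r in refs) / len(refs)
    return ExpressionProfile(
        library_id=c.library_id,
        expr={g: logc[g] - ref_mean for g in panel.gene_names},
        reference_mean=ref_mean,
    )


def score_signature(e: ExpressionProfile, s: SignatureDefinition) -> SignatureScore:
    """Mean reference-normalised expression over the signature's members."""
    missing = [g for g in sorted(s.member_genes) if g not in e.expr]
    if missing:
        raise ValueError(f"signature {s.name}: member gene(s) missing from profile: {missing}")
    members = sorted(s.member_genes)
    score = sum(e.expr[g] for g in members) / len(members)
    return SignatureScore(library_id=e.library_id, signature=s.name, score=score)
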