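"""End-to-end orchestration of the reads-based and UMI-based pipelines.

One pass over a library: parse pairs, align both mates, keep
filter-passing target-consistent pairs, then (reads mode) count pairs per
target and (UMIs mode) extract UMI/tag off R2, group, apply the 2%
filter, pick representatives and count surviving groups.  Mutation
calling piles up base calls on the same alignments, with UMI depth taken
over representative reads only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import mutcall, quant, readproc, stats, umiproc
from .panel import TargetPanel, umi_space_size

__all__ = ["LibraryResult", "quantify_library", "mutation_report", "saturation_point"]


@dataclass
class LibraryResult:
    """Everything one library yields: counts both ways, expression,
    signature scores, UMI groups, QC tallies and the retained pairs."""

    library_id: str
    counts_reads: quant.CountsTable
    counts_umis: quant.CountsTable
    expression_reads: quant.ExpressionProfile
    expression_umis: quant.ExpressionProfile
    signature_scores: list[quant.SignatureScore]
    qc: readproc.QcTally
    umi_tally: umiproc.UmiTally
    groups_all: dict[str, list[umiproc.UmiGroup]]
    groups_kept: dict[str, list[umiproc.UmiGroup]]
    pairs: list[tuple[readproc.ReadPairRecord, readproc.AlignedRead, readproc.AlignedRead]] = field(
        repr=False, default_factory=list
    )

    @property
    def representative_ids(self) -> set[str]:
        return {
            g.representative
            for glist in self.groups_kept.values()
            for g in glist
            if g.representative is not None
        }


def quantify_library(
    r1_path: str | Path,
    r2_path: str | Path,
    panel: TargetPanel,
    seed: int,
    library_id: str = "library",
    aligner: readproc.PanelAligner | None = None,
    keep_pairs: bool = True,
) -> LibraryResult:
    """Run both pipelines on one paired FASTQ library."""
    qc = readproc.QcTally()
    aligner = aligner or readproc.PanelAligner(panel)
    pairs = list(
        readproc.align_pairs(
            readproc.parse_fastq_pairs(r1_path, r2_path), panel, aligner, qc
        )
    )
    counts_reads = quant.count_reads(pairs, panel, library_id)

    umi_tally = umiproc.UmiTally()
    assignments = []
    for pair, _a1, _a2 in pairs:
        a = umiproc.extract_umi_and_gene(pair.r2_seq, panel, pair.read_id, umi_tally)
        if a is not None:
            assignments.append(a)
    groups_all = umiproc.group_by_umi(assignments)
    groups_kept = umiproc.filter_umi_groups(groups_all)
    umiproc.select_representatives(groups_kept, seed)
    counts_umis = quant.count_umis(
        groups_kept, panel, library_id, library_size=counts_reads.library_size
    )

    expr_reads = quant.to_expression(counts_reads, panel)
    expr_umis = quant.to_expression(counts_umis, panel)
    scores = [quant.score_signature(expr_umis, s) for s in panel.signatures]
    return LibraryResult(
        library_id=library_id,
        counts_reads=counts_reads,
        counts_umis=counts_umis,
        expression_reads=expr_reads,
        expression_umis=expr_umis,
        signature_scores=scores,
        qc=qc,
        umi_tally=umi_tally,
        groups_all=groups_all,
        groups_kept=groups_kept,
        pairs=pairs if keep_pairs else [],
    )


def mutation_report(
    result: LibraryResult, panel: TargetPanel, ratio_on_all_reads: bool = False
) -> list[mutcall.MutationCall]:
    """Reads-mode and UMIs-mode calls for every panel hotspot."""
    calls: list[mutcall.MutationCall] = []
    reps = result.representative_ids
    for h in panel.hotspots:
        p = mutcall.pileup_hotspot(result.pairs, h, representative_ids=reps)
        calls.append(mutcall.call_mutation_reads(p, ratio_on_all_reads=ratio_on_all_reads))
        calls.append(mutcall.call_mutation_umis(p))
    return calls


def saturation_point(result: LibraryResult, panel: TargetPanel) -> stats.SaturationPoint:
    """Library-level saturation: distinct UMIs across all targets jointly."""
    distinct = sum(len(glist) for glist in result.groups_all.values())
    return stats.SaturationPoint(
        library_id=result.library_id,
        library_size_n=result.counts_reads.library_size,
        distinct_umis=distinct,
        umi_space=umi_space_size(panel),
    )
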