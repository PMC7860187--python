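"""UMI pipeline: R2 structure parsing, UMI grouping, abundance filter,
representative selection.

Read 2 of each pair carries the molecular identity: positions 1-8 are the
UMI attached during reverse transcription, positions 9-25 the 17-nt
gene-specific reverse-primer sequence.  The tag must match a panel target
exactly; any mismatch, or a UMI containing a non-ACGT base, excludes the
read (tallied, not an error).

Reads sharing a (target, UMI) pair are PCR duplicates of one molecule.
Within each target, groups containing 2% or less of the reads of that
target's largest group are discarded as likely UMI artefacts; the
comparison is exact rational arithmetic (50 * n <= max), so there are no
float boundary surprises.  One surviving read per group is then drawn
uniformly at random as the molecule's representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .panel import TargetPanel, REVTAG_LEN

__all__ = [
    "UmiAssignment",
    "UmiGroup",
    "UmiTally",
    "extract_umi_and_gene",
    "group_by_umi",
    "filter_umi_groups",
    "select_representatives",
    "write_group_table",
]

_VALID_UMI = frozenset("ACGT")


@dataclass
class UmiAssignment:
    read_id: str
    target: str
    umi: str


@dataclass
class UmiGroup:
    """All reads sharing one (target, UMI) pair, i.e. one source molecule."""

    target: str
    umi: str
    read_ids: list[str] = field(default_factory=list)
    representative: str | None = None

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


@dataclass
class UmiTally:
    reads_in: int = 0
    assigned: int = 0
    tag_mismatch: int = 0
    irregular_umi: int = 0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k, v in vars(self).items():
                fh.write(f"{k}\t{v}\n")


def extract_umi_and_gene(
    r2_seq: str,
    panel: TargetPanel,
    read_id: str = "",
    tally: UmiTally | None = None,
) -> UmiAssignment | None:
    """Parse UMI (positions 1-8) and gene tag (9-25) off an R2 sequence.

    Returns ``None`` (and tallies the reason) unless the tag matches one
    panel reverse_tag exactly and the UMI is full-length plain A/C/G/T.
    """
    if tally is not None:
        tally.reads_in += 1
    k = panel.umi_len
    r2_seq = r2_seq.upper()
    if len(r2_seq) < k + REVTAG_LEN:
        if tally is not None:
            tally.irregular_umi += 1
        return None
    umi = r2_seq[:k]
    tag = r2_seq[k : k + REVTAG_LEN]
    if not set(umi) <= _VALID_UMI:
        if tally is not None:
            tally.irregular_umi += 1
        return None
    target = panel.tag_to_gene.get(tag)
    if target is None:
        if tally is not None:
            tally.tag_mismatch += 1
        return None
    if tally is not None:
        tally.assigned += 1
    return UmiAssignment(read_id=read_id, target=target, umi=umi)


def group_by_umi(assignments: Iterable[UmiAssignment]) -> dict[str, list[UmiGroup]]:
    """Bucket assignments into one group per distinct (target, UMI)."""
    groups: dict[tuple[str, str], UmiGroup] = {}
    for a in assignments:
        key = (a.target, a.umi)
        g = groups.get(key)
        if g is None:
            g = groups[key] = UmiGroup(target=a.target, umi=a.umi)
        g.read_ids.append(a.read_id)
    out: dict[str, list[UmiGroup]] = {}
    for (target, _umi), g in groups.items():
        out.setdefault(target, []).append(g)
    return out


def filter_umi_groups(groups: dict[str, list[UmiGroup]]) -> dict[str, list[UmiGroup]]:
    """Drop groups holding <= 2% of the reads of the target's largest group.

    The comparison is 50 * n_reads <= max(n_reads) in integer arithmetic;
    the maximal group always survives.
    """
    out: dict[str, list[UmiGroup]] = {}
    for target, glist in groups.items():
        if not glist:
            out[target] = []
            continue
        m = max(g.n_reads for g in glist)
        out[target] = [g for g in glist if 50 * g.n_reads > m]
    return out


def select_representatives(
    groups: dict[str, list[UmiGroup]], seed: int
) -> dict[str, list[UmiGroup]]:
    """Pick one read uniformly at random per group (in place; returns input).

    Groups are visited in (target, umi) lexicographic order with a single
    generator seeded once, so the draw is reproducible for a given seed and
    read insertion order.
    """
    rng = np.random.default_rng(seed)
    flat = [g for _t, glist in sorted(groups.items()) for g in sorted(glist, key=lambda g: g.umi)]
    for g in flat:
        g.representative = g.read_ids[int(rng.integers(g.n_reads))]
    return groups


def write_group_table(
    groups_all: dict[str, list[UmiGroup]],
    groups_kept: dict[str, list[UmiGroup]],
    path: str | Path,
) -> None:
    """UMI-group TSV: target, umi, n_reads, representative, kept flag."""
    kept = {(g.target, g.umi) for glist in groups_kept.values() for g in glist}
    with open(path, "w") as fh:
        fh.write("target\tumi\tn_reads\trepresentative\tkept\n")
        for target in sorted(groups_all):
            for g in sorted(groups_all[target], key=lambda g: g.umi):
                flag = int((g.target, g.umi) in kept)
                fh.write(f"{g.target}\t{g.umi}\t{g.n_reads}\t{g.representative or ''}\t{flag}\n")
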