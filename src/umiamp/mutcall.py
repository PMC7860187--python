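"""Hotspot pileups and transcribed-mutation calling.

The assay reports a single-nucleotide mutation from total reads when the
depth at the position exceeds 100 reads, the allele fraction exceeds 5%,
and the ratio of variant-supporting R1 to R2 reads lies within
[0.8, 1.2] (a mate-concordance check against strand-specific artefacts).
The UMI pipeline additionally requires at least 10 unique UMIs covering
the position, with depth and allele fraction computed on the one
representative read per UMI group.

Boundary semantics follow the printed rules exactly: depth strictly
greater than 100, AF strictly greater than 5%, ratio inclusive, UMI depth
inclusive at 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .panel import HotspotVariant
from .readproc import AlignedRead, ReadPairRecord

__all__ = [
    "HotspotPileup",
    "MutationCall",
    "AfSummary",
    "pileup_hotspot",
    "compute_af",
    "call_mutation_reads",
    "call_mutation_umis",
    "af_summary",
    "write_mutation_report",
]

MIN_DEPTH_READS = 100  # strict: depth must exceed this
MIN_AF_PCT = 5.0  # strict
RATIO_LOW, RATIO_HIGH = 0.8, 1.2  # inclusive
MIN_DEPTH_UMIS = 10  # inclusive


@dataclass
class HotspotPileup:
    hotspot: HotspotVariant
    depth_reads: int = 0
    depth_umis: int = 0
    alt_reads: int = 0
    alt_umis: int = 0
    alt_r1: int = 0
    alt_r2: int = 0
    cover_r1: int = 0  # all covering R1/R2 calls, for the alternative ratio reading
    cover_r2: int = 0


@dataclass
class MutationCall:
    hotspot: HotspotVariant
    af_pct: float
    called: bool
    mode: str  # "reads" | "umis"
    failed_criteria: list[str] = field(default_factory=list)


@dataclass
class AfSummary:
    label: str
    n: int
    mean: float
    sd: float
    cv_pct: float


def _call_at(a: AlignedRead | None, position: int) -> str | None:
    if a is None or a.base_calls is None:
        return None
    return a.base_calls.get(position)


def pileup_hotspot(
    consistent_pairs: Iterable[tuple[ReadPairRecord, AlignedRead, AlignedRead]],
    h: HotspotVariant,
    representative_ids: set[str] | None = None,
) -> HotspotPileup:
    """Tally base calls over the hotspot position.

    Every mate whose alignment covers the position with a non-gap call
    contributes one unit of read depth (so a doubly-covering pair adds
    two).  UMI depth and alt counts use only pairs named in
    ``representative_ids`` (one per surviving UMI group), taking the R1
    call where present, else R2.

    Raises ``ValueError`` on tabular-ingested alignments, which carry no
    per-base calls.
    """
    p = HotspotPileup(hotspot=h)
    pos, alt = h.position, h.alt_base
    for pair, a1, a2 in consistent_pairs:
        if a1.target != h.gene:
            continue
        if a1.base_calls is None or a2.base_calls is None:
            raise ValueError(
                "pileup requires per-base calls; tabular-ingested alignments "
                "cannot be used for mutation calling"
            )
        c1 = _call_at(a1, pos)
        c2 = _call_at(a2, pos)
        if c1 is not None:
            p.depth_reads += 1
            p.cover_r1 += 1
            if c1 == alt:
                p.alt_reads += 1
                p.alt_r1 += 1
        if c2 is not None:
            p.depth_reads += 1
            p.cover_r2 += 1
            if c2 == alt:
                p.alt_reads += 1
                p.alt_r2 += 1
        if representative_ids is not None and pair.read_id in representative_ids:
            c = c1 if c1 is not None else c2
            if c is not None:
                p.depth_umis += 1
                if c == alt:
                    p.alt_umis += 1
    return p


def compute_af(p: HotspotPileup, mode: str) -> float:
    """Allele fraction as a percentage, in the chosen counting mode."""
    if mode == "reads":
        depth, altn = p.depth_reads, p.alt_reads
    elif mode == "umis":
        depth, altn = p.depth_umis, p.alt_umis
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if depth == 0:
        raise ValueError(f"zero {mode} depth at {p.hotspot.label or p.hotspot.gene}")
    return 100.0 * altn / depth


def call_mutation_reads(p: HotspotPileup, ratio_on_all_reads: bool = False) -> MutationCall:
    """Reads-mode call: depth > 100, AF > 5%, R1/R2 ratio in [0.8, 1.2].

    By default the ratio compares variant-supporting R1 and R2 reads;
    ``ratio_on_all_reads`` switches to all covering reads per mate.
    """
    failed: list[str] = []
    if p.depth_reads > MIN_DEPTH_READS:
        af = compute_af(p, "reads")
    else:
        af = 100.0 * p.alt_reads / p.depth_reads if p.depth_reads else 0.0
        failed.append(f"depth_reads {p.depth_reads} <= {MIN_DEPTH_READS}")
    if not af > MIN_AF_PCT:
        failed.append(f"af {af:.3f}% <= {MIN_AF_PCT}%")
    num, den = (p.cover_r1, p.cover_r2) if ratio_on_all_reads else (p.alt_r1, p.alt_r2)
    if den == 0:
        failed.append("r1_r2_ratio undefined (no supporting R2 reads)")
    else:
        ratio = num / den
        if not (RATIO_LOW <= ratio <= RATIO_HIGH):
            failed.append(f"r1_r2_ratio {ratio:.3f} outside [{RATIO_LOW}, {RATIO_HIGH}]")
    return MutationCall(
        hotspot=p.hotspot, af_pct=af, called=not failed, mode="reads", failed_criteria=failed
    )


def call_mutation_umis(p: HotspotPileup) -> MutationCall:
    """UMIs-mode call: at least 10 unique UMIs at the position and AF > 5%."""
    failed: list[str] = []
    if p.depth_umis >= MIN_DEPTH_UMIS:
        af = compute_af(p, "umis")
    else:
        af = 100.0 * p.alt_umis / p.depth_umis if p.depth_umis else 0.0
        failed.append(f"depth_umis {p.depth_umis} < {MIN_DEPTH_UMIS}")
    if not af > MIN_AF_PCT:
        failed.append(f"af {af:.3f}% <= {MIN_AF_PCT}%")
    return MutationCall(
        hotspot=p.hotspot, af_pct=af, called=not failed, mode="umis", failed_criteria=failed
    )


def af_summary(af_pcts: Sequence[float], label: str = "") -> AfSummary:
    """Across-replicate mean, sample SD and CV% of allele fraction."""
    if len(af_pcts) < 2:
        raise ValueError("need at least 2 replicates for an AF summary")
    arr = np.asarray(af_pcts, dtype=float)
    mean = float(arr.mean())
    if mean == 0.0:
        raise ValueError("mean AF is zero; CV undefined")
    sd = float(arr.std(ddof=1))
    return AfSummary(label=label, n=len(arr), mean=mean, sd=sd, cv_pct=100.0 * sd / mean)


def write_mutation_report(calls: Iterable[MutationCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tgene\tposition\tmode\taf_pct\tcalled\tfailed_criteria\n")
        for c in calls:
            h = c.hotspot
            fh.write(
                f"{h.label}\t{h.gene}\t{h.position}\t{c.mode}\t{c.af_pct:.4f}\t"
                f"{int(c.called)}\t{';'.join(c.failed_criteria)}\n"
            )
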