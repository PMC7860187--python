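"""Target panel model: genes, primers, hotspot variants and signature sets.

A targeted amplicon RNA-seq assay is defined by a small set of target cDNA
sequences, each amplified by a gene-specific forward primer and a
gene-specific reverse primer.  In the UMI-tagged protocol the reverse
primer carries an 8-nt random UMI between the sequencing adaptor and the
17-nt gene-specific sequence, so read 2 of every pair starts with
``UMI(8) + reverse_tag(17)`` and the reverse tag identifies the target
gene without alignment.

The panel also declares hotspot variants (single-nucleotide changes at
known positions on a target cDNA) and multi-gene expression signatures
(member genes scored against a set of reference/control genes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TargetGene",
    "HotspotVariant",
    "SignatureDefinition",
    "TargetPanel",
    "PanelValidationError",
    "load_panel",
    "write_reference",
    "umi_space_size",
    "toy_panel",
]

_GENE_NAME_RE = re.compile(r"^[A-Za-z0-9_.-]+$")
_NT_RE = re.compile(r"^[ACGT]+$")

# 17-nt Illumina adaptor halves printed on the assay's fusion primers.
DEFAULT_FWD_ADAPTOR = "CGCTCTTCCGATCTCTG"
DEFAULT_REV_ADAPTOR = "TGCTCTTCCGATCTGAC"

REVTAG_LEN = 17


class PanelValidationError(ValueError):
    """A panel record violates one of the assay invariants."""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class TargetGene:
    """One target: its cDNA sequence and the primers that amplify it.

    ``reverse_tag`` is the 17-nt gene-specific part of the reverse primer;
    its reverse complement is the 3' end of the amplicon on the cDNA plus
    strand.  ``forward_primer`` is a prefix-region subsequence of the cDNA
    defining the amplicon 5' end.
    """

    name: str
    cdna_seq: str
    reverse_tag: str
    forward_primer: str
    amplicon_len: int = 0  # 0 -> derived from primer positions

    def __post_init__(self) -> None:
        if not _GENE_NAME_RE.match(self.name):
            raise PanelValidationError(f"gene name {self.name!r} contains illegal characters")
        for label, seq in (
            ("cdna_seq", self.cdna_seq),
            ("reverse_tag", self.reverse_tag),
            ("forward_primer", self.forward_primer),
        ):
            if not _NT_RE.match(seq):
                raise PanelValidationError(f"{self.name}: {label} is not plain A/C/G/T")
        if len(self.reverse_tag) != REVTAG_LEN:
            raise PanelValidationError(
                f"{self.name}: reverse_tag length {len(self.reverse_tag)} != {REVTAG_LEN}"
            )
        if self.forward_primer not in self.cdna_seq:
            raise PanelValidationError(f"{self.name}: forward_primer not found in cdna_seq")
        tag_rc = _revcomp(self.reverse_tag)
        if tag_rc not in self.cdna_seq:
            raise PanelValidationError(
                f"{self.name}: reverse_tag reverse-complement not found in cdna_seq"
            )
        start = self.cdna_seq.index(self.forward_primer)  # 0-based amplicon start
        end = self.cdna_seq.index(tag_rc) + REVTAG_LEN  # 0-based exclusive amplicon end
        derived = end - start
        if derived <= 0:
            raise PanelValidationError(f"{self.name}: primers imply a non-positive amplicon")
        if self.amplicon_len == 0:
            self.amplicon_len = derived
        elif self.amplicon_len != derived:
            raise PanelValidationError(
                f"{self.name}: declared amplicon_len {self.amplicon_len} "
                f"inconsistent with primer positions (derived {derived})"
            )
        self._amplicon_start0 = start
        self._amplicon_end0 = end

    @property
    def amplicon_seq(self) -> str:
        """Plus-strand amplicon sequence (forward primer through reverse-tag RC)."""
        return self.cdna_seq[self._amplicon_start0 : self._amplicon_end0]

    @property
    def amplicon_start(self) -> int:
        """1-based start of the amplicon on the cDNA."""
        return self._amplicon_start0 + 1


@dataclass
class HotspotVariant:
    """A single-nucleotide hotspot on a target cDNA (1-based position)."""

    gene: str
    position: int
    ref_base: str
    alt_base: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise PanelValidationError(f"hotspot {self.label or self.gene}: ref == alt")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT":
                raise PanelValidationError(f"hotspot {self.label or self.gene}: base {b!r}")
        if self.position < 1:
            raise PanelValidationError(f"hotspot {self.label or self.gene}: position < 1")


@dataclass
class SignatureDefinition:
    """A multi-gene signature: mean over members minus mean over references."""

    name: str
    member_genes: frozenset[str]
    reference_genes: frozenset[str]
    combine_rule: str = "mean_diff"

    def __post_init__(self) -> None:
        self.member_genes = frozenset(self.member_genes)
        self.reference_genes = frozenset(self.reference_genes)
        if not self.member_genes:
            raise PanelValidationError(f"signature {self.name}: empty member set")
        if self.member_genes & self.reference_genes:
            raise PanelValidationError(
                f"signature {self.name}: member and reference sets overlap"
            )
        if self.combine_rule != "mean_diff":
            raise PanelValidationError(
                f"signature {self.name}: unknown combine_rule {self.combine_rule!r}"
            )


@dataclass
class TargetPanel:
    """A validated assay definition."""

    genes: list[TargetGene]
    hotspots: list[HotspotVariant] = field(default_factory=list)
    signatures: list[SignatureDefinition] = field(default_factory=list)
    fwd_adaptor: str = DEFAULT_FWD_ADAPTOR
    rev_adaptor: str = DEFAULT_REV_ADAPTOR
    umi_len: int = 8

    def __post_init__(self) -> None:
        if self.umi_len < 1:
            raise PanelValidationError("umi_len must be >= 1")
        names = [g.name for g in self.genes]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise PanelValidationError(f"duplicate gene name(s): {sorted(dup)}")
        tags = [g.reverse_tag for g in self.genes]
        dup_tags = {t for t in tags if tags.count(t) > 1}
        if dup_tags:
            offenders = [g.name for g in self.genes if g.reverse_tag in dup_tags]
            raise PanelValidationError(
                f"reverse_tag shared between genes {offenders}: gene assignment ambiguous"
            )
        by_name = {g.name: g for g in self.genes}
        for h in self.hotspots:
            if h.gene not in by_name:
                raise PanelValidationError(f"hotspot {h.label or h.gene}: unknown gene {h.gene}")
            cdna = by_name[h.gene].cdna_seq
            if h.position > len(cdna):
                raise PanelValidationError(
                    f"hotspot {h.label or h.gene}: position {h.position} beyond cDNA"
                )
            if cdna[h.position - 1] != h.ref_base:
                raise PanelValidationError(
                    f"hotspot {h.label or h.gene}: cDNA has "
                    f"{cdna[h.position - 1]!r} at position {h.position}, not {h.ref_base!r}"
                )
        for s in self.signatures:
            missing = (s.member_genes | s.reference_genes) - set(by_name)
            if missing:
                raise PanelValidationError(
                    f"signature {s.name}: unknown gene(s) {sorted(missing)}"
                )
        self._by_name = by_name
        self._by_tag = {g.reverse_tag: g.name for g in self.genes}

    # -- lookups -------------------------------------------------------
    def gene(self, name: str) -> TargetGene:
        return self._by_name[name]

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    @property
    def tag_to_gene(self) -> dict[str, str]:
        return dict(self._by_tag)

    @property
    def reference_genes(self) -> frozenset[str]:
        """Union of the signatures' reference (control) gene sets."""
        out: frozenset[str] = frozenset()
        for s in self.signatures:
            out |= s.reference_genes
        return out


def umi_space_size(panel_or_len: TargetPanel | int) -> int:
    """Number of distinct UMI sequences: 4**umi_len (65,536 for 8-nt UMIs)."""
    n = panel_or_len.umi_len if isinstance(panel_or_len, TargetPanel) else int(panel_or_len)
    return 4**n


def load_panel(path: str | Path) -> TargetPanel:
    """Load and validate a panel from a YAML config.

    Raises :class:`PanelValidationError` naming the offending record on any
    invariant violation.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        genes = [
            TargetGene(
                name=g["name"],
                cdna_seq=g["cdna_seq"].upper(),
                reverse_tag=g["reverse_tag"].upper(),
                forward_primer=g["forward_primer"].upper(),
                amplicon_len=int(g.get("amplicon_len", 0)),
            )
            for g in raw["genes"]
        ]
        hotspots = [
            HotspotVariant(
                gene=h["gene"],
                position=int(h["position"]),
                ref_base=h["ref_base"].upper(),
                alt_base=h["alt_base"].upper(),
                label=h.get("label", ""),
            )
            for h in raw.get("hotspots", [])
        ]
        signatures = [
            SignatureDefinition(
                name=s["name"],
                member_genes=frozenset(s["member_genes"]),
                reference_genes=frozenset(s["reference_genes"]),
                combine_rule=s.get("combine_rule", "mean_diff"),
            )
            for s in raw.get("signatures", [])
        ]
    except KeyError as exc:  # missing mandatory field
        raise PanelValidationError(f"panel config missing field {exc}") from exc
    return TargetPanel(
        genes=genes,
        hotspots=hotspots,
        signatures=signatures,
        fwd_adaptor=raw.get("fwd_adaptor", DEFAULT_FWD_ADAPTOR).upper(),
        rev_adaptor=raw.get("rev_adaptor", DEFAULT_REV_ADAPTOR).upper(),
        umi_len=int(raw.get("umi_len", 8)),
    )


def save_panel(panel: TargetPanel, path: str | Path) -> None:
    """Write a panel back to YAML (round-trips through :func:`load_panel`)."""
    doc = {
        "umi_len": panel.umi_len,
        "fwd_adaptor": panel.fwd_adaptor,
        "rev_adaptor": panel.rev_adaptor,
        "genes": [
            {
                "name": g.name,
                "cdna_seq": g.cdna_seq,
                "reverse_tag": g.reverse_tag,
                "forward_primer": g.forward_primer,
                "amplicon_len": g.amplicon_len,
            }
            for g in panel.genes
        ],
        "hotspots": [
            {
                "gene": h.gene,
                "position": h.position,
                "ref_base": h.ref_base,
                "alt_base": h.alt_base,
                "label": h.label,
            }
            for h in panel.hotspots
        ],
        "signatures": [
            {
                "name": s.name,
                "member_genes": sorted(s.member_genes),
                "reference_genes": sorted(s.reference_genes),
                "combine_rule": s.combine_rule,
            }
            for s in panel.signatures
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_reference(panel: TargetPanel, path: str | Path) -> None:
    """Emit the custom cDNA reference FASTA (one record per target, panel order)."""
    if not panel.genes:
        raise PanelValidationError("cannot write a reference for an empty panel")
    records = [
        SeqRecord(Seq(g.cdna_seq), id=g.name, description="") for g in panel.genes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Bundled toy assay (synthetic sequences; the production panel's primers are
# proprietary and are not reproduced here).
# ---------------------------------------------------------------------------

def _random_cdna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(length))


def toy_panel(umi_len: int = 8) -> TargetPanel:
    """A small synthetic 5-gene panel used in tests and examples.

    Two signature member genes (ESR1, PIK3CA), one shared member (NAT1),
    two control genes; one synthetic PIK3CA hotspot.  Sequences are random
    but fixed (seeded), with realistic amplicon lengths (150-200 nt).
    """
    import random

    rng = random.Random(20210204)
    lengths = {"ESR1": 182, "PIK3CA": 176, "NAT1": 158, "CTRL1": 191, "CTRL2": 165}
    genes = []
    tags_seen: set[str] = set()
    for name, length in lengths.items():
        while True:
            cdna = _random_cdna(rng, length)
            tag = _revcomp(cdna[-REVTAG_LEN:])
            # tag uniqueness and a clean single occurrence of each primer
            if tag in tags_seen:
                continue
            fwd = cdna[:20]
            if cdna.count(fwd) == 1 and cdna.count(_revcomp(tag)) == 1:
                break
        tags_seen.add(tag)
        genes.append(TargetGene(name=name, cdna_seq=cdna, reverse_tag=tag, forward_primer=fwd))
    pik3ca = next(g for g in genes if g.name == "PIK3CA")
    pos = 88
    ref = pik3ca.cdna_seq[pos - 1]
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    hotspot = HotspotVariant(
        gene="PIK3CA", position=pos, ref_base=ref, alt_base=alt,
        label="PIK3CA hotspot (synthetic)",
    )
    signatures = [
        SignatureDefinition(
            name="ERPR_index",
            member_genes=frozenset({"ESR1", "NAT1"}),
            reference_genes=frozenset({"CTRL1", "CTRL2"}),
        ),
        SignatureDefinition(
            name="PI3K_ges",
            member_genes=frozenset({"PIK3CA", "NAT1"}),
            reference_genes=frozenset({"CTRL1", "CTRL2"}),
        ),
    ]
    return TargetPanel(genes=genes, hotspots=[hotspot], signatures=signatures, umi_len=umi_len)
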