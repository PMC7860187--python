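"""Synthetic paired-end UMI-tagged amplicon libraries with full ground truth.

The generator emulates the UMI-tagged amplicon protocol: each detected
mRNA molecule is a gene's amplicon tagged at reverse transcription with a
random 8-nt UMI, then amplified by a per-molecule-efficiency branching
PCR and sequenced as a read pair.  Read 2 starts with the UMI followed by
the 17-nt gene-specific reverse-primer tag and the reverse complement of
the amplicon; read 1 is the forward strand of the amplicon running into
the reverse adaptor.

Sample type and protocol map onto two knobs:

* ``rt_efficiency`` — probability an input molecule is successfully
  reverse transcribed (fresh-frozen ~0.8, FFPE ~0.3: fragmented,
  chemically modified RNA reverse-transcribes poorly).
* ``pcr_efficiency_beta`` — Beta(a, b) of per-molecule amplification
  efficiency per cycle. Beta(20, 1) gives the nearly even amplification
  of the optimised droplet protocol; Beta(0.5, 2) the strong
  amplification bias of the original bulk protocol.

Hotspot mutations are planted at the molecule level with a configurable
molecular allele fraction, so every downstream estimate can be checked
against truth.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel import TargetPanel, save_panel, toy_panel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_molecules",
    "amplify_and_sequence",
    "make_fixture_suite",
    "draw_uniform_umis",
]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated library."""

    panel: TargetPanel
    seed: int
    n_molecules_per_gene: dict[str, int] | tuple[float, float] = (5.5, 1.0)
    rt_efficiency: float = 0.8  # FF default; FFPE ~0.3
    pcr_cycles: int = 40
    pcr_efficiency_beta: tuple[float, float] = (20.0, 1.0)
    seq_error_rate: float = 0.001
    planted_af: dict[str, float] = field(default_factory=dict)  # hotspot label -> fraction
    insert_len_range: tuple[int, int] = (150, 200)
    read_len: int = 215
    library_size: int | None = None  # None -> emit every amplified copy
    force_unique_umis: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.rt_efficiency <= 1.0:
            raise ValueError("rt_efficiency must be in [0, 1]")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be in [0, 1)")
        for label, af in self.planted_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"planted_af[{label!r}] outside [0, 1]")
        lo, hi = self.insert_len_range
        for g in self.panel.genes:
            if not lo <= g.amplicon_len <= hi:
                raise ValueError(
                    f"{g.name}: amplicon length {g.amplicon_len} outside "
                    f"insert range [{lo}, {hi}]"
                )


@dataclass
class GroundTruth:
    """Per-molecule truth: gene, UMI, mutation label, and reads emitted."""

    gene: list[str]
    umi: list[str]
    mutant: np.ndarray  # bool per molecule (carries its gene's hotspot alt)
    hotspot_label: list[str | None]
    duplication_factor: np.ndarray | None = None  # reads emitted per molecule

    @property
    def n_molecules(self) -> int:
        return len(self.gene)

    @property
    def molecules_per_gene(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.gene:
            out[g] = out.get(g, 0) + 1
        return out

    @property
    def true_af(self) -> dict[str, float]:
        """Realised molecular mutant fraction per hotspot label."""
        tot: dict[str, int] = {}
        mut: dict[str, int] = {}
        for i, lab in enumerate(self.hotspot_label):
            if lab is None:
                continue
            tot[lab] = tot.get(lab, 0) + 1
            mut[lab] = mut.get(lab, 0) + int(self.mutant[i])
        return {lab: mut[lab] / tot[lab] for lab in tot}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("molecule_id\tgene\tumi\tmutant\thotspot\treads\n")
            dup = self.duplication_factor
            for i in range(self.n_molecules):
                fh.write(
                    f"m{i}\t{self.gene[i]}\t{self.umi[i]}\t{int(self.mutant[i])}\t"
                    f"{self.hotspot_label[i] or ''}\t{int(dup[i]) if dup is not None else ''}\n"
                )


def _umi_strings(rng: np.random.Generator, n: int, umi_len: int, unique: bool) -> list[str]:
    k = 4**umi_len
    if unique:
        if n > k:
            raise ValueError(f"cannot draw {n} unique UMIs from a space of {k}")
        codes = rng.choice(k, size=n, replace=False)
    else:
        codes = rng.integers(0, k, size=n)
    out = []
    for c in codes:
        s = []
        for _ in range(umi_len):
            s.append("ACGT"[c & 3])
            c >>= 2
        out.append("".join(s))
    return out


def simulate_molecules(cfg: SimulationConfig) -> GroundTruth:
    """Draw the post-RT molecule population with UMIs and mutation labels.

    Per gene the molecule count is Poisson(abundance * rt_efficiency),
    with abundance taken from the per-gene map or drawn log-normally.
    Hotspot-gene molecules are flagged mutant with the planted fraction.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    panel = cfg.panel
    genes: list[str] = []
    for g in panel.genes:
        if isinstance(cfg.n_molecules_per_gene, dict):
            abundance = float(cfg.n_molecules_per_gene.get(g.name, 0))
        else:
            mu, sigma = cfg.n_molecules_per_gene
            abundance = float(np.exp(rng.normal(mu, sigma)))
        n = int(rng.poisson(abundance * cfg.rt_efficiency))
        genes.extend([g.name] * n)
    n_mol = len(genes)
    umis = _umi_strings(rng, n_mol, panel.umi_len, cfg.force_unique_umis)
    hotspot_by_gene: dict[str, tuple[str, float]] = {}
    for h in panel.hotspots:
        af = cfg.planted_af.get(h.label, cfg.planted_af.get(h.gene, 0.0))
        hotspot_by_gene[h.gene] = (h.label or h.gene, af)
    mutant = np.zeros(n_mol, dtype=bool)
    labels: list[str | None] = [None] * n_mol
    for i, g in enumerate(genes):
        if g in hotspot_by_gene:
            lab, af = hotspot_by_gene[g]
            labels[i] = lab
            if af > 0:
                mutant[i] = rng.random() < af
    return GroundTruth(gene=genes, umi=umis, mutant=mutant, hotspot_label=labels)


def _molecule_template(cfg: SimulationConfig, gene_name: str, mutant: bool) -> tuple[str, str]:
    """(R1, R2) error-free read sequences for a molecule of this gene."""
    panel = cfg.panel
    g = panel.gene(gene_name)
    amp = g.amplicon_seq
    if mutant:
        for h in panel.hotspots:
            if h.gene == gene_name:
                off = h.position - g.amplicon_start  # 0-based within amplicon
                if 0 <= off < len(amp):
                    amp = amp[:off] + h.alt_base + amp[off + 1 :]
    r1 = amp + _revcomp(panel.rev_adaptor)
    r2_body = _revcomp(amp) + _revcomp(panel.fwd_adaptor)
    return r1[: cfg.read_len], r2_body  # UMI prepended to r2 later


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size == 0:
        return seq
    for i in hit:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def amplify_and_sequence(
    cfg: SimulationConfig,
    gt: GroundTruth,
    r1_path: str | Path,
    r2_path: str | Path,
    provenance_path: str | Path | None = None,
) -> int:
    """PCR-amplify the molecules and write gzipped R1/R2 FASTQ.

    Each molecule amplifies by a branching process: per cycle every copy
    duplicates with the molecule's own efficiency drawn from
    Beta(a, b).  Reads are a multinomial subsample of the final copy pool
    of size ``library_size`` (all copies when ``library_size`` is None,
    meant for small-cycle exact-recovery runs).  Substitution errors are
    applied per base at ``seq_error_rate``.  Returns the number of read
    pairs written; fills ``gt.duplication_factor``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n_mol = gt.n_molecules
    if n_mol == 0:
        raise ValueError("no molecules to sequence")
    a, b = cfg.pcr_efficiency_beta
    # b == 0 denotes the degenerate "efficiency exactly 1" limit (every copy
    # duplicates every cycle), used for exact-recovery runs
    eff = np.ones(n_mol) if b == 0 else rng.beta(a, b, size=n_mol)
    copies = np.ones(n_mol, dtype=np.int64)
    for _ in range(cfg.pcr_cycles):
        copies = copies + rng.binomial(copies, eff)
    total = int(copies.sum())
    if cfg.library_size is None:
        dup = copies.copy()
    else:
        if cfg.library_size > total:
            raise ValueError(
                f"requested library size {cfg.library_size} exceeds the "
                f"{total} amplified copies"
            )
        dup = rng.multinomial(cfg.library_size, copies / copies.sum())
    gt.duplication_factor = dup

    # per-gene/mutant template cache; per-read UMI prepend + errors
    templates: dict[tuple[str, bool], tuple[str, str]] = {}
    order = rng.permutation(int(dup.sum()))
    mol_of_read = np.repeat(np.arange(n_mol), dup)[order]
    qual = {n: "I" * n for n in set()}  # filled lazily

    def q(n: int) -> str:
        s = qual.get(n)
        if s is None:
            s = qual[n] = "I" * n
        return s

    # fileobj + mtime=0 keeps the gzip header free of name/timestamp, so
    # identical seeds give byte-identical files
    with open(r1_path, "wb") as fh1, open(r2_path, "wb") as fh2, gzip.GzipFile(
        filename="", fileobj=fh1, mode="wb", mtime=0
    ) as raw1, gzip.GzipFile(filename="", fileobj=fh2, mode="wb", mtime=0) as raw2:
        prov_lines = ["read_id\tmolecule_id\tgene\tumi\tmutant\n"]
        for idx, mi in enumerate(mol_of_read):
            mi = int(mi)
            key = (gt.gene[mi], bool(gt.mutant[mi]))
            tpl = templates.get(key)
            if tpl is None:
                tpl = templates[key] = _molecule_template(cfg, key[0], key[1])
            r1 = tpl[0]
            r2 = (gt.umi[mi] + tpl[1])[: cfg.read_len]
            if cfg.seq_error_rate > 0:
                r1 = _apply_errors(r1, rng, cfg.seq_error_rate)
                r2 = _apply_errors(r2, rng, cfg.seq_error_rate)
            rid = f"sim:{idx}"
            raw1.write(f"@{rid}/1\n{r1}\n+\n{q(len(r1))}\n".encode())
            raw2.write(f"@{rid}/2\n{r2}\n+\n{q(len(r2))}\n".encode())
            if provenance_path is not None:
                prov_lines.append(
                    f"{rid}\tm{mi}\t{gt.gene[mi]}\t{gt.umi[mi]}\t{int(gt.mutant[mi])}\n"
                )
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            fh.writelines(prov_lines)
    return int(dup.sum())


def draw_uniform_umis(n: int, k: int, rng: np.random.Generator) -> int:
    """Distinct UMIs among n uniform i.i.d. draws from a space of k."""
    if n == 0:
        return 0
    return int(np.unique(rng.integers(0, k, size=n)).size)


def make_fixture_suite(
    out_dir: str | Path,
    seed: int = 20210204,
    n_pairs: int = 50_000,
) -> dict[str, Path]:
    """Write the canonical small datasets: toy panel, FF-like and FFPE-like
    libraries, and a mutation-bearing library (molecular AF 0.20), each
    with its ground-truth table.  Byte-reproducible for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = toy_panel()
    paths: dict[str, Path] = {"panel": out / "panel.yaml"}
    save_panel(panel, paths["panel"])
    specs = {
        "ff": dict(rt_efficiency=0.8, planted_af={}),
        "ffpe": dict(rt_efficiency=0.3, planted_af={}),
        "mut": dict(
            rt_efficiency=0.8,
            planted_af={panel.hotspots[0].label: 0.20},
        ),
    }
    for i, (name, kw) in enumerate(specs.items()):
        cfg = SimulationConfig(
            panel=panel,
            seed=seed + i,
            n_molecules_per_gene={g: 400 for g in panel.gene_names},
            library_size=n_pairs,
            **kw,
        )
        gt = simulate_molecules(cfg)
        r1 = out / f"{name}_R1.fastq.gz"
        r2 = out / f"{name}_R2.fastq.gz"
        amplify_and_sequence(cfg, gt, r1, r2, out / f"{name}_provenance.tsv")
        gt.to_tsv(out / f"{name}_truth.tsv")
        paths[f"{name}_r1"] = r1
        paths[f"{name}_r2"] = r2
        paths[f"{name}_truth"] = out / f"{name}_truth.tsv"
    return paths
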