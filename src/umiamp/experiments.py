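"""Validation experiments run at desk scale.

The headline comparisons behind the assay (technical-replicate CV of
reads-based vs UMI-based measurements, saturation against the binomial
ideal, planted-mutation recovery) are re-created here on synthetic
libraries whose ground truth is known.  Library sizes are kept small
(hundreds to low thousands of read pairs; tens of replicates) — large
enough for the qualitative contrasts and binomial error bars to be
meaningful, small enough to run on a laptop in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np

from . import mutcall, pipeline, stats
from .panel import TargetPanel, toy_panel, umi_space_size
from .readproc import PanelAligner
from .simulate import SimulationConfig, amplify_and_sequence, draw_uniform_umis, simulate_molecules

__all__ = [
    "saturation_mc",
    "nb_dispersion_recovery",
    "exact_recovery",
    "af_recovery",
    "CvContrast",
    "cv_contrast",
]

HIGH_BIAS_BETA = (0.5, 2.0)  # original bulk-PCR-like amplification bias
LOW_BIAS_BETA = (20.0, 1.0)  # optimised droplet-PCR-like evenness


def saturation_mc(
    n_values: tuple[int, ...] = (10_000, 100_000, 1_000_000),
    n_seeds: int = 50,
    umi_len: int = 8,
    seed: int = 0,
) -> dict[int, dict[str, float]]:
    """Observed vs binomial saturation for uniform i.i.d. UMI draws.

    For each library size, draws UMIs uniformly over the 4**umi_len space
    across ``n_seeds`` replicates and reports the mean observed
    saturation, the binomial expectation, and the Monte-Carlo standard
    error of the mean.
    """
    k = umi_space_size(umi_len)
    out: dict[int, dict[str, float]] = {}
    for n in n_values:
        obs = np.empty(n_seeds)
        for s in range(n_seeds):
            rng = np.random.default_rng([seed, n % (2**20), s])
            obs[s] = 100.0 * draw_uniform_umis(n, k, rng) / k
        out[n] = {
            "observed_mean_pct": float(obs.mean()),
            "theoretical_pct": stats.theoretical_saturation(n, k),
            "mc_se": float(obs.std(ddof=1) / np.sqrt(n_seeds)),
            # discreteness floor: one UMI in % of the space (near-exhausted
            # libraries can have zero empirical spread)
            "one_umi_pct": 100.0 / k,
        }
    return out


def nb_dispersion_recovery(
    r_true_values: tuple[float, ...] = (0.5, 2.0, 10.0),
    umi_len: int = 8,
    seed: int = 0,
) -> dict[float, float]:
    """Fit the NB saturation curve to points generated at known dispersion.

    Points span library sizes 1e4-1e6 with mild multiplicative noise on
    the distinct-UMI counts; returns fitted r per true r.
    """
    k = umi_space_size(umi_len)
    rng = np.random.default_rng([seed, 17])
    n_grid = np.geomspace(1e4, 1e6, 12).astype(int)
    out: dict[float, float] = {}
    for r in r_true_values:
        points = []
        for i, n in enumerate(n_grid):
            mu = n / k
            sat = 1.0 - (1.0 + mu / r) ** (-r)
            distinct = int(round(k * sat * float(np.exp(rng.normal(0, 0.01)))))
            points.append(
                stats.SaturationPoint(
                    library_id=f"r{r}:{i}", library_size_n=int(n),
                    distinct_umis=max(distinct, 1), umi_space=k,
                )
            )
        out[r] = stats.fit_nb_saturation(points, k).dispersion_r
    return out


def _run_library(cfg: SimulationConfig, panel: TargetPanel, aligner: PanelAligner,
                 workdir: Path, tag: str) -> pipeline.LibraryResult:
    gt = simulate_molecules(cfg)
    r1, r2 = workdir / f"{tag}_R1.fastq.gz", workdir / f"{tag}_R2.fastq.gz"
    amplify_and_sequence(cfg, gt, r1, r2)
    res = pipeline.quantify_library(r1, r2, panel, seed=cfg.seed, library_id=tag, aligner=aligner)
    res.ground_truth = gt  # type: ignore[attr-defined]
    return res


def exact_recovery(
    n_seeds: int = 20,
    molecules_per_gene: int = 60,
    seed: int = 0,
    panel: TargetPanel | None = None,
) -> dict[str, float]:
    """Error-free, collision-free end-to-end runs: UMI counts vs truth.

    Each run uses unique UMIs, zero sequencing error, degenerate
    amplification (one doubling cycle), and emits every copy, so the UMI
    pipeline should return the simulated molecule counts exactly.
    Returns the fraction of (seed, gene) cells recovered exactly and the
    maximum absolute deviation.
    """
    panel = panel or toy_panel()
    aligner = PanelAligner(panel)
    exact = 0
    cells = 0
    max_dev = 0
    with TemporaryDirectory() as td:
        for s in range(n_seeds):
            cfg = SimulationConfig(
                panel=panel,
                seed=seed * 1000 + s,
                n_molecules_per_gene={g: molecules_per_gene for g in panel.gene_names},
                pcr_cycles=1,
                pcr_efficiency_beta=(1.0, 0.0),
                seq_error_rate=0.0,
                library_size=None,
                force_unique_umis=True,
            )
            res = _run_library(cfg, panel, aligner, Path(td), f"er{s}")
            truth = res.ground_truth.molecules_per_gene  # type: ignore[attr-defined]
            for g in panel.gene_names:
                cells += 1
                dev = abs(res.counts_umis.counts[g] - truth.get(g, 0))
                max_dev = max(max_dev, dev)
                exact += dev == 0
    return {"fraction_exact": exact / cells, "max_abs_deviation": float(max_dev)}


def af_recovery(
    planted_af: float = 0.20,
    n_seeds: int = 20,
    molecules_per_gene: int = 60,
    seed: int = 0,
    panel: TargetPanel | None = None,
) -> dict[str, float]:
    """Pooled UMI-mode AF estimate at a planted molecular mutant fraction.

    Same error-free regime as :func:`exact_recovery`; pools alt and total
    UMI depth at the hotspot across seeds and reports the estimate with
    the half-width of the binomial 95% CI around the planted value.
    """
    panel = panel or toy_panel()
    hotspot = panel.hotspots[0]
    aligner = PanelAligner(panel)
    alt = depth = 0
    with TemporaryDirectory() as td:
        for s in range(n_seeds):
            cfg = SimulationConfig(
                panel=panel,
                seed=seed * 1000 + 500 + s,
                n_molecules_per_gene={g: molecules_per_gene for g in panel.gene_names},
                pcr_cycles=1,
                pcr_efficiency_beta=(1.0, 0.0),
                seq_error_rate=0.0,
                library_size=None,
                force_unique_umis=True,
                planted_af={hotspot.label: planted_af},
            )
            res = _run_library(cfg, panel, aligner, Path(td), f"af{s}")
            p = mutcall.pileup_hotspot(res.pairs, hotspot, res.representative_ids)
            alt += p.alt_umis
            depth += p.depth_umis
    est = alt / depth
    half = 1.96 * np.sqrt(planted_af * (1 - planted_af) / depth)
    return {
        "estimated_af_pct": 100.0 * est,
        "planted_af_pct": 100.0 * planted_af,
        "ci_halfwidth_pct": 100.0 * float(half),
        "pooled_depth_umis": float(depth),
    }


@dataclass
class CvContrast:
    """Across-replicate CVs of counts and hotspot AF, both counting modes."""

    bias_beta: tuple[float, float]
    n_replicates: int
    median_cv_counts_reads: float
    median_cv_counts_umis: float
    cv_af_reads: float
    cv_af_umis: float


def cv_contrast(
    bias_beta: tuple[float, float],
    n_replicates: int = 20,
    molecules_per_gene: int = 80,
    library_size: int = 3000,
    planted_af: float = 0.30,
    pcr_cycles: int = 20,
    seed: int = 0,
    panel: TargetPanel | None = None,
) -> CvContrast:
    """Technical-replicate CV under a given amplification-bias regime.

    One molecule population is amplified and sequenced ``n_replicates``
    times with fresh per-molecule PCR efficiencies drawn from
    ``bias_beta``; reads-based and UMI-based per-gene counts and hotspot
    AFs are collected per replicate, and the across-replicate CV is
    returned (median over genes for counts).

    The defaults put the libraries inside the assay's operating range:
    ~7.5 reads per molecule, so most of the library complexity is
    sequenced, and a moderate cycle count, so the hotspot's UMI depth
    stays above the 10-UMI floor the mutation caller itself requires.
    With efficiencies compounding over many more cycles under a wide
    Beta, a handful of molecules monopolise the read pool and the AF is
    not a valid assay measurement in the first place.
    """
    panel = panel or toy_panel()
    hotspot = panel.hotspots[0]
    aligner = PanelAligner(panel)
    base_cfg = SimulationConfig(
        panel=panel,
        seed=seed * 100 + 7,
        n_molecules_per_gene={g: molecules_per_gene for g in panel.gene_names},
        pcr_cycles=pcr_cycles,
        pcr_efficiency_beta=bias_beta,
        planted_af={hotspot.label: planted_af},
        library_size=library_size,
    )
    gt = simulate_molecules(base_cfg)  # shared molecule population
    counts_r: dict[str, list[int]] = {g: [] for g in panel.gene_names}
    counts_u: dict[str, list[int]] = {g: [] for g in panel.gene_names}
    afs_r: list[float] = []
    afs_u: list[float] = []
    with TemporaryDirectory() as td:
        for rep in range(n_replicates):
            cfg = SimulationConfig(
                panel=panel,
                seed=seed * 100 + 7 + 13 * (rep + 1),
                n_molecules_per_gene=base_cfg.n_molecules_per_gene,
                pcr_cycles=pcr_cycles,
                pcr_efficiency_beta=bias_beta,
                planted_af=base_cfg.planted_af,
                library_size=library_size,
            )
            r1 = Path(td) / f"rep{rep}_R1.fastq.gz"
            r2 = Path(td) / f"rep{rep}_R2.fastq.gz"
            amplify_and_sequence(cfg, gt, r1, r2)
            res = pipeline.quantify_library(r1, r2, panel, seed=cfg.seed,
                                            library_id=f"rep{rep}", aligner=aligner)
            for g in panel.gene_names:
                counts_r[g].append(res.counts_reads.counts[g])
                counts_u[g].append(res.counts_umis.counts[g])
            p = mutcall.pileup_hotspot(res.pairs, hotspot, res.representative_ids)
            afs_r.append(mutcall.compute_af(p, "reads"))
            afs_u.append(mutcall.compute_af(p, "umis"))

    def cv(vals) -> float:
        arr = np.asarray(vals, dtype=float)
        return float(100.0 * arr.std(ddof=1) / arr.mean())

    return CvContrast(
        bias_beta=bias_beta,
        n_replicates=n_replicates,
        median_cv_counts_reads=float(np.median([cv(v) for v in counts_r.values()])),
        median_cv_counts_umis=float(np.median([cv(v) for v in counts_u.values()])),
        cv_af_reads=cv(afs_r),
        cv_af_umis=cv(afs_u),
    )
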