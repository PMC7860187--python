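"""Concordance, reproducibility and sequencing-saturation statistics.

Lin's concordance correlation coefficient (CCC) measures agreement of two
measurement series against the identity line and factors into a precision
term (Pearson rho) and an accuracy term C_b = 2 / (v + 1/v + u**2), where
v = s_x / s_y is the scale shift and u = (mean_x - mean_y) / sqrt(s_x s_y)
the location shift.  Moments are population (1/n) moments, per Lin's
original estimator; the 95% CI uses the Fisher z-transform of the CCC.

Saturation: with library size n and UMI space k = 4**umi_len, reads whose
UMIs are uniform i.i.d. draws observe on average a fraction
1 - (1 - 1/k)**n of the k possible UMIs.  Overdispersed amplification is
modelled by a negative binomial on reads-per-possible-UMI with mean
mu = n/k and dispersion r, giving saturation 1 - (1 + mu/r)**(-r); the
binomial curve is the r -> infinity limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats as sps

__all__ = [
    "ConcordanceResult",
    "SaturationPoint",
    "NbSaturationFit",
    "ProtocolComparison",
    "lins_ccc",
    "replicate_abs_difference",
    "compare_protocol_metrics",
    "theoretical_saturation",
    "expected_reads_per_umi",
    "fit_nb_saturation",
    "reads_per_target",
]

ALPHA = 0.05


@dataclass
class ConcordanceResult:
    ccc: float
    ci_low: float
    ci_high: float
    rho: float
    bias_cb: float
    scale_v: float
    location_u: float
    n: int


@dataclass
class SaturationPoint:
    library_id: str
    library_size_n: int
    distinct_umis: int
    umi_space: int

    @property
    def saturation_pct(self) -> float:
        return 100.0 * self.distinct_umis / self.umi_space

    @property
    def reads_per_umi(self) -> float:
        return self.library_size_n / self.distinct_umis


@dataclass
class NbSaturationFit:
    dispersion_r: float
    umi_space: int
    residuals: np.ndarray

    def predict_pct(self, n) -> np.ndarray:
        """Fitted saturation (%) at library size(s) n."""
        mu = np.asarray(n, dtype=float) / self.umi_space
        return 100.0 * (1.0 - (1.0 + mu / self.dispersion_r) ** (-self.dispersion_r))


@dataclass
class ProtocolComparison:
    location_test: str
    location_p: float
    levene_p: float
    location_significant: bool
    variance_significant: bool


def lins_ccc(x: Sequence[float], y: Sequence[float]) -> ConcordanceResult:
    """Lin's CCC with its precision/accuracy decomposition and Fisher-z CI.

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), population
    moments.  Raises on length mismatch, n < 3, non-finite input or zero
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    mx, my = x.mean(), y.mean()
    vx = float(np.mean((x - mx) ** 2))
    vy = float(np.mean((y - my) ** 2))
    if vx == 0.0 or vy == 0.0:
        raise ValueError("zero variance in input vector")
    sxy = float(np.mean((x - mx) * (y - my)))
    ccc = 2.0 * sxy / (vx + vy + (mx - my) ** 2)
    rho = sxy / math.sqrt(vx * vy)
    v = math.sqrt(vx / vy)
    u = (mx - my) / (vx * vy) ** 0.25
    cb = 2.0 / (v + 1.0 / v + u * u)
    if abs(ccc) >= 1.0:  # perfect (anti)concordance: Fisher z degenerates
        ci_low = ci_high = ccc
    else:
        z = math.atanh(ccc)
        half = sps.norm.ppf(1 - ALPHA / 2) / math.sqrt(n - 2)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    return ConcordanceResult(
        ccc=ccc,
        ci_low=ci_low,
        ci_high=ci_high,
        rho=rho,
        bias_cb=cb,
        scale_v=v,
        location_u=u,
        n=n,
    )


def replicate_abs_difference(
    expr_a: dict[str, float], expr_b: dict[str, float]
) -> tuple[dict[str, float], float]:
    """Per-gene |difference| between two replicate profiles, and its median."""
    if set(expr_a) != set(expr_b):
        raise ValueError("replicate profiles cover different gene sets")
    diffs = {g: abs(expr_a[g] - expr_b[g]) for g in expr_a}
    return diffs, float(np.median(list(diffs.values())))


def compare_protocol_metrics(
    m1: Sequence[float], m2: Sequence[float], paired: bool
) -> ProtocolComparison:
    """Nonparametric location test plus Levene's variance test at alpha 0.05.

    Paired samples use the Wilcoxon signed-rank test (explicit error when
    every paired difference is zero, where the test is undefined);
    unpaired use the Mann-Whitney U-test.  Levene's test is the
    median-centred (Brown-Forsythe) variant.
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired vectors must have equal length")
        if np.all(a == b):
            raise ValueError("all paired differences are zero; signed-rank test undefined")
        loc_name, loc_p = "wilcoxon_signed_rank", float(sps.wilcoxon(a, b).pvalue)
    else:
        loc_name, loc_p = "mann_whitney_u", float(sps.mannwhitneyu(a, b).pvalue)
    lev_p = float(sps.levene(a, b, center="median").pvalue)
    return ProtocolComparison(
        location_test=loc_name,
        location_p=loc_p,
        levene_p=lev_p,
        location_significant=loc_p < ALPHA,
        variance_significant=lev_p < ALPHA,
    )


def theoretical_saturation(n: int, k: int) -> float:
    """Expected % of the k possible UMIs seen after n uniform i.i.d. draws."""
    if k < 1:
        raise ValueError("UMI space must be >= 1")
    if n < 0:
        raise ValueError("library size must be >= 0")
    if k == 1:
        return 100.0 if n else 0.0
    return float(100.0 * -np.expm1(n * np.log1p(-1.0 / k)))


def expected_reads_per_umi(n: int, k: int) -> float:
    """Expected library size / distinct UMIs under uniform UMI draws."""
    if n < 1:
        raise ValueError("library size must be >= 1")
    return n / (k * theoretical_saturation(n, k) / 100.0)


def fit_nb_saturation(points: Sequence[SaturationPoint], k: int | None = None) -> NbSaturationFit:
    """Fit the negative-binomial saturation curve's dispersion r.

    Least squares of observed saturation_pct against
    100 (1 - (1 + (n/k)/r)^(-r)) over the supplied points, optimising
    log r for positivity.  Needs >= 3 points at >= 2 distinct library
    sizes; reports residuals with a non-convergence error otherwise.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 saturation points")
    k = k or points[0].umi_space
    n = np.array([p.library_size_n for p in points], dtype=float)
    sat = np.array([p.saturation_pct for p in points], dtype=float)
    if np.unique(n).size < 2:
        raise ValueError("cannot fit dispersion: all points share one library size")

    def resid(logr: np.ndarray) -> np.ndarray:
        r = np.exp(logr[0])
        mu = n / k
        return 100.0 * (1.0 - (1.0 + mu / r) ** (-r)) - sat

    sol = optimize.least_squares(resid, x0=[0.0], method="lm", max_nfev=2000)
    if not sol.success:
        raise ValueError(f"NB saturation fit did not converge; residuals {sol.fun}")
    return NbSaturationFit(dispersion_r=float(np.exp(sol.x[0])), umi_space=k, residuals=sol.fun)


def reads_per_target(total_reads: int, n_targets: int) -> int:
    """Floor-average reads per target (e.g. 400,000 over 47 targets -> 8,510)."""
    if n_targets < 1:
        raise ValueError("need at least one target")
    return total_reads // n_targets
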