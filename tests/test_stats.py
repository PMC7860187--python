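import math

import numpy as np
import pytest

from umiamp.stats import (
    SaturationPoint,
    compare_protocol_metrics,
    expected_reads_per_umi,
    fit_nb_saturation,
    lins_ccc,
    reads_per_target,
    replicate_abs_difference,
    theoretical_saturation,
)


def ccc_oracle(x, y):
    """Direct-definition concordance: 2*sxy / (sx2 + sy2 + (mx-my)^2)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    sxy = np.mean((x - mx) * (y - my))
    return 2 * sxy / (np.mean((x - mx) ** 2) + np.mean((y - my) ** 2) + (mx - my) ** 2)


class TestLinsCcc:
    def test_identity_is_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r = lins_ccc(x, x)
        assert r.ccc == pytest.approx(1.0)
        assert r.rho == pytest.approx(1.0)
        assert r.bias_cb == pytest.approx(1.0)
        assert r.scale_v == pytest.approx(1.0)
        assert r.location_u == pytest.approx(0.0)

    def test_constant_shift_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        c = 1.5
        r = lins_ccc(x, x + c)
        s2 = np.mean((x - x.mean()) ** 2)
        assert r.rho == pytest.approx(1.0)
        assert r.ccc == pytest.approx(2 * s2 / (2 * s2 + c**2), abs=1e-12)

    def test_matches_direct_definition_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 2.1, 2.9, 4.2])
        r = lins_ccc(x, y)
        assert r.ccc == pytest.approx(ccc_oracle(x, y), abs=1e-12)

    def test_decomposition_identity_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(3, 40)
            x = rng.normal(rng.normal(0, 2), rng.uniform(0.5, 3), n)
            y = x * rng.uniform(0.5, 2) + rng.normal(0, 1, n)
            r = lins_ccc(x, y)
            assert r.ccc == pytest.approx(ccc_oracle(x, y), abs=1e-12)
            assert r.ccc == pytest.approx(
                r.rho * 2 / (r.scale_v + 1 / r.scale_v + r.location_u**2), abs=1e-12
            )
            assert abs(r.ccc) <= abs(r.rho) + 1e-12

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(1, 2, 20)
        a, b = lins_ccc(x, y), lins_ccc(y, x)
        assert a.ccc == pytest.approx(b.ccc, abs=1e-12)
        assert a.scale_v == pytest.approx(1 / b.scale_v, abs=1e-12)
        assert a.location_u == pytest.approx(-b.location_u, abs=1e-12)

    def test_ci_brackets_ccc(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 30)
        r = lins_ccc(x, x + rng.normal(0, 0.3, 30))
        assert r.ci_low < r.ccc < r.ci_high

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            lins_ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestReplicateDifference:
    def test_identical_profiles(self):
        e = {"A": 1.0, "B": -0.5}
        diffs, med = replicate_abs_difference(e, e)
        assert med == 0.0 and all(v == 0.0 for v in diffs.values())

    def test_uniform_offset(self):
        a = {"A": 1.0, "B": 2.0, "C": 0.0}
        b = {g: v + 0.3 for g, v in a.items()}
        _, med = replicate_abs_difference(a, b)
        assert med == pytest.approx(0.3)

    def test_gene_set_mismatch(self):
        with pytest.raises(ValueError):
            replicate_abs_difference({"A": 1.0}, {"B": 1.0})


class TestProtocolComparison:
    def test_all_tied_paired_differences_error(self):
        with pytest.raises(ValueError, match="tied|zero"):
            compare_protocol_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)

    def test_shifted_samples_detected_unpaired(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 300)
        b = rng.normal(1, 1, 300)
        r = compare_protocol_metrics(a, b, paired=False)
        assert r.location_test == "mann_whitney_u"
        assert r.location_p < 0.05 and r.location_significant

    def test_levene_keeps_type_i_error_near_nominal(self):
        rng = np.random.default_rng(9)
        rejections = sum(
            compare_protocol_metrics(
                rng.normal(0, 1, 40), rng.normal(0.5, 1, 40), paired=False
            ).variance_significant
            for _ in range(200)
        )
        assert rejections / 200 < 0.12  # ~5% nominal, generous MC slack

    def test_paired_uses_signed_rank(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 50)
        r = compare_protocol_metrics(a, a + rng.normal(0.8, 0.5, 50), paired=True)
        assert r.location_test == "wilcoxon_signed_rank"
        assert r.location_p < 0.05


class TestSaturationMath:
    def test_zero_reads_zero_saturation(self):
        assert theoretical_saturation(0, 65_536) == 0.0

    def test_n_equals_k_is_one_minus_inv_e(self):
        k = 65_536
        sat = theoretical_saturation(k, k)
        assert sat == pytest.approx(100 * (1 - (1 - 1 / k) ** k), abs=1e-9)
        assert sat == pytest.approx(100 * (1 - math.exp(-1)), abs=0.01)
        assert round(sat, 2) == 63.21

    def test_monotone_to_100(self):
        k = 65_536
        vals = [theoretical_saturation(n, k) for n in (0, 100, 1000, 10_000, 10**5, 10**6)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert 99.9 < vals[-1] < 100.0

    def test_reads_per_umi_closed_forms(self):
        assert expected_reads_per_umi(1, 65_536) == pytest.approx(1.0)
        k = 65_536
        assert expected_reads_per_umi(k, k) == pytest.approx(1 / (1 - (1 - 1 / k) ** k), abs=1e-9)
        assert expected_reads_per_umi(k, k) == pytest.approx(1.582, abs=1e-3)

    def test_reads_per_umi_monotone_in_n(self):
        k = 65_536
        vals = [expected_reads_per_umi(n, k) for n in (1, 10, 10**3, 10**5, 10**6)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_saturation_and_reads_per_umi_consistent(self):
        k = 65_536
        for n in (10, 10**4, 10**6):
            sat = theoretical_saturation(n, k) / 100
            assert n / (k * sat) == pytest.approx(expected_reads_per_umi(n, k), rel=1e-12)


class TestNbSaturationFit:
    @staticmethod
    def _points(r, k=65_536, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = []
        for i, n in enumerate(np.geomspace(1e4, 1e6, 10).astype(int)):
            mu = n / k
            sat = 1 - (1 + mu / r) ** (-r)
            d = int(round(k * sat * np.exp(rng.normal(0, noise))))
            pts.append(SaturationPoint(f"p{i}", int(n), max(d, 1), k))
        return pts

    def test_binomial_limit_consistency(self):
        # points generated from the binomial model (r -> inf): fitted curve
        # within 0.5 percentage points of the binomial curve over the range
        k = 65_536
        pts = [
            SaturationPoint(f"p{i}", int(n), int(round(k * -np.expm1(n * np.log1p(-1 / k)))), k)
            for i, n in enumerate(np.geomspace(1e4, 1e6, 10).astype(int))
        ]
        fit = fit_nb_saturation(pts, k)
        for p in pts:
            assert abs(fit.predict_pct(p.library_size_n) - p.saturation_pct) < 0.5

    @pytest.mark.parametrize("r_true", [0.5, 2.0, 10.0])
    def test_dispersion_recovery_within_20pct(self, r_true):
        fit = fit_nb_saturation(self._points(r_true, noise=0.005), 65_536)
        assert fit.dispersion_r == pytest.approx(r_true, rel=0.2)

    def test_overdispersed_curve_sits_below_binomial(self):
        fit = fit_nb_saturation(self._points(0.8), 65_536)
        for n in (10**4, 10**5, 10**6):
            assert fit.predict_pct(n) < theoretical_saturation(n, 65_536)

    def test_degenerate_single_point_errors(self):
        p = SaturationPoint("p", 10_000, 5000, 65_536)
        with pytest.raises(ValueError):
            fit_nb_saturation([p, p, p])


class TestReadsPerTarget:
    @pytest.mark.parametrize(
        "total,targets,expected",
        [(400_000, 47, 8_510), (3_000_000, 1_385, 2_166), (3_000_000, 507, 5_917)],
    )
    def test_recommended_depth_arithmetic(self, total, targets, expected):
        assert reads_per_target(total, targets) == expected
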