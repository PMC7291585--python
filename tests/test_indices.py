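"""indices: the five agreement measures and the report assembly."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from agreekit import (
    AgreementSettings,
    DiffModelFit,
    FullModelFit,
    anova_loa,
    build_report,
    ccc_repeated,
    cia,
    coverage_probability,
    loa_from_diff_model,
    loa_from_full_model,
    msd,
    naive_indices,
    pair_differences,
    repeatability_coefficient,
    sample_paired_differences,
    tdi,
)
from agreekit.errors import DataError, UndefinedIndexError

from conftest import make_table


@pytest.fixture(scope="module")
def published_fit():
    """Fit object carrying the published component estimates."""
    return FullModelFit.from_components(
        device_diff=-1.28,
        var_subject=11.4,
        var_activity=16.6,
        var_subject_device=0.4,
        var_subject_activity=6.0,
        var_device_activity=3.7,
        var_resid=10.5,
    )


@pytest.fixture(scope="module")
def published_diff_fit():
    return DiffModelFit.from_components(
        mu0_star=-1.60,
        var_subject_star=0.96,
        var_activity_star=7.57,
        var_resid_star=17.37,
    )


class TestCCC:
    def test_published_components(self, published_fit):
        # direct arithmetic on the rounded component estimates
        assert ccc_repeated(published_fit) == pytest.approx(0.688, abs=5e-4)

    def test_perfect_agreement_limit(self):
        fit = FullModelFit.from_components(0.0, 3.0, 2.0, 0.0, 1.0, 0.0, 0.0)
        assert ccc_repeated(fit) == pytest.approx(1.0)

    def test_zero_total_variance_undefined(self):
        fit = FullModelFit.from_components(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(UndefinedIndexError):
            ccc_repeated(fit)

    def test_shift_invariance(self, published_fit):
        shifted = FullModelFit.from_components(
            device_diff=published_fit.device_diff,
            var_subject=published_fit.var_subject,
            var_activity=published_fit.var_activity,
            var_subject_device=published_fit.var_subject_device,
            var_subject_activity=published_fit.var_subject_activity,
            var_device_activity=published_fit.var_device_activity,
            var_resid=published_fit.var_resid,
            mu=published_fit.mu + 100.0,
        )
        assert ccc_repeated(shifted) == ccc_repeated(published_fit)

    def test_monotone_in_subject_variance(self, published_fit):
        vals = []
        for vs in (1.0, 5.0, 11.4, 30.0, 100.0):
            fit = FullModelFit.from_components(
                -1.28, vs, 16.6, 0.4, 6.0, 3.7, 10.5
            )
            vals.append(ccc_repeated(fit))
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestMSD:
    def test_published_components(self, published_fit):
        assert msd(published_fit) == pytest.approx(30.8384)
        assert round(msd(published_fit), 1) == 30.8

    def test_all_zero(self):
        assert msd(FullModelFit.from_components(0, 0, 0, 0, 0, 0, 0)) == 0.0

    def test_sign_free_in_device_diff(self, published_fit):
        flipped = FullModelFit.from_components(1.28, 11.4, 16.6, 0.4, 6.0, 3.7, 10.5)
        assert msd(flipped) == pytest.approx(msd(published_fit))

    def test_monte_carlo_oracle(self, published_fit):
        d = sample_paired_differences(
            1_000_000, -1.28, 0.4, 3.7, 10.5, rng=42
        )
        assert np.mean(d**2) == pytest.approx(msd(published_fit), rel=0.01)

    def test_invariant_under_common_shift(self, published_fit):
        # adding a constant to both devices changes mu only
        assert msd(published_fit) == msd(
            FullModelFit.from_components(-1.28, 11.4, 16.6, 0.4, 6.0, 3.7, 10.5, mu=55.0)
        )


class TestCPandTDI:
    def test_published_cp(self):
        assert coverage_probability(30.8384, 5.0) == pytest.approx(0.632, abs=5e-4)
        assert round(coverage_probability(30.8384, 5.0), 2) == 0.63

    def test_published_tdi(self):
        assert tdi(30.8384, 0.95) == pytest.approx(10.884, abs=5e-3)
        assert round(tdi(30.8384, 0.95), 1) == 10.9

    def test_huge_delta_gives_one(self):
        assert coverage_probability(30.8384, 1e6) == pytest.approx(1.0)

    def test_zero_msd(self):
        assert coverage_probability(0.0, 5.0) == 1.0
        assert tdi(0.0, 0.9) == 0.0

    def test_argument_errors(self):
        with pytest.raises(DataError):
            coverage_probability(-1.0, 5.0)
        with pytest.raises(DataError):
            coverage_probability(4.0, -2.0)
        with pytest.raises(DataError):
            tdi(4.0, 1.5)

    @pytest.mark.parametrize("msd_value", [0.4, 4.0, 30.8384, 300.0])
    @pytest.mark.parametrize("p", [0.05, 0.5, 0.8, 0.95, 0.999])
    def test_duality(self, msd_value, p):
        assert coverage_probability(msd_value, tdi(msd_value, p)) == pytest.approx(
            p, abs=1e-12
        )

    def test_cp_monotone(self):
        deltas = np.linspace(0.5, 20, 15)
        cps = [coverage_probability(30.8384, d) for d in deltas]
        assert all(a < b for a, b in zip(cps, cps[1:]))
        msds = np.linspace(1, 100, 15)
        cps2 = [coverage_probability(m, 5.0) for m in msds]
        assert all(a > b for a, b in zip(cps2, cps2[1:]))

    def test_tdi_monte_carlo_median(self):
        # p = 0.5: TDI is the median absolute difference
        rng = np.random.default_rng(7)
        d = rng.normal(0.0, 2.0, size=1_000_000)
        assert tdi(4.0, 0.5) == pytest.approx(
            np.median(np.abs(d)), rel=0.01
        )

    def test_cp_monte_carlo(self):
        d = sample_paired_differences(1_000_000, -1.28, 0.4, 3.7, 10.5, rng=3)
        frac = np.mean(np.abs(d) < 5.0)
        assert coverage_probability(30.8384, 5.0) == pytest.approx(frac, abs=0.003)


class TestCIA:
    def test_published_components(self, published_fit):
        assert cia(published_fit) == pytest.approx(0.681, abs=5e-4)
        assert round(cia(published_fit), 2) == 0.68

    def test_equals_one_without_device_terms(self):
        fit = FullModelFit.from_components(0.0, 5.0, 2.0, 0.0, 1.0, 0.0, 3.0)
        assert cia(fit) == pytest.approx(1.0)

    def test_zero_residual_undefined(self):
        fit = FullModelFit.from_components(1.0, 5.0, 2.0, 0.5, 1.0, 0.5, 0.0)
        with pytest.raises(UndefinedIndexError):
            cia(fit)

    def test_monotone_in_interaction_variances(self):
        vals = []
        for scale in (1.0, 0.5, 0.25, 0.1):
            fit = FullModelFit.from_components(
                -1.28, 11.4, 16.6, 0.4 * scale, 6.0, 3.7 * scale, 10.5
            )
            vals.append(cia(fit))
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_invariant_to_subject_and_activity_variance(self, published_fit):
        other = FullModelFit.from_components(-1.28, 99.0, 0.01, 0.4, 42.0, 3.7, 10.5)
        assert cia(other) == pytest.approx(cia(published_fit))


class TestRepeatability:
    def test_published(self, published_fit):
        assert repeatability_coefficient(published_fit) == pytest.approx(8.98, abs=5e-3)

    def test_zero(self):
        assert repeatability_coefficient(
            FullModelFit.from_components(0, 0, 0, 0, 0, 0, 0)
        ) == 0.0

    def test_half_unit_variance(self):
        fit = FullModelFit.from_components(0, 0, 0, 0, 0, 0, 0.5)
        assert repeatability_coefficient(fit) == pytest.approx(1.96)


class TestLoA:
    def test_published_diff_model(self, published_diff_fit):
        bias, lo, hi = loa_from_diff_model(published_diff_fit)
        assert bias == pytest.approx(-1.60)
        assert lo == pytest.approx(-11.57, abs=5e-3)
        assert hi == pytest.approx(8.37, abs=5e-3)

    def test_zero_variance(self):
        fit = DiffModelFit.from_components(-2.0, 0.0, 0.0, 0.0)
        assert loa_from_diff_model(fit) == (-2.0, -2.0, -2.0)

    def test_unit_multiplier_arithmetic(self):
        fit = DiffModelFit.from_components(0.0, 1.0, 1.0, 2.0)
        bias, lo, hi = loa_from_diff_model(fit, multiplier=1.0)
        assert (bias, lo, hi) == (0.0, -2.0, 2.0)

    def test_full_model_published(self, published_fit):
        bias, lo, hi = loa_from_full_model(published_fit)
        assert bias == pytest.approx(-1.28)
        assert lo == pytest.approx(-11.87, abs=5e-3)
        assert hi == pytest.approx(9.31, abs=5e-3)

    def test_full_model_identical_devices(self):
        fit = FullModelFit.from_components(0.0, 5.0, 2.0, 0.0, 1.0, 0.0, 0.0)
        assert loa_from_full_model(fit) == (0.0, 0.0, 0.0)

    def test_halfwidth_msd_identity(self, published_fit):
        # (upper-lower) = 2 m sqrt(MSD - bias^2)
        m = 1.96
        bias, lo, hi = loa_from_full_model(published_fit, m)
        assert hi - lo == pytest.approx(
            2 * m * math.sqrt(msd(published_fit) - bias**2)
        )


class TestNaiveIndices:
    def test_identical_devices(self):
        rows = []
        vals = [18.0, 22.0, 25.0, 17.0]
        for i, v in enumerate(vals):
            rows.append((f"s{i % 2}", "gold", "sit", i // 2 + 1, v))
            rows.append((f"s{i % 2}", "chest", "sit", i // 2 + 1, v))
        pairs = pair_differences(make_table(rows))
        out = naive_indices(pairs)
        assert out["pearson"] == pytest.approx(1.0)
        assert out["lin_ccc"] == pytest.approx(1.0)
        assert out["simple_loa"] == (0.0, 0.0)

    def test_toy_pairs_hand_arithmetic(self):
        ref = np.array([20.0, 16.0, 24.0, 20.0])
        tst = np.array([18.0, 14.0, 23.0, 17.0])
        rows = []
        for i, (r, t) in enumerate(zip(ref, tst)):
            rows.append((f"s{i % 2}", "gold", "sit", i // 2 + 1, r))
            rows.append((f"s{i % 2}", "chest", "sit", i // 2 + 1, t))
        pairs = pair_differences(make_table(rows))
        out = naive_indices(pairs)
        # brute-force oracle on the toy numbers
        pear = np.corrcoef(ref, tst)[0, 1]
        s1, s2 = np.var(ref), np.var(tst)
        s12 = np.mean((ref - ref.mean()) * (tst - tst.mean()))
        lin = 2 * s12 / (s1 + s2 + (ref.mean() - tst.mean()) ** 2)
        d = tst - ref
        assert out["pearson"] == pytest.approx(pear)
        assert out["lin_ccc"] == pytest.approx(lin)
        assert out["bias"] == pytest.approx(d.mean())
        assert out["simple_loa"][0] == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))

    def test_zero_variance_undefined(self):
        rows = [
            ("A", "gold", "sit", 1, 5.0),
            ("A", "chest", "sit", 1, 5.0),
            ("B", "gold", "sit", 1, 5.0),
            ("B", "chest", "sit", 1, 6.0),
            ("A", "gold", "sit", 2, 5.0),
            ("A", "chest", "sit", 2, 4.0),
        ]
        pairs = pair_differences(make_table(rows))
        with pytest.raises(UndefinedIndexError):
            naive_indices(pairs)


class TestAnovaLoA:
    def test_balanced_toy_hand_anova(self):
        rows = [
            ("A", "gold", "sit", 1, 0.0),
            ("A", "chest", "sit", 1, 1.0),
            ("A", "gold", "sit", 2, 0.0),
            ("A", "chest", "sit", 2, 3.0),
            ("B", "gold", "sit", 1, 0.0),
            ("B", "chest", "sit", 1, 5.0),
            ("B", "gold", "sit", 2, 0.0),
            ("B", "chest", "sit", 2, 7.0),
        ]
        pairs = pair_differences(make_table(rows))
        bias, lo, hi = anova_loa(pairs)
        # MSW=2, MSB=16, n0=2 -> between=7, SD=3
        assert bias == pytest.approx(4.0)
        assert lo == pytest.approx(4.0 - 1.96 * 3.0)
        assert hi == pytest.approx(4.0 + 1.96 * 3.0)

    def test_constant_differences(self):
        rows = []
        for s in "AB":
            for t in (1, 2):
                rows.append((s, "gold", "sit", t, 10.0))
                rows.append((s, "chest", "sit", t, 12.5))
        pairs = pair_differences(make_table(rows))
        bias, lo, hi = anova_loa(pairs)
        assert (bias, lo, hi) == (2.5, 2.5, 2.5)

    def test_single_differences_error(self):
        rows = []
        for s in "ABC":
            rows.append((s, "gold", "sit", 1, 10.0))
            rows.append((s, "chest", "sit", 1, 11.0))
        pairs = pair_differences(make_table(rows))
        with pytest.raises(DataError, match="single difference"):
            anova_loa(pairs)


class TestBuildReport:
    def test_published_values_all_fail_at_cad_5(self, published_fit, published_diff_fit):
        settings = AgreementSettings(cad_delta=5.0)
        rpt = build_report(
            full_fit=published_fit, diff_fit=published_diff_fit, settings=settings
        )
        assert rpt.verdicts["loa"] == "do not agree"
        assert rpt.verdicts["cp"] == "do not agree"
        assert rpt.verdicts["tdi"] == "do not agree"
        assert rpt.verdicts["cia"] == "do not agree"
        assert "ccc" not in rpt.verdicts  # no threshold supplied

    def test_cad_12_flips_loa_and_tdi(self, published_fit, published_diff_fit):
        settings = AgreementSettings(cad_delta=12.0)
        rpt = build_report(
            full_fit=published_fit, diff_fit=published_diff_fit, settings=settings
        )
        assert rpt.verdicts["loa"] == "agree"
        assert rpt.verdicts["tdi"] == "agree"
        # CP(12) from MSD 30.8384 is ~0.969 >= 0.95
        assert rpt.cp == pytest.approx(0.969, abs=2e-3)
        assert rpt.verdicts["cp"] == "agree"

    def test_perfect_agreement(self):
        fit = FullModelFit.from_components(0.0, 5.0, 2.0, 0.0, 1.0, 0.0, 1e-6)
        dfit = DiffModelFit.from_components(0.0, 0.0, 0.0, 0.0)
        rpt = build_report(full_fit=fit, diff_fit=dfit)
        assert all(v == "agree" for v in rpt.verdicts.values())

    def test_requires_at_least_one_fit(self):
        with pytest.raises(DataError):
            build_report()

    def test_json_roundtrip(self, published_fit, published_diff_fit):
        import json

        rpt = build_report(full_fit=published_fit, diff_fit=published_diff_fit)
        payload = json.loads(rpt.to_json())
        assert payload["msd"] == pytest.approx(30.8384)
        assert payload["verdicts"]["loa"] == "do not agree"
        assert "diff_model" in payload["loa"]

    def test_text_rendering(self, published_fit, published_diff_fit):
        rpt = build_report(full_fit=published_fit, diff_fit=published_diff_fit)
        text = rpt.to_text()
        assert "Mean bias -1.60" in text
        assert "CIA" in text


class TestDeviceRelabelInvariance:
    def test_indices_under_device_swap(self, small_synth_table):
        from agreekit import fit_diff_model, fit_full_model

        f1 = fit_full_model(small_synth_table)
        f2 = fit_full_model(small_synth_table.with_devices_swapped())
        assert msd(f2) == pytest.approx(msd(f1), rel=1e-4)
        assert ccc_repeated(f2) == pytest.approx(ccc_repeated(f1), abs=1e-5)
        assert cia(f2) == pytest.approx(cia(f1), rel=1e-4)
        assert f2.device_diff == pytest.approx(-f1.device_diff, abs=1e-5)

        d1 = fit_diff_model(pair_differences(small_synth_table))
        d2 = fit_diff_model(pair_differences(small_synth_table.with_devices_swapped()))
        assert d2.mu0_star == pytest.approx(-d1.mu0_star, abs=1e-6)
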