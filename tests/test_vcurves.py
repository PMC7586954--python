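"""Vulnerability-curve evaluation, fitting, P50, and genotype comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import f_oneway

from cottonhydro.synthetic import gen_vc_measurements
from cottonhydro.vcurves import (NonIdentifiableError, VCMeasurement,
                                 VulnerabilityCurve, anova_oneway,
                                 compare_vc_parameters, evaluate_vc, fit_vc,
                                 p50, tukey_hsd)

SHOOT = VulnerabilityCurve(1.55, 0.75, ksmax=2.55)
ROOT = VulnerabilityCurve(0.29, 0.59, organ="root")


class TestEvaluate:
    def test_zero_pressure_is_fully_conductive(self):
        ks, plc = evaluate_vc(SHOOT, 0.0)
        assert plc == 0.0
        assert ks == pytest.approx(2.55)

    def test_pressure_at_b_gives_one_e_fold(self):
        # psi = -b forces a unit exponent regardless of c
        _, plc = evaluate_vc(SHOOT, -1.55)
        assert plc == pytest.approx(100.0 * (1.0 - math.exp(-1.0)), abs=1e-9)

    def test_half_loss_pressure_closed_form(self):
        # invert PLC = 50 -> psi50 = -b ln2**(1/c)
        _, plc = evaluate_vc(SHOOT, -0.951)
        assert plc == pytest.approx(50.0, abs=0.05)

    def test_positive_pressure_rejected(self):
        with pytest.raises(ValueError):
            evaluate_vc(SHOOT, 0.5)

    def test_ks_requires_ksmax(self):
        ks, _ = evaluate_vc(ROOT, -1.0)
        assert ks is None

    def test_plc_monotone_and_bounded(self):
        pressures = -np.linspace(0.0, 30.0, 400)
        _, plc = evaluate_vc(SHOOT, pressures)
        assert np.all(np.diff(plc) >= 0)
        assert plc[0] == 0.0
        assert plc[-1] <= 100.0
        assert plc[-1] > 99.0  # PLC -> 100 as psi -> -inf


class TestP50:
    @pytest.mark.parametrize("b, c, expected", [
        (1.55, 0.75, -0.95),   # species shoot
        (0.29, 0.59, -0.16),   # species root
    ])
    def test_published_species_values(self, b, c, expected):
        assert p50(VulnerabilityCurve(b, c)) == pytest.approx(expected, abs=0.005)

    def test_exponential_special_case(self):
        # c = 1 reduces the Weibull to an exponential: psi50 = -b ln 2
        assert p50(VulnerabilityCurve(2.0, 1.0)) == pytest.approx(-2.0 * math.log(2))

    @settings(max_examples=40, deadline=None)
    @given(b=st.floats(0.05, 10.0), c=st.floats(0.2, 5.0))
    def test_closed_form_matches_bisection(self, b, c):
        curve = VulnerabilityCurve(b, c)
        root = brentq(lambda psi: evaluate_vc(curve, psi)[1] - 50.0,
                      -1e3 * b, -1e-12, xtol=1e-12)
        assert p50(curve) == pytest.approx(root, abs=1e-9)


class TestFit:
    def test_noiseless_recovery_is_exact(self):
        pressures = -np.linspace(0.2, 4.0, 8)
        ms = [VCMeasurement(pressure=p, plc=SHOOT.plc(p)) for p in pressures]
        fit = fit_vc(ms, scale="plc")
        assert fit.curve.b == pytest.approx(1.55, abs=1e-6)
        assert fit.curve.c == pytest.approx(0.75, abs=1e-6)
        assert fit.residual_sum_squares < 1e-12

    def test_noisy_recovery_within_15_percent(self):
        table = gen_vc_measurements(VulnerabilityCurve(1.55, 0.75),
                                    -np.linspace(0.25, 4.5, 6),
                                    noise_sd=5.0, n_segments=3, seed=1)
        fit = fit_vc(table.rename(columns={"pressure_mpa": "pressure"}))
        assert abs(fit.curve.b - 1.55) / 1.55 < 0.15

    def test_bias_shrinks_with_sample_size(self):
        errs = []
        for n in (10, 40, 160):
            rel = []
            for seed in range(8):
                pressures = -np.linspace(0.2, 4.5, n)
                table = gen_vc_measurements(VulnerabilityCurve(1.55, 0.75),
                                            pressures, noise_sd=5.0,
                                            n_segments=1, seed=seed)
                fit = fit_vc(table.rename(columns={"pressure_mpa": "pressure"}))
                rel.append(abs(fit.curve.b - 1.55) / 1.55)
            errs.append(np.mean(rel))
        assert errs[2] < errs[0]

    def test_all_one_pressure_not_identifiable(self):
        ms = [VCMeasurement(pressure=0.0, plc=0.0) for _ in range(5)]
        with pytest.raises(NonIdentifiableError):
            fit_vc(ms)

    def test_flat_response_not_identifiable(self):
        ms = [VCMeasurement(pressure=-p, plc=40.0) for p in (0.5, 1.0, 2.0)]
        with pytest.raises(NonIdentifiableError):
            fit_vc(ms)

    def test_ks_scale_matches_plc_shape_when_ksmax_known(self):
        pressures = -np.linspace(0.2, 4.0, 10)
        ms = [VCMeasurement(pressure=p, ks=SHOOT.ks(p)) for p in pressures]
        fit = fit_vc(ms, scale="ks", ksmax=2.55)
        assert fit.curve.b == pytest.approx(1.55, abs=1e-6)
        assert fit.curve.c == pytest.approx(0.75, abs=1e-6)


class TestComparison:
    def test_identical_groups_give_zero_f(self):
        f_stat, _, _, _, _ = anova_oneway([[1.0, 1.0], [1.0, 1.0]])
        assert f_stat == 0.0
        pairs = tukey_hsd([[1.0, 1.0], [1.0, 1.0]])
        assert not pairs["significant"].any()

    def test_two_group_f_matches_hand_arithmetic(self):
        # means 1 and 2, SSB = 1.5, SSW = 0.04, F = (1.5/1)/(0.04/4) = 150
        g1, g2 = [1.0, 1.1, 0.9], [2.0, 2.1, 1.9]
        f_stat, p_val, df_b, df_w, _ = anova_oneway([g1, g2])
        assert f_stat == pytest.approx(150.0, rel=1e-12)
        assert (df_b, df_w) == (1, 4)
        f_sp, p_sp = f_oneway(g1, g2)
        assert f_stat == pytest.approx(f_sp)
        assert p_val == pytest.approx(p_sp)

    def test_tukey_flags_only_outlier_group(self):
        groups = [[1.0, 1.1, 0.9], [1.05, 0.95, 1.0], [5.0, 5.1, 4.9]]
        pairs = tukey_hsd(groups, labels=["a", "b", "c"])
        flagged = pairs[pairs["significant"]]
        assert len(flagged) == 2
        assert all("c" in (r.group_a, r.group_b) for r in flagged.itertuples())

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(7)
        data = {"a": rng.normal(1.0, 0.2, 5), "b": rng.normal(1.4, 0.2, 5),
                "c": rng.normal(1.1, 0.2, 5)}
        ours = tukey_hsd(list(data.values()), labels=list(data))
        vals = np.concatenate(list(data.values()))
        labels = np.repeat(list(data), [len(v) for v in data.values()])
        ref = pairwise_tukeyhsd(vals, labels)
        np.testing.assert_allclose(np.sort(ours["p_adj"]),
                                   np.sort(ref.pvalues), atol=1e-6)

    def test_compare_vc_parameters_report(self):
        rng = np.random.default_rng(3)
        rows = []
        for geno, b_mean in [("steep", 0.5), ("shallow", 1.6)]:
            for _ in range(3):
                b = b_mean + rng.normal(0, 0.05)
                rows.append({"genotype": geno, "b": b, "c": 0.75,
                             "p50": p50(VulnerabilityCurve(b, 0.75))})
        report = compare_vc_parameters(pd.DataFrame(rows))
        assert report["b"]["p"] < 0.05
        assert report["b"]["tukey"]["significant"].all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0]])
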