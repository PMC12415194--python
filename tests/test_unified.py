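"""Unified leakage model: responses, bulk averaging, classification, fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transleak import (
    QuenchParams,
    RequenchCurve,
    SigmoidResponse,
    UnifiedParams,
    bulk_observables,
    chi_squared,
    classify_behavior,
    fit_ideal_graded,
    fit_unified,
    predict_curve,
    qin_graded,
    quench_factor,
    response,
    vesicle_outcomes,
)
from transleak.synth import SynthSpec, gen_requench_dataset


class TestResponse:
    def test_midpoint_is_half(self):
        for kind in ("smoothstep", "logistic"):
            r = SigmoidResponse(kind=kind, c1=7.0, c2=0.45)
            assert response(0.45, r) == pytest.approx(0.5, abs=1e-12)

    def test_logistic_closed_form(self):
        r = SigmoidResponse(kind="logistic", c1=10.0, c2=0.7)
        assert response(1.0, r) == pytest.approx(1.0 / (1.0 + np.exp(-3.0)), rel=1e-12)

    def test_constant_kind(self):
        r = SigmoidResponse.constant(1.0)
        cp = np.linspace(0, 1, 9)
        np.testing.assert_array_equal(response(cp, r), 1.0)

    def test_smoothstep_saturates_at_bounded_support(self):
        r = SigmoidResponse(c1=10.0, c2=0.6)  # support [0.3, 0.9]
        assert response(0.9, r) == 1.0
        assert response(0.3, r) == 0.0
        assert 0.0 < response(0.6, r) < 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        kind=st.sampled_from(["smoothstep", "logistic"]),
        c1=st.floats(0.5, 50.0),
        c2=st.floats(0.0, 1.0),
        a=st.floats(0.0, 1.0),
        b=st.floats(0.0, 1.0),
    )
    def test_nondecreasing_and_bounded(self, kind, c1, c2, a, b):
        r = SigmoidResponse(kind=kind, c1=c1, c2=c2)
        lo, hi = sorted((a, b))
        ra, rb = response(lo, r), response(hi, r)
        assert 0.0 <= ra <= 1.0 and 0.0 <= rb <= 1.0
        assert ra <= rb + 1e-12

    def test_domain_error(self):
        with pytest.raises(ValueError):
            response(1.5, SigmoidResponse())


class TestVesicleOutcomes:
    def test_ideal_limits(self, quench):
        aon = UnifiedParams.ideal_all_or_none(SigmoidResponse(c1=3, c2=0.4), quench)
        _, f = vesicle_outcomes(np.linspace(0, 1, 5), aon)
        np.testing.assert_array_equal(f, 1.0)
        graded = UnifiedParams.ideal_graded(SigmoidResponse(c1=3, c2=0.4), quench)
        p, _ = vesicle_outcomes(np.linspace(0, 1, 5), graded)
        np.testing.assert_array_equal(p, 1.0)

    def test_midpoint_probability(self, quench):
        params = UnifiedParams(
            SigmoidResponse(c1=3, c2=0.4), SigmoidResponse(c1=10, c2=0.7), quench
        )
        p, _ = vesicle_outcomes(0.4, params)
        assert p == pytest.approx(0.5, abs=1e-12)


class TestBulkObservables:
    def test_pleak_one_reproduces_ideal_graded_pointwise(self, quench):
        params = UnifiedParams.ideal_graded(SigmoidResponse(c1=10, c2=0.5), quench)
        cp = np.linspace(0, 1, 101)
        fout, qin, deg = bulk_observables(cp, params)
        _, f = vesicle_outcomes(cp, params)
        expected = qin_graded(f, quench)
        np.testing.assert_array_equal(fout[~deg], f[~deg])
        np.testing.assert_allclose(qin[~deg], expected[~deg], rtol=0, atol=0)

    def test_foutv_one_gives_flat_qin(self, quench):
        params = UnifiedParams.ideal_all_or_none(SigmoidResponse(c1=3, c2=0.4), quench)
        cp = np.linspace(0, 1, 101)
        fout, qin, deg = bulk_observables(cp, params)
        q0 = quench_factor(quench.dpx0, quench)
        assert not deg.any()
        assert np.max(np.abs(qin - q0)) < 1e-12
        p, _ = vesicle_outcomes(cp, params)
        np.testing.assert_array_equal(fout, p)

    def test_no_peptide_no_leakage(self, graded_params):
        fout, qin, deg = bulk_observables(0.0, graded_params)
        assert fout == 0.0
        assert qin == pytest.approx(
            quench_factor(graded_params.quench.dpx0, graded_params.quench)
        )
        assert not deg

    def test_degenerate_fully_leaked_flagged(self, quench):
        params = UnifiedParams(
            SigmoidResponse.constant(1.0), SigmoidResponse.constant(1.0), quench
        )
        fout, qin, deg = bulk_observables(0.5, params)
        assert deg and fout == 1.0 and qin == 1.0

    def test_fout_nondecreasing_in_cp(self, mixed_params):
        cp = np.linspace(0, 1, 200)
        fout, _, _ = bulk_observables(cp, mixed_params)
        assert np.all(np.diff(fout) >= -1e-12)


class TestClassification:
    def test_ideal_all_or_none(self, quench):
        curve = predict_curve(
            np.linspace(0, 1, 30),
            UnifiedParams.ideal_all_or_none(SigmoidResponse(c1=3, c2=0.4), quench),
        )
        assert classify_behavior(curve) == "all_or_none"

    def test_ideal_graded_with_paper_alpha(self):
        qp = QuenchParams(alpha=1.43)
        curve = predict_curve(
            np.linspace(0, 1, 30),
            UnifiedParams.ideal_graded(SigmoidResponse(c1=10, c2=0.5), qp),
        )
        assert classify_behavior(curve) == "graded"

    def test_mixed_parameters_classified_mixed(self, mixed_params):
        curve = predict_curve(np.linspace(0, 1, 50), mixed_params)
        assert classify_behavior(curve) == "mixed"

    def test_too_few_points_rejected(self, quench):
        curve = RequenchCurve(fout=[0.1, 0.2, 0.3], qin=[0.3, 0.3, 0.3])
        with pytest.raises(ValueError):
            classify_behavior(curve)


class TestChiSquared:
    def _data(self, n=6):
        fout = np.linspace(0.1, 0.9, n)
        qin = np.linspace(0.3, 0.8, n)
        return RequenchCurve(fout=fout, qin=qin, sd=np.full(n, 0.02))

    def test_model_equals_data_gives_zero(self):
        data = self._data()
        model = RequenchCurve(fout=data.fout, qin=data.qin)
        assert chi_squared(model, data, n_params=2) == 0.0

    def test_single_sd_offset_with_unit_dof(self):
        data = RequenchCurve(
            fout=[0.2, 0.5, 0.8], qin=[0.40, 0.50, 0.60], sd=[0.02, 0.02, 0.02]
        )
        model = RequenchCurve(fout=[0.2, 0.5, 0.8], qin=[0.40, 0.52, 0.60])
        # one point off by exactly 1 sd, N - n_params = 1
        assert chi_squared(model, data, n_params=2) == pytest.approx(1.0)

    def test_missing_or_zero_sd_rejected(self):
        data = RequenchCurve(fout=[0.2, 0.5, 0.8], qin=[0.4, 0.5, 0.6])
        model = RequenchCurve(fout=[0.2, 0.5, 0.8], qin=[0.4, 0.5, 0.6])
        with pytest.raises(ValueError):
            chi_squared(model, data, n_params=1)
        data2 = RequenchCurve(
            fout=[0.2, 0.5, 0.8], qin=[0.4, 0.5, 0.6], sd=[0.02, 0.0, 0.02]
        )
        with pytest.raises(ValueError):
            chi_squared(model, data2, n_params=1)

    def test_calibration_on_honest_noise(self, graded_params, cp_grid):
        # chi2 of the generating model on honestly-noised data averages ~1
        chis = []
        truth = predict_curve(cp_grid, graded_params)
        for seed in range(100):
            spec = SynthSpec(seed=seed, n_replicates=1, qin_sd_inflation=0.0,
                             params=graded_params)
            data = gen_requench_dataset(spec, cp_grid)
            chis.append(chi_squared(truth, data, n_params=0))
        assert np.mean(chis) == pytest.approx(1.0, abs=0.1)


class TestFitUnified:
    def test_noiseless_recovery_within_one_percent(self, graded_params, cp_grid):
        spec = SynthSpec(seed=0, qin_sd_base=0.0, params=graded_params)
        data = gen_requench_dataset(spec, cp_grid)
        data.sd = np.full(len(data), 0.02)  # weights only; data are exact
        res = fit_unified(data)
        truth = np.array([3.0, 0.4, 10.0, 0.7])
        assert res.success
        np.testing.assert_allclose(res.theta, truth, rtol=0.01)

    def test_all_zero_sd_rejected(self, graded_params, cp_grid):
        spec = SynthSpec(seed=0, qin_sd_base=0.0, params=graded_params)
        data = gen_requench_dataset(spec, cp_grid)
        data.sd = np.zeros(len(data))
        with pytest.raises(ValueError):
            fit_unified(data)

    def test_missing_cp_rejected(self):
        data = RequenchCurve(
            fout=np.linspace(0.1, 0.9, 8),
            qin=np.linspace(0.3, 0.8, 8),
            sd=np.full(8, 0.02),
        )
        with pytest.raises(ValueError):
            fit_unified(data)


class TestFitIdealGraded:
    def test_noiseless_recovery_exact(self):
        qp = QuenchParams(dpx0=0.011e-3, alpha=1.43)
        fout = np.linspace(0.0, 0.95, 12)
        curve = RequenchCurve(
            fout=fout, qin=qin_graded(fout, qp), sd=np.full(12, 0.01)
        )
        res = fit_ideal_graded(curve)
        assert res.success and not res.at_bound
        assert res.dpx0 == pytest.approx(0.011e-3, rel=1e-4)
        assert res.alpha == pytest.approx(1.43, rel=1e-4)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_flat_all_or_none_data_flagged(self, quench):
        # forcing the graded relation through flat data pins alpha at a bound
        fout = np.linspace(0.05, 0.9, 10)
        q0 = quench_factor(quench.dpx0, quench)
        curve = RequenchCurve(fout=fout, qin=np.full(10, q0), sd=np.full(10, 0.01))
        res = fit_ideal_graded(curve)
        assert res.at_bound

    def test_single_point_rejected(self):
        curve = RequenchCurve(fout=[0.5], qin=[0.5], sd=[0.01])
        with pytest.raises(ValueError):
            fit_ideal_graded(curve)
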