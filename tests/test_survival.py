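"""Digitized-curve reading, pseudo-IPD reconstruction and parametric MLE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btccea.simulate import SimulationSpec, digitize, simulate_ipd
from btccea.survival import (
    CurveValidationError,
    DegenerateInputError,
    DigitizedCurve,
    ParametricFit,
    PseudoIPD,
    fit_parametric,
    log_likelihood,
    read_digitized_curve,
    reconstruct_pseudo_ipd,
    select_by_aic,
)

# Published combo-arm OS Weibull parameters, reused as a realistic truth.
LAM, GAM = 0.0156467, 1.2807604


def write_csv(tmp_path, rows, header="time,survival"):
    path = tmp_path / "curve.csv"
    path.write_text(header + "\n" + "\n".join(",".join(map(str, r)) for r in rows))
    return path


class TestReadDigitizedCurve:
    def test_passthrough_with_anchor(self, tmp_path):
        path = write_csv(tmp_path, [(0, 1.0), (6, 0.8), (12, 0.5)])
        curve = read_digitized_curve(path)
        assert len(curve.times) == 3
        assert curve.times[0] == 0 and curve.survival[0] == 1.0

    def test_anchor_prepended(self, tmp_path):
        path = write_csv(tmp_path, [(6, 0.8), (12, 0.5)])
        curve = read_digitized_curve(path)
        assert len(curve.times) == 3
        assert (curve.times[0], curve.survival[0]) == (0.0, 1.0)

    def test_rising_survival_rejected_naming_row(self, tmp_path):
        path = write_csv(tmp_path, [(6, 0.8), (12, 0.9)])
        with pytest.raises(CurveValidationError, match="row 2"):
            read_digitized_curve(path)

    def test_survival_outside_unit_interval_rejected(self, tmp_path):
        path = write_csv(tmp_path, [(6, 1.2), (12, 0.5)])
        with pytest.raises(CurveValidationError, match=r"outside \[0, 1\]"):
            read_digitized_curve(path)

    def test_day_unit_conversion(self, tmp_path):
        path = write_csv(tmp_path, [(21, 0.8), (42, 0.5)])
        curve = read_digitized_curve(path, time_unit="day")
        np.testing.assert_allclose(curve.times, [0.0, 1.0, 2.0])

    def test_risk_table_column_read(self, tmp_path):
        path = write_csv(
            tmp_path, [(0, 1.0, 100), (5, 0.8, 80), (10, 0.5, "")], header="time,survival,n_risk"
        )
        curve = read_digitized_curve(path)
        np.testing.assert_allclose(curve.n_at_risk, [100, 80])


class TestReconstructPseudoIPD:
    def test_single_interval_midpoint_allocation(self):
        curve = DigitizedCurve("OS", "combo", np.array([0.0, 10.0]), np.array([1.0, 0.5]))
        ipd = reconstruct_pseudo_ipd(curve, 100)
        assert ipd.n == 100 and ipd.n_events == 50
        assert np.all(ipd.times[ipd.events == 1] == 5.0)
        assert np.all(ipd.times[ipd.events == 0] == 10.0)

    def test_two_interval_allocation(self):
        curve = DigitizedCurve(
            "OS", "combo", np.array([0.0, 5.0, 10.0]), np.array([1.0, 0.8, 0.4])
        )
        ipd = reconstruct_pseudo_ipd(curve, 10)
        ev = ipd.times[ipd.events == 1]
        assert list(ev) == [2.5, 2.5, 7.5, 7.5, 7.5, 7.5]
        assert (ipd.events == 0).sum() == 4 and np.all(ipd.times[ipd.events == 0] == 10.0)

    def test_all_zero_events_degenerate(self):
        curve = DigitizedCurve(
            "OS", "combo", np.array([0.0, 5.0]), np.array([1.0, 0.999])
        )
        with pytest.raises(DegenerateInputError):
            reconstruct_pseudo_ipd(curve, 100)

    def test_assumed_n_floor(self):
        curve = DigitizedCurve("OS", "combo", np.array([0.0, 5.0]), np.array([1.0, 0.5]))
        with pytest.raises(DegenerateInputError):
            reconstruct_pseudo_ipd(curve, 9)

    @given(st.integers(20, 500), st.floats(0.05, 0.7))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_record_count_conserved(self, n, s_final):
        curve = DigitizedCurve(
            "OS", "combo", np.array([0.0, 4.0, 9.0]),
            np.array([1.0, (1 + s_final) / 2, s_final]),
        )
        ipd = reconstruct_pseudo_ipd(curve, n)
        assert ipd.n == n
        assert abs(ipd.n_events - n * (1 - s_final)) <= 1.0

    def test_risk_table_rescaling_matches_counts(self):
        # digitization error inflates drops; the risk table corrects them
        curve = DigitizedCurve(
            "OS", "combo",
            np.array([0.0, 5.0, 10.0]),
            np.array([1.0, 0.7, 0.4]),
            risk_times=np.array([5.0, 10.0]),
            n_at_risk=np.array([80.0, 45.0]),
        )
        ipd = reconstruct_pseudo_ipd(curve, 100)
        assert (ipd.times[ipd.events == 1] == 2.5).sum() == 20
        assert (ipd.times[ipd.events == 1] == 7.5).sum() == 35

    def test_simulate_digitize_reconstruct_refit_round_trip(self):
        spec = SimulationSpec(lam=LAM, gam=GAM, n=500, censor_cycles=40.0,
                              grid_points=30, rounding=0.0, seed=7)
        curve = digitize(spec, ipd=simulate_ipd(spec))
        fit = fit_parametric(reconstruct_pseudo_ipd(curve, 500))
        assert fit.lam == pytest.approx(LAM, rel=0.10)
        assert fit.gam == pytest.approx(GAM, rel=0.10)


class TestFitParametric:
    def uncensored(self, n=2000, lam=LAM, gam=GAM, seed=2):
        rng = np.random.default_rng(seed)
        t = (-np.log(rng.uniform(size=n)) / lam) ** (1.0 / gam)
        return PseudoIPD(times=t, events=np.ones(n, dtype=int))

    def test_exponential_closed_form_mle(self):
        ipd = self.uncensored(n=500, gam=1.0, lam=0.1, seed=3)
        fit = fit_parametric(ipd, "exponential")
        assert fit.lam == pytest.approx(ipd.n_events / ipd.times.sum(), rel=1e-12)
        assert fit.gam == 1.0
        assert fit.aic == pytest.approx(2 - 2 * fit.log_likelihood)

    def test_weibull_parameter_recovery(self):
        fit = fit_parametric(self.uncensored())
        assert fit.lam == pytest.approx(LAM, rel=0.05)
        assert fit.gam == pytest.approx(GAM, rel=0.05)

    def test_aic_prefers_weibull_on_weibull_data(self):
        ipd = self.uncensored()
        wb = fit_parametric(ipd, "weibull")
        ex = fit_parametric(ipd, "exponential")
        assert wb.aic < ex.aic
        assert wb.aic == pytest.approx(4 - 2 * wb.log_likelihood)

    def test_exponential_nesting(self):
        spec = SimulationSpec(lam=0.05, gam=1.0, n=800, censor_cycles=30.0, seed=5)
        ipd = simulate_ipd(spec)  # includes censoring
        ex = fit_parametric(ipd, "exponential")
        nested = fit_parametric(ipd, "weibull", fix_gamma=1.0)
        assert nested.lam == pytest.approx(ex.lam, abs=1e-8)
        assert nested.log_likelihood == pytest.approx(ex.log_likelihood, abs=1e-8)

    def test_mle_beats_perturbed_parameters(self):
        ipd = self.uncensored(n=400, seed=21)
        fit = fit_parametric(ipd)
        ll = log_likelihood(fit.lam, fit.gam, ipd)
        assert ll >= log_likelihood(fit.lam * 1.1, fit.gam, ipd)
        assert ll >= log_likelihood(fit.lam, fit.gam * 1.1, ipd)

    def test_matches_lifelines_on_censored_data(self):
        from lifelines import WeibullFitter

        spec = SimulationSpec(lam=LAM, gam=GAM, n=600, censor_cycles=35.0, seed=13)
        ipd = simulate_ipd(spec)
        fit = fit_parametric(ipd)
        wf = WeibullFitter().fit(ipd.times, ipd.events)
        # lifelines uses S(t) = exp(-(t/lambda_)**rho_)
        assert fit.gam == pytest.approx(wf.rho_, rel=1e-4)
        assert fit.lam == pytest.approx(wf.lambda_ ** -wf.rho_, rel=1e-4)
        assert fit.log_likelihood == pytest.approx(wf.log_likelihood_, rel=1e-6)

    def test_all_censored_rejected(self):
        ipd = PseudoIPD(times=np.full(20, 5.0), events=np.zeros(20, dtype=int))
        with pytest.raises(DegenerateInputError):
            fit_parametric(ipd)


class TestSelectByAIC:
    def test_published_aic_ordering_selects_weibull(self):
        wb = ParametricFit("weibull", LAM, GAM, (4 + 1549.654) / 2, -1549.654, 341)
        ex = ParametricFit("exponential", 0.03, 1.0, (2 + 1028.268) / 2, -1028.268, 341)
        assert select_by_aic([wb, ex]) is wb

    def test_tie_breaks_toward_fewer_parameters(self):
        wb = ParametricFit("weibull", 0.1, 1.2, -3.0, 10.0, 50)
        ex = ParametricFit("exponential", 0.1, 1.0, -4.0, 10.0, 50)
        assert select_by_aic([wb, ex]) is ex

    def test_single_fit_identity(self):
        fit = ParametricFit("weibull", 0.1, 1.2, -3.0, 10.0, 50)
        assert select_by_aic([fit]) is fit

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_by_aic([])


def test_noise_free_round_trip_recovers_parameters():
    """Fine-grid, large-n reconstruction from the exact law recovers (lam, gam)
    within 5% relative error."""
    spec = SimulationSpec(lam=LAM, gam=GAM, n=2000, censor_cycles=60.0,
                          grid_points=60, rounding=0.0, seed=0)
    curve = digitize(spec)  # exact parametric curve, no sampling noise
    fit = fit_parametric(reconstruct_pseudo_ipd(curve, 2000))
    assert fit.lam == pytest.approx(LAM, rel=0.05)
    assert fit.gam == pytest.approx(GAM, rel=0.05)
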