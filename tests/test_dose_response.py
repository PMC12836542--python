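"""Dose ladder, vehicle normalisation, 5PL fitting, ED50/GI50 and ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from tumourtrace.dose_response import (
    DegenerateFitError,
    LogLogistic5,
    dose_ladder,
    ed50,
    fit_ll5,
    gi50,
    ll5,
    normalize_to_control,
    rank_sensitivity,
    sensitivity_report,
)
from tumourtrace.readouts import well_readouts


class TestDoseLadder:
    def test_five_step_tenfold_screen(self):
        assert dose_ladder(0.1, 1000, 10) == [0.1, 1.0, 10.0, 100.0, 1000.0]

    def test_single_step(self):
        assert dose_ladder(5, 5, 2) == [5.0]

    def test_powers_of_two(self):
        assert dose_ladder(1, 8, 2) == [1.0, 2.0, 4.0, 8.0]

    def test_inexact_ladder_rejected_with_endpoints(self):
        with pytest.raises(ValueError, match="nearest valid"):
            dose_ladder(1, 500, 10)

    @pytest.mark.parametrize("args", [(0, 10, 2), (10, 1, 2), (1, 10, 1.0), (1, 10, 0.5)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            dose_ladder(*args)


class TestLL5Function:
    def test_symmetric_midpoint(self):
        assert ll5(10.0, b=2.0, c=0.2, d=1.0, e=10.0, f=1.0) == pytest.approx(0.6)

    def test_asymptotes(self):
        assert ll5(1e12, b=1.0, c=0.1, d=1.0, e=10.0, f=1.5) == pytest.approx(0.1, abs=1e-6)
        assert ll5(1e-12, b=1.0, c=0.1, d=1.0, e=10.0, f=1.5) == pytest.approx(1.0, abs=1e-6)

    def test_direct_evaluation(self):
        assert ll5(10.0, b=1.0, c=0.0, d=1.0, e=10.0, f=2.0) == pytest.approx(0.25)

    def test_monotone_for_fixed_sign_b(self):
        x = np.geomspace(1e-3, 1e4, 200)
        for b in (1.3, -0.8):
            y = ll5(x, b=b, c=0.1, d=1.2, e=7.0, f=0.6)
            diffs = np.diff(y)
            assert np.all(diffs <= 1e-12) if b > 0 else np.all(diffs >= -1e-12)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            ll5(0.0, 1, 0, 1, 10, 1)
        with pytest.raises(ValueError):
            ll5(1.0, 1, 0, 1, -10, 1)
        with pytest.raises(ValueError):
            ll5(1.0, 1, 0, 1, 10, 0)


def _series(value_by_day, conc, rep=1, vehicle=False, sample="S1"):
    """A WellTimeSeries with prescribed total_area values."""
    from tumourtrace.readouts import READOUTS, WellTimeSeries

    days = sorted(value_by_day)
    data = pd.DataFrame(index=pd.Index(days, name="day"), columns=READOUTS, dtype=float)
    data["total_area"] = [value_by_day[d] for d in days]
    data["relative_total_area"] = data["total_area"] / value_by_day[days[0]]
    return WellTimeSeries(
        well_id=f"W{conc}_{rep}",
        sample_id=sample,
        drug="drugX" if not vehicle else "vehicle",
        concentration_nM=conc,
        replicate=rep,
        is_vehicle=vehicle,
        data=data,
        anchor_day=days[0],
    )


class TestNormalizeToControl:
    def test_unit_vehicle_denominator(self):
        treated = [_series({1: 0.5}, 10.0, rep=1), _series({1: 0.7}, 10.0, rep=2)]
        vehicle = [_series({1: 1.0}, 0.0, vehicle=True, rep=r) for r in (1, 2)]
        pts = normalize_to_control(treated, vehicle, "total_area", 1)
        assert sorted(pts["response"]) == [0.5, 0.7]
        assert list(pts.columns) == [
            "sample_id", "day", "readout", "concentration_nM", "replicate", "response",
        ]

    def test_treated_equal_to_vehicle_mean_gives_one(self):
        treated = [_series({1: 3.0}, 100.0)]
        vehicle = [_series({1: 2.0}, 0.0, vehicle=True), _series({1: 4.0}, 0.0, vehicle=True)]
        assert normalize_to_control(treated, vehicle, "total_area", 1)["response"].iloc[0] == 1.0

    def test_no_vehicle_value_is_error(self):
        with pytest.raises(ValueError):
            normalize_to_control([_series({1: 1.0}, 10.0)], [], "total_area", 1)

    def test_vehicle_well_as_treated_is_error(self):
        veh = _series({1: 1.0}, 0.0, vehicle=True)
        with pytest.raises(ValueError):
            normalize_to_control([veh], [veh], "total_area", 1)

    def test_missing_treated_day_skipped(self):
        treated = [_series({1: 1.0}, 10.0), _series({1: 1.0, 2: 0.8}, 100.0)]
        vehicle = [_series({1: 1.0, 2: 1.0}, 0.0, vehicle=True)]
        pts = normalize_to_control(treated, vehicle, "total_area", 2)
        assert len(pts) == 1 and pts["concentration_nM"].iloc[0] == 100.0


LADDER = [0.1, 1.0, 10.0, 100.0, 1000.0]
TRUTH = dict(b=1.2, c=0.1, d=1.0, e=15.0, f=1.5)


def _points(noise_sd=0.0, seed=0, reps=4, truth=TRUTH):
    doses = np.repeat(LADDER, reps)
    y = ll5(doses, **truth)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, doses.size)
    return pd.DataFrame({"concentration_nM": doses, "response": y})


class TestFitLL5:
    def test_noiseless_parameter_recovery(self):
        fit = fit_ll5(_points())
        assert fit.converged
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.e == pytest.approx(15.0, rel=1e-3)  # well within 10%
        assert fit.b == pytest.approx(1.2, rel=1e-3)
        assert fit.f == pytest.approx(1.5, rel=1e-2)

    def test_noisy_fit_is_stabilised_through_symmetric_fallback(self):
        """At this noise level the e-f direction is statistically
        undetermined; the fit must fall back to the symmetric model and
        land near the symmetric model's own noiseless optimum."""
        anchor = LogLogistic5(
            _points()["concentration_nM"], _points()["response"]
        ).fit(f_fixed=True)
        fit = fit_ll5(_points(noise_sd=0.05, seed=1))
        assert fit.converged and fit.b > 0
        assert fit.ill_conditioned and fit.f == 1.0
        assert fit.e == pytest.approx(anchor.e, rel=0.25)

    def test_all_identical_responses_degenerate(self):
        pts = pd.DataFrame({"concentration_nM": LADDER, "response": [1.0] * 5})
        with pytest.raises(DegenerateFitError):
            fit_ll5(pts)

    def test_fewer_than_five_doses_falls_back_to_f1(self):
        pts = _points()
        pts = pts[pts["concentration_nM"] < 1000]
        fit = fit_ll5(pts)
        assert fit.fallback_f1 and fit.f == 1.0

    def test_inactive_drug_flat_curve_contract(self):
        rng = np.random.default_rng(3)
        pts = pd.DataFrame(
            {"concentration_nM": np.repeat(LADDER, 4),
             "response": 1.0 + rng.normal(0, 0.01, 20)}
        )
        fit = fit_ll5(pts)
        # the fitted curve is flat over the whole observed dose range …
        assert np.ptp(fit.predict(np.asarray(LADDER))) < 0.05
        # … and a span tolerance flags the midpoint dose as unreliable
        assert ed50(fit, span_tol=0.2) is None

    def test_fitted_curve_monotone_on_ladder(self):
        fit = fit_ll5(_points(noise_sd=0.03, seed=7))
        y = fit.predict(np.asarray(LADDER))
        assert all(b <= a + 1e-9 for a, b in zip(y, y[1:]))

    def test_increasing_response_gives_negative_slope(self):
        # y(0+) = c, y(inf) = d for b < 0: this truth rises with dose
        truth = dict(b=-1.0, c=0.2, d=1.0, e=10.0, f=1.0)
        fit = fit_ll5(_points(truth=truth))
        assert fit.b < 0
        y = fit.predict(np.asarray(LADDER))
        assert all(b >= a for a, b in zip(y, y[1:]))

    def test_summary_mentions_potency(self):
        text = fit_ll5(_points()).summary()
        assert "ED50" in text and "GI50" in text and "converged=True" in text


class TestED50:
    def test_symmetric_case_equals_e(self):
        fit = fit_ll5(_points(truth=dict(b=1.0, c=0.1, d=1.0, e=20.0, f=1.0)))
        assert ed50(fit) == pytest.approx(fit.e, rel=1e-9)

    def test_closed_form_example(self):
        from tumourtrace.dose_response import LL5Results

        fit = LL5Results(b=1.0, c=0.0, d=1.0, e=10.0, f=2.0, converged=True,
                         rss=0.0, n_points=20)
        assert ed50(fit) == pytest.approx(10.0 * (np.sqrt(2) - 1), rel=1e-12)

    def test_against_bisection_oracle(self):
        from tumourtrace.dose_response import LL5Results

        rng = np.random.default_rng(99)
        for _ in range(200):
            b = rng.uniform(0.3, 3.0) * rng.choice([-1, 1])
            c, d = sorted(rng.uniform(-0.2, 1.4, 2))
            if d - c < 0.05:
                continue
            e, f = rng.uniform(0.5, 500), rng.uniform(0.2, 5.0)
            fit = LL5Results(b=b, c=c, d=d, e=e, f=f, converged=True, rss=0.0, n_points=20)
            x = ed50(fit)
            target = 0.5 * (c + d)
            root = optimize.brentq(
                lambda t: ll5(np.exp(t), b, c, d, e, f) - target,
                np.log(x) - 5, np.log(x) + 5, xtol=1e-13, rtol=1e-15,
            )
            assert x == pytest.approx(np.exp(root), rel=1e-9)


class TestGI50:
    def _fit(self, **kw):
        from tumourtrace.dose_response import LL5Results

        base = dict(b=1.0, c=0.0, d=1.0, e=10.0, f=1.0, converged=True, rss=0.0, n_points=20)
        base.update(kw)
        return LL5Results(**base)

    def test_unit_span_symmetric_case_coincides_with_ed50(self):
        fit = self._fit(e=20.0)
        assert gi50(fit) == pytest.approx(20.0) == pytest.approx(ed50(fit))

    def test_undefined_when_curve_never_reaches_half(self):
        assert gi50(self._fit(c=0.6)) is None

    def test_algebraic_inversion_example(self):
        fit = self._fit(c=0.1, d=1.1, e=20.0)
        assert gi50(fit) == pytest.approx(30.0, rel=1e-12)

    def test_inverse_consistency(self):
        fit = self._fit(b=0.9, c=0.2, d=1.1, e=33.0, f=2.2)
        x = gi50(fit)
        assert ll5(x, fit.b, fit.c, fit.d, fit.e, fit.f) == pytest.approx(0.5, abs=1e-12)


class TestRanking:
    def _fit(self, c=0.1, e=10.0):
        from tumourtrace.dose_response import LL5Results

        return LL5Results(b=1.0, c=c, d=1.0, e=e, f=1.0, converged=True, rss=0.0, n_points=20)

    def test_max_inhibition_orders_by_lower_asymptote(self):
        fits = {"A": self._fit(c=0.4), "B": self._fit(c=0.1)}
        assert rank_sensitivity(fits, "max_inhibition") == ["B", "A"]

    def test_ed50_orders_ascending(self):
        fits = {"A": self._fit(e=50.0), "B": self._fit(e=5.0)}
        assert rank_sensitivity(fits, "ed50") == ["B", "A"]

    def test_undefined_ranks_last(self):
        fits = {"A": self._fit(c=0.6), "B": self._fit(c=0.1)}
        report = sensitivity_report(fits)
        assert report.loc["A", "gi50"] is None or np.isnan(report.loc["A", "gi50"])
        assert rank_sensitivity(fits, "gi50") == ["B", "A"]

    def test_report_contains_all_criteria(self):
        report = sensitivity_report({"A": self._fit(), "B": self._fit(c=0.3)})
        for col in ("max_inhibition", "ed50", "gi50"):
            assert col in report.columns and f"rank_{col}" in report.columns

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sensitivity({"A": self._fit()})
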