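"""Unwinding pipeline: normalization chain, spline, arrival-time estimator, CI."""

import numpy as np
import pandas as pd
import pytest

import replirate as rr
from replirate.errors import ValidationError
from conftest import make_plate


def small_plate(values_by_cell):
    """Plate from explicit per-cell replicate lists:
    {(site_label, timepoint): [q1, q2, ...]}"""
    rows = []
    for (label, t), qs in values_by_cell.items():
        for r, q in enumerate(qs, start=1):
            rows.append(("c", label, t, r, q))
    return pd.DataFrame(
        rows, columns=["condition", "site_label", "timepoint_min", "replicate", "quantity"]
    )


class TestQuantitiesFromCq:
    def test_doubling_per_cycle(self):
        cq = pd.DataFrame({
            "site_label": ["200", "200", "control"],
            "timepoint_min": [5.0, 5.0, 5.0],
            "replicate": [1, 2, 1],
            "Cq": [20.0, 21.0, 19.0],
        })
        from replirate.unwinding import quantities_from_cq

        out = quantities_from_cq(cq, cq_ref=20.0)
        assert out["quantity"].to_numpy() == pytest.approx([1.0, 0.5, 2.0])
        assert "Cq" not in out.columns


class TestSummarizeTriplicates:
    def test_mean_and_cv_hand_computed(self):
        plate = small_plate({
            ("200", 5.0): [1.0, 1.0, 1.0],
            ("200", 10.0): [0.8, 1.0, 1.2],
            ("control", 5.0): [1.0, 1.0, 1.0],
            ("control", 10.0): [1.0, 1.0, 1.0],
        })
        out = rr.summarize_triplicates(plate).set_index(["site_label", "timepoint_min"])
        assert out.loc[("200", 5.0), "mean"] == pytest.approx(1.0)
        assert out.loc[("200", 5.0), "cv"] == pytest.approx(0.0)
        assert out.loc[("200", 10.0), "mean"] == pytest.approx(1.0)
        # sample sd of (0.8, 1.0, 1.2) is 0.2
        assert out.loc[("200", 10.0), "cv"] == pytest.approx(0.2)

    def test_single_replicate_names_cell(self):
        plate = small_plate({
            ("200", 5.0): [1.0],
            ("control", 5.0): [1.0, 1.0],
        })
        with pytest.raises(ValidationError, match=r"site 200, t=5"):
            rr.summarize_triplicates(plate)

    def test_incomplete_grid_rejected(self):
        plate = small_plate({
            ("200", 5.0): [1.0, 1.0],
            ("200", 10.0): [1.0, 1.0],
            ("control", 5.0): [1.0, 1.0],
        })
        with pytest.raises(ValidationError, match="incomplete"):
            rr.summarize_triplicates(plate)


class TestNormalizeToControl:
    def test_simple_ratio(self):
        plate = small_plate({
            ("200", 5.0): [0.5, 0.5],
            ("control", 5.0): [1.0, 1.0],
        })
        out = rr.normalize_to_control(rr.summarize_triplicates(plate))
        assert out["ratio"].to_numpy() == pytest.approx([0.5])

    def test_loading_factor_cancels_exactly(self):
        fr = np.tile(np.linspace(0.1, 1.0, 11), (5, 1))
        base = make_plate(fr, cv=0.0, loading_cv=0.0)
        scaled = base.copy()
        g = {t: 0.5 + 0.1 * i for i, t in enumerate(sorted(base["timepoint_min"].unique()))}
        scaled["quantity"] = scaled["quantity"] * scaled["timepoint_min"].map(g)
        r1 = rr.normalize_to_control(rr.summarize_triplicates(base))
        r2 = rr.normalize_to_control(rr.summarize_triplicates(scaled))
        np.testing.assert_allclose(
            r1.sort_values(["site_label", "timepoint_min"])["ratio"],
            r2.sort_values(["site_label", "timepoint_min"])["ratio"],
            rtol=1e-12,
        )

    def test_missing_control_named(self):
        plate = small_plate({("200", 5.0): [1.0, 1.0]})
        with pytest.raises(ValidationError, match="control"):
            rr.normalize_to_control(rr.summarize_triplicates(plate))


class TestNormalizeToReference:
    def ratios(self, table):
        rows = [
            {"site_label": s, "timepoint_min": t, "ratio": v, "cv": 0.0}
            for (s, t), v in table.items()
        ]
        return pd.DataFrame(rows)

    def test_divides_by_reference_plateau(self):
        r = self.ratios({
            ("200", 5.0): 0.4, ("200", 10.0): 0.8,
            ("1000", 5.0): 0.2, ("1000", 10.0): 0.6,
        })
        curves = rr.normalize_to_reference(r)
        assert curves.reference_site == 200
        assert curves.f_hat[curves.sites.index(200), -1] == pytest.approx(1.0)
        assert curves.f_hat[curves.sites.index(1000), 0] == pytest.approx(0.25)

    def test_idempotent_when_already_normalized(self):
        r = self.ratios({
            ("200", 5.0): 0.5, ("200", 10.0): 1.0,
            ("1000", 5.0): 0.1, ("1000", 10.0): 0.7,
        })
        curves = rr.normalize_to_reference(r)
        np.testing.assert_allclose(
            curves.f_hat, [[0.5, 1.0], [0.1, 0.7]], rtol=1e-12
        )

    def test_clipping_and_warning(self):
        r = self.ratios({
            ("200", 5.0): 0.5, ("200", 10.0): 1.0,
            ("1000", 5.0): 1.3, ("1000", 10.0): 1.4,
        })
        curves = rr.normalize_to_reference(r)
        assert curves.f_hat.max() == pytest.approx(1.25)
        assert any("clipped" in f for f in curves.flags)


class TestFitSiteSpline:
    def test_interpolates_monotone_points(self):
        t = [0.0, 5.0, 10.0, 20.0, 30.0]
        y = [0.0, 0.2, 0.6, 0.9, 1.0]
        fit = rr.fit_site_spline(t, y)
        assert fit(np.array(t)) == pytest.approx(y)
        grid = np.linspace(0, 30, 301)
        assert np.all(np.diff(fit(grid)) >= -1e-12)

    def test_pava_pools_violating_pair(self):
        fit = rr.fit_site_spline(
            [0.0, 5.0, 10.0, 20.0, 30.0], [0.0, 0.5, 0.4, 0.9, 1.0]
        )
        # pool-adjacent-violators averages the (0.5, 0.4) violation to 0.45
        assert fit.values == pytest.approx([0.0, 0.45, 0.45, 0.9, 1.0])
        assert np.all(np.diff(fit(np.linspace(0, 30, 301))) >= -1e-12)

    def test_no_extrapolation(self):
        fit = rr.fit_site_spline([0.0, 5.0, 10.0, 20.0], [0, 0.5, 0.8, 1.0])
        with pytest.raises(ValidationError, match="extrapolation"):
            fit(25.0)

    def test_too_few_or_unsorted_timepoints(self):
        with pytest.raises(ValidationError, match="4 timepoints"):
            rr.fit_site_spline([0.0, 5.0, 10.0], [0, 0.5, 1.0])
        with pytest.raises(ValidationError, match="ascending"):
            rr.fit_site_spline([0.0, 5.0, 5.0, 10.0], [0, 0.4, 0.5, 1.0])


class StepCurve:
    """f(t) = 1{t >= d/v}, with the SplineFit evaluation interface."""

    def __init__(self, d, v, t_max):
        self.d, self.v, self.t_max, self.t_min = d, v, t_max, 0.0

    def __call__(self, t):
        return (np.asarray(t, dtype=float) >= self.d / self.v).astype(float)


class RampCurve:
    """f(t) = min(1, t v / d)."""

    def __init__(self, d, v, t_max):
        self.d, self.v, self.t_max, self.t_min = d, v, t_max, 0.0

    def __call__(self, t):
        return np.minimum(1.0, np.asarray(t, dtype=float) * self.v / self.d)


class TestEstimateUnwindingRate:
    def test_step_curves_closed_form(self):
        v, T = 100.0, 50.0
        fits = {d: StepCurve(d, v, T) for d in (1000, 1500, 2000)}
        est = rr.estimate_unwinding_rate(fits)
        for d, tau, r in est.per_site:
            # trapezoid quadrature resolves the step to half a 0.1-min bin
            assert tau == pytest.approx(d / v, abs=0.051)
            assert r == pytest.approx(v, rel=0.01)
        assert est.rate == pytest.approx(v, rel=0.01)

    def test_ramp_curve_halves_arrival_time(self):
        # integral of (1 - min(1, t/10)) over [0, 50] equals 5
        est = rr.estimate_unwinding_rate(
            {1000: RampCurve(1000, 100.0, 50.0)}, sites_used=[1000]
        )
        _, tau, r = est.per_site[0]
        assert tau == pytest.approx(5.0, rel=1e-3)
        assert r == pytest.approx(200.0, rel=1e-3)

    def test_non_saturated_flagged(self):
        est = rr.estimate_unwinding_rate(
            {2000: RampCurve(2000, 10.0, 50.0)}, sites_used=[2000]
        )
        assert any("non-saturated" in f for f in est.flags)

    def test_roundtrip_noise_free_deterministic_motor(self):
        """Dense timepoints, no pausing, no delay: the chain recovers v."""
        v = 120.0
        tps = tuple(np.round(np.arange(0.0, 30.01, 0.25), 3))
        p = rr.UnwindingParams(
            n_molecules=10, v=v, k_in=0.0, activation_rate=None,
            duration=30.0, timepoints=tps, seed=0,
        )
        plate = rr.simulate_qpcr_readout(
            rr.simulate_unwinding(p), rr.QpcrNoiseModel(cv=0.0, loading_cv=0.0), seed=0
        )
        est = rr.analyze_plate(plate)
        assert est.rate == pytest.approx(v, rel=0.02)

    def test_activation_delay_bias_curve(self):
        """With Exp(lam) activation delay, tau_d = d/v + 1/lam, so site rates
        rise with distance toward v; distal-site averaging shrinks the bias."""
        v, lam = 100.0, 1.0
        p = rr.UnwindingParams(
            n_molecules=20000, v=v, k_in=0.0, activation_rate=lam,
            duration=50.0, timepoints=tuple(float(t) for t in range(1, 51)),
            seed=21,
        )
        plate = rr.simulate_qpcr_readout(
            rr.simulate_unwinding(p), rr.QpcrNoiseModel(cv=0.0, loading_cv=0.0), seed=21
        )
        est = rr.analyze_plate(plate, sites_used=[500, 1000, 1500, 2000])
        rates = {d: r for d, _, r in est.per_site}
        for d in rates:
            assert rates[d] == pytest.approx(d / (d / v + 1 / lam), rel=0.03)
        assert rates[2000] > rates[1000] > rates[500]


class TestBootstrapCI:
    def test_zero_noise_ci_collapses(self, step_fractions):
        plate = make_plate(step_fractions, cv=0.0, loading_cv=0.0)
        est = rr.bootstrap_rate_ci(plate, B=200, seed=0)
        assert est.ci[1] - est.ci[0] < 1e-9 * est.rate

    def test_deterministic_under_seed(self):
        p = rr.UnwindingParams(n_molecules=300, seed=2)
        plate = rr.simulate_qpcr_readout(rr.simulate_unwinding(p), seed=2)
        a = rr.bootstrap_rate_ci(plate, B=150, seed=7)
        b = rr.bootstrap_rate_ci(plate, B=150, seed=7)
        assert a.ci == b.ci and a.rate == b.rate

    def test_point_estimate_matches_fast_path(self):
        """The array fast path used inside the bootstrap must agree with the
        reference chain on unresampled data."""
        from replirate.unwinding import _plate_array, _rate_from_cell_means

        p = rr.UnwindingParams(n_molecules=500, seed=4)
        plate = rr.simulate_qpcr_readout(rr.simulate_unwinding(p), seed=4)
        est = rr.analyze_plate(plate)
        q, labels, times, _ = _plate_array(plate)
        fast = _rate_from_cell_means(
            q.mean(axis=-1), labels, times,
            sites_used=est.sites_used, reference_site=None,
            control_label="control", anchor_zero=True,
        )
        assert fast == pytest.approx(est.rate, rel=1e-12)

    def test_row_order_invariance(self):
        p = rr.UnwindingParams(n_molecules=300, seed=6)
        plate = rr.simulate_qpcr_readout(rr.simulate_unwinding(p), seed=6)
        shuffled = plate.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = rr.bootstrap_rate_ci(plate, B=120, seed=3)
        b = rr.bootstrap_rate_ci(shuffled, B=120, seed=3)
        assert a.rate == pytest.approx(b.rate, rel=1e-12)
        assert a.ci == pytest.approx(b.ci, rel=1e-12)

    def test_missing_control_rejected(self):
        p = rr.UnwindingParams(n_molecules=100, seed=1)
        plate = rr.simulate_qpcr_readout(rr.simulate_unwinding(p), seed=1)
        no_control = plate[plate["site_label"] != "control"]
        with pytest.raises(ValidationError, match="control"):
            rr.analyze_plate(no_control)


class TestEndToEndLoadingInvariance:
    def test_full_chain_invariant_to_shared_loading(self):
        p = rr.UnwindingParams(n_molecules=400, seed=8)
        plate = rr.simulate_qpcr_readout(
            rr.simulate_unwinding(p), rr.QpcrNoiseModel(cv=0.01, loading_cv=0.0), seed=8
        )
        scaled = plate.copy()
        factors = {t: 0.2 + 0.3 * i for i, t in
                   enumerate(sorted(plate["timepoint_min"].unique()))}
        scaled["quantity"] *= scaled["timepoint_min"].map(factors)
        a = rr.analyze_plate(plate)
        b = rr.analyze_plate(scaled)
        assert a.rate == pytest.approx(b.rate, rel=1e-12)
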