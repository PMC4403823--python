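"""5PL fitting, pH50, Bohr coefficient, cooperativity, dP50/dT."""

import numpy as np
import pytest

import bluesat as bs
from bluesat.errors import DegenerateFitError, PH50Undefined
from bluesat.traces import SaturationSeries

from conftest import random_fivepl


def _series_from(params: bs.FivePL, ph, po2=4.0, temp=10.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    sat = params(ph)
    if noise_sd:
        sat = sat + rng.normal(0.0, noise_sd, size=ph.size)
    return SaturationSeries(
        ph_free=ph, saturation=np.clip(sat, 0.0, 1.0), po2=po2, temperature=temp
    )


def _curve(params: bs.FivePL, po2=4.0, temp=10.0, ph_range=(6.0, 8.5)) -> bs.PHOxygenCurve:
    return bs.PHOxygenCurve(
        params=params, po2=po2, temperature=temp, n_points=60, ph_range=ph_range
    )


class TestFit5PL:
    def test_noiseless_recovery(self):
        truth = bs.FivePL(b=7.0, c=0.05, d=0.98, e=7.2, f=1.4)
        ph = np.linspace(6.4, 8.1, 60)
        curve = bs.fit_5pl(_series_from(truth, ph), n_boot=0)
        for got, want in zip(curve.params.as_tuple(), truth.as_tuple()):
            assert got == pytest.approx(want, rel=1e-6)

    def test_too_few_points_rejected(self):
        truth = bs.FivePL(b=7.0, c=0.0, d=1.0, e=7.2, f=1.0)
        ph = np.linspace(6.8, 7.6, 5)
        with pytest.raises(ValueError, match="6 distinct"):
            bs.fit_5pl(_series_from(truth, ph), n_boot=0)

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        truth = bs.FivePL(b=7.0, c=0.02, d=1.0, e=7.2, f=1.0)
        ph = np.linspace(6.4, 8.1, 60)
        series = _series_from(truth, ph, noise_sd=0.02, seed=11)
        a = bs.fit_5pl(series, n_boot=60, seed=5)
        b = bs.fit_5pl(series, n_boot=60, seed=5)
        assert a.boot_ci == b.boot_ci and a.boot_ci
        for name, value in zip("bcdef", a.params.as_tuple()):
            lo, hi = a.boot_ci[name]
            assert lo <= value <= hi

    def test_inflection_recovery_under_noise(self):
        """The curve's inflection pH (e + ln f / b; equal to e for the
        symmetric truth) is recovered within 0.02 pH in >= 95% of 200 noisy
        replicates.  The raw e parameter is tested via the inflection because
        it is only identified jointly with b and f."""
        truth = bs.FivePL(b=8.0, c=0.0, d=1.0, e=7.25, f=1.0)
        ph = np.linspace(6.4, 8.1, 60)
        hits = 0
        for seed in range(200):
            series = _series_from(truth, ph, noise_sd=0.02, seed=seed)
            curve = bs.fit_5pl(series, n_boot=0)
            hits += abs(curve.params.max_slope_ph - 7.25) < 0.02
        assert hits >= 190


class TestPH50:
    def test_symmetric_curve_ph50_is_e(self):
        assert bs.ph50(_curve(bs.FivePL(b=8.0, c=0.0, d=1.0, e=7.3, f=1.0))) == pytest.approx(
            7.3, abs=1e-8
        )

    def test_high_lower_asymptote_undefined(self):
        with pytest.raises(PH50Undefined):
            bs.ph50(_curve(bs.FivePL(b=8.0, c=0.6, d=1.0, e=7.3, f=1.0)))

    def test_crossing_outside_observed_range_undefined(self):
        curve = _curve(bs.FivePL(b=8.0, c=0.0, d=1.0, e=6.5, f=1.0), ph_range=(6.8, 8.1))
        with pytest.raises(PH50Undefined, match="outside observed"):
            bs.ph50(curve)

    def test_grid_oracle_equivalence(self):
        """Root finder matches a dense-grid brute force to 1e-4 pH on random 5PLs."""
        rng = np.random.default_rng(42)
        grid = np.linspace(4.0, 10.5, 10**6)
        for _ in range(200):
            p = random_fivepl(rng)
            root = bs.ph50(_curve(p), within_observed_range=False)
            brute = grid[np.argmin(np.abs(p(grid) - 0.5))]
            assert root == pytest.approx(brute, abs=1e-4)


class TestP50AndBohr:
    def test_collinear_exact(self):
        """pH50s placed exactly on a -1.22 Bohr line return that line."""
        slope, intercept = -1.22, 9.0
        curves = []
        for po2 in (1.0, 4.0, 13.0):
            ph50 = (np.log10(po2) - intercept) / slope
            curves.append(
                _curve(bs.FivePL(b=8.0, c=0.0, d=1.0, e=ph50, f=1.0), po2=po2,
                       ph_range=(ph50 - 1, ph50 + 1))
            )
        assert bs.bohr_coefficient(curves) == pytest.approx(-1.22, abs=1e-9)
        target = 7.27
        assert bs.p50_at_ph(curves, target) == pytest.approx(
            10 ** (intercept + slope * target), rel=1e-9
        )

    def test_round_trip_recovers_anchors(self, clean_curves_10c):
        """Zero-noise chain recovers P50 2.34 kPa at pH 7.27 and Bohr -1.22."""
        assert bs.p50_at_ph(clean_curves_10c, 7.27) == pytest.approx(2.34, rel=0.01)
        assert bs.bohr_coefficient(clean_curves_10c) == pytest.approx(-1.22, rel=1e-6)

    def test_strong_bohr_round_trip(self):
        """O. pallidus-like Bohr slope -1.97 recovered to 1e-6 with zero noise."""
        gt = bs.GroundTruthPigment(bohr_slope=-1.97, p50_ref=1.63, capacity=1.13)
        noise = bs.NoiseModel(abs_sd=0.0, ph_sd=0.0, max_drift_rate=0.0, seed=0)
        curves = []
        for tr in bs.simulate_chamber_experiment(gt, bs.ChamberProtocol(), noise):
            cal = bs.CalibrationModel(amax0=1.0, amax_drift=0.0, amin=tr.amin_true)
            curves.append(bs.fit_5pl(bs.compute_saturation(tr, cal), n_boot=0))
        assert bs.bohr_coefficient(curves) == pytest.approx(-1.97, rel=1e-6)

    def test_single_curve_needs_pooled_slope(self):
        c = _curve(bs.FivePL(b=8.0, c=0.0, d=1.0, e=7.3, f=1.0), po2=4.0)
        with pytest.raises(PH50Undefined):
            bs.p50_at_ph([c], 7.3)
        # with a pooled Bohr slope a single defined pH50 suffices
        assert bs.p50_at_ph([c], 7.3, slope=-1.22) == pytest.approx(4.0, rel=1e-9)

    def test_identical_ph50s_degenerate(self):
        p = bs.FivePL(b=8.0, c=0.0, d=1.0, e=7.3, f=1.0)
        with pytest.raises(DegenerateFitError):
            bs.bohr_coefficient([_curve(p, po2=4.0), _curve(p, po2=13.0)])

    def test_pooled_bohr_centers_within_temperature(self):
        """Curves from two temperatures on offset Bohr lines still give the
        common slope, not a line through the pooled cloud."""
        slope = -1.5
        curves = []
        for temp, intercept in ((10.0, 9.0), (0.0, 8.2)):
            for po2 in (1.0, 4.0):
                ph50 = (np.log10(po2) - intercept) / slope
                curves.append(
                    _curve(bs.FivePL(b=8.0, c=0.0, d=1.0, e=ph50, f=1.0), po2=po2,
                           temp=temp, ph_range=(ph50 - 1, ph50 + 1))
                )
        assert bs.bohr_coefficient(curves) == pytest.approx(slope, abs=1e-9)

    def test_monotone_in_ground_truth_affinity(self):
        """Raising ground-truth P50 strictly raises the estimated P50 at pH 7.27."""
        estimates = []
        for p50_ref in (1.5, 2.34, 3.5, 5.0):
            gt = bs.GroundTruthPigment(p50_ref=p50_ref)
            noise = bs.NoiseModel(abs_sd=0.0, ph_sd=0.0, max_drift_rate=0.0, seed=0)
            curves = []
            for tr in bs.simulate_chamber_experiment(gt, bs.ChamberProtocol(), noise):
                cal = bs.CalibrationModel(amax0=1.0, amax_drift=0.0, amin=tr.amin_true)
                curves.append(bs.fit_5pl(bs.compute_saturation(tr, cal), n_boot=0))
            estimates.append(bs.p50_at_ph(curves, 7.27))
        assert np.all(np.diff(estimates) > 0)


class TestCooperativity:
    def test_symmetric_closed_form(self):
        """For the symmetric logistic the max slope is b/4."""
        curve = _curve(bs.FivePL(b=9.0, c=0.0, d=1.0, e=7.2, f=1.0))
        assert bs.cooperativity(curve, 1.58) == pytest.approx(1.58 * 9.0 / 4.0, rel=1e-9)

    def test_zero_capacity(self):
        curve = _curve(bs.FivePL(b=9.0, c=0.0, d=1.0, e=7.2, f=1.0))
        assert bs.cooperativity(curve, 0.0) == 0.0

    def test_grid_oracle_equivalence(self):
        """Numeric maximiser matches a finite-difference grid maximum to 1e-6."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = random_fivepl(rng)
            coop = bs.cooperativity(_curve(p), 1.0)
            grid = np.linspace(p.e - 3.0, p.e + 3.0, 200_001)
            s = p(grid)
            slopes = np.diff(s) / np.diff(grid)
            k = int(np.argmax(slopes))
            # parabolic refinement of the discrete maximum
            window = slopes[max(k - 1, 0): k + 2]
            brute = window.max()
            assert coop == pytest.approx(brute, rel=1e-5)


class TestDeltaP50:
    def _bp(self, temp, ph, p50):
        return bs.BindingParams(
            species="x", temperature=temp, ph50_by_po2={}, p50_at=[(ph, p50)],
            bohr=-1.2, cooperativity=1.0,
        )

    def test_charcoti_pair(self):
        """0.41 kPa @ 0C/pH 7.42 to 2.34 kPa @ 10C/pH 7.27 gives 0.193 kPa/degC."""
        got = bs.delta_p50_per_degC(
            self._bp(0.0, 7.42, 0.41), self._bp(10.0, 7.27, 2.34), 7.42, 7.27
        )
        assert got == pytest.approx(0.193, abs=1e-12)

    def test_pallidus_pair(self):
        got = bs.delta_p50_per_degC(
            self._bp(10.0, 7.27, 1.63), self._bp(20.0, 7.11, 6.07), 7.27, 7.11
        )
        assert got == pytest.approx(0.444, abs=1e-12)

    def test_equal_p50s_zero(self):
        got = bs.delta_p50_per_degC(
            self._bp(0.0, 7.42, 1.0), self._bp(10.0, 7.27, 1.0), 7.42, 7.27
        )
        assert got == 0.0

    def test_equal_temperatures_rejected(self):
        with pytest.raises(ValueError):
            bs.delta_p50_per_degC(
                self._bp(10.0, 7.27, 1.0), self._bp(10.0, 7.27, 2.0), 7.27, 7.27
            )
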