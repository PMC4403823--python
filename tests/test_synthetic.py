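"""Generator behaviour: binding surface, chamber runs, alpha-stat, respirometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import bluesat as bs
from bluesat.synthetic import TRACE_COLUMNS


class TestBindingSurface:
    def test_half_saturation_at_ph50(self, charcoti_gt):
        """Symmetric curve with zero residual crosses 0.5 exactly on the Bohr line."""
        surf = bs.build_binding_surface(charcoti_gt)
        for po2 in (21, 13, 4, 1):
            ph50 = surf.ph50(po2, 10.0)
            assert surf(ph50, po2, 10.0) == pytest.approx(0.5, abs=1e-12)

    def test_doubling_po2_shifts_ph50_by_log2(self):
        """With a Bohr slope of -1, doubling PO2 moves pH50 down by log10(2)."""
        surf = bs.build_binding_surface(bs.GroundTruthPigment(bohr_slope=-1.0))
        shift = surf.ph50(2.0, 10.0) - surf.ph50(1.0, 10.0)
        assert shift == pytest.approx(-np.log10(2.0), abs=1e-12)

    def test_residual_saturation_floor(self):
        """A 33.6% lower asymptote keeps >= 33.6% of oxygen bound at any pH."""
        gt = bs.GroundTruthPigment(lower_asymptote=0.336)
        surf = bs.build_binding_surface(gt)
        ph = np.linspace(4.0, 9.5, 2000)
        s = surf(ph, 1.0, 10.0)
        assert s.min() == pytest.approx(0.336, abs=1e-6)

    def test_monotone_in_ph_and_po2(self, charcoti_gt):
        """Saturation is non-decreasing in pH and in PO2 on a 100x4 grid."""
        surf = bs.build_binding_surface(charcoti_gt)
        ph = np.linspace(6.0, 8.5, 100)
        grid = np.array([surf(ph, po2, 10.0) for po2 in (1, 4, 13, 21)])
        assert np.all(np.diff(grid, axis=1) >= 0)  # in pH
        assert np.all(np.diff(grid, axis=0) >= 0)  # in PO2
        assert np.all((grid >= 0) & (grid <= 1))

    def test_zero_bohr_slope_rejected(self):
        with pytest.raises(ValueError, match="bohr_slope"):
            bs.GroundTruthPigment(bohr_slope=0.0)

    @given(
        bohr=st.floats(-3.0, -0.3),
        p50=st.floats(0.3, 8.0),
        asym=st.floats(0.3, 4.0),
        low=st.floats(0.0, 0.45),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_surface_invariants_property(self, bohr, p50, asym, low):
        """Any valid pigment yields a bounded, doubly monotone surface."""
        gt = bs.GroundTruthPigment(
            bohr_slope=bohr, p50_ref=p50, asymmetry=asym, lower_asymptote=low
        )
        surf = bs.build_binding_surface(gt)
        ph = np.linspace(5.5, 9.0, 100)
        grid = np.array([surf(ph, po2, 10.0) for po2 in (1.0, 4.0, 13.0, 21.0)])
        assert np.all((grid >= 0.0) & (grid <= 1.0))
        assert np.all(np.diff(grid, axis=1) >= -1e-12)
        assert np.all(np.diff(grid, axis=0) >= -1e-12)


class TestChamberSimulation:
    def test_noiseless_round_trip(self, charcoti_gt):
        """Back-computed saturation equals the ground-truth surface to 1e-12."""
        protocol = bs.ChamberProtocol(temperature=10.0)
        noise = bs.NoiseModel(abs_sd=0.0, ph_sd=0.0, max_drift_rate=0.0, seed=0)
        surf = bs.build_binding_surface(charcoti_gt)
        for tr in bs.simulate_chamber_experiment(charcoti_gt, protocol, noise):
            cal = bs.CalibrationModel(amax0=1.0, amax_drift=0.0, amin=tr.amin_true)
            series = bs.compute_saturation(tr, cal)
            truth = np.clip(surf(series.ph_free, tr.po2, 10.0), 0, 1)
            assert np.max(np.abs(series.saturation - truth)) <= 1e-12

    def test_o2_cal_absorbance_follows_drift_exactly(self, charcoti_gt):
        protocol = bs.ChamberProtocol()
        noise = bs.NoiseModel(abs_sd=0.0, ph_sd=0.0, max_drift_rate=0.036, seed=0)
        (trace, *_) = bs.simulate_chamber_experiment(charcoti_gt, protocol, noise)
        cal = trace.segment("o2_cal")
        t = cal["time_s"].to_numpy()
        expected = 1.0 + 0.036 * t / 3600.0
        assert np.allclose(cal["a347"].to_numpy(), expected, atol=1e-14)

    def test_ramp_ph_monotone_before_noise(self, charcoti_gt):
        noise = bs.NoiseModel(abs_sd=0.0, ph_sd=0.0, seed=0)
        (trace, *_) = bs.simulate_chamber_experiment(charcoti_gt, bs.ChamberProtocol(), noise)
        ph = trace.segment("ramp")["ph_raw"].to_numpy()
        assert np.all(np.diff(ph) < 0)
        # raw pH carries the +0.136 scale offset
        assert ph[0] == pytest.approx(8.1 + 0.136, abs=1e-12)

    def test_segments_bracket_ramp(self, charcoti_gt):
        noise = bs.NoiseModel(seed=0)
        (trace, *_) = bs.simulate_chamber_experiment(charcoti_gt, bs.ChamberProtocol(), noise)
        segs = trace.data["segment"].tolist()
        first_ramp, last_ramp = segs.index("ramp"), len(segs) - 1 - segs[::-1].index("ramp")
        assert "o2_cal" in segs[:first_ramp]
        assert "n2_cal" in segs[last_ramp:]

    def test_seed_determinism_and_csv_bytes(self, charcoti_gt, tmp_path):
        """Same seed: byte-identical CSVs; different seed: different traces."""
        protocol = bs.ChamberProtocol()
        a = bs.simulate_chamber_experiment(charcoti_gt, protocol, bs.NoiseModel(seed=5))
        b = bs.simulate_chamber_experiment(charcoti_gt, protocol, bs.NoiseModel(seed=5))
        c = bs.simulate_chamber_experiment(charcoti_gt, protocol, bs.NoiseModel(seed=6))
        for ta, tb, tc in zip(a, b, c):
            pd.testing.assert_frame_equal(ta.data, tb.data)
            assert not ta.data["a347"].equals(tc.data["a347"])
        pa = bs.write_traces(a, tmp_path / "a")
        pb = bs.write_traces(b, tmp_path / "b")
        for fa, fb in zip(pa, pb):
            assert fa.read_bytes() == fb.read_bytes()

    def test_written_csv_dialect_and_read_back(self, charcoti_gt, tmp_path):
        traces = bs.simulate_chamber_experiment(
            charcoti_gt, bs.ChamberProtocol(), bs.NoiseModel(seed=3)
        )
        paths = bs.write_traces(traces, tmp_path, gt=charcoti_gt)
        header = paths[0].read_text().splitlines()[0]
        assert header == ",".join(TRACE_COLUMNS)
        back = bs.read_trace(paths[0])
        assert back.po2 == traces[0].po2
        assert back.temperature == traces[0].temperature


class TestAlphaStatSeries:
    def test_noiseless_slope_recovered_exactly(self):
        df = bs.simulate_alpha_stat_series(-0.0153, 7.42, [0, 10, 20], 11, 0.0, seed=1)
        fit = stats.linregress(df["temperature"], df["ph"])
        assert fit.slope == pytest.approx(-0.0153, abs=1e-12)
        assert fit.intercept == pytest.approx(7.42, abs=1e-12)

    def test_zero_slope_constant(self):
        df = bs.simulate_alpha_stat_series(0.0, 7.3, [0, 10], 5, 0.0, seed=1)
        assert np.all(df["ph"] == 7.3)

    def test_empty_temps_rejected(self):
        with pytest.raises(ValueError):
            bs.simulate_alpha_stat_series(-0.0153, 7.42, [], 5, 0.01, seed=1)


class TestRespirometry:
    def test_step_size_arithmetic(self):
        """1.58 mmol/L in 10 ul into 2 ml steps the chamber by 7.9 umol/L."""
        df = bs.simulate_respirometry(1.58, 10.0, 2.0, noise_sd=0.0, seed=0)
        pre = df[df.time_s < 600]["o2_umol_l"]
        post = df[df.time_s >= 600]["o2_umol_l"]
        assert post.median() - pre.median() == pytest.approx(7.9, abs=1e-12)

    def test_zero_capacity_no_step(self):
        df = bs.simulate_respirometry(0.0, 10.0, 2.0, noise_sd=0.0, seed=0)
        assert np.ptp(df["o2_umol_l"].to_numpy()) == pytest.approx(0.0, abs=1e-12)

    def test_background_flux_slope_exact(self):
        df = bs.simulate_respirometry(1.0, 10.0, 2.0, background_flux=12.0, noise_sd=0.0)
        pre = df[df.time_s < 600]
        slope, *_ = stats.linregress(pre["time_s"], pre["o2_umol_l"])[:5]
        assert slope * 3600.0 == pytest.approx(12.0, abs=1e-9)

    def test_sample_volume_must_fit_chamber(self):
        with pytest.raises(ValueError):
            bs.simulate_respirometry(1.0, 3000.0, 2.0)
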