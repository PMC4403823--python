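"""Synthetic diffusion-chamber, alpha-stat and respirometry data.

The study's raw traces are not deposited, so this module generates
diffusion-chamber runs (absorbance at 347 nm plus raw pH at four constant
PO2 levels while PCO2 ramps the pH down), alpha-stat pH-temperature series
and respirometry injection traces from a known ground-truth pigment.  Every
downstream stage is tested as a round trip against that ground truth.

The chamber protocol emulated: calibration with pure O2 (maximum
oxygenation signal, drifting linearly over the run) and pure N2 (minimum
signal, which stays above zero for cold pigments that do not deoxygenate
completely), then a ramp of continuously decreasing pH (~8.1 -> 6.8) at
constant PO2, sampled every 30 s.  Raw pH reads above the free hydrogen ion
scale by a constant offset (+0.136 by default) because the optode is
calibrated against low-ionic-strength standards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fivepl import FivePL

__all__ = [
    "GroundTruthPigment",
    "ChamberProtocol",
    "NoiseModel",
    "ChamberTrace",
    "BindingSurface",
    "build_binding_surface",
    "simulate_chamber_experiment",
    "simulate_alpha_stat_series",
    "simulate_respirometry",
    "write_traces",
    "read_trace",
]

TRACE_COLUMNS = ["time_s", "a347", "ph_raw", "po2_kpa", "temp_c", "segment"]
SEGMENTS = ("o2_cal", "n2_cal", "ramp")


@dataclass(frozen=True)
class GroundTruthPigment:
    """Known-truth haemocyanin used to generate synthetic experiments.

    Parameters
    ----------
    capacity : oxygen carrying capacity, mmol O2 per litre haemolymph.
    bohr_slope : Bohr coefficient, d log10 P50 / d pH (negative for a
        normal Bohr effect: acidification lowers affinity).
    p50_ref : PO2 (kPa) of half saturation at ``ph_ref`` and ``ref_temp``.
    ph_ref : pH anchor of ``p50_ref``.
    steepness : 5PL steepness per pH unit.  The default 8.0 corresponds to
        a maximum curve slope of ~2 per pH unit, i.e. a cooperativity of
        ~3.2 Dmmol O2 L-1/DpH at a capacity of 1.58 mmol/L.
    asymmetry : 5PL asymmetry exponent (1.0 = symmetric logistic).
    lower_asymptote : residual saturation fraction at low pH, at ref_temp.
    temp_coeff : dP50/dT, kPa per degC around ``ref_temp``.
    ref_temp : reference temperature (degC) of ``p50_ref``.
    lower_asymptote_dT : change of the residual saturation per degC
        (negative values emulate the colder-is-less-deoxygenated pattern).
    """

    capacity: float = 1.58
    bohr_slope: float = -1.22
    p50_ref: float = 2.34
    ph_ref: float = 7.27
    steepness: float = 8.0
    asymmetry: float = 1.0
    lower_asymptote: float = 0.0
    temp_coeff: float = 0.193
    ref_temp: float = 10.0
    lower_asymptote_dT: float = 0.0

    def __post_init__(self) -> None:
        if not self.capacity > 0:
            raise ValueError("capacity must be > 0")
        if not self.steepness > 0:
            raise ValueError("steepness must be > 0")
        if not self.asymmetry > 0:
            raise ValueError("asymmetry must be > 0")
        if not 0.0 <= self.lower_asymptote < 0.5:
            raise ValueError("lower_asymptote must be in [0, 0.5)")
        if self.bohr_slope == 0:
            raise ValueError("bohr_slope = 0 leaves pH50 undefined")

    def p50_at_temp(self, temperature: float) -> float:
        p50 = self.p50_ref + self.temp_coeff * (temperature - self.ref_temp)
        if p50 <= 0:
            raise ValueError(
                f"temperature {temperature} degC gives non-positive P50 ({p50:.3g} kPa)"
            )
        return p50

    def lower_asymptote_at_temp(self, temperature: float) -> float:
        c = self.lower_asymptote + self.lower_asymptote_dT * (temperature - self.ref_temp)
        return float(np.clip(c, 0.0, 0.4999))


class BindingSurface:
    """Saturation surface S(pH, PO2, T) of a ground-truth pigment.

    A 5PL in pH whose half-saturation pH follows the Bohr line

        pH50(PO2, T) = ph_ref + (log10 PO2 - log10 P50(T)) / bohr_slope

    so that PO2 and temperature enter only through the curve position and
    the temperature-dependent lower asymptote.
    """

    def __init__(self, gt: GroundTruthPigment):
        self.gt = gt

    def ph50(self, po2: float, temperature: float) -> float:
        gt = self.gt
        p50 = gt.p50_at_temp(temperature)
        return gt.ph_ref + (np.log10(po2) - np.log10(p50)) / gt.bohr_slope

    def curve(self, po2: float, temperature: float) -> FivePL:
        gt = self.gt
        return FivePL.anchored_at(
            ph50=self.ph50(po2, temperature),
            b=gt.steepness,
            c=gt.lower_asymptote_at_temp(temperature),
            d=1.0,
            f=gt.asymmetry,
        )

    def __call__(self, ph, po2: float, temperature: float):
        return self.curve(po2, temperature)(ph)


def build_binding_surface(gt: GroundTruthPigment) -> BindingSurface:
    """Return the callable saturation surface of a ground-truth pigment."""
    return BindingSurface(gt)


@dataclass(frozen=True)
class ChamberProtocol:
    """Diffusion-chamber run design.

    PO2 levels default to the four constant tensions 21, 13, 4 and 1 kPa;
    pH ramps linearly in time from ph_range[0] down to ph_range[1] (driven
    experimentally by a 0-10 kPa PCO2 ramp, which is not modelled beyond
    its effect on pH); samples every 30 s; pure-O2 calibration segments at
    the start and end bracket the ramp together with a pure-N2 segment.
    """

    po2_levels: tuple[float, ...] = (21.0, 13.0, 4.0, 1.0)
    pco2_range: tuple[float, float] = (0.0, 10.0)
    ph_range: tuple[float, float] = (8.1, 6.8)
    temperature: float = 10.0
    sample_interval: float = 30.0
    cal_segments: tuple[float, float] = (300.0, 300.0)
    ramp_duration: float = 1800.0

    def __post_init__(self) -> None:
        if not all(p > 0 for p in self.po2_levels):
            raise ValueError("po2_levels must be positive")
        if not all(a > b for a, b in zip(self.po2_levels, self.po2_levels[1:])):
            raise ValueError("po2_levels must be strictly decreasing")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be > 0")
        if not self.ph_range[0] > self.ph_range[1]:
            raise ValueError("ph_range must decrease (start > end)")
        if not self.ramp_duration > 0:
            raise ValueError("ramp_duration must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections of a chamber run.

    abs_sd / ph_sd are i.i.d. Gaussian noise magnitudes; max_drift_rate is
    the signed linear drift of the maximum oxygenation signal in AU per
    hour; ph_scale_offset is added to the true free-scale pH to produce
    the raw (NIST-calibrated) reading.  Of these only the offset has an
    experimentally determined magnitude; noise defaults are fixture
    choices.
    """

    abs_sd: float = 0.005
    ph_sd: float = 0.005
    max_drift_rate: float = -0.02
    ph_scale_offset: float = 0.136
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abs_sd < 0 or self.ph_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class ChamberTrace:
    """One diffusion-chamber run at a single constant PO2.

    ``data`` holds rows (time_s, a347, ph_raw, po2_kpa, temp_c, segment)
    with time strictly increasing and segment in {o2_cal, n2_cal, ramp}.
    """

    data: pd.DataFrame
    po2: float
    temperature: float
    amin_true: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trace missing columns {missing}")
        t = self.data["time_s"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.data["a347"].to_numpy())):
            raise ValueError("a347 must be finite")
        bad = set(self.data["segment"]) - set(SEGMENTS)
        if bad:
            raise ValueError(f"unknown segment labels {bad}")

    def segment(self, label: str) -> pd.DataFrame:
        return self.data[self.data["segment"] == label]

    @property
    def duration(self) -> float:
        t = self.data["time_s"].to_numpy()
        return float(t[-1] - t[0])


def _segment_times(protocol: ChamberProtocol) -> list[tuple[str, float, float]]:
    cal_o2, cal_n2 = protocol.cal_segments
    t0 = 0.0
    spans = []
    for label, dur in (
        ("o2_cal", cal_o2),
        ("ramp", protocol.ramp_duration),
        ("n2_cal", cal_n2),
        ("o2_cal", cal_o2),
    ):
        spans.append((label, t0, t0 + dur))
        t0 += dur
    return spans


def simulate_chamber_experiment(
    gt: GroundTruthPigment,
    protocol: ChamberProtocol,
    noise: NoiseModel,
    amax0: float = 1.0,
    amin: float = 0.1,
) -> list[ChamberTrace]:
    """Simulate one chamber run per PO2 level.

    True absorbance is Amin + S * (Amax(t) - Amin) with
    Amax(t) = amax0 + drift * t; during pure-O2 calibration S = 1, during
    pure-N2 calibration S equals the temperature-dependent residual
    saturation of the pigment (the non-zero minimum oxygenation signal of
    cold pigments), and during the ramp S follows the binding surface at
    the linearly decreasing true free-scale pH.
    """
    surface = build_binding_surface(gt)
    rng = np.random.default_rng(noise.seed)
    temp = protocol.temperature
    drift_per_s = noise.max_drift_rate / 3600.0
    c_resid = gt.lower_asymptote_at_temp(temp)
    spans = _segment_times(protocol)
    traces: list[ChamberTrace] = []
    for po2 in protocol.po2_levels:
        curve = surface.curve(po2, temp)
        rows = []
        for label, t_start, t_end in spans:
            n = max(int(np.floor((t_end - t_start) / protocol.sample_interval)), 1)
            times = t_start + protocol.sample_interval * np.arange(n)
            if label == "o2_cal":
                s = np.ones(n)
                ph_true = np.full(n, protocol.ph_range[0] if t_start == 0 else protocol.ph_range[1])
                po2_col = 100.0
            elif label == "n2_cal":
                s = np.full(n, c_resid)
                ph_true = np.full(n, protocol.ph_range[1])
                po2_col = 0.0
            else:
                frac = (times - t_start) / protocol.ramp_duration
                ph_true = protocol.ph_range[0] + frac * (protocol.ph_range[1] - protocol.ph_range[0])
                s = np.asarray(curve(ph_true))
                po2_col = po2
            amax_t = amax0 + drift_per_s * times
            a_true = amin + s * (amax_t - amin)
            a_obs = a_true + rng.normal(0.0, noise.abs_sd, size=n) if noise.abs_sd else a_true
            ph_obs = ph_true + noise.ph_scale_offset
            if noise.ph_sd:
                ph_obs = ph_obs + rng.normal(0.0, noise.ph_sd, size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": times,
                        "a347": a_obs,
                        "ph_raw": ph_obs,
                        "po2_kpa": po2_col,
                        "temp_c": temp,
                        "segment": label,
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        traces.append(ChamberTrace(data=df, po2=po2, temperature=temp, amin_true=amin))
    return traces


def simulate_alpha_stat_series(
    slope: float,
    intercept: float,
    temps: Sequence[float],
    n_per_temp: int,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Replicated haemolymph pH measurements across temperatures.

    pH = intercept + slope * T + N(0, noise_sd); ``intercept`` is the pH
    at 0 degC.  Emulates the alpha-stat assay (replicates at a few set
    temperatures, OLS slope ~ -0.0153 pH/degC).
    """
    temps = list(temps)
    if len(temps) == 0:
        raise ValueError("temps must be non-empty")
    if n_per_temp < 1:
        raise ValueError("n_per_temp must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.repeat(np.asarray(temps, dtype=float), n_per_temp)
    ph = intercept + slope * t
    if noise_sd:
        ph = ph + rng.normal(0.0, noise_sd, size=t.size)
    return pd.DataFrame({"temperature": t, "ph": ph})


def simulate_respirometry(
    capacity: float,
    sample_vol: float,
    chamber_vol: float,
    background_flux: float = 0.0,
    seed: int = 0,
    baseline: float = 250.0,
    injection_time: float = 600.0,
    duration: float = 1200.0,
    dt: float = 2.0,
    noise_sd: float = 0.2,
) -> pd.DataFrame:
    """Oxygen-concentration trace of one respirometry injection.

    The injected sample (``sample_vol`` ul into ``chamber_vol`` ml of
    cyanide solution) liberates its full oxygen content, stepping the
    chamber concentration by capacity * sample_vol / chamber_vol (umol/L)
    on top of a linear background flux (umol/L/h).  For a seawater control
    injection pass the dissolved-O2 content of seawater as ``capacity``.
    """
    if sample_vol <= 0 or chamber_vol <= 0:
        raise ValueError("volumes must be > 0")
    if sample_vol * 1e-3 >= chamber_vol:
        raise ValueError("sample volume must be far smaller than chamber volume")
    if capacity < 0:
        raise ValueError("capacity must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration, dt)
    step = capacity * sample_vol / chamber_vol  # mmol/L * ul/ml == umol/L
    conc = baseline + background_flux * times / 3600.0
    conc = conc + step * (times >= injection_time)
    if noise_sd:
        conc = conc + rng.normal(0.0, noise_sd, size=times.size)
    return pd.DataFrame({"time_s": times, "o2_umol_l": conc})


def write_traces(
    traces: list[ChamberTrace],
    outdir: str | Path,
    gt: GroundTruthPigment | None = None,
    protocol: ChamberProtocol | None = None,
    noise: NoiseModel | None = None,
) -> list[Path]:
    """Write one CSV per PO2 level plus a manifest of the generating state."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tr in traces:
        path = outdir / f"trace_po2_{tr.po2:g}kPa.csv"
        tr.data.to_csv(path, index=False, float_format="%.10g", columns=TRACE_COLUMNS)
        paths.append(path)
    manifest = {
        "po2_levels": [tr.po2 for tr in traces],
        "amin_true": traces[0].amin_true if traces else None,
        "ground_truth": asdict(gt) if gt is not None else None,
        "protocol": asdict(protocol) if protocol is not None else None,
        "noise": asdict(noise) if noise is not None else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def read_trace(path: str | Path) -> ChamberTrace:
    """Read a chamber-trace CSV written by :func:`write_traces`."""
    df = pd.read_csv(path)
    ramp = df[df["segment"] == "ramp"]
    if ramp.empty:
        raise ValueError(f"{path}: no ramp segment")
    return ChamberTrace(
        data=df,
        po2=float(ramp["po2_kpa"].iloc[0]),
        temperature=float(df["temp_c"].iloc[0]),
    )
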