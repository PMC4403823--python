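"""Raw-trace processing: signal calibration, pH correction, saturation.

Converts diffusion-chamber traces into free-scale-pH saturation series and
respirometry traces into oxygen carrying capacities.  Calibration follows
the chamber protocol: the maximum oxygenation signal (pure-O2 segments)
drifts linearly over a run and is continuously readjusted; the minimum
signal is either measured (pure-N2 segment) or, for cold pigments that do
not deoxygenate fully, predicted from a reference-wavelength regression
with a 5% uncertainty band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError, StepDetectionError
from .synthetic import ChamberTrace

__all__ = [
    "CalibrationModel",
    "SaturationSeries",
    "calibrate_max_signal",
    "predict_min_signal",
    "fit_min_signal_model",
    "correct_ph",
    "compute_saturation",
    "carrying_capacity_from_respirometry",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationModel:
    """Signal calibration for one chamber run.

    amax(t) = amax0 + amax_drift * t/3600 is the (drifting) maximum
    oxygenation signal; amin the minimum; ph_offset the constant
    subtracted from raw pH to reach the free hydrogen ion scale (0.136 by
    default, determined against Tris-buffered seawater standards).
    """

    amax0: float
    amax_drift: float  # AU per hour
    amin: float
    amin_rel_uncertainty: float = 0.05
    ph_offset: float = 0.136
    source: str = "measured"

    def __post_init__(self) -> None:
        if not 0.0 <= self.amin_rel_uncertainty < 1.0:
            raise ValueError("amin_rel_uncertainty must be in [0, 1)")
        if self.source not in ("measured", "predicted"):
            raise ValueError("source must be 'measured' or 'predicted'")

    def amax(self, time_s):
        return self.amax0 + self.amax_drift * np.asarray(time_s, dtype=float) / 3600.0

    @property
    def amin_band(self) -> tuple[float, float]:
        lo = self.amin * (1.0 - self.amin_rel_uncertainty)
        hi = self.amin * (1.0 + self.amin_rel_uncertainty)
        return (min(lo, hi), max(lo, hi))


@dataclass
class SaturationSeries:
    """Free-scale pH vs saturation points of one run at constant PO2."""

    ph_free: np.ndarray
    saturation: np.ndarray
    po2: float
    temperature: float
    source: str = ""
    saturation_lo: np.ndarray | None = None  # amin band propagated
    saturation_hi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ph_free = np.asarray(self.ph_free, dtype=float)
        self.saturation = np.asarray(self.saturation, dtype=float)
        if self.ph_free.shape != self.saturation.shape:
            raise ValueError("ph_free and saturation must have equal length")
        if np.any((self.saturation < 0) | (self.saturation > 1)):
            raise ValueError("saturation must lie in [0, 1] after clipping")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ph_free": self.ph_free,
                "saturation": self.saturation,
                "po2_kpa": self.po2,
                "temp_c": self.temperature,
            }
        )


def calibrate_max_signal(trace: ChamberTrace) -> tuple[float, float]:
    """Least-squares line through the pure-O2 calibration absorbances.

    Returns (amax0 [AU at t=0], drift [AU per hour]).  A single-time-point
    calibration yields zero drift with a logged warning.
    """
    cal = trace.segment("o2_cal")
    if cal.empty:
        raise CalibrationError("trace has no o2_cal segment")
    t = cal["time_s"].to_numpy(dtype=float)
    a = cal["a347"].to_numpy(dtype=float)
    if np.unique(t).size < 2:
        log.warning("single-time-point O2 calibration: drift set to 0")
        return float(a.mean()), 0.0
    slope, intercept = np.polyfit(t, a, 1)
    return float(intercept), float(slope * 3600.0)


def fit_min_signal_model(ref_values, amin_values) -> tuple[float, float]:
    """Fit the (intercept, slope) linear model predicting minimum absorbance
    from the reference-wavelength value of the first recorded spectrum.

    Calibrated once on experiments with fully deoxygenated pigments and then
    applied to runs where the pigment does not deoxygenate completely.
    """
    ref = np.asarray(ref_values, dtype=float)
    amin = np.asarray(amin_values, dtype=float)
    if ref.size < 2:
        raise ValueError("need >= 2 calibration experiments")
    slope, intercept = np.polyfit(ref, amin, 1)
    return float(intercept), float(slope)


def predict_min_signal(
    ref_value: float,
    model: tuple[float, float],
    rel_uncertainty: float = 0.05,
    observed_min: float | None = None,
) -> tuple[float, tuple[float, float]]:
    """Predict the minimum oxygenation signal from a reference wavelength.

    Returns (amin, (band_lo, band_hi)) with band = amin * (1 +- 5%).
    Warns if the prediction exceeds the observed minimum ramp absorbance,
    which would imply negative saturations.
    """
    intercept, slope = model
    if not (np.isfinite(intercept) and np.isfinite(slope)):
        raise ValueError("model coefficients must be finite")
    amin = float(intercept + slope * ref_value)
    band = (amin * (1.0 - rel_uncertainty), amin * (1.0 + rel_uncertainty))
    band = (min(band), max(band))
    if observed_min is not None and amin >= observed_min:
        warnings.warn(
            f"predicted amin ({amin:.4g}) >= observed minimum absorbance "
            f"({observed_min:.4g}); saturations may go negative",
            stacklevel=2,
        )
    return amin, band


def correct_ph(ph_raw, ph_offset: float = 0.136, drift_correction: float = 0.0, time_s=None):
    """Raw-to-free-scale pH: ph_free(t) = ph_raw(t) - offset - drift * t.

    ``drift_correction`` is instrumental optode drift in pH per hour;
    requires ``time_s`` when non-zero.  Offsets far outside the determined
    range (0.130-0.142) are rejected unless ``ph_offset`` is overridden
    deliberately at the call site via exact zero (identity).
    """
    ph_raw = np.asarray(ph_raw, dtype=float)
    if ph_offset != 0.0 and not 0.10 <= ph_offset <= 0.20:
        raise ValueError(f"ph_offset {ph_offset} outside plausible range [0.10, 0.20]")
    out = ph_raw - ph_offset
    if drift_correction:
        if time_s is None:
            raise ValueError("time_s required for drift correction")
        out = out - drift_correction * np.asarray(time_s, dtype=float) / 3600.0
    return out if out.ndim else float(out)


def compute_saturation(
    trace: ChamberTrace,
    cal: CalibrationModel,
    ph_drift: float = 0.0,
) -> SaturationSeries:
    """Calibrated saturation of the ramp segment.

    S(t) = (A(t) - amin) / (amax(t) - amin), clipped to [0, 1]; the 5%
    amin uncertainty band is propagated into saturation_lo/hi envelopes.
    """
    ramp = trace.segment("ramp")
    if ramp.empty:
        raise CalibrationError("trace has no ramp segment")
    t = ramp["time_s"].to_numpy(dtype=float)
    a = ramp["a347"].to_numpy(dtype=float)
    amax_t = cal.amax(t)
    denom = amax_t - cal.amin
    if np.any(denom <= 0):
        raise CalibrationError("amax(t) <= amin within the ramp: calibration invalid")
    s = np.clip((a - cal.amin) / denom, 0.0, 1.0)
    lo_amin, hi_amin = cal.amin_band
    # a larger assumed amin raises computed saturation at the low end
    s_lo = np.clip((a - lo_amin) / (amax_t - lo_amin), 0.0, 1.0)
    s_hi = np.clip((a - hi_amin) / (amax_t - hi_amin), 0.0, 1.0)
    band = np.sort(np.vstack([s_lo, s_hi]), axis=0)
    ph_free = correct_ph(ramp["ph_raw"].to_numpy(), cal.ph_offset, ph_drift, time_s=t)
    return SaturationSeries(
        ph_free=ph_free,
        saturation=s,
        po2=trace.po2,
        temperature=trace.temperature,
        source=cal.source,
        saturation_lo=band[0],
        saturation_hi=band[1],
    )


def _injection_step(trace: pd.DataFrame, settle: int = 3) -> tuple[float, float]:
    """Plateau-median step size and pre-injection noise sd of one trace.

    The injection time is the largest jump of a rolling-median-smoothed
    series; background flux is removed with a least-squares line fitted to
    the pre-injection segment only (the post segment may carry the step
    transient), and the step is the difference of plateau medians of the
    residuals.
    """
    t = trace["time_s"].to_numpy(dtype=float)
    c = trace["o2_umol_l"].to_numpy(dtype=float)
    if t.size < 10:
        raise StepDetectionError("respirometry trace too short")
    smooth = pd.Series(c).rolling(5, center=True, min_periods=1).median().to_numpy()
    k = int(np.argmax(np.abs(np.diff(smooth)))) + 1
    if k < 5 or k > t.size - 5:
        raise StepDetectionError("no interior injection step found")
    pre_t, pre_c = t[: k - settle], c[: k - settle]
    post_c = c[k + settle :]
    post_t = t[k + settle :]
    slope, intercept = np.polyfit(pre_t, pre_c, 1)
    pre_resid = pre_c - (intercept + slope * pre_t)
    post_resid = post_c - (intercept + slope * post_t)
    step = float(np.median(post_resid) - np.median(pre_resid))
    noise_sd = float(np.std(pre_resid, ddof=1))
    return step, noise_sd


def carrying_capacity_from_respirometry(
    sample_trace: pd.DataFrame,
    seawater_control_trace: pd.DataFrame,
    sample_vol: float,
    chamber_vol: float,
) -> float:
    """Oxygen carrying capacity (mmol O2 / L haemolymph) from respirometry.

    capacity = (step_sample - step_control) * chamber_vol / sample_vol,
    with each step measured as the difference of plateau medians after
    removing the fitted linear background flux.  The seawater control
    removes the dissolved-O2 contribution of the injected liquid.
    """
    if sample_vol <= 0 or chamber_vol <= 0:
        raise ValueError("volumes must be > 0")
    step_s, sd_s = _injection_step(sample_trace)
    step_c, _ = _injection_step(seawater_control_trace)
    if abs(step_s) < 3.0 * max(sd_s, 1e-12):
        raise StepDetectionError(
            f"sample step {step_s:.3g} umol/L below 3x noise sd ({sd_s:.3g})"
        )
    # umol/L chamber * (chamber_vol ml / sample_vol ul) == mmol/L sample
    return (step_s - step_c) * chamber_vol / sample_vol
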