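"""5PL pH oxygen-saturation curve fitting and derived binding parameters.

The affinity of haemocyanin for oxygen is characterised here through
fixed-PO2 pH-saturation curves: an empirical five-parameter logistic is
fitted to each (pH, saturation) series, its 50%-saturation pH (pH50) is
located, and a linear regression of log10 PO2 on pH50 across the curves of
one pigment yields both the Bohr coefficient (the slope) and P50 at any pH
of interest (the line evaluated and exponentiated).  Cooperativity of
oxygenation-linked proton binding is the carrying capacity times the
maximum slope of a fitted curve (Dmmol O2 L-1 per DpH).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import DegenerateFitError, FitError, PH50Undefined
from .fivepl import FivePL, five_pl
from .traces import SaturationSeries

__all__ = [
    "PHOxygenCurve",
    "BindingParams",
    "fit_5pl",
    "ph50",
    "p50_at_ph",
    "bohr_coefficient",
    "cooperativity",
    "delta_p50_per_degC",
]

_BOUNDS_LO = np.array([0.05, -0.05, 0.40, -np.inf, 0.05])
_BOUNDS_HI = np.array([200.0, 0.60, 1.05, np.inf, 20.0])


@dataclass
class PHOxygenCurve:
    """One fitted pH oxygen-saturation curve at constant PO2 and temperature."""

    params: FivePL
    po2: float
    temperature: float
    n_points: int
    ph_range: tuple[float, float]  # observed span of the data
    boot_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 6:
            raise ValueError("a pH oxygen-saturation curve needs >= 6 points")

    def __call__(self, ph):
        return self.params(ph)


@dataclass
class BindingParams:
    """Derived pigment parameters of one species at one temperature."""

    species: str
    temperature: float
    ph50_by_po2: dict[float, float]
    p50_at: list[tuple[float, float]]  # (pH, P50 kPa)
    bohr: float
    cooperativity: float
    dp50_dt: float | None = None

    def p50_lookup(self, ph: float) -> float:
        for p, v in self.p50_at:
            if abs(p - ph) < 1e-9:
                return v
        raise KeyError(f"no P50 stored at pH {ph}")


def _residuals(theta, ph, sat):
    return five_pl(ph, *theta) - sat


def _starts(ph: np.ndarray, sat: np.ndarray) -> list[np.ndarray]:
    """Five deterministic starts from data quantiles (5PL fits are
    initialisation-sensitive)."""
    c0 = float(np.clip(np.percentile(sat, 2), -0.04, 0.45))
    d0 = float(np.clip(np.percentile(sat, 98), 0.55, 1.04))
    mid = 0.5 * (c0 + d0)
    e0 = float(ph[np.argmin(np.abs(sat - mid))])
    span = max(ph.max() - ph.min(), 0.1)
    return [
        np.array([4.0, c0, d0, e0, 1.0]),
        np.array([8.0, c0, d0, e0, 1.0]),
        np.array([16.0, c0, d0, e0, 1.0]),
        np.array([8.0, c0, d0, e0 + 0.15 * span, 2.0]),
        np.array([8.0, c0, d0, e0 - 0.15 * span, 0.5]),
    ]


def _fit_once(ph, sat, theta0):
    theta0 = np.clip(theta0, _BOUNDS_LO + 1e-9, _BOUNDS_HI - 1e-9)
    return optimize.least_squares(
        _residuals,
        theta0,
        args=(ph, sat),
        bounds=(_BOUNDS_LO, _BOUNDS_HI),
        method="trf",
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=5000,
    )


def fit_5pl(series: SaturationSeries, n_boot: int = 1000, seed: int = 0) -> PHOxygenCurve:
    """Fit a 5PL to one saturation series with bootstrap 95% CIs.

    Nonlinear least squares from five deterministic multi-starts; residual
    resampling (seeded) for per-parameter percentile intervals.  Raises
    :class:`FitError` on non-convergence and ValueError for < 6 distinct
    pH points.
    """
    ph = np.asarray(series.ph_free, dtype=float)
    sat = np.asarray(series.saturation, dtype=float)
    if np.unique(ph).size < 6:
        raise ValueError("need >= 6 distinct pH points to fit a 5PL")
    best = None
    tried = []
    for theta0 in _starts(ph, sat):
        res = _fit_once(ph, sat, theta0)
        tried.append((theta0.tolist(), res.status, float(res.cost)))
        # status 0 (max_nfev) with a machine-precision residual is a valid
        # fit: near-flat series leave the 5PL under-determined and TRF keeps
        # wandering along the ridge without improving
        converged = res.success or res.cost <= 1e-10
        if converged and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError(f"5PL fit did not converge; starts tried: {tried}")
    theta = best.x
    fitted = five_pl(ph, *theta)
    resid = sat - fitted
    names = ("b", "c", "d", "e", "f")
    boot_ci: dict[str, tuple[float, float]] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            sat_b = fitted + rng.choice(resid, size=resid.size, replace=True)
            res_b = _fit_once(ph, sat_b, theta)
            if res_b.success:
                draws.append(res_b.x)
        if len(draws) >= max(10, n_boot // 2):
            draws = np.asarray(draws)
            lo = np.percentile(draws, 2.5, axis=0)
            hi = np.percentile(draws, 97.5, axis=0)
            # percentile bands widened to bracket the point estimate
            boot_ci = {
                k: (float(min(l, v)), float(max(h, v)))
                for k, l, h, v in zip(names, lo, hi, theta)
            }
    return PHOxygenCurve(
        params=FivePL(*theta),
        po2=series.po2,
        temperature=series.temperature,
        n_points=int(ph.size),
        ph_range=(float(ph.min()), float(ph.max())),
        boot_ci=boot_ci,
        seed=seed,
    )


def ph50(curve: PHOxygenCurve, within_observed_range: bool = True) -> float:
    """pH at 50% saturation of a fitted curve, by bracketed root finding.

    Raises :class:`PH50Undefined` when the fitted asymptotes exclude 0.5
    (e.g. cold curves with residual saturation >= 50%) or when, with
    ``within_observed_range``, the crossing falls outside the pH span of
    the underlying data (an extrapolated pH50 would corrupt the Bohr
    regression).
    """
    p = curve.params
    if p.c >= 0.5:
        raise PH50Undefined(f"lower asymptote {p.c:.3f} >= 0.5: pH50 undefined")
    if p.d <= 0.5:
        raise PH50Undefined(f"upper asymptote {p.d:.3f} <= 0.5: pH50 undefined")
    guess = p.half_saturation_ph()
    lo, hi = guess - 1.0, guess + 1.0
    for _ in range(60):
        if (p(lo) - 0.5) * (p(hi) - 0.5) < 0:
            break
        lo -= 0.5
        hi += 0.5
    root = optimize.brentq(lambda x: p(x) - 0.5, lo, hi, xtol=1e-8)
    if within_observed_range:
        ph_lo, ph_hi = curve.ph_range
        if not ph_lo <= root <= ph_hi:
            raise PH50Undefined(
                f"pH50 {root:.3f} outside observed pH range [{ph_lo:.2f}, {ph_hi:.2f}]"
            )
    return float(root)


def _ph50_points(curves: Sequence[PHOxygenCurve]) -> list[tuple[float, float, float]]:
    """(pH50, log10 PO2, temperature) for every curve with a defined pH50."""
    pts = []
    for c in curves:
        try:
            pts.append((ph50(c), float(np.log10(c.po2)), c.temperature))
        except PH50Undefined:
            continue
    return pts


def p50_at_ph(
    curves: Sequence[PHOxygenCurve],
    target_ph: float,
    slope: float | None = None,
) -> float:
    """P50 (kPa) at ``target_ph`` from the Bohr line of one temperature.

    Each fixed-PO2 curve contributes the point (pH50, log10 PO2); the
    least-squares line is evaluated at ``target_ph`` and exponentiated.
    With a pooled Bohr ``slope`` supplied, a single defined pH50 suffices
    (the line of that slope through the point(s)); otherwise two defined
    pH50s are required.  Extrapolation beyond the pH50 range is flagged
    with a warning.
    """
    pts = _ph50_points(curves)
    if not pts:
        raise PH50Undefined("no curve with a defined pH50")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if slope is None:
        if len(pts) < 2:
            raise PH50Undefined("fewer than 2 curves with a defined pH50")
        if np.ptp(x) < 1e-12:
            raise DegenerateFitError("identical pH50 values: Bohr line degenerate")
        slope_, intercept = np.polyfit(x, y, 1)
    else:
        slope_ = slope
        intercept = float(np.mean(y - slope_ * x))
    if not x.min() <= target_ph <= x.max():
        warnings.warn(
            f"P50 at pH {target_ph:.2f} extrapolates beyond the pH50 range "
            f"[{x.min():.2f}, {x.max():.2f}]",
            stacklevel=2,
        )
    return float(10.0 ** (intercept + slope_ * target_ph))


def bohr_coefficient(curves: Sequence[PHOxygenCurve]) -> float:
    """Bohr coefficient Dlog10 P50 / DpH.

    Each curve's PO2 *is* the P50 at its own pH50, so regressing log10
    PO2 on pH50 yields the Bohr slope directly.  Curves from different
    temperatures are pooled by centering within each temperature group
    before the (unweighted) regression -- the Dlog10 P50 vs DpH50
    construction -- since curves at different temperatures lie on Bohr
    lines offset by the temperature effect on affinity.
    """
    pts = _ph50_points(curves)
    if len(pts) < 2:
        raise PH50Undefined("fewer than 2 curves with a defined pH50")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    temps = np.array([p[2] for p in pts])
    sxy = 0.0
    sxx = 0.0
    for t in np.unique(temps):
        m = temps == t
        if m.sum() < 2:
            continue
        dx = x[m] - x[m].mean()
        dy = y[m] - y[m].mean()
        sxy += float(dx @ dy)
        sxx += float(dx @ dx)
    if sxx < 1e-12:
        raise DegenerateFitError("identical pH50 values: Bohr line degenerate")
    return sxy / sxx


def cooperativity(curve: PHOxygenCurve, capacity: float) -> float:
    """Oxygenation-linked proton-binding cooperativity, Dmmol O2 L-1/DpH.

    capacity times the maximum |dS/dpH| of the fitted curve; maximised
    numerically and checked against the analytic stationary point of the
    5PL derivative.
    """
    if capacity < 0:
        raise ValueError("capacity must be >= 0")
    if capacity == 0:
        return 0.0
    p = curve.params
    x0 = p.max_slope_ph
    res = optimize.minimize_scalar(
        lambda x: -p.deriv(x), bounds=(x0 - 2.0, x0 + 2.0), method="bounded",
        options={"xatol": 1e-10},
    )
    num = -float(res.fun)
    ana = p.max_slope
    if not np.isclose(num, ana, rtol=1e-6, atol=1e-12):
        raise FitError(
            f"cooperativity maximiser ({num:.6g}) disagrees with the analytic "
            f"stationary point ({ana:.6g})"
        )
    return capacity * num


def delta_p50_per_degC(
    bp_low: BindingParams,
    bp_high: BindingParams,
    venous_ph_low: float,
    venous_ph_high: float,
) -> float:
    """Temperature sensitivity DP50/DT (kPa per degC).

    The difference quotient of P50 between two temperatures, each taken at
    the alpha-stat shifted venous pH of that temperature.
    """
    dt = bp_high.temperature - bp_low.temperature
    if dt == 0:
        raise ValueError("temperatures must differ")
    p50_lo = bp_low.p50_lookup(venous_ph_low)
    p50_hi = bp_high.p50_lookup(venous_ph_high)
    return (p50_hi - p50_lo) / dt
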