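"""Five-parameter logistic (5PL) curve in pH.

The empirical model for pH oxygen-saturation curves of haemocyanin at
constant PO2:

    S(pH) = c + (d - c) / (1 + exp(b * (e - pH)))**f

with b > 0 the steepness, c/d the lower/upper asymptotes, e the
inflection-region anchor and f > 0 the asymmetry exponent.  For f = 1 the
curve is the symmetric four-parameter logistic and e is both the inflection
point and the half-saturation pH (when c = 0, d = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FivePL", "five_pl", "five_pl_deriv"]


def five_pl(ph, b, c, d, e, f):
    """Evaluate the 5PL saturation model at ``ph`` (scalar or array)."""
    ph = np.asarray(ph, dtype=float)
    z = b * (e - ph)
    # log-space form avoids overflow of (1 + exp(z))**f for steep curves
    out = c + (d - c) * np.exp(-f * np.logaddexp(0.0, z))
    return out if out.ndim else float(out)


def five_pl_deriv(ph, b, c, d, e, f):
    """Analytic dS/dpH of the 5PL model."""
    ph = np.asarray(ph, dtype=float)
    z = b * (e - ph)
    out = (d - c) * f * b * np.exp(z - (f + 1.0) * np.logaddexp(0.0, z))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FivePL:
    """Parameter bundle for one fitted (or ground-truth) 5PL curve.

    Attributes
    ----------
    b : steepness per pH unit (> 0; curve increases with pH).
    c : lower asymptote (residual saturation fraction).
    d : upper asymptote.
    e : inflection-region pH anchor.
    f : asymmetry exponent (> 0; f = 1 gives the symmetric logistic).
    """

    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ValueError(f"asymmetry f must be > 0, got {self.f}")
        if not self.b > 0:
            raise ValueError(f"steepness b must be > 0, got {self.b}")
        if not self.c < self.d:
            raise ValueError(f"asymptotes require c < d, got c={self.c}, d={self.d}")

    def __call__(self, ph):
        return five_pl(ph, self.b, self.c, self.d, self.e, self.f)

    def deriv(self, ph):
        return five_pl_deriv(ph, self.b, self.c, self.d, self.e, self.f)

    @property
    def max_slope_ph(self) -> float:
        """pH of the steepest point: where u = exp(b(e - pH)) equals 1/f."""
        return self.e + np.log(self.f) / self.b

    @property
    def max_slope(self) -> float:
        """Closed-form maximum of dS/dpH ((d-c)*b/4 for the symmetric case)."""
        u = 1.0 / self.f
        return (self.d - self.c) * self.f * self.b * u / (1.0 + u) ** (self.f + 1.0)

    def half_saturation_ph(self) -> float:
        """Analytic pH at S = 0.5; requires c < 0.5 < d."""
        if not (self.c < 0.5 < self.d):
            raise ValueError("curve asymptotes do not bracket S = 0.5")
        ratio = (self.d - self.c) / (0.5 - self.c)
        return self.e - np.log(ratio ** (1.0 / self.f) - 1.0) / self.b

    @staticmethod
    def anchored_at(ph50: float, b: float, c: float, d: float, f: float) -> "FivePL":
        """Build a 5PL whose 50%-saturation pH equals ``ph50`` exactly."""
        if not (c < 0.5 < d):
            raise ValueError("cannot anchor at 50% saturation: asymptotes exclude 0.5")
        ratio = (d - c) / (0.5 - c)
        e = ph50 + np.log(ratio ** (1.0 / f) - 1.0) / b
        return FivePL(b=b, c=c, d=d, e=float(e), f=f)

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.b, self.c, self.d, self.e, self.f)
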