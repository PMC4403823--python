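"""In-vivo oxygen transport: alpha-stat pH, saturations, O2 budgets.

Projects fitted pH oxygen-saturation curves to in-vivo conditions.  Venous
pH follows the alpha-stat pattern (linear decrease with temperature,
-0.0153 pH/degC); arterial pH sits a constant 0.11 units above venous.
Arterial and venous PO2 (13 / 4 resting / 1 kPa exercised, from Octopus
vulgaris) are held constant across temperatures.  The transport budget per
litre haemolymph combines haemocyanin-bound oxygen (capacity times the
arterio-venous saturation difference) with physically dissolved oxygen
(Henry-law scaling of the air-saturated seawater solubility).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .curves import PHOxygenCurve

__all__ = [
    "AlphaStatModel",
    "InVivoConditions",
    "TransportBudget",
    "venous_ph",
    "arterial_ph",
    "o2_solubility",
    "dissolved_o2",
    "saturation_at",
    "transport_budget",
    "hc_concentration",
]


@dataclass(frozen=True)
class AlphaStatModel:
    """Linear alpha-stat pH-temperature model for venous haemolymph.

    Default slope -0.0153 pH/degC through pH 7.42 at 0 degC: the line that
    reproduces the venous pH set 7.42/7.27/7.19/7.11 at 0/10/15/20 degC
    (to two decimals) used throughout the in-vivo projections.
    """

    slope: float = -0.0153
    anchor_ph: float = 7.42
    anchor_temp: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError("alpha-stat slope must be negative")


def venous_ph(model: AlphaStatModel, temperature: float) -> float:
    """Alpha-stat venous pH at ``temperature`` (valid -2..30 degC)."""
    if not -2.0 <= temperature <= 30.0:
        raise ValueError("temperature outside the physiological range [-2, 30] degC")
    return model.anchor_ph + model.slope * (temperature - model.anchor_temp)


def arterial_ph(venous: float, offset: float = 0.11) -> float:
    """Arterial pH assumed ``offset`` units above venous pH."""
    return venous + offset


# Garcia & Gordon (1992) combined fit to the Benson & Krause oxygen
# solubility data; umol O2 per kg seawater at air saturation.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def _o2_solubility_umol_kg(temperature: float, salinity: float) -> float:
    ts = np.log((298.15 - temperature) / (273.15 + temperature))
    ln_c = sum(a * ts**i for i, a in enumerate(_GG_A))
    ln_c += salinity * sum(b * ts**i for i, b in enumerate(_GG_B))
    ln_c += _GG_C0 * salinity**2
    return float(np.exp(ln_c))


def _seawater_density_kg_l(temperature: float, salinity: float) -> float:
    """EOS-80 (UNESCO 1983) surface seawater density, kg per litre."""
    t = temperature
    s = salinity
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return (rho_w + a * s + b * s**1.5 + c * s**2) / 1000.0


def o2_solubility(temperature: float, salinity: float = 35.0) -> float:
    """Air-saturated seawater O2 concentration, umol per litre.

    Benson-Krause solubility (Garcia-Gordon combined fit, umol/kg)
    converted to per-litre with the EOS-80 surface density.  359.5 umol/L
    at 0 degC / 35 psu within 1%.
    """
    if not -2.0 <= temperature <= 40.0:
        raise ValueError("temperature outside solubility-fit range [-2, 40] degC")
    if not 0.0 <= salinity <= 42.0:
        raise ValueError("salinity outside solubility-fit range [0, 42] psu")
    return _o2_solubility_umol_kg(temperature, salinity) * _seawater_density_kg_l(
        temperature, salinity
    )


def dissolved_o2(
    po2: float, temperature: float, salinity: float = 35.0, air_po2: float = 21.0
) -> float:
    """Dissolved O2 (umol/L) at partial pressure ``po2``, Henry-law scaled."""
    if po2 < 0:
        raise ValueError("po2 must be >= 0")
    if po2 > air_po2 * 1.1:
        raise ValueError(f"po2 {po2} kPa beyond the air-equilibrated range")
    return o2_solubility(temperature, salinity) * po2 / air_po2


@dataclass(frozen=True)
class InVivoConditions:
    """In-vivo gas tensions and pH for one temperature.

    PO2 defaults follow Octopus vulgaris (arterial 13 kPa, venous 4 kPa
    resting / 1 kPa exercised) and are held constant across temperatures;
    venous pH is alpha-stat derived, arterial pH 0.11 units higher.
    """

    temperature: float
    venous_ph: float
    arterial_po2: float = 13.0
    venous_po2: float = 4.0
    salinity: float = 35.0
    arterial_ph_offset: float = 0.11
    air_po2: float = 21.0

    def __post_init__(self) -> None:
        if not self.arterial_po2 > self.venous_po2 > 0:
            raise ValueError("require arterial_po2 > venous_po2 > 0")
        if not 0.0 < self.salinity <= 45.0:
            raise ValueError("salinity must be in (0, 45] psu")

    @classmethod
    def at_temperature(
        cls,
        temperature: float,
        alpha_stat: AlphaStatModel | None = None,
        **kwargs,
    ) -> "InVivoConditions":
        model = alpha_stat or AlphaStatModel()
        return cls(temperature=temperature, venous_ph=venous_ph(model, temperature), **kwargs)

    @property
    def arterial_ph(self) -> float:
        return arterial_ph(self.venous_ph, self.arterial_ph_offset)


@dataclass(frozen=True)
class TransportBudget:
    """Oxygen delivered per litre haemolymph for one arterio-venous transition.

    All concentrations mmol O2 per litre; fractions dimensionless.
    ``dissolved_fraction_of_total`` follows the air-saturated-dissolved
    over (dissolved + full capacity) convention of the source analysis.
    """

    s_arterial: float
    s_venous: float
    bound_release_frac: float
    bound_release: float
    dissolved_arterial: float
    dissolved_venous: float
    dissolved_release: float
    total_content: float
    total_release: float
    dissolved_fraction_of_total: float
    dissolved_fraction_of_release: float


def saturation_at(
    curves: Sequence[PHOxygenCurve], ph: float, po2: float
) -> float:
    """Saturation at (pH, PO2) from fixed-PO2 curves of one temperature.

    Evaluates every fitted curve at ``ph`` and interpolates linearly in
    log10 PO2; no extrapolation outside the fitted PO2 range.
    """
    if not curves:
        raise ValueError("no curves given")
    order = np.argsort([c.po2 for c in curves])
    po2s = np.array([curves[i].po2 for i in order], dtype=float)
    if not po2s.min() <= po2 <= po2s.max():
        raise ValueError(
            f"PO2 {po2} kPa outside the fitted range [{po2s.min():g}, {po2s.max():g}]"
        )
    sats = np.array([float(curves[i](ph)) for i in order])
    return float(np.interp(np.log10(po2), np.log10(po2s), sats))


def transport_budget(
    curves: Sequence[PHOxygenCurve],
    capacity: float,
    cond: InVivoConditions,
) -> TransportBudget:
    """Bound plus dissolved oxygen delivery per litre haemolymph.

    Bound release is capacity * (S_arterial - S_venous) with saturations
    taken at the alpha-stat arterial/venous pH and PO2 of ``cond``;
    dissolved terms scale the air-saturated solubility to each PO2.
    """
    if capacity <= 0:
        raise ValueError("capacity must be > 0")
    s_a = saturation_at(curves, cond.arterial_ph, cond.arterial_po2)
    s_v = saturation_at(curves, cond.venous_ph, cond.venous_po2)
    if s_a == 0:
        raise ValueError("arterial saturation is zero: release fraction undefined")
    sol = o2_solubility(cond.temperature, cond.salinity) / 1000.0  # mmol/L
    d_a = dissolved_o2(cond.arterial_po2, cond.temperature, cond.salinity, cond.air_po2) / 1000.0
    d_v = dissolved_o2(cond.venous_po2, cond.temperature, cond.salinity, cond.air_po2) / 1000.0
    bound_release = capacity * (s_a - s_v)
    dissolved_release = d_a - d_v
    total_content = capacity * s_a + d_a
    total_release = bound_release + dissolved_release
    return TransportBudget(
        s_arterial=s_a,
        s_venous=s_v,
        bound_release_frac=(s_a - s_v) / s_a,
        bound_release=bound_release,
        dissolved_arterial=d_a,
        dissolved_venous=d_v,
        dissolved_release=dissolved_release,
        total_content=total_content,
        total_release=total_release,
        dissolved_fraction_of_total=sol / (sol + capacity),
        dissolved_fraction_of_release=dissolved_release / total_release,
    )


def hc_concentration(
    capacity: float, binding_sites: int = 70, mw: float = 3.5e6
) -> float:
    """Functional haemocyanin concentration (g/L = mg/ml) from capacity.

    c(Hc) = C_O2 / n(HcO2) * MW with C_O2 in mol/L: the 3.5 MDa octopod
    haemocyanin binds one O2 at each of its 70 binding sites.
    """
    if capacity < 0:
        raise ValueError("capacity must be >= 0")
    if binding_sites <= 0:
        raise ValueError("binding_sites must be > 0")
    return capacity * 1e-3 / binding_sites * mw
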