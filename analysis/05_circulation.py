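"""Circulatory supply-demand balance for the Antarctic octopod.

Compares metabolic oxygen demand (0.63 mmol O2 kg-1 h-1 at 0 degC, Q10
2.12) with haemocyanin-bound oxygen delivery per pass from the transport
table, and reports the required blood-volume turnover (blood volume 5.2%
v/w) plus the constant-supply vs measured-supply circulation increase for
a 0 -> 10 degC warming.  Writes results/circulation.csv.
"""

from pathlib import Path

import pandas as pd

import bluesat as bs

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    transport = pd.read_csv(ROOT / "transport.csv")
    rest = transport[
        (transport.species == "P_charcoti") & (transport.venous_po2_kpa == 4.0)
    ]
    delivered = dict(zip(rest["temperature"], rest["bound_release"]))
    delivered = {t: v for t, v in delivered.items() if v > 0}
    scen = bs.CirculationScenario(
        mo2_ref=0.63, t_ref=0.0, delivered_per_l=delivered,
        q10=2.12, blood_volume_frac=0.052,
    )
    df = bs.run_scenario(scen)
    t_lo, t_hi = min(delivered), max(delivered)
    const, meas = bs.circulation_increase(
        df.loc[df.temperature == t_lo, "mo2_mmol_kg_h"].iloc[0],
        df.loc[df.temperature == t_hi, "mo2_mmol_kg_h"].iloc[0],
        delivered[t_lo], delivered[t_hi],
    )
    out = ROOT / "circulation.csv"
    df.to_csv(out, index=False, float_format="%.6g")
    print(df.round(4).to_string(index=False))
    print(f"constant-supply circulation increase {t_lo:g}->{t_hi:g} degC: {const:.1f}%")
    print(f"measured-supply circulation increase: {meas:.1f}%")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
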