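"""Fit 5PL pH oxygen-saturation curves and derive binding parameters.

Fits each saturation series, locates pH50 per PO2 level, pools the
Bohr regression per species (within-temperature centering), evaluates
P50 at each temperature's alpha-stat venous pH and the cooperativity of
oxygenation-linked proton binding.  Writes results/binding_params.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import bluesat as bs
from bluesat.pipeline import default_study_config, substream_seed

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"


def load_series(rundir: Path) -> list[bs.SaturationSeries]:
    out = []
    for path in sorted(rundir.glob("saturation_*.csv")):
        df = pd.read_csv(path)
        out.append(
            bs.SaturationSeries(
                ph_free=df["ph_free"].to_numpy(),
                saturation=df["saturation"].to_numpy(),
                po2=float(df["po2_kpa"].iloc[0]),
                temperature=float(df["temp_c"].iloc[0]),
            )
        )
    return out


def main() -> None:
    config = default_study_config(seed=SEED)
    alpha = config.alpha_stat.build()
    rows = []
    for sp in config.species:
        curves_by_temp = {}
        for temp in sp.temperatures:
            rundir = ROOT / "saturation" / f"{sp.name}_{temp:g}C"
            curves_by_temp[temp] = [
                bs.fit_5pl(s, n_boot=200, seed=substream_seed(SEED, f"fit:{sp.name}:{temp}:{s.po2}"))
                for s in load_series(rundir)
            ]
        all_curves = [c for cs in curves_by_temp.values() for c in cs]
        bohr = bs.bohr_coefficient(all_curves)
        capacity = sp.pigment.capacity
        for temp, curves in sorted(curves_by_temp.items()):
            vph = bs.venous_ph(alpha, temp)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    p50 = bs.p50_at_ph(curves, vph, slope=bohr)
                except bs.BluesatError:
                    p50 = float("nan")
            coop = float(np.mean([bs.cooperativity(c, capacity) for c in curves]))
            rows.append(
                {
                    "species": sp.name,
                    "temperature": temp,
                    "venous_ph": round(vph, 3),
                    "p50_kpa": p50,
                    "bohr": bohr,
                    "cooperativity": coop,
                    "capacity_mmol_l": capacity,
                    "hc_mg_ml": bs.hc_concentration(capacity),
                }
            )
    df = pd.DataFrame(rows)
    out = ROOT / "binding_params.csv"
    df.to_csv(out, index=False, float_format="%.6g")
    print(df.round(3).to_string(index=False))
    print(f"-> {out}")


if __name__ == "__main__":
    main()
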