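"""Calibrate raw traces into free-scale-pH saturation series.

For each simulated run: fit the linear drift of the maximum oxygenation
signal from the bracketing pure-O2 segments, take the minimum signal from
the pure-N2 plateau (or the reference-wavelength prediction for the cold
Antarctic runs, whose pigment never deoxygenates fully), subtract the
0.136 pH-scale offset, and write ph_free/saturation CSVs under
results/saturation/.
"""

import json
from pathlib import Path

from bluesat import CalibrationModel, calibrate_max_signal, compute_saturation, predict_min_signal, read_trace

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    outroot = ROOT / "saturation"
    for rundir in sorted((ROOT / "traces").glob("*_*C")):
        manifest = json.loads((rundir / "manifest.json").read_text())
        predicted = rundir.name.startswith("P_charcoti")
        outdir = outroot / rundir.name
        outdir.mkdir(parents=True, exist_ok=True)
        for path in sorted(rundir.glob("trace_*.csv")):
            trace = read_trace(path)
            amax0, drift = calibrate_max_signal(trace)
            if predicted:
                amin, _ = predict_min_signal(manifest["amin_true"], (0.0, 1.0))
                source = "predicted"
            else:
                amin = float(trace.segment("n2_cal")["a347"].median())
                source = "measured"
            cal = CalibrationModel(
                amax0=amax0, amax_drift=drift, amin=amin, source=source
            )
            series = compute_saturation(trace, cal)
            series.to_frame().to_csv(outdir / f"saturation_{path.stem}.csv", index=False)
        print(f"{rundir.name}: amin {source}, drift {drift:+.4f} AU/h")


if __name__ == "__main__":
    main()
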