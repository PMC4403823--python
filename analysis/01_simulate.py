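"""Simulate diffusion-chamber experiments for the three study pigments.

Generates one chamber run per PO2 level (21, 13, 4, 1 kPa) for each
species/temperature combination and writes the raw traces under
results/traces/<species>_<temp>C/.  These stand in for the study's
undeposited raw measurements; the ground-truth anchors follow the
published binding parameters of each species.
"""

from pathlib import Path

from bluesat import NoiseModel, simulate_chamber_experiment, write_traces
from bluesat.pipeline import default_study_config, substream_seed

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "traces"


def main() -> None:
    config = default_study_config(seed=SEED)
    for sp in config.species:
        gt = sp.pigment.build()
        for temp in sp.temperatures:
            protocol = config.protocol.build(temp)
            noise = NoiseModel(
                seed=substream_seed(SEED, f"sim:{sp.name}:{temp}"),
                **config.noise.model_dump(),
            )
            traces = simulate_chamber_experiment(gt, protocol, noise)
            outdir = OUT / f"{sp.name}_{temp:g}C"
            paths = write_traces(traces, outdir, gt=gt, protocol=protocol, noise=noise)
            print(f"{sp.name} @ {temp:g} degC: {len(paths)} traces -> {outdir}")


if __name__ == "__main__":
    main()
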