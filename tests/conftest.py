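import numpy as np
import pytest

import bluesat as bs


@pytest.fixture(scope="session")
def charcoti_gt() -> bs.GroundTruthPigment:
    """Antarctic-octopod-like ground truth: P50 2.34 kPa at pH 7.27 / 10 degC,
    Bohr slope -1.22, capacity 1.58 mmol O2/L."""
    return bs.GroundTruthPigment()


@pytest.fixture(scope="session")
def clean_curves_10c(charcoti_gt) -> list[bs.PHOxygenCurve]:
    """Noiseless simulate -> calibrate -> fit chain at 10 degC (4 PO2 levels)."""
    protocol = bs.ChamberProtocol(temperature=10.0)
    noise = bs.NoiseModel(abs_sd=0.0, ph_sd=0.0, max_drift_rate=-0.02, seed=7)
    traces = bs.simulate_chamber_experiment(charcoti_gt, protocol, noise)
    curves = []
    for tr in traces:
        amax0, drift = bs.calibrate_max_signal(tr)
        cal = bs.CalibrationModel(amax0=amax0, amax_drift=drift, amin=tr.amin_true)
        curves.append(bs.fit_5pl(bs.compute_saturation(tr, cal), n_boot=0))
    return curves


def random_fivepl(rng: np.random.Generator) -> bs.FivePL:
    """A random valid 5PL crossing 50% saturation, for oracle-equivalence tests."""
    return bs.FivePL(
        b=float(rng.uniform(1.0, 30.0)),
        c=float(rng.uniform(0.0, 0.45)),
        d=float(rng.uniform(0.8, 1.05)),
        e=float(rng.uniform(6.5, 8.0)),
        f=float(rng.uniform(0.2, 5.0)),
    )
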