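import numpy as np
import pandas as pd
import pytest

from crtox.model_core import CultureState
from crtox.reference import reference_params
from crtox.simulate import integrate_batch


@pytest.fixture(scope="session")
def ref2():
    """Model-2 reference: (species dict, abiotic, spec)."""
    return reference_params("model2")


@pytest.fixture(scope="session")
def ref1():
    """Model-1 reference: (species dict, None, spec)."""
    return reference_params("model1")


@pytest.fixture(scope="session")
def daily_times():
    return np.arange(0.0, 193.0, 24.0)


@pytest.fixture(scope="session")
def mono_at_truth_model1(ref1, daily_times):
    """Noiseless model-1 At mono-culture curves at the four LA levels."""
    species, _, spec = ref1
    out = {}
    for c0 in (0.05, 0.1, 0.5, 0.75):
        traj = integrate_batch(CultureState(B_At=5e5, C=c0), species["At"],
                               species["Ct"], spec, daily_times)
        out[c0] = traj.column("B_At")
    return out


def tidy_growth(curves: dict, times, replicates=1, noise_rng=None, sigma=0.0,
                floor=100.0) -> pd.DataFrame:
    """Tidy mono-culture frame from {concentration: CFU array}."""
    rows = []
    for c0, b in curves.items():
        for rep in range(1, replicates + 1):
            v = np.asarray(b, dtype=float)
            if noise_rng is not None and sigma > 0:
                v = v * noise_rng.lognormal(-sigma ** 2 / 2, sigma, size=v.size)
            v = np.maximum(v, floor)
            rows += [{"concentration_au": c0, "time_h": t, "cfu_per_ml": x}
                     for t, x in zip(times, v)]
    return pd.DataFrame(rows)
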