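import numpy as np
import pytest

from glycoscape import carbo_masses as cm
from glycoscape import phantom as ph
from glycoscape import preprocess as pp


@pytest.fixture(scope="session")
def panel():
    return cm.build_default_panel()


@pytest.fixture(scope="session")
def noiseless_phantom(panel):
    """Small 3-region phantom with no noise and no drift (exact limit)."""
    cfg = ph.default_config(noise_cv=0.0, drift_amplitude=0.0, seed=0,
                            grid=(30, 30), panel=panel)
    ds, truth = ph.make_phantom(cfg, panel)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def noiseless_fm(noiseless_phantom, panel):
    _, ds, truth = noiseless_phantom
    fm = pp.tic_normalize(pp.integrate_panel(ds, panel))
    return fm, truth


def make_fm(values, panel, normalized=True):
    """Wrap a plain numeric matrix as a FeatureMatrix over panel columns."""
    import pandas as pd

    values = np.asarray(values, dtype=np.float64)
    n, p = values.shape
    cols = [str(lbl) for lbl in panel.nominal_labels[:p]]
    frame = pd.DataFrame(
        {"x": np.arange(n) % 100, "y": np.arange(n) // 100,
         "scan_index": np.arange(n)}
    )
    return pp.FeatureMatrix(
        values=pd.DataFrame(values, columns=cols),
        tic=values.sum(axis=1) + 1.0,
        frame=frame,
        panel=panel,
        normalized=normalized,
    )
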