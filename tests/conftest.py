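import numpy as np
import pandas as pd
import pytest

from skinsens import curves, synthetic


@pytest.fixture(scope="session")
def noise_free_panel():
    """A 500-compound assay panel with no noise and full sources."""
    panel, truth = synthetic.gen_assay_call_panel(
        500, ghs_mix=(0.1, 0.45, 0.45), missingness=0.0, flip_noise=0.0, seed=11
    )
    return panel, {t.compound_id: t.true_ghs for t in truth}


@pytest.fixture()
def clean_series():
    """Noise-free activation series from known Hill parameters."""

    def _make(s0=0.0, sinf=100.0, ac50=1.0, h=1.0, conc_range=(0.0028, 92.0)):
        conc = np.logspace(np.log10(conc_range[0]), np.log10(conc_range[1]), 15)
        return curves.ConcentrationResponseSeries(
            "X", "ks", conc, curves.hill_curve(conc, s0, sinf, ac50, h)
        )

    return _make
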