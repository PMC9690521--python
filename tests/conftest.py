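import numpy as np
import pandas as pd
import pytest

import scapekit as sk
from scapekit.ensemble import SpectrumEnsemble
from scapekit.spectral import make_binning


@pytest.fixture(scope="session")
def urban_run():
    """Default urban scenario simulated once and pushed through the pipeline."""
    from scapekit import denoising, fcm

    sources, settings = sk.default_urban_scenario(7)
    ens, truth = sk.simulate_ensemble(sources, **settings)
    den, report = denoising.denoise_ensemble(ens)
    den, report = denoising.remove_outliers(den, 0.9995, report)
    mat = fcm.compute_fcm(den, fmax=13_000.0, min_pairs=30)
    return {"sources": sources, "settings": settings, "ensemble": ens,
            "truth": truth, "denoised": den, "report": report, "fcm": mat}


def small_ensemble(values, nyquist=22_050.0, start="2020-01-06",
                   freq="30min", site_id="T"):
    """Build a SpectrumEnsemble from a plain [n x B] array."""
    values = np.asarray(values, dtype=float)
    n, B = values.shape
    scheme = make_binning(n_points=4 * B, nyquist=nyquist, B=B)
    ts = pd.date_range(start, periods=n, freq=freq)
    return SpectrumEnsemble(values=values, timestamps=ts, scheme=scheme,
                            site_id=site_id, scale="log10",
                            provenance=["bin", "log"])


@pytest.fixture
def make_ensemble():
    return small_ensemble
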