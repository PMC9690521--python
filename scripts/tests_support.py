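"""Small helpers shared by the acceptance script."""

import numpy as np
import pandas as pd

from scapekit.ensemble import SpectrumEnsemble
from scapekit.spectral import make_binning


def make_plain_ensemble(values, nyquist=22_050.0):
    """Wrap a plain [n x B] array as a log-scale SpectrumEnsemble."""
    values = np.asarray(values, dtype=float)
    n, B = values.shape
    scheme = make_binning(n_points=4 * B, nyquist=nyquist, B=B)
    ts = pd.date_range("2020-01-06", periods=n, freq="30min")
    return SpectrumEnsemble(values=values, timestamps=ts, scheme=scheme,
                            site_id="synthetic", scale="log10",
                            provenance=["bin", "log"])
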