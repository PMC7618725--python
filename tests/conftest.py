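import numpy as np
import pandas as pd
import pytest

from gaspread.spectral import BandPowerBins


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bandpower(values: np.ndarray,
                   band_names=("beta", "gamma", "high_gamma"),
                   t_start=-1.0, bin_width=0.1) -> BandPowerBins:
    """Wrap a trials x regions x bands x bins array as BandPowerBins."""
    n_bins = values.shape[3]
    edges = t_start + bin_width * np.arange(n_bins + 1)
    return BandPowerBins(value=np.asarray(values, dtype=float),
                         bin_edges=edges, band_names=tuple(band_names))


def make_clinical(n_hc: int, n_als: int, seed: int = 0) -> pd.DataFrame:
    """Minimal covariate table with the confound columns the designs need."""
    r = np.random.default_rng(seed)
    n = n_hc + n_als
    sex = r.choice(["F", "M"], n)
    mri = r.integers(0, 2, n)
    # guarantee variation so centered confounds never collapse to zero
    sex[:2] = ["F", "M"]
    mri[:2] = [0, 1]
    return pd.DataFrame({
        "participant_id": [f"hc{i:03d}" for i in range(1, n_hc + 1)]
        + [f"als{i:03d}" for i in range(1, n_als + 1)],
        "group": ["HC"] * n_hc + ["ALS"] * n_als,
        "age": r.normal(61, 13, n).round(1),
        "sex": sex,
        "missing_mri": mri,
    })
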