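import numpy as np
import pandas as pd
import pytest

from ramanmap.dataset import SpectralDataset, Spectrum


@pytest.fixture
def axis_fp():
    """Full fingerprint axis, 1 cm^-1 step."""
    return np.arange(460.0, 1801.0)


@pytest.fixture
def axis_small():
    """Short valid axis (21 points) for toy datasets."""
    return np.linspace(500.0, 1500.0, 21)


def make_metadata(ids, subject="S1", dose=0.0, map_id="M1", step=15.0, n_cols=100):
    """Grid metadata for a list of spectrum ids (row-major positions)."""
    rows = []
    for i, sid in enumerate(ids):
        rows.append(
            {
                "spectrum_id": sid,
                "subject_id": subject,
                "dose_Gy": dose,
                "section_id": "T1",
                "map_id": map_id,
                "x_um": (i % n_cols) * step,
                "y_um": (i // n_cols) * step,
            }
        )
    return pd.DataFrame(rows).set_index("spectrum_id")


def make_dataset(axis, intensities, state="raw", **meta_kwargs):
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    ids = [f"s{i:03d}" for i in range(intensities.shape[0])]
    return SpectralDataset(
        axis=axis,
        intensities=intensities,
        metadata=make_metadata(ids, **meta_kwargs),
        state=state,
    )


def gaussian(axis, center, sigma=4.0, amplitude=1.0):
    return amplitude * np.exp(-0.5 * ((axis - center) / sigma) ** 2)


@pytest.fixture
def spectrum_factory(axis_fp):
    def _make(intensity, state="raw", sid="s0", flags=()):
        return Spectrum(sid, axis_fp, intensity, set(flags), state)

    return _make
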