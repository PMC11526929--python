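import numpy as np
import pytest

from fpbarcodes.reference import ReferenceMatrix
from fpbarcodes.synthetic import CellSimConfig, make_reference_set


@pytest.fixture
def small_refs():
    """Six well-separated spectra over 16 channels."""
    return make_reference_set(6, 16, seed=11)


@pytest.fixture
def small_basis(small_refs):
    """Noise-free truth basis: the six spectra plus a flat autofluorescence column."""
    cols = [s.channel_weights for s in small_refs] + [np.ones(16)]
    labels = [s.fp_id for s in small_refs] + ["autofluorescence"]
    return ReferenceMatrix(basis=np.column_stack(cols), column_labels=labels)


@pytest.fixture
def quiet_config():
    """Noise-free, background-free simulation with fixed expression."""
    return CellSimConfig(
        n_cells=20,
        expression_median=1e4,
        expression_sigma=0.0,
        autofluorescence_level=0.0,
        autofluorescence_sigma=0.0,
        noise_cv=0.0,
        noise_floor=0.0,
        seed=1,
    )
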