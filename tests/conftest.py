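import numpy as np
import pytest

import monoclass as mc
from monoclass.synthetic_cells import CLASSES, CellRecord


def label_records(labels):
    """Image-free records for reviewer-panel simulations."""
    return [
        CellRecord(cell_id=f"c{i:05d}", patient_id="p0", image=None, mask=None,
                   true_label=lab)
        for i, lab in enumerate(labels)
    ]


@pytest.fixture(scope="session")
def separable_records():
    """60 well-separated cells (low jitter), small patches for speed."""
    return mc.generate_dataset(60, (0.4, 0.3, 0.3), n_patients=5, rng_seed=11,
                               jitter=0.02, patch_size=64)


@pytest.fixture(scope="session")
def one_cell():
    return mc.generate_cell(mc.class_preset("monocyte", jitter=0.05, patch_size=96), 3)


@pytest.fixture(scope="session")
def balanced_label_records():
    rng = np.random.default_rng(21)
    labels = rng.choice(CLASSES, size=300).tolist()
    return label_records(labels)
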