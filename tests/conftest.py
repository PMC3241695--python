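import numpy as np
import pytest

from dicistro import composition_nca as nca
from dicistro import synthetic_data as sd


@pytest.fixture(scope="session")
def halv_mimic():
    """Synthetic genome mirroring the studied di-cistronic layout
    (827 / 5451 / 118 / 3030 / 139 nt) with catalogue motifs embedded."""
    return sd.build_dicistronic_genome(sd.halv_mimic_spec(seed=1))


@pytest.fixture(scope="session")
def default_panel():
    """Default host-labeled control panel (117/63/167/5) plus feature matrix."""
    records, labels = sd.make_control_panel(seed=1)
    X = np.vstack(
        [nca.build_features(nca.composition_profile(r)) for r in records]
    )
    y = np.asarray([labels[r.id] for r in records])
    return records, labels, X, y
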