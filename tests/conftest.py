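import numpy as np
import pandas as pd
import pytest

from mirtraffic import nucclass
from mirtraffic.synthgen import NucleiFieldSpec, make_nuclei_field


@pytest.fixture(scope="session")
def default_field_seed7():
    """The generator's default 100-nucleus field, seed 7 (all interphase)."""
    return make_nuclei_field(NucleiFieldSpec(n_cells=100, rng_seed=7))


@pytest.fixture(scope="session")
def four_class_training():
    """Balanced four-class nuclei features (~200/class) with true labels."""
    feats, labels = [], []
    for seed in range(8):
        spec = NucleiFieldSpec(
            n_cells=100, class_mix=(0.25, 0.25, 0.25, 0.25), rng_seed=100 + seed
        )
        field, truth = make_nuclei_field(spec)
        df = nucclass.extract_features(field, truth.label_mask)
        feats.append(df)
        labels.extend(truth.classes[lab - 1] for lab in df["label"])
    return pd.concat(feats, ignore_index=True), np.asarray(labels)
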