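import numpy as np
import pytest

import vitalgan as vg
from vitalgan.schema import CLASS_HIGH, CLASS_LOW, PREDICTOR_NAMES


@pytest.fixture(scope="session")
def real43():
    """A paper-scale simulated cohort: 43 records, both classes present."""
    return vg.generate_cohort(43, seed=7)


@pytest.fixture(scope="session")
def sim_synth_1000():
    """A 1000-record cohort from the same simulator, tagged synthetic — the
    positive-control stand-in for a perfect generator."""
    ds = vg.generate_cohort(1000, seed=11)
    return vg.LabeledDataset(ds.features, ds.labels, "synthetic", ds.pef)


def make_dataset(columns: dict, labels, provenance="real", fill=50.0):
    """Build a LabeledDataset from a few named columns; the rest are constant."""
    n = len(labels)
    feats = np.full((n, len(PREDICTOR_NAMES)), fill)
    for name, vals in columns.items():
        feats[:, PREDICTOR_NAMES.index(name)] = vals
    return vg.LabeledDataset(feats, np.asarray(labels, dtype=object), provenance)


@pytest.fixture()
def toy_separable():
    """One informative feature, perfectly separable: fev1 {1.8,1.9,2.0} low
    vs {2.4,2.5,2.6} high."""
    return make_dataset(
        {"fev1": [1.8, 1.9, 2.0, 2.4, 2.5, 2.6]},
        [CLASS_LOW] * 3 + [CLASS_HIGH] * 3,
    )


@pytest.fixture()
def xor_dataset():
    """Four equal clusters on (fev1, map); class = (fev1>2) XOR (map>90)."""
    fev1, mp, labels = [], [], []
    for f in (1.0, 3.0):
        for m in (80.0, 100.0):
            fev1 += [f] * 10
            mp += [m] * 10
            labels += [CLASS_HIGH if (f > 2) ^ (m > 90) else CLASS_LOW] * 10
    return make_dataset({"fev1": fev1, "map": mp}, labels)
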