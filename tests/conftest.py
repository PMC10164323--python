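from __future__ import annotations

import numpy as np
import pytest

from owsum.chem import OccurrenceMatrix
from owsum.records import LabelMatrix
from owsum.synthetic import toy_fixture


@pytest.fixture(scope="session")
def toy():
    """The 4-molecule, 3-feature, 2-class hand-checkable worked set."""
    return toy_fixture()


def random_instance(
    rng: np.random.Generator,
    max_objects: int = 6,
    max_features: int = 5,
    max_classes: int = 3,
) -> tuple[OccurrenceMatrix, LabelMatrix]:
    """Random small instance with every class non-empty.

    Multilabel objects allowed; all-zero feature rows and all-zero feature
    columns (untrained features) allowed.
    """
    n_cls = int(rng.integers(2, max_classes + 1))
    n_obj = int(rng.integers(n_cls, max_objects + 1))
    n_feat = int(rng.integers(1, max_features + 1))
    occ_vals = rng.integers(0, 2, size=(n_obj, n_feat)).astype(np.uint8)
    while True:
        lab_vals = rng.integers(0, 2, size=(n_obj, n_cls)).astype(np.uint8)
        # every object needs >=1 label, every class >=1 member
        for k in range(n_obj):
            if lab_vals[k].sum() == 0:
                lab_vals[k, int(rng.integers(0, n_cls))] = 1
        if (lab_vals.sum(axis=0) > 0).all():
            break
    ids = tuple(f"o{k}" for k in range(n_obj))
    occ = OccurrenceMatrix(ids, tuple(f"p{j}" for j in range(n_feat)),
                           occ_vals)
    labels = LabelMatrix(ids, tuple(f"c{i}" for i in range(n_cls)), lab_vals)
    return occ, labels
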