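import numpy as np
import pytest

import sigclass as sc


@pytest.fixture(scope="session")
def model3():
    """Small k=3 pore model shared across tests."""
    return sc.generate_pore_model(3, (60.0, 120.0), seed=7)


@pytest.fixture(scope="session")
def bin_cfg(model3):
    return sc.BinningConfig.from_model(model3, 6)


@pytest.fixture(scope="session")
def toy_index(model3, bin_cfg):
    """Two-class toy collection and its index (four shreds per class count)."""
    refA = sc.random_reference(2000, 1)
    refB = sc.random_reference(1500, 2)
    docs = [
        ("refA", "classA", sc.reference_to_binseq(refA, model3, bin_cfg)),
        ("refB", "classB", sc.reference_to_binseq(refB, model3, bin_cfg)),
    ]
    coll = sc.shred_collection(
        docs, shred_size=400, class_polarity={"classA": "positive", "classB": "null"}
    )
    return coll, sc.build_index(coll)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
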