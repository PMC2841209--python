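from datetime import datetime

import numpy as np
import pytest

from mitoprofile.core import ReferenceSequence
from mitoprofile.fixtures import generate_profile, generate_reference
from mitoprofile.store import Store

FROZEN_TIME = datetime(2009, 10, 9, 15, 7)


@pytest.fixture
def tiny_ref() -> ReferenceSequence:
    return ReferenceSequence(name="tiny", residues="ACGTACGT")


@pytest.fixture
def ref_1kb() -> ReferenceSequence:
    return generate_reference(seed=11, length=1000)


@pytest.fixture
def frozen_store() -> Store:
    """In-memory store under a frozen clock for deterministic history."""
    store = Store(":memory:", clock=lambda: FROZEN_TIME)
    yield store
    store.close()


@pytest.fixture
def random_profiles(ref_1kb):
    """Deterministic batch of generated profiles on the 1 kb reference."""
    rng = np.random.default_rng(42)
    return [
        generate_profile(rng, ref_1kb, f"S{i:03d}", int(rng.integers(0, 9)))
        for i in range(30)
    ]
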