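from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rrbsdesign import SequenceRecord, default_catalog

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def random_record_factory():
    """Seeded random genomes with mammalian-ish composition plus some N."""

    def make(seed: int, length: int, n_fraction: float = 0.0) -> SequenceRecord:
        rng = np.random.default_rng(seed)
        probs = [0.295, 0.205, 0.205, 0.295]
        bases = rng.choice(list("ACGT"), size=length, p=probs)
        if n_fraction > 0:
            mask = rng.random(length) < n_fraction
            bases[mask] = "N"
        return SequenceRecord(id=f"rand{seed}", sequence="".join(bases))

    return make
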