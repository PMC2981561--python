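"""Shared fixtures and hypothesis settings for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barcotu.io import BarcodeDataset, BarcodeRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(seqs: dict[str, str], **common) -> BarcodeDataset:
    """Dataset from an id -> sequence mapping (records in dict order)."""
    records = [BarcodeRecord(record_id=rid, sequence=s, **common) for rid, s in seqs.items()]
    n = {len(s) for s in seqs.values()}
    length = n.pop() if len(n) == 1 else None
    return BarcodeDataset(records, alignment_length=length)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
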