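import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers.py importable

from ori_induce import GenomeBinning


@pytest.fixture
def small_binning() -> GenomeBinning:
    """One 100-kb chromosome of ten 10-kb bins, nothing masked."""
    return GenomeBinning([("chr1", 100_000)], 10_000)
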