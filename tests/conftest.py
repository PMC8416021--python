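import numpy as np
import pytest

from dsbscreen.library import GuideRecord, build_index
from dsbscreen.quant import AnchorConfig

from helpers import KNOWN_GUIDES, write_library_tsv


@pytest.fixture()
def reference_index(tmp_path):
    """Nine published per-gene guide spacers used as fixture records."""
    from dsbscreen.library import load_library

    path = write_library_tsv(tmp_path / "reference_library.tsv", KNOWN_GUIDES)
    return load_library(path)


@pytest.fixture()
def anchor19():
    """Anchor configuration for a fixed-length 19-mer spacer library."""
    return AnchorConfig(spacer_length_range=(19, 19))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_index(rng):
    """30 guides over 10 genes, including two duplicated (ambiguous) spacers."""
    from dsbscreen.simulate import random_spacers

    spacers = random_spacers(28, 19, rng)
    records = []
    k = 0
    for gi in range(10):
        for sj in range(3):
            gid = f"gene{gi:02d}_sg{sj}"
            if gi == 9 and sj in (1, 2):  # last two guides reuse earlier spacers
                sp = spacers[sj]
            else:
                sp = spacers[k]
                k += 1
            records.append(GuideRecord(gid, f"gene{gi:02d}", sp))
    return build_index(records)
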