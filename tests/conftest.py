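import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rnasespec import CleavageModel, probe31

PROBE31 = "GCAUCAGAAAUACACCCGUAGGGCUUUGAGA"


@pytest.fixture(scope="session")
def probe():
    """The 31-nt reference specificity probe (5'-OH/3'-OH)."""
    seq = probe31()
    assert str(seq) == PROBE31
    return seq


@pytest.fixture(scope="session")
def mc1_like_model():
    """Uridine-directed model used in recovery experiments: strong ApU/CpU,
    intermediate UpU, trace GpU, weak CpA, all other bonds uncut."""
    return CleavageModel(
        p={("A", "U"): 0.9, ("C", "U"): 0.9, ("U", "U"): 0.5,
           ("G", "U"): 0.0125, ("C", "A"): 0.15},
        name="mc1_like",
    )
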