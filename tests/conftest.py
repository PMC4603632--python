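import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from coevokit.coevo import CopyProfile
from coevokit.seqcore import SubstitutionMatrix


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.load("BLOSUM62")


@pytest.fixture(scope="session")
def toy_matrix():
    """3-letter alphabet, match +2 / mismatch -1 — for oracle comparisons."""
    return SubstitutionMatrix.from_match_mismatch("ABC", 2.0, -1.0)


@pytest.fixture()
def eutherian_panel():
    """The 8-species panel: family A unique in primates/guinea pig/armadillo
    (0 in armadillo), duplicated in mouse, rat and cow; family B single
    everywhere except the same three duplicated species."""
    return [
        CopyProfile("Dasypus_novemcinctus", 0, 1),
        CopyProfile("Homo_sapiens", 1, 1, complete_genome=True),
        CopyProfile("Pan_troglodytes", 1, 1, complete_genome=True),
        CopyProfile("Macaca_mulatta", 1, 1),
        CopyProfile("Cavia_porcellus", 1, 1),
        CopyProfile("Mus_musculus", 2, 2, complete_genome=True),
        CopyProfile("Rattus_norvegicus", 2, 2),
        CopyProfile("Bos_taurus", 2, 2),
    ]
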