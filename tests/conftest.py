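import matplotlib

matplotlib.use("Agg")

from pathlib import Path

import pytest

from acuassoc.preprocessing import PairInstance
from acuassoc.network import CooccurrenceMatrix, build_matrix
from acuassoc.vocab import SynonymTable

DEMO_SYNONYMS = Path(__file__).parent.parent / "src" / "acuassoc" / "data" / "synonyms_demo.csv"


@pytest.fixture(scope="session")
def demo_table() -> SynonymTable:
    return SynonymTable.from_csv(DEMO_SYNONYMS)


def pairs_from_counts(counts: dict[tuple[str, str], int]) -> list[PairInstance]:
    """Expand a {(diagnosis, acupoint): count} dict into pair instances."""
    pairs = []
    i = 0
    for (diagnosis, acupoint), n in counts.items():
        for _ in range(n):
            pairs.append(PairInstance(diagnosis, acupoint, f"r{i}"))
            i += 1
    return pairs


def matrix_from_counts(counts: dict[tuple[str, str], int]) -> CooccurrenceMatrix:
    return build_matrix(pairs_from_counts(counts))
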