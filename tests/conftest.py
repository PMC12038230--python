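import pytest

from panhap.pangenome import FamilyMatrix


@pytest.fixture
def small_matrix() -> FamilyMatrix:
    """3 genomes, hand-built membership for exact assertions."""
    return FamilyMatrix(
        genomes=["A", "B", "C"],
        families=["f1", "f2", "f3", "f4"],
        members={
            "f1": {"A": ["A_g1"], "B": ["B_g1"], "C": ["C_g1"]},
            "f2": {"A": ["A_g2", "A_g3"], "B": ["B_g2"]},
            "f3": {"C": ["C_g2", "C_g3"]},
            "f4": {"A": ["A_g4"], "B": ["B_g3"], "C": ["C_g4"]},
        },
    )
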