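import pytest

from chdbkit import GenotypeCounts


@pytest.fixture
def f2_counts() -> GenotypeCounts:
    """The 205 F2 segregants from the three het x het Oranda crosses."""
    return GenotypeCounts(n11=69, n12=101, n22=35, label="F2")


@pytest.fixture
def strain_tables() -> list[GenotypeCounts]:
    """Genotyped strain subpopulations (102 fish over nine subpopulations)."""
    rows = [
        ("Butterfly-20151124", 10, 0, 0),
        ("Butterfly-20150707", 14, 0, 0),
        ("Heimutan-20151124", 16, 0, 0),
        ("Heimutan-20150707", 12, 0, 0),
        ("Oranda", 12, 9, 0),
        ("Ryukin", 4, 0, 0),
        ("SingleFin-Japan", 11, 0, 0),
        ("SingleFin-China", 5, 0, 0),
        ("SingleFin-Taiwan", 9, 0, 0),
    ]
    return [GenotypeCounts(n11, n12, n22, label) for label, n11, n12, n22 in rows]
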