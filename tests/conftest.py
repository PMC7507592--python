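import pytest

from healtheil.data_model import ProvinceRecord, ResourcePanel, paper_fixture


@pytest.fixture(scope="session")
def totals_panel():
    """National totals 2013-2018 with raw counts."""
    return paper_fixture("totals_2013_2018")


@pytest.fixture(scope="session")
def provinces_panel():
    """31-province printed densities for 2018 (density-flagged)."""
    return paper_fixture("provinces_2018")


@pytest.fixture()
def two_group_panel():
    """Four equal-population provinces in two regions; resource shares
    (0.4, 0.2 | 0.3, 0.1) — the hand-decomposable reference case."""
    rows = [
        ("a", "western", 0.4),
        ("b", "western", 0.2),
        ("c", "middle", 0.3),
        ("d", "middle", 0.1),
    ]
    records = [
        ProvinceRecord(province=p, year=2018, population=1.0, region=r, beds=y * 1000)
        for p, r, y in rows
    ]
    return ResourcePanel(records=records)
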