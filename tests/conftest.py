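import pytest

import cupscan as cs
from cupscan.cup_scan import CupCategory


def mixed_script() -> cs.RearrangementScript:
    """One operation of every kind; exercises all six position categories."""
    return cs.RearrangementScript(
        {"chr1": 3000, "chr2": 2000},
        (
            cs.Delete("chr1", 100, 150),
            cs.Insert("chr1", 400, 60),
            cs.Invert("chr1", 600, 700),
            cs.Translocate("chr1", 900, 1000, "chr2", 500),
            cs.Translocate("chr2", 1500, 1550, "chr2", 1800),  # same-chrom: stable
            cs.Duplicate("chr1", 1200, 1300, "chr2", 1000),
            cs.Duplicate("chr1", 1500, 1600, "chr1", 2000, score_tie=True),
            cs.AsymmetricBackmap("chr1", 2200, 2250),  # dropped -> Reject_2
            cs.AsymmetricBackmap("chr1", 2400, 2450, "chr2", 300),  # -> CHR_Jump_2
            cs.AsymmetricBackmap("chr2", 100, 150, "chr2", 700),  # -> POS_Jump
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def mixed_realization() -> cs.Realization:
    return cs.realize(mixed_script())


@pytest.fixture(scope="session")
def identity_realization() -> cs.Realization:
    return cs.realize(cs.RearrangementScript({"chrA": 1000}))


def assert_scans_equal(a, b):
    for cat in CupCategory:
        assert a.regions[cat] == b.regions[cat], cat
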