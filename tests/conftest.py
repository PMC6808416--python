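import numpy as np
import pytest

from splicehet import JunctionProfile


def make_profile(sample_id, entries):
    """Build a profile from {(chrom, start, end, strand): count}."""
    return JunctionProfile(sample_id, {k: float(v) for k, v in entries.items()})


@pytest.fixture
def shared_donor_pair():
    """Two samples over one shared-donor unit (A,B,C) plus a two-way unit.

    Sample P observes all three alternatives of the first unit; sample Q
    misses junction B, which triggers the pseudo-count path.
    """
    p = make_profile(
        "P",
        {
            ("chr1", 100, 200, "+"): 5,
            ("chr1", 100, 300, "+"): 3,
            ("chr1", 100, 400, "+"): 2,
            ("chr2", 50, 99, "+"): 10,
            ("chr2", 50, 120, "+"): 10,
        },
    )
    q = make_profile(
        "Q",
        {
            ("chr1", 100, 200, "+"): 4,
            ("chr1", 100, 400, "+"): 6,
            ("chr2", 50, 99, "+"): 10,
            ("chr2", 50, 120, "+"): 10,
        },
    )
    return p, q


def jsd_reference(p, q):
    """Independent Jensen-Shannon divergence: per-index loop, base-2 logs.

    Written against the defining equations directly (midpoint distribution,
    two one-sided KL sums accumulated element by element) so it shares no
    code path with the implementation under test.
    """
    total = 0.0
    for pi, qi in zip(p, q):
        mi = (pi + qi) / 2.0
        if pi > 0:
            total += 0.5 * pi * np.log2(pi / mi)
        if qi > 0:
            total += 0.5 * qi * np.log2(qi / mi)
    return total
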