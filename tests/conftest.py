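import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def brute_force_jenks_sdcm(values, k):
    """Exhaustive enumeration over all contiguous partitions of the sorted values.

    Independent oracle for the dynamic-programming solver; feasible for
    n <= 12, k <= 4.
    """
    xs = np.sort(np.asarray(values, dtype=float))
    n = xs.size
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        splits = (0, *cuts, n)
        cost = sum(
            float(((xs[a:b] - xs[a:b].mean()) ** 2).sum())
            for a, b in zip(splits, splits[1:])
        )
        best = min(best, cost)
    return best


def brute_force_clusters(hits, max_gap_bp):
    """Maximal co-located runs by exhaustive pairwise gap checking.

    For every contig, every maximal set of hits in which consecutive
    (position-sorted) members are within the gap limit; independent of the
    sweep implementation.
    """
    out = []
    contigs = sorted({h.contig for h in hits})
    for contig in contigs:
        chunk = sorted(
            (h for h in hits if h.contig == contig), key=lambda h: (h.start, h.end, h.query)
        )
        for size in range(len(chunk), 0, -1):
            for combo in itertools.combinations(range(len(chunk)), size):
                members = [chunk[i] for i in combo]
                # must be consecutive in sorted order and within the gap rule
                if list(combo) != list(range(combo[0], combo[-1] + 1)):
                    continue
                ok = all(
                    max(0, b.start - a.end) <= max_gap_bp
                    for a, b in zip(members, members[1:])
                )
                boundary_ok = True
                if combo[0] > 0:
                    boundary_ok &= max(0, members[0].start - chunk[combo[0] - 1].end) > max_gap_bp
                if combo[-1] < len(chunk) - 1:
                    boundary_ok &= (
                        max(0, chunk[combo[-1] + 1].start - members[-1].end) > max_gap_bp
                    )
                if ok and boundary_ok:
                    out.append(tuple(members))
    # deduplicate (maximality makes runs unique per span)
    return sorted(set(out), key=lambda ms: (ms[0].contig, ms[0].start))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
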