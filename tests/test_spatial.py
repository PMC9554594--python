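"""Nodule spatial statistics: spacings, fractions, histograms and Jenks windowing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_force_jenks_sdcm
from rhizopipe.errors import DegenerateInputError, ValidationError
from rhizopipe.spatial import (
    JenksConfig,
    clustered_fraction,
    consecutive_spacings,
    derive_windows,
    frequency_map,
    jenks_exact,
    jenks_iterative,
    pool_positions,
    randomized_control,
    spacing_histogram,
)
from rhizopipe.synthetic import StrainProfile, gen_root_systems


# -- pooling and spacings ----------------------------------------------------

def test_pool_positions_counts_and_filters():
    profile = StrainProfile(name="x", mean_nodules_per_root=8, pattern="uniform")
    rs = gen_root_systems(profile, n_plants=2, roots_per_plant=2, seed=1)
    pooled = pool_positions(rs)
    assert pooled.size == rs.n_nodules()
    assert np.all(np.diff(pooled) >= 0)
    tap = pool_positions(rs, root_filter="tap")
    basal = pool_positions(rs, root_filter="basal")
    assert tap.size + basal.size == pooled.size
    # tap-only set: basal filter selects nothing
    rs_tap = gen_root_systems(profile, n_plants=1, roots_per_plant=1, seed=2)
    assert pool_positions(rs_tap, root_filter="basal").size == 0


@pytest.mark.parametrize(
    "per_root, expected",
    [
        ([[5.0, 7.5, 20.0]], [2.5, 12.5]),
        ([[13.0]], []),
        ([[0.0, 10.0], [0.0, 10.0]], [10.0, 10.0]),  # never a cross-root gap
        ([[7.5, 5.0, 20.0]], [2.5, 12.5]),           # order-insensitive
    ],
)
def test_consecutive_spacings(per_root, expected):
    assert consecutive_spacings(per_root).tolist() == pytest.approx(expected)


def test_spacings_reject_negative_positions():
    with pytest.raises(ValidationError):
        consecutive_spacings([[-1.0, 2.0]])


@given(st.lists(st.lists(st.floats(0, 300), min_size=0, max_size=10), min_size=1, max_size=6))
def test_per_root_gap_conservation(per_root):
    """Per root, the gaps sum to the positional range (max - min)."""
    gaps = consecutive_spacings(per_root)
    expected = sum(
        max(r) - min(r) for r in per_root if len(r) >= 2
    )
    assert gaps.sum() == pytest.approx(expected, abs=1e-9)


# -- clustered fraction ------------------------------------------------------

def test_clustered_fraction_gap_basis():
    assert clustered_fraction([2.5, 12.5], threshold_mm=3.0, basis="gap") == 0.5
    assert clustered_fraction([5.0, 8.0], threshold_mm=3.0, basis="gap") == 0.0


def test_clustered_fraction_nodule_basis():
    # nodules at 0,2,10: the first two are mutual <3mm neighbours, 10 is not
    frac = clustered_fraction([[0.0, 2.0, 10.0]], threshold_mm=3.0, basis="nodule")
    assert frac == pytest.approx(2 / 3)


def test_clustered_fraction_empty_denominator_is_an_error():
    with pytest.raises(DegenerateInputError):
        clustered_fraction([], basis="gap")
    with pytest.raises(DegenerateInputError):
        clustered_fraction([[]], basis="nodule")


# -- histograms --------------------------------------------------------------

def test_spacing_histogram_binning():
    h = spacing_histogram([0.5, 1.5, 1.9, 3.0], bin_width_mm=1.0)
    assert h.counts.tolist() == [1, 2, 0, 1]
    assert h.total == 4


def test_spacing_histogram_empty():
    h = spacing_histogram([], bin_width_mm=1.0)
    assert h.counts.sum() == 0


def test_frequency_map_half_open_edges():
    h = frequency_map([2.0, 4.0, 7.0], bin_width_mm=5.0)
    assert h.counts.tolist() == [2, 1]
    # a position exactly on the edge belongs to the upper bin
    h2 = frequency_map([5.0], bin_width_mm=5.0)
    assert h2.counts.tolist() == [0, 1]


@given(st.lists(st.floats(0, 100), min_size=0, max_size=60))
def test_histogram_conserves_counts(gaps):
    assert spacing_histogram(gaps, 1.0).total == len(gaps)


# -- Jenks exact -------------------------------------------------------------

def test_jenks_exact_separated_clusters():
    r = jenks_exact([1, 1, 1, 9, 9, 9], k=2)
    assert r.sdcm == 0.0
    assert r.gvf == 1.0
    assert r.breaks == (1.0,)


def test_jenks_exact_worked_example():
    """{1,2,4,8,16}, k=2: optimal split {1,2,4,8}|{16} (verified by brute force)."""
    r = jenks_exact([1, 2, 4, 8, 16], k=2)
    assert r.sdcm == pytest.approx(28.75)
    assert r.sdam == pytest.approx(148.8)
    assert r.gvf == pytest.approx(0.8068, abs=5e-4)
    assert r.breaks == (8.0,)


def test_jenks_single_class_has_zero_gvf():
    r = jenks_exact([3.0, 1.0, 4.0, 1.5], k=1)
    assert r.sdcm == pytest.approx(r.sdam)
    assert r.gvf == 0.0


def test_jenks_rejects_too_many_classes():
    with pytest.raises(ValidationError):
        jenks_exact([1.0, 2.0], k=3)
    with pytest.raises(ValidationError):
        jenks_exact([1.0, 1.0, 1.0], k=2)  # fewer distinct values than classes


@given(
    st.lists(st.floats(-50, 50), min_size=4, max_size=12, unique=True),
    st.integers(2, 4),
)
def test_jenks_exact_matches_enumeration_oracle(values, k):
    if len(set(values)) < k:
        return
    r = jenks_exact(values, k)
    assert r.sdcm == pytest.approx(brute_force_jenks_sdcm(values, k), abs=1e-9)


def test_gvf_nondecreasing_in_k(rng):
    x = rng.uniform(0, 250, size=60)
    gvfs = [jenks_exact(x, k).gvf for k in range(1, 8)]
    assert all(b >= a - 1e-12 for a, b in zip(gvfs, gvfs[1:]))
    assert all(0.0 <= g <= 1.0 for g in gvfs)


def test_assignments_respect_breaks(rng):
    x = rng.normal(size=80)
    r = jenks_exact(x, 5)
    for v, c in zip(x, r.assignments):
        lo = -np.inf if c == 0 else r.breaks[c - 1]
        hi = np.inf if c == r.n_classes - 1 else r.breaks[c]
        assert lo < v <= hi or (c == 0 and v <= hi)


# -- Jenks iterative ---------------------------------------------------------

@pytest.mark.parametrize("values,k", [
    ([1, 1, 1, 9, 9, 9], 2),
    ([1, 2, 4, 8, 16], 2),
    (list(np.random.default_rng(5).uniform(0, 250, 150)), 6),
])
def test_iterative_matches_exact_on_small_inputs(values, k):
    exact = jenks_exact(values, k)
    it = jenks_iterative(values, JenksConfig(n_classes=k, max_iterations=25_000, seed=11))
    assert it.sdcm == pytest.approx(exact.sdcm, rel=1e-9)
    assert it.breaks == exact.breaks


def test_iterative_never_beats_exact_and_is_deterministic(rng):
    x = rng.uniform(0, 250, size=400)
    cfg = JenksConfig(n_classes=10, max_iterations=2_000, seed=3)
    a = jenks_iterative(x, cfg)
    b = jenks_iterative(x, cfg)
    assert a.breaks == b.breaks and a.sdcm == b.sdcm
    assert a.gvf <= jenks_exact(x, 10).gvf + 1e-12


def test_uniform_large_n_gvf_limit():
    """Exact GVF on uniform data approaches 1 - 1/k^2 (0.99 for k=10)."""
    x = randomized_control(5_000, 0.0, 250.0, seed=42)
    r = jenks_exact(x, 10)
    assert r.gvf == pytest.approx(0.99, abs=0.005)


# -- windows and control -----------------------------------------------------

def test_derive_windows_trivial():
    vals = [1.0, 1.0, 9.0, 9.0]
    r = jenks_exact(vals, 2)
    w = derive_windows(r, vals)
    assert [(x.start_mm, x.end_mm, x.n_nodules) for x in w] == [(1.0, 1.0, 2), (9.0, 9.0, 2)]


def test_control_windows_roughly_even():
    vals = randomized_control(500, 0.0, 250.0, seed=9)
    r = jenks_iterative(vals, JenksConfig(seed=9))
    w = derive_windows(r, vals)
    spans = [x.span_mm for x in w]
    assert len(w) == 10
    assert max(spans) / min(spans) <= 2.0


def test_randomized_control_bounds_and_determinism():
    v = randomized_control(500, 0.0, 250.0, seed=17)
    assert v.min() >= 0.0 and v.max() <= 250.0
    se = 250.0 / np.sqrt(12 * 500)
    assert abs(v.mean() - 125.0) <= 3 * se
    assert np.array_equal(v, randomized_control(500, 0.0, 250.0, seed=17))
    with pytest.raises(ValidationError):
        randomized_control(0)
    with pytest.raises(ValidationError):
        randomized_control(10, 5.0, 5.0)


def test_windowed_recovery_from_generator_truth():
    """10-window synthetic nodulation: k=10 Jenks recovers >= 8/10 true centres within 3 mm."""
    profile = StrainProfile(
        name="nifA", mean_nodules_per_root=30, pattern="windowed",
        n_windows=10, first_window_mm=10.0, window_growth=1.1, within_window_sd_mm=1.0,
    )
    rs = gen_root_systems(profile, n_plants=15, roots_per_plant=1, seed=21)
    pooled = pool_positions(rs)
    r = jenks_exact(pooled, 10)
    windows = derive_windows(r, pooled)
    centres = [w.center_mm for w in windows]
    true_centres = [0.5 * (a + b) for a, b in rs.true_windows]
    recovered = sum(min(abs(c - t) for c in centres) <= 3.0 for t in true_centres)
    assert recovered >= 8
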