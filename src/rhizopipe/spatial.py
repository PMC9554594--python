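"""1D spatial statistics of root-nodule positions.

Positions are distances in mm from the root--shoot junction (the proximal
extremity of the root).  The module provides pooling, consecutive-spacing
analysis, clustered fractions, binned histograms, Jenks natural-breaks
classification (an exact dynamic-programming solver and a budgeted iterative
one), nodulation-window derivation from class limits, and the uniform
randomized control population.

Jenks natural breaks partitions sorted values into ``k`` contiguous classes
minimizing the sum of squared deviations from class means (SDCM).  The fit is
summarised by the goodness of variance fit

    GVF = (SDAM - SDCM) / SDAM,

where SDAM is the total squared deviation from the grand mean.  GVF is 1 for
a perfect classification and 0 for a single class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "NoduleObservation",
    "RootSystemSet",
    "JenksConfig",
    "JenksResult",
    "NodulationWindow",
    "SpacingHistogram",
    "pool_positions",
    "consecutive_spacings",
    "clustered_fraction",
    "spacing_histogram",
    "frequency_map",
    "jenks_exact",
    "jenks_iterative",
    "derive_windows",
    "randomized_control",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoduleObservation:
    """A single nodule on a root axis.

    Parameters
    ----------
    plant, root : str
        Identifiers of the plant and the root axis the nodule sits on.
    root_type : {"tap", "basal"}
    position_mm : float
        Distance from the root--shoot junction, >= 0.
    area_mm2, circularity : float, optional
        ROI morphometrics as produced by image measurement.
    diameter_mm : float
        Nodule diameter; 1.0 mm is the field's working mean.
    """

    plant: str
    root: str
    root_type: str = "tap"
    position_mm: float = 0.0
    area_mm2: float | None = None
    circularity: float | None = None
    diameter_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.root_type not in ("tap", "basal"):
            raise ValidationError(f"root_type must be 'tap' or 'basal', got {self.root_type!r}")
        if self.position_mm < 0:
            raise ValidationError("position_mm must be >= 0")
        if self.diameter_mm <= 0:
            raise ValidationError("diameter_mm must be > 0")
        if self.circularity is not None and not (0.0 <= self.circularity <= 1.0):
            raise ValidationError("circularity must lie in [0, 1]")


@dataclass
class Root:
    """One root axis with its length and nodules."""

    name: str
    root_type: str
    length_mm: float
    nodules: list[NoduleObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValidationError("root length must be > 0")

    def positions(self) -> np.ndarray:
        return np.asarray([n.position_mm for n in self.nodules], dtype=float)


@dataclass
class Plant:
    name: str
    roots: list[Root] = field(default_factory=list)


@dataclass
class RootSystemSet:
    """All measured root systems of one inoculation condition (strain)."""

    strain: str
    plants: list[Plant] = field(default_factory=list)
    #: ground-truth window intervals when the set was simulated, else None
    true_windows: list[tuple[float, float]] | None = None

    def iter_roots(self, root_filter: str | None = None) -> Iterable[Root]:
        for plant in self.plants:
            for root in plant.roots:
                if root_filter is None or root.root_type == root_filter:
                    yield root

    def n_nodules(self) -> int:
        return sum(len(r.nodules) for r in self.iter_roots())


@dataclass(frozen=True)
class JenksConfig:
    n_classes: int = 10
    max_iterations: int = 25_000
    seed: int = 0
    mode: Literal["exact", "iterative"] = "exact"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass(frozen=True)
class JenksResult:
    """Breaks, per-value class assignments and the variance decomposition."""

    breaks: tuple[float, ...]       # upper bounds of classes 1..k-1 (class maxima)
    assignments: np.ndarray         # class index (0-based) per *input-order* value
    sdam: float
    sdcm: float

    @property
    def gvf(self) -> float:
        """Goodness of variance fit; 1.0 by convention when SDAM == 0."""
        if self.sdam == 0.0:
            return 1.0
        return (self.sdam - self.sdcm) / self.sdam

    @property
    def n_classes(self) -> int:
        return len(self.breaks) + 1


@dataclass(frozen=True)
class NodulationWindow:
    """A contiguous root interval in which nodules developed."""

    start_mm: float
    end_mm: float
    class_index: int
    n_nodules: int

    def __post_init__(self) -> None:
        if self.start_mm > self.end_mm:
            raise ValidationError("window start must be <= end")

    @property
    def center_mm(self) -> float:
        return 0.5 * (self.start_mm + self.end_mm)

    @property
    def span_mm(self) -> float:
        return self.end_mm - self.start_mm


@dataclass(frozen=True)
class SpacingHistogram:
    """Left-closed right-open bins starting at 0."""

    bin_width_mm: float
    counts: np.ndarray

    @property
    def edges(self) -> np.ndarray:
        return np.arange(len(self.counts) + 1) * self.bin_width_mm

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# Pooling, spacings, fractions, histograms
# ---------------------------------------------------------------------------

def pool_positions(root_set: RootSystemSet, root_filter: str | None = None) -> np.ndarray:
    """Concatenate nodule positions over all (matching) roots, sorted ascending.

    An empty selection yields an empty vector, not an error.
    """
    if root_filter is not None and root_filter not in ("tap", "basal"):
        raise ValidationError(f"root_filter must be 'tap', 'basal' or None, got {root_filter!r}")
    parts = [r.positions() for r in root_set.iter_roots(root_filter)]
    if not parts:
        return np.empty(0, dtype=float)
    return np.sort(np.concatenate(parts))


def consecutive_spacings(positions_per_root: Iterable[Sequence[float]]) -> np.ndarray:
    """Gaps between consecutive nodules along each individual root.

    Each root with m >= 2 nodules contributes m-1 gaps (differences of the
    sorted positions); gaps never span roots.  Per root, the gaps sum to
    max(position) - min(position).
    """
    gaps: list[np.ndarray] = []
    for pos in positions_per_root:
        arr = np.asarray(pos, dtype=float)
        if arr.size and (arr < 0).any():
            raise ValidationError("positions must be >= 0")
        if arr.size >= 2:
            gaps.append(np.diff(np.sort(arr)))
    if not gaps:
        return np.empty(0, dtype=float)
    return np.concatenate(gaps)


def clustered_fraction(
    data: Iterable[float] | Iterable[Sequence[float]],
    threshold_mm: float = 3.0,
    basis: Literal["gap", "nodule"] = "gap",
) -> float:
    """Fraction of nodulation falling into root sections shorter than a threshold.

    basis="gap"
        ``data`` is a flat gap vector; returns (# gaps < threshold) / (# gaps).
    basis="nodule"
        ``data`` is an iterable of per-root position vectors; returns the
        fraction of nodules whose nearest same-root neighbour lies closer than
        the threshold.

    Raises :class:`DegenerateInputError` when the denominator is 0.
    """
    if threshold_mm <= 0:
        raise ValidationError("threshold_mm must be > 0")
    if basis == "gap":
        gaps = np.asarray(list(data), dtype=float)
        if gaps.size == 0:
            raise DegenerateInputError("clustered_fraction undefined: no gaps")
        return float(np.count_nonzero(gaps < threshold_mm) / gaps.size)
    if basis == "nodule":
        close = 0
        total = 0
        for pos in data:  # type: ignore[assignment]
            arr = np.sort(np.asarray(pos, dtype=float))
            total += arr.size
            if arr.size < 2:
                continue
            d = np.diff(arr)
            nearest = np.minimum(np.r_[d, np.inf], np.r_[np.inf, d])
            close += int(np.count_nonzero(nearest < threshold_mm))
        if total == 0:
            raise DegenerateInputError("clustered_fraction undefined: no nodules")
        return close / total
    raise ValidationError(f"basis must be 'gap' or 'nodule', got {basis!r}")


def _bin_counts(values: np.ndarray, bin_width: float) -> np.ndarray:
    if bin_width <= 0:
        raise ValidationError("bin width must be > 0")
    if values.size and (values < 0).any():
        raise ValidationError("values must be >= 0")
    if values.size == 0:
        return np.zeros(1, dtype=int)
    idx = np.floor(values / bin_width).astype(int)
    return np.bincount(idx)


def spacing_histogram(gaps: Sequence[float], bin_width_mm: float = 1.0) -> SpacingHistogram:
    """Bin consecutive-nodule gaps into [0,w), [w,2w), ... left-closed bins."""
    counts = _bin_counts(np.asarray(gaps, dtype=float), bin_width_mm)
    return SpacingHistogram(bin_width_mm=bin_width_mm, counts=counts)


def frequency_map(positions: Sequence[float], bin_width_mm: float = 5.0) -> SpacingHistogram:
    """Bin nodule positions along the root axis (same half-open convention)."""
    counts = _bin_counts(np.asarray(positions, dtype=float), bin_width_mm)
    return SpacingHistogram(bin_width_mm=bin_width_mm, counts=counts)


# ---------------------------------------------------------------------------
# Jenks natural breaks
# ---------------------------------------------------------------------------

def _prepare(values: Sequence[float], k: int) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("values must be a non-empty 1D vector")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if np.unique(x).size < k:
        raise ValidationError(
            f"k={k} exceeds the number of distinct values ({np.unique(x).size})"
        )
    return x

def _sdam(x: np.ndarray) -> float:
    return float(np.sum((x - x.mean()) ** 2))


def _segment_sse(s1: np.ndarray, s2: np.ndarray, i: np.ndarray | int, j: int) -> np.ndarray:
    """Within-segment sum of squares for sorted x[i:j], via prefix sums."""
    n = j - np.asarray(i)
    tot = s1[j] - s1[i]
    return (s2[j] - s2[i]) - tot * tot / n


def _splits_to_result(
    x: np.ndarray, order: np.ndarray, xs: np.ndarray, splits: list[int]
) -> JenksResult:
    """Build a JenksResult from sorted data and split indices (class c = xs[splits[c]:splits[c+1]])."""
    k = len(splits) - 1
    sdcm = 0.0
    breaks: list[float] = []
    assign_sorted = np.empty(xs.size, dtype=int)
    for c in range(k):
        seg = xs[splits[c]: splits[c + 1]]
        sdcm += float(np.sum((seg - seg.mean()) ** 2))
        assign_sorted[splits[c]: splits[c + 1]] = c
        if c < k - 1:
            breaks.append(float(seg[-1]))
    assignments = np.empty(x.size, dtype=int)
    assignments[order] = assign_sorted
    return JenksResult(
        breaks=tuple(breaks), assignments=assignments, sdam=_sdam(xs), sdcm=sdcm
    )


def jenks_exact(values: Sequence[float], k: int) -> JenksResult:
    """Globally optimal k-class natural-breaks classification.

    Dynamic programming over the sorted order (Fisher's optimal partitioning):
    ``D[c][j]`` is the minimal SDCM of the first ``j`` sorted values split into
    ``c`` contiguous classes.  O(k n^2) time with vectorised inner minimisation.
    Ties in optimal cost are broken toward earlier split points.
    """
    x = _prepare(values, k)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    # D[j] = minimal SDCM of the first j sorted values in c classes (j = 0..n)
    D = np.full(n + 1, np.inf)
    D[1:] = np.array([_segment_sse(s1, s2, 0, j) for j in range(1, n + 1)])
    ptr = np.zeros((k + 1, n + 1), dtype=int)
    for c in range(2, k + 1):
        D_new = np.full(n + 1, np.inf)
        for j in range(c, n + 1):
            i = np.arange(c - 1, j)
            cand = D[i] + _segment_sse(s1, s2, i, j)
            best = int(np.argmin(cand))  # first minimum -> smallest split index
            D_new[j] = cand[best]
            ptr[c, j] = i[best]
        D = D_new
    splits = [n]
    j = n
    for c in range(k, 1, -1):
        j = int(ptr[c, j])
        splits.append(j)
    splits.append(0)
    splits.reverse()
    return _splits_to_result(x, order, xs, splits)


def _sdcm_of_splits(s1: np.ndarray, s2: np.ndarray, splits: np.ndarray) -> float:
    i = splits[:-1]
    j = splits[1:]
    return float(np.sum(_segment_sse(s1, s2, i, j)))


def jenks_iterative(values: Sequence[float], cfg: JenksConfig | None = None) -> JenksResult:
    """Budgeted local-search natural-breaks classification.

    Random contiguous initialisations (restart 0 is a deterministic
    equal-count split) followed by steepest-descent boundary moves: each
    inner split index may shift by one position, and only moves that decrease
    SDCM are accepted.  Accepted moves are charged against
    ``cfg.max_iterations``, shared across restarts.  The best partition over
    all restarts is returned; on small inputs this coincides with the exact
    solver.
    """
    if cfg is None:
        cfg = JenksConfig()
    k = cfg.n_classes
    x = _prepare(values, k)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs * xs)])
    rng = np.random.default_rng(cfg.seed)

    # random restarts keep drawing on the shared move budget; the cap only
    # bounds runtime when restarts converge after very few accepted moves
    n_restarts = 250
    budget = cfg.max_iterations
    best_splits: np.ndarray | None = None
    best_cost = np.inf

    for restart in range(n_restarts):
        if restart == 0:
            inner = np.round(np.linspace(0, n, k + 1)).astype(int)[1:-1]
        else:
            inner = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False))
        splits = np.concatenate([[0], inner, [n]])
        cost = _sdcm_of_splits(s1, s2, splits)
        improved = True
        while improved and budget > 0:
            improved = False
            # single-boundary relocation: place one break at its best position
            for m in range(1, k):
                lo, hi = splits[m - 1], splits[m + 1]
                cand = np.arange(lo + 1, hi)  # classes must stay non-empty
                cur = _segment_sse(s1, s2, lo, splits[m]) + _segment_sse(
                    s1, s2, splits[m], hi
                )
                costs = _segment_sse(s1, s2, lo, cand) + _segment_sse(s1, s2, cand, hi)
                best = int(np.argmin(costs))
                if costs[best] < cur - 1e-12:
                    cost += float(costs[best] - cur)
                    splits[m] = int(cand[best])
                    budget -= 1
                    improved = True
                    if budget <= 0:
                        break
            if improved or budget <= 0:
                continue
            # pairwise relocation of adjacent breaks, escaping single-move optima
            for m in range(1, k - 1):
                lo, hi = splits[m - 1], splits[m + 2]
                c = np.arange(lo + 1, hi)
                cur = (
                    _segment_sse(s1, s2, lo, splits[m])
                    + _segment_sse(s1, s2, splits[m], splits[m + 1])
                    + _segment_sse(s1, s2, splits[m + 1], hi)
                )
                left = _segment_sse(s1, s2, lo, c)
                right = _segment_sse(s1, s2, c, hi)
                with np.errstate(invalid="ignore", divide="ignore"):
                    tot = s1[c][None, :] - s1[c][:, None]
                    width = c[None, :] - c[:, None]
                    mid = (s2[c][None, :] - s2[c][:, None]) - tot * tot / width
                total = left[:, None] + mid + right[None, :]
                total[width <= 0] = np.inf
                p_idx, q_idx = np.unravel_index(np.argmin(total), total.shape)
                if total[p_idx, q_idx] < cur - 1e-12:
                    cost += float(total[p_idx, q_idx] - cur)
                    splits[m] = int(c[p_idx])
                    splits[m + 1] = int(c[q_idx])
                    budget -= 1
                    improved = True
                    break
            if improved or budget <= 0:
                continue
            # eject-and-reinsert: pull one break out (merging its classes) and
            # place it at the best position inside any remaining class
            for m in range(1, k):
                merge_penalty = (
                    _segment_sse(s1, s2, splits[m - 1], splits[m + 1])
                    - _segment_sse(s1, s2, splits[m - 1], splits[m])
                    - _segment_sse(s1, s2, splits[m], splits[m + 1])
                )
                rem = np.delete(splits, m)
                best_gain = 0.0
                best_pos = -1
                for a, b in zip(rem[:-1], rem[1:]):
                    if b - a < 2:
                        continue
                    cand = np.arange(a + 1, b)
                    split_costs = _segment_sse(s1, s2, a, cand) + _segment_sse(
                        s1, s2, cand, b
                    )
                    idx = int(np.argmin(split_costs))
                    gain = float(_segment_sse(s1, s2, a, b) - split_costs[idx])
                    if gain > best_gain:
                        best_gain = gain
                        best_pos = int(cand[idx])
                if best_pos >= 0 and best_gain - merge_penalty > 1e-12:
                    cost += float(merge_penalty - best_gain)
                    splits = np.sort(np.concatenate([rem, [best_pos]]))
                    budget -= 1
                    improved = True
                    break
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_splits = splits.copy()
        if budget <= 0:
            break

    assert best_splits is not None
    return _splits_to_result(x, order, xs, list(int(s) for s in best_splits))


def derive_windows(result: JenksResult, values: Sequence[float]) -> list[NodulationWindow]:
    """Root windows [class min, class max] with nodule counts, per Jenks class."""
    x = np.asarray(values, dtype=float)
    if x.size != result.assignments.size:
        raise ValidationError("values must be the vector the JenksResult was computed from")
    windows = []
    for c in range(result.n_classes):
        members = x[result.assignments == c]
        if members.size == 0:
            continue
        windows.append(
            NodulationWindow(
                start_mm=float(members.min()),
                end_mm=float(members.max()),
                class_index=c,
                n_nodules=int(members.size),
            )
        )
    return windows


def randomized_control(
    n: int = 500, lo_mm: float = 0.0, hi_mm: float = 250.0, seed: int = 0
) -> np.ndarray:
    """The negative-control population: n i.i.d. uniform positions on [lo, hi]."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if lo_mm >= hi_mm:
        raise ValidationError("lo_mm must be < hi_mm")
    rng = np.random.default_rng(seed)
    return rng.uniform(lo_mm, hi_mm, size=n)
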