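"""One-way ANOVA, Tukey HSD and compact-letter displays.

The workhorse comparison throughout the pipeline: ordinary (fixed-effects,
equal-variance) one-way ANOVA followed by Tukey's honestly-significant-
difference test at alpha = 0.05, summarised as a compact letter display where
two groups share a letter exactly when their Tukey-adjusted p exceeds alpha.

The F statistic and p value are computed from the classical sum-of-squares
decomposition so that degenerate inputs have defined answers (all groups
identical -> F = 0, p = 1; zero within-group variance with distinct means ->
p = 0).  Tukey-adjusted p values come from :func:`scipy.stats.tukey_hsd`,
which applies the Tukey--Kramer correction for unequal group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GroupedMeasurements",
    "LetterDisplay",
    "one_way_anova",
    "tukey_hsd",
    "compact_letters",
]


@dataclass(frozen=True)
class GroupedMeasurements:
    """Replicate measurements keyed by group label (>= 2 groups, each n >= 2)."""

    groups: tuple[str, ...]
    values: tuple[tuple[float, ...], ...]

    @classmethod
    def from_dict(cls, data: dict[str, "np.typing.ArrayLike"]) -> "GroupedMeasurements":
        groups = tuple(data.keys())
        values = tuple(tuple(float(v) for v in np.asarray(data[g]).ravel()) for g in groups)
        return cls(groups=groups, values=values)

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValidationError("need >= 2 groups")
        if len(self.groups) != len(self.values):
            raise ValidationError("group labels and value vectors must align")
        for g, v in zip(self.groups, self.values):
            if len(v) < 2:
                raise ValidationError(f"group {g!r} needs >= 2 replicates")

    def arrays(self) -> list[np.ndarray]:
        return [np.asarray(v, dtype=float) for v in self.values]

    def means(self) -> dict[str, float]:
        return {g: float(np.mean(v)) for g, v in zip(self.groups, self.values)}


def one_way_anova(data: GroupedMeasurements) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA.

    Returns ``(F, p)``.  SSB = 0 yields F = 0, p = 1; SSW = 0 with SSB > 0
    yields F = inf, p = 0.
    """
    arrays = data.arrays()
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ssb <= 0.0:
        return 0.0, 1.0
    if ssw <= 0.0:
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def tukey_hsd(data: GroupedMeasurements, alpha: float = 0.05) -> np.ndarray:
    """Pairwise Tukey-adjusted p-value matrix (symmetric, diagonal 1).

    Based on the studentized range distribution with the pooled within-group
    variance; unequal replicate counts use the Tukey--Kramer form.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    arrays = data.arrays()
    k = len(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw <= 0.0:
        # no within-group variance: identical means -> p=1, distinct -> p=0
        means = [a.mean() for a in arrays]
        p = np.ones((k, k))
        for i in range(k):
            for j in range(k):
                if i != j and means[i] != means[j]:
                    p[i, j] = 0.0
        return p
    res = stats.tukey_hsd(*arrays)
    p = np.array(res.pvalue, dtype=float)
    np.fill_diagonal(p, 1.0)
    return p


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: groups sharing a letter are not distinguishable."""

    groups: tuple[str, ...]
    letters: tuple[str, ...]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.groups, self.letters))


def compact_letters(
    pmatrix: np.ndarray,
    groups: list[str] | tuple[str, ...],
    alpha: float = 0.05,
    means: dict[str, float] | None = None,
) -> LetterDisplay:
    """Insert-and-absorb compact letter display from a pairwise p matrix.

    Guarantees the display invariant exactly: two groups share at least one
    letter iff their adjusted p > alpha.  When ``means`` is given, groups are
    lettered in order of descending mean so that 'a' marks the largest group.
    """
    p = np.asarray(pmatrix, dtype=float)
    k = len(groups)
    if p.shape != (k, k):
        raise ValidationError("p matrix shape must match the number of groups")
    order = list(range(k))
    if means is not None:
        order.sort(key=lambda i: (-means[groups[i]], groups[i]))
    sig = p <= alpha
    np.fill_diagonal(sig, False)

    # insert step: start from one column holding every group; each significant
    # pair splits any column containing both into two copies, one without each
    # member.  Non-significant pairs stay together in at least one copy, so the
    # display invariant holds by construction.
    cols: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_cols: list[set[int]] = []
            for col in cols:
                if i in col and j in col:
                    new_cols.append(col - {i})
                    new_cols.append(col - {j})
                else:
                    new_cols.append(col)
            # absorb: drop columns contained in another (keep first of equals)
            cols = []
            for idx, c in enumerate(new_cols):
                redundant = any(
                    c < other or (c == other and idx2 < idx)
                    for idx2, other in enumerate(new_cols)
                    if idx2 != idx
                )
                if c and not redundant:
                    cols.append(c)
    for i in range(k):  # fully-separated group keeps its own letter
        if not any(i in c for c in cols):
            cols.append({i})

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    # letter columns in the order their best-ranked member appears
    rank = {g: r for r, g in enumerate(order)}
    cols.sort(key=lambda c: min(rank[i] for i in c))
    letters = ["" for _ in range(k)]
    for letter, col in zip(alphabet, cols):
        for i in col:
            letters[i] += letter
    letters = ["".join(sorted(s)) for s in letters]
    return LetterDisplay(groups=tuple(groups), letters=tuple(letters))
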