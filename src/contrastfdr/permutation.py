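"""Permutation equivalence classes and permutation-based contrast scores.

For unequal replicate numbers (enrichment) and for differential analysis,
per-feature negative controls are built by permuting the pooled m+n
replicate columns across the two conditions. Two permutations are
equivalent when they assign the same set of columns to the
pseudo-experimental group, so an equivalence class is identified with an
m-subset of column indices. For differential analysis with m = n a class
and its complement coincide (the interestingness statistic is the absolute
mean difference), leaving C(2m, m)/2 distinct classes; the canonical
representative is the subset containing column 0.

The identity class (the original condition assignment) always comes first;
h further classes are sampled uniformly without replacement, or all of
them are enumerated when the design is small. Class sampling goes through
a lexicographic integer<->subset bijection (combinatorial unranking) so a
given seed reproduces the same plan on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .scores import MeasurementPair

__all__ = [
    "PermutationPlan",
    "PermutedStatMatrix",
    "count_equivalence_classes",
    "build_plan",
    "permuted_statistics",
    "contrast_from_permutations",
]

#: enumerate every class when the design admits at most this many non-identity
#: classes; otherwise sample DEFAULT_H of them
DEFAULT_H_CAP = 100


@dataclass
class PermutationPlan:
    """Identity class plus h sampled/enumerated non-identity classes."""

    mode: str
    m: int
    n: int
    classes: list  # tuples of column indices assigned to the pseudo-experimental group
    seed: int | None = None
    exhaustive: bool = False

    @property
    def h(self) -> int:
        return len(self.classes) - 1

    def indicator(self) -> np.ndarray:
        """(m+n) x (h+1) 0/1 matrix; column ℓ marks class ℓ's columns."""
        a = np.zeros((self.m + self.n, len(self.classes)))
        for col, cls in enumerate(self.classes):
            a[list(cls), col] = 1.0
        return a


@dataclass
class PermutedStatMatrix:
    """d x (h+1) interestingness statistics; column 0 is the identity class."""

    values: np.ndarray
    mode: str = "enrichment"

    @property
    def h(self) -> int:
        return self.values.shape[1] - 1


def count_equivalence_classes(m: int, n: int, mode: str = "enrichment") -> int:
    """Number of permutation equivalence classes for an (m, n) design.

    Enrichment: C(m+n, m). Differential: the same unless m = n, where a
    split and its mirror are indistinguishable, giving C(2m, m)/2.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    if mode not in ("enrichment", "differential"):
        raise ValueError(f"unknown mode {mode!r}")
    total = comb(m + n, m)
    if mode == "differential" and m == n:
        return total // 2
    return total


def _unrank_subset(rank: int, n_items: int, k: int) -> tuple:
    """Lexicographic unranking of k-subsets of range(n_items)."""
    out = []
    x = 0
    for i in range(k):
        while True:
            c = comb(n_items - x - 1, k - i - 1)
            if rank < c:
                out.append(x)
                x += 1
                break
            rank -= c
            x += 1
    return tuple(out)


def _sample_ranks(total: int, h: int, rng: np.random.Generator) -> np.ndarray:
    """h distinct integers from 1..total-1 (rank 0 is the identity class)."""
    if total - 1 <= 4 * h or total < 10**6:
        return rng.choice(total - 1, size=h, replace=False) + 1
    chosen: set[int] = set()
    while len(chosen) < h:  # rejection sampling for huge spaces
        chosen.update(int(v) for v in rng.integers(1, total, size=h - len(chosen)))
    return np.array(sorted(chosen))


def build_plan(
    m: int,
    n: int,
    mode: str = "enrichment",
    h: int | str = "auto",
    seed: int | None = 1,
) -> PermutationPlan:
    """Build the ordered list of equivalence classes for a design.

    ``h`` may be an integer (1..h_max), ``"max"`` (exhaustive), or ``"auto"``
    (exhaustive when h_max <= 100, else 100 sampled classes). The identity
    class {0,...,m-1} is always first. When exhaustive, the plan is
    seed-independent.
    """
    if mode == "differential" and m + n < 3:
        raise ValueError(
            "differential analysis needs at least 3 replicates in total "
            "(m + n >= 3): a 1vs1 design has a single equivalence class"
        )
    total = count_equivalence_classes(m, n, mode)
    h_max = total - 1
    if h_max < 1:
        raise ValueError("design admits no non-identity equivalence class")
    if h == "auto":
        h = h_max if h_max <= DEFAULT_H_CAP else DEFAULT_H_CAP
    elif h == "max":
        h = h_max
    h = int(h)
    if not 1 <= h <= h_max:
        raise ValueError(f"h must be in 1..{h_max}, got {h}")

    # differential with m == n: canonical representatives contain column 0,
    # i.e. {0} + (m-1)-subsets of columns 1..m+n-1
    fold = mode == "differential" and m == n
    identity = tuple(range(m))

    if h == h_max:
        if fold:
            # representatives are {0} + (m-1)-subsets of columns 1..m+n-1
            classes = [identity] + [
                (0,) + tuple(i + 1 for i in _unrank_subset(r, m + n - 1, m - 1))
                for r in range(1, total)
            ]
        else:
            classes = [identity] + [
                _unrank_subset(r, m + n, m) for r in range(1, total)
            ]
        return PermutationPlan(mode, m, n, classes, seed=None, exhaustive=True)

    rng = np.random.default_rng(seed)
    ranks = _sample_ranks(total, h, rng)
    if fold:
        classes = [identity] + [
            (0,) + tuple(i + 1 for i in _unrank_subset(int(r), m + n - 1, m - 1))
            for r in ranks
        ]
    else:
        classes = [identity] + [_unrank_subset(int(r), m + n, m) for r in ranks]
    return PermutationPlan(mode, m, n, classes, seed=seed, exhaustive=False)


def permuted_statistics(
    data: MeasurementPair, plan: PermutationPlan
) -> PermutedStatMatrix:
    """Interestingness statistic of every feature under every class.

    For class ℓ with pseudo-experimental columns S: the mean over S minus
    the mean over the complement (enrichment), or its absolute value
    (differential).
    """
    if plan.m != data.m or plan.n != data.n:
        raise ValueError(
            f"plan is for a {plan.m}vs{plan.n} design but data is "
            f"{data.m}vs{data.n}"
        )
    w = data.pooled()
    a = plan.indicator()
    m, n = data.m, data.n
    group_sums = w @ a
    t = group_sums * (1.0 / m + 1.0 / n) - w.sum(axis=1, keepdims=True) / n
    if plan.mode == "differential":
        t = np.abs(t)
    return PermutedStatMatrix(values=t, mode=plan.mode)


def contrast_from_permutations(
    stats: PermutedStatMatrix, kind: str = "max"
) -> np.ndarray:
    """Combine sorted class statistics into one contrast score per feature.

    With T(0) >= T(1) >= ... the sorted h+1 statistics and T_id the identity
    statistic (column 0):

    * minus score: T(0) − T(1) when the identity attains the maximum
      (ties count as attaining it, so a tie scores 0), else T(1) − T(0);
    * maximum score: |T(0)| when the identity is the strict unique maximum,
      0 when the two largest tie, else −|T(0)|.
    """
    if stats.h < 1:
        raise ValueError("need at least one non-identity class (h >= 1)")
    v = stats.values
    t_id = v[:, 0]
    perm = v[:, 1:]
    if perm.shape[1] == 1:
        p1 = perm[:, 0]
        p2 = np.full_like(p1, -np.inf)
    else:
        part = np.partition(perm, perm.shape[1] - 2, axis=1)
        p1 = part[:, -1]  # largest permuted statistic
        p2 = part[:, -2]  # second largest
    if kind == "minus":
        # identity attains the max (incl. ties): T(1) is the best permuted value
        id_max = t_id >= p1
        second = np.maximum(t_id, p2)  # when identity is not the max
        return np.where(id_max, t_id - p1, second - p1)
    if kind == "max":
        top = np.maximum(t_id, p1)
        second = np.where(t_id >= p1, p1, np.maximum(t_id, p2))
        out = np.where(t_id > p1, np.abs(top), -np.abs(top))
        out = np.where(top == second, 0.0, out)
        return out
    raise ValueError(f"unknown contrast kind {kind!r}")
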