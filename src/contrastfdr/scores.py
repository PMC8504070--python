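"""Per-feature summary statistics and direct contrast scores.

A feature's evidence of enrichment is summarized by comparing its
measurement vector ``x`` under the experimental condition against ``y``
under the background condition. Three summaries are supported:

* ``minus`` — difference of sample means, ``x̄ − ȳ``;
* ``max`` — ``max(x̄, ȳ) · sign(x̄ − ȳ)``, i.e. the larger mean signed by
  which condition it came from (zero on ties);
* ``tstat`` — the pooled-variance two-sample t statistic.

For an equal-replicate design (m = n) the row-wise summary applied to the
two matrices directly yields one signed contrast score per feature; under
the null (identically distributed measurements across all replicates) each
score is symmetric about zero, which is what the thresholding procedures
exploit in place of p-value calibration.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MeasurementPair",
    "SummaryKind",
    "summarize_minus",
    "summarize_max",
    "summarize_tstat",
    "direct_contrast_scores",
]


class SummaryKind(str, enum.Enum):
    """Closed enumeration of per-feature summary statistics."""

    MINUS = "minus"
    MAX = "max"
    TSTAT = "tstat"


@dataclass
class MeasurementPair:
    """Two feature-by-replicate measurement matrices.

    Parameters
    ----------
    x : (d, m) array
        Measurements under the experimental condition.
    y : (d, n) array
        Measurements under the background condition.
    feature_ids : sequence of d unique labels, optional
        Defaults to ``"f0" ... f{d-1}``.
    """

    x: np.ndarray
    y: np.ndarray
    feature_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x.ndim != 2 or self.y.ndim != 2:
            raise ValueError("measurement matrices must be 2-dimensional")
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"feature counts differ: x has {self.x.shape[0]} rows, "
                f"y has {self.y.shape[0]}"
            )
        if self.x.shape[1] < 1 or self.y.shape[1] < 1:
            raise ValueError("each condition needs at least one replicate")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("measurements must not contain NaN")
        if self.feature_ids is None:
            self.feature_ids = np.array([f"f{i}" for i in range(self.d)])
        else:
            self.feature_ids = np.asarray(self.feature_ids)
            if len(self.feature_ids) != self.d:
                raise ValueError("feature_ids length must equal the feature count")
            if len(set(self.feature_ids.tolist())) != self.d:
                raise ValueError("feature_ids must be unique")

    @property
    def d(self) -> int:
        return self.x.shape[0]

    @property
    def m(self) -> int:
        return self.x.shape[1]

    @property
    def n(self) -> int:
        return self.y.shape[1]

    def validate_nonnegative(self) -> None:
        """Raise if any measurement is negative.

        The enrichment interpretation of the ``max`` summary assumes
        non-negative measurements; shift or transform the data first if it
        contains negatives (all score constructions remain well defined
        numerically either way).
        """
        for name, mat in (("experimental", self.x), ("background", self.y)):
            if (mat < 0).any():
                i, j = np.argwhere(mat < 0)[0]
                raise ValueError(
                    f"negative measurement in {name} matrix at feature "
                    f"{self.feature_ids[i]!r}, replicate column {j}; shift or "
                    "transform the data to be non-negative"
                )

    def pooled(self) -> np.ndarray:
        """The d x (m+n) pooled matrix W = [X | Y]."""
        return np.hstack([self.x, self.y])


def _as_vec(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if v.size == 0:
        raise ValueError(f"{name} must contain at least one replicate")
    return v


def summarize_minus(x, y) -> float:
    """Difference of sample means ``x̄ − ȳ``."""
    x, y = _as_vec(x, "x"), _as_vec(y, "y")
    return float(x.mean() - y.mean())


def summarize_max(x, y) -> float:
    """``max(x̄, ȳ) · sign(x̄ − ȳ)``; zero when the means tie."""
    x, y = _as_vec(x, "x"), _as_vec(y, "y")
    xm, ym = x.mean(), y.mean()
    return float(max(xm, ym) * np.sign(xm - ym))


def summarize_tstat(x, y) -> float:
    """Pooled two-sample t-type statistic ``(x̄−ȳ)/sqrt(SS/(m+n−2))``.

    With zero pooled sum of squares the statistic is ``sign(x̄−ȳ)·inf``
    (with a warning) when the numerator is nonzero — constant replicates
    still rank — and an error when numerator and denominator both vanish.
    """
    x, y = _as_vec(x, "x"), _as_vec(y, "y")
    m, n = x.size, y.size
    if m + n < 3:
        raise ValueError("tstat needs m + n >= 3 replicates")
    num = x.mean() - y.mean()
    ss = float(((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum())
    if ss == 0.0:
        if num == 0.0:
            raise ValueError("degenerate 0/0 t statistic: constant, equal replicates")
        warnings.warn(
            "zero pooled variance; returning signed infinity", RuntimeWarning
        )
        return float(np.sign(num) * np.inf)
    return float(num / np.sqrt(ss / (m + n - 2)))


def direct_contrast_scores(
    data: MeasurementPair, kind: SummaryKind | str = SummaryKind.MINUS
) -> np.ndarray:
    """Row-wise contrast scores for the equal-replicate enrichment design.

    Only defined for m = n; unequal designs must go through the permutation
    construction (:mod:`contrastfdr.permutation`).
    """
    kind = SummaryKind(kind)
    if data.m != data.n:
        raise ValueError(
            "direct contrast scores require equal replicate numbers (m == n); "
            "use the permutation-based construction for unequal designs"
        )
    xm = data.x.mean(axis=1)
    ym = data.y.mean(axis=1)
    if kind is SummaryKind.MINUS:
        return xm - ym
    if kind is SummaryKind.MAX:
        return np.maximum(xm, ym) * np.sign(xm - ym)
    # tstat, vectorized row-wise
    m, n = data.m, data.n
    if m + n < 3:
        raise ValueError("tstat needs m + n >= 3 replicates")
    ss = ((data.x - xm[:, None]) ** 2).sum(axis=1) + (
        (data.y - ym[:, None]) ** 2
    ).sum(axis=1)
    num = xm - ym
    out = np.empty(data.d)
    zero = ss == 0.0
    if (zero & (num == 0.0)).any():
        raise ValueError("degenerate 0/0 t statistic for a constant feature row")
    if zero.any():
        warnings.warn(
            "zero pooled variance for some features; signed infinity scores",
            RuntimeWarning,
        )
    out[zero] = np.sign(num[zero]) * np.inf
    nz = ~zero
    out[nz] = num[nz] / np.sqrt(ss[nz] / (m + n - 2))
    return out
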