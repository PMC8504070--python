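"""Classical p-value-based comparator methods for the benchmark.

Two p-value calculation approaches:

* pooled — a feature's experimental average is referred to the empirical
  distribution of all d features' background averages (the add-one
  convention (1 + count)/(d + 1) avoids zero p-values); valid only when
  the background is homogeneous across features and d is large;
* paired — a per-feature two-sample test: Gaussian (z-test when the noise
  sd is known, pooled-variance t-test otherwise) or Poisson (exact
  conditional binomial test of the two count sums). Deliberate
  mis-implementations are exposed for benchmarking: the "2as1"
  misformulation treats the background mean as a known constant
  (one-sample test), and a "misspecified" comparator is simply the Poisson
  test applied to over-dispersed (negative-binomial) counts.

P-values are thresholded by Benjamini–Hochberg or Storey's q-value
procedure (single fixed lambda).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scores import MeasurementPair

__all__ = [
    "pooled_pvalues",
    "paired_pvalues",
    "bh_discoveries",
    "storey_discoveries",
    "storey_qvalues",
]


def pooled_pvalues(data: MeasurementPair) -> np.ndarray:
    """Right-tail empirical p-values of X-row means vs pooled Y-row means."""
    if data.d < 2:
        raise ValueError("pooled p-values need at least 2 features")
    xbar = data.x.mean(axis=1)
    ybar = np.sort(data.y.mean(axis=1))
    d = data.d
    n_ge = d - np.searchsorted(ybar, xbar, side="left")
    return (1.0 + n_ge) / (d + 1.0)


def _two_sided(cdf_lo: np.ndarray, sf_hi: np.ndarray) -> np.ndarray:
    return np.minimum(1.0, 2.0 * np.minimum(cdf_lo, sf_hi))


def paired_pvalues(
    data: MeasurementPair,
    family: str = "gaussian",
    sided: str = "two",
    formulation: str = "two-sample",
    sigma: float | None = None,
) -> np.ndarray:
    """Per-feature parametric test p-values.

    ``sigma`` supplies a known Gaussian noise sd (z-test); otherwise the
    pooled-variance t-test is used. ``formulation="one-sample-2as1"``
    reproduces the pathological misformulation that conditions on the
    observed background mean as if it were a constant.
    """
    if sided not in ("two", "one"):
        raise ValueError("sided must be 'two' or 'one'")
    m, n = data.m, data.n
    xbar = data.x.mean(axis=1)
    ybar = data.y.mean(axis=1)

    if family == "gaussian":
        if formulation == "two-sample":
            if sigma is not None:
                z = (xbar - ybar) / (sigma * np.sqrt(1.0 / m + 1.0 / n))
                dist = stats.norm()
            else:
                if m < 2 or n < 2:
                    raise ValueError(
                        "two-sample t-test needs >= 2 replicates per condition "
                        "when the noise sd is unknown"
                    )
                ss = ((data.x - xbar[:, None]) ** 2).sum(axis=1) + (
                    (data.y - ybar[:, None]) ** 2
                ).sum(axis=1)
                sp = np.sqrt(ss / (m + n - 2))
                denom = sp * np.sqrt(1.0 / m + 1.0 / n)
                with np.errstate(divide="ignore", invalid="ignore"):
                    z = np.where(denom > 0, (xbar - ybar) / np.where(denom > 0, denom, 1.0),
                                 np.sign(xbar - ybar) * np.inf)
                z = np.where((denom == 0) & (xbar == ybar), 0.0, z)
                dist = stats.t(df=m + n - 2)
        elif formulation == "one-sample-2as1":
            # treats ybar as a known null mean; ignores its sampling error
            if sigma is not None:
                z = (xbar - ybar) / (sigma / np.sqrt(m))
                dist = stats.norm()
            else:
                if m < 2:
                    raise ValueError("one-sample t-test needs m >= 2")
                sx = data.x.std(axis=1, ddof=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    z = np.where(sx > 0, (xbar - ybar) / np.where(sx > 0, sx, 1.0) * np.sqrt(m),
                                 np.sign(xbar - ybar) * np.inf)
                z = np.where((sx == 0) & (xbar == ybar), 0.0, z)
                dist = stats.t(df=m - 1)
        else:
            raise ValueError(f"unknown formulation {formulation!r}")
        if sided == "one":
            return dist.sf(z)
        return _two_sided(dist.cdf(z), dist.sf(z))

    if family == "poisson":
        sx = data.x.sum(axis=1)
        sy = data.y.sum(axis=1)
        if formulation == "two-sample":
            # conditional on the total, X-sum ~ Binomial(total, m/(m+n))
            total = sx + sy
            p0 = m / (m + n)
            upper = stats.binom.sf(sx - 1, total, p0)  # P(B >= sx)
            lower = stats.binom.cdf(sx, total, p0)
            upper = np.where(total > 0, upper, 1.0)
            lower = np.where(total > 0, lower, 1.0)
        elif formulation == "one-sample-2as1":
            # X-sum referred to Poisson with the background mean as known rate
            lam = m * ybar
            upper = np.where(lam > 0, stats.poisson.sf(sx - 1, np.maximum(lam, 1e-300)), np.where(sx > 0, 0.0, 1.0))
            lower = np.where(lam > 0, stats.poisson.cdf(sx, np.maximum(lam, 1e-300)), 1.0)
        else:
            raise ValueError(f"unknown formulation {formulation!r}")
        if sided == "one":
            return np.asarray(upper, dtype=float)
        return _two_sided(np.asarray(lower, float), np.asarray(upper, float))

    raise ValueError(f"unknown family {family!r}")


def _validate_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_discoveries(p, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up: indices of rejected hypotheses."""
    p = _validate_p(p)
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return np.nonzero(reject)[0]


def storey_qvalues(p, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single fixed lambda for the pi0 estimate."""
    p = _validate_p(p)
    if not 0.0 <= lam < 1.0:
        raise ValueError("lambda must lie in [0, 1)")
    d = p.size
    pi0 = min(1.0, (p > lam).sum() / (d * (1.0 - lam)))
    order = np.argsort(p, kind="stable")
    ranked = pi0 * p[order] * d / np.arange(1, d + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]  # enforce monotonicity
    qvals = np.empty(d)
    qvals[order] = np.minimum(ranked, 1.0)
    return qvals


def storey_discoveries(p, q: float, lam: float = 0.5) -> np.ndarray:
    """Indices with Storey q-value <= q."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    return np.nonzero(storey_qvalues(p, lam=lam) <= q)[0]
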