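"""Synthetic two-condition data and the FDR/power benchmark runner.

The generator emulates the standard two-condition measurement model of
high-throughput omics benchmarks: d independent features, each with m
experimental and n background replicates drawn i.i.d. from one of three
families (Gaussian, Poisson, negative binomial). The background is either
*homogeneous* (one background mean for all features) or *heterogeneous*
(per-feature background means drawn from a positive distribution — the
realistic case). A fraction pi1 of features is "interesting":

* enrichment — the experimental mean is the background mean times the
  fold-change ``effect`` (for the mean-zero homogeneous Gaussian case the
  effect acts as an additive shift of ``effect * noise_sd``);
* differential — the fold change is applied upward or downward with equal
  probability.

Uninteresting features have all m+n values drawn from a single
distribution, so the exchangeability assumption behind the contrast-score
procedures holds exactly. Optional per-feature outliers multiply one
random replicate by a large factor; optional block correlation couples
features through a Gaussian copula while preserving marginals.

Default scale parameters (background mean 5 for counts, 0 for Gaussian;
heterogeneous means ~ Gamma(2, 5) for counts, ~ Uniform(0, 10) for
Gaussian; fold change 3; negative-binomial size 2; pi1 = 0.1) are the
package's fixed study conditions, configurable per run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .api import run_analysis
from .baselines import paired_pvalues, pooled_pvalues, storey_qvalues
from .scores import MeasurementPair

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "evaluate_fdp_power",
    "run_benchmark",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated two-condition dataset."""

    d: int = 10000
    design: tuple[int, int] = (3, 3)
    family: str = "gaussian"  # gaussian | poisson | negbin
    background: str = "heterogeneous"  # homogeneous | heterogeneous
    mode: str = "enrichment"  # enrichment | differential
    pi1: float = 0.1
    effect: float = 3.0
    dispersion: float = 2.0  # negative-binomial size parameter
    noise_sd: float = 1.0  # gaussian only
    mu0: float | None = None  # homogeneous background mean (family default if None)
    outlier_rate: float = 0.0
    outlier_factor: float = 10.0
    correlation: float | None = None  # within-block copula correlation
    block_size: int = 50
    seed: int = 1

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not 0.0 <= self.pi1 < 1.0:
            raise ValueError("pi1 must lie in [0, 1)")
        if self.family not in ("gaussian", "poisson", "negbin"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.background not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown background {self.background!r}")
        if self.mode not in ("enrichment", "differential"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.effect <= 0 or self.dispersion <= 0 or self.noise_sd <= 0:
            raise ValueError("effect, dispersion and noise_sd must be positive")
        m, n = self.design
        if m < 1 or n < 1:
            raise ValueError("both conditions need at least one replicate")


@dataclass
class GroundTruth:
    """Which features are interesting, and the true per-condition means."""

    interesting: np.ndarray  # boolean, length d
    mu_x: np.ndarray
    mu_y: np.ndarray

    @property
    def n_interesting(self) -> int:
        return int(self.interesting.sum())


def _background_means(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.background == "homogeneous":
        mu0 = config.mu0
        if mu0 is None:
            mu0 = 0.0 if config.family == "gaussian" else 5.0
        return np.full(config.d, float(mu0))
    if config.family == "gaussian":
        return rng.uniform(0.0, 10.0, size=config.d)
    return rng.gamma(shape=2.0, scale=5.0, size=config.d)


def _draw(config: SimulationConfig, mu: np.ndarray, n_rep: int,
          rng: np.random.Generator) -> np.ndarray:
    """i.i.d. replicates (d x n_rep) with per-feature means mu."""
    mu = np.broadcast_to(mu[:, None], (mu.size, n_rep))
    if config.family == "gaussian":
        return rng.normal(mu, config.noise_sd)
    if config.family == "poisson":
        return rng.poisson(mu).astype(float)
    r = config.dispersion
    return rng.negative_binomial(r, r / (r + mu)).astype(float)


def _draw_correlated(config: SimulationConfig, mu: np.ndarray, n_rep: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian-copula draws: block-correlated, marginals preserved."""
    rho = float(config.correlation)  # type: ignore[arg-type]
    if not 0.0 <= rho < 1.0:
        raise ValueError("correlation must lie in [0, 1)")
    d = mu.size
    z = np.empty((d, n_rep))
    for start in range(0, d, config.block_size):
        stop = min(start + config.block_size, d)
        shared = rng.normal(size=(1, n_rep))
        own = rng.normal(size=(stop - start, n_rep))
        z[start:stop] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
    u = stats.norm.cdf(z)
    mu_b = np.broadcast_to(mu[:, None], z.shape)
    if config.family == "gaussian":
        return stats.norm.ppf(u, loc=mu_b, scale=config.noise_sd)
    if config.family == "poisson":
        return stats.poisson.ppf(u, mu_b).astype(float)
    r = config.dispersion
    return stats.nbinom.ppf(u, r, r / (r + mu_b)).astype(float)


def generate_dataset(config: SimulationConfig) -> tuple[MeasurementPair, GroundTruth]:
    """One synthetic dataset plus its ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    d = config.d
    m, n = config.design

    mu_y = _background_means(config, rng)
    n_int = int(round(config.pi1 * d))
    interesting = np.zeros(d, dtype=bool)
    interesting[rng.choice(d, size=n_int, replace=False)] = True

    mu_x = mu_y.copy()
    additive = config.family == "gaussian" and config.background == "homogeneous" \
        and np.all(mu_y == 0.0)
    if config.mode == "enrichment":
        if additive:
            mu_x[interesting] = mu_y[interesting] + config.effect * config.noise_sd
        else:
            mu_x[interesting] = config.effect * mu_y[interesting]
    else:
        up = rng.random(d) < 0.5
        shift = config.effect * config.noise_sd
        if additive:
            mu_x[interesting & up] += shift
            mu_x[interesting & ~up] -= shift
        else:
            mu_x[interesting & up] *= config.effect
            mu_x[interesting & ~up] /= config.effect

    draw = _draw_correlated if config.correlation is not None else _draw
    x = draw(config, mu_x, m, rng)
    y = draw(config, mu_y, n, rng)

    if config.outlier_rate > 0:
        hit = rng.random(d) < config.outlier_rate
        cols = rng.integers(0, m + n, size=d)
        idx = np.nonzero(hit)[0]
        for j in idx:  # one random replicate of the pooled m+n per hit feature
            c = cols[j]
            if c < m:
                x[j, c] *= config.outlier_factor
            else:
                y[j, c - m] *= config.outlier_factor

    pair = MeasurementPair(x=x, y=y)
    return pair, GroundTruth(interesting=interesting, mu_x=mu_x, mu_y=mu_y)


def evaluate_fdp_power(discoveries, truth: GroundTruth) -> tuple[float, float]:
    """False discovery proportion and power of a discovery index set.

    FDP = |discoveries ∩ uninteresting| / max(|discoveries|, 1);
    power = |discoveries ∩ interesting| / max(|interesting|, 1).
    """
    disc = np.asarray(discoveries, dtype=int)
    d = truth.interesting.size
    if disc.size and (disc.min() < 0 or disc.max() >= d):
        raise IndexError("discovery indices out of range")
    n_disc = disc.size
    tp = int(truth.interesting[disc].sum())
    fdp = (n_disc - tp) / max(n_disc, 1)
    power = tp / max(truth.n_interesting, 1)
    return float(fdp), float(power)


def _method_fdr_curves(method: str, pair: MeasurementPair, config: SimulationConfig,
                       seed: int) -> np.ndarray:
    """Per-feature 'reject at q if value <= q' vector for one method.

    Contrast-score methods use per-feature FDR estimates (which reproduce
    the cutoff's discovery set at every q); p-value methods use BH-adjusted
    p-values or Storey q-values.
    """
    sided = "one" if config.mode == "enrichment" else "two"
    if method == "clipper":
        res = run_analysis(pair, mode=config.mode, q=0.05, seed=seed,
                           require_nonnegative=False)
        return res.fdr_estimates

    if method in ("BH-pool", "qvalue-pool"):
        p = pooled_pvalues(pair)
    else:
        if method.endswith("-2as1"):
            family = "gaussian" if config.family == "gaussian" else "poisson"
            sigma = config.noise_sd if config.family == "gaussian" else None
            p = paired_pvalues(pair, family=family, sided=sided,
                               formulation="one-sample-2as1", sigma=sigma)
        elif method.endswith("-mis"):
            # misspecification: Poisson test on (over-dispersed) counts
            p = paired_pvalues(pair, family="poisson", sided=sided)
        else:  # correctly specified paired test
            if config.family == "gaussian":
                p = paired_pvalues(pair, family="gaussian", sided=sided,
                                   sigma=config.noise_sd)
            elif config.family == "poisson":
                p = paired_pvalues(pair, family="poisson", sided=sided)
            else:
                raise ValueError(
                    "no correctly-specified paired test is provided for the "
                    "negative-binomial family; use the -mis comparator"
                )

    if method.startswith("qvalue"):
        return storey_qvalues(p)
    # BH-adjusted p-values: reject at q iff adjusted <= q
    d = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * d / np.arange(1, d + 1)
    adj = np.minimum(np.minimum.accumulate(adj[::-1])[::-1], 1.0)
    out = np.empty(d)
    out[order] = adj
    return out


def run_benchmark(
    config: SimulationConfig,
    methods: Sequence[str] = ("clipper",),
    q_grid: Sequence[float] = tuple(np.round(np.arange(0.01, 0.11, 0.01), 2)),
    n_reps: int = 200,
) -> pd.DataFrame:
    """Mean FDP/power (with Monte-Carlo SEs) per method x target q.

    Replicate r uses seed ``config.seed + r`` so runs are reproducible and
    trivially parallelizable. A method failure on one replicate is recorded
    as NaN for that cell rather than aborting the benchmark.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    q_grid = [float(q) for q in q_grid]
    fdp = {m: {q: [] for q in q_grid} for m in methods}
    pwr = {m: {q: [] for q in q_grid} for m in methods}
    for rep in range(n_reps):
        cfg = replace(config, seed=config.seed + rep)
        pair, truth = generate_dataset(cfg)
        for method in methods:
            try:
                curve = _method_fdr_curves(method, pair, cfg, seed=cfg.seed)
            except Exception:
                for q in q_grid:
                    fdp[method][q].append(np.nan)
                    pwr[method][q].append(np.nan)
                continue
            for q in q_grid:
                disc = np.nonzero(curve <= q)[0]
                f, p = evaluate_fdp_power(disc, truth)
                fdp[method][q].append(f)
                pwr[method][q].append(p)

    rows = []
    for method in methods:
        for q in q_grid:
            f = np.asarray(fdp[method][q])
            p = np.asarray(pwr[method][q])
            ok = ~np.isnan(f)
            k = int(ok.sum())
            rows.append({
                "method": method,
                "q_target": q,
                "mean_FDP": float(np.nanmean(f)) if k else np.nan,
                "mc_se_FDP": float(np.nanstd(f, ddof=1) / np.sqrt(k)) if k > 1 else np.nan,
                "mean_power": float(np.nanmean(p)) if k else np.nan,
                "mc_se_power": float(np.nanstd(p, ddof=1) / np.sqrt(k)) if k > 1 else np.nan,
                "n_reps": k,
            })
    return pd.DataFrame(rows)
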