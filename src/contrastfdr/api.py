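"""Top-level analysis pipeline: score construction + thresholding.

Default route, resolved from the analysis mode and replicate counts:

* enrichment with m = n  -> direct minus contrast scores + BC cutoff
  (no permutation machinery involved);
* enrichment with m != n -> permutation statistics (mean difference),
  maximum contrast score, GZ cutoff;
* differential (m + n >= 3) -> permutation statistics (absolute mean
  difference), maximum contrast score, GZ cutoff.

Explicit ``score``/``procedure`` overrides are honored where the
combination is defined (e.g. the maximum contrast score with BC for an
equal-replicate enrichment analysis). Between-sample normalization is the
caller's responsibility and should happen before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .permutation import PermutationPlan, build_plan, contrast_from_permutations, permuted_statistics
from .scores import MeasurementPair, direct_contrast_scores
from .thresholding import DiscoveryResult, bc_threshold, gz_threshold

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "rescore_paired_qvalues"]

MODES = ("enrichment", "differential")


@dataclass
class AnalysisConfig:
    """User-facing knobs; ``auto`` fields are resolved against (mode, m, n)."""

    mode: str = "enrichment"
    q: float = 0.05
    score: str = "auto"  # auto | minus | max
    procedure: str = "auto"  # auto | BC | GZ
    h: int | str = "auto"  # int | "auto" | "max"
    seed: int = 1


@dataclass
class AnalysisResult:
    """Resolved configuration, contrast scores and the discovery set."""

    config: AnalysisConfig
    contrast_scores: np.ndarray
    result: DiscoveryResult
    feature_ids: np.ndarray
    plan: PermutationPlan | None = None

    @property
    def cutoff(self) -> float:
        return self.result.cutoff

    @property
    def discoveries(self) -> np.ndarray:
        return self.result.discoveries

    @property
    def discovery_ids(self) -> np.ndarray:
        return self.feature_ids[self.result.discoveries]

    @property
    def fdr_estimates(self) -> np.ndarray:
        return self.result.fdr_estimates


def resolve_config(config: AnalysisConfig, m: int, n: int) -> AnalysisConfig:
    """Deterministic resolution of the ``auto`` fields."""
    if config.mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {config.mode!r}")
    if not 0.0 < config.q < 1.0:
        raise ValueError(f"target FDR q must lie in (0, 1), got {config.q}")
    if config.mode == "differential" and m + n < 3:
        raise ValueError(
            "differential analysis requires at least 3 replicates in total"
        )
    score, procedure = config.score, config.procedure
    if config.mode == "enrichment" and m == n:
        score = "minus" if score == "auto" else score
        procedure = "BC" if procedure == "auto" else procedure
    else:
        score = "max" if score == "auto" else score
        procedure = "GZ" if procedure == "auto" else procedure
        if procedure == "BC":
            raise ValueError(
                "the BC procedure is only available for equal-replicate "
                "enrichment analysis; use GZ here"
            )
    if score not in ("minus", "max"):
        raise ValueError(f"score must be minus or max, got {score!r}")
    if procedure not in ("BC", "GZ"):
        raise ValueError(f"procedure must be BC or GZ, got {procedure!r}")
    return replace(config, score=score, procedure=procedure)


def run_analysis(
    data: MeasurementPair,
    mode: str = "enrichment",
    q: float = 0.05,
    score: str = "auto",
    procedure: str = "auto",
    h: int | str = "auto",
    seed: int = 1,
    require_nonnegative: bool = True,
) -> AnalysisResult:
    """Run the full pipeline on a measurement pair.

    Set ``require_nonnegative=False`` for data on a signed scale (e.g.
    Gaussian measurements or log ratios); every score construction remains
    well defined, only the enrichment reading of the direct ``max`` score
    presumes a non-negative scale.
    """
    config = AnalysisConfig(mode=mode, q=q, score=score, procedure=procedure, h=h, seed=seed)
    if require_nonnegative:
        data.validate_nonnegative()
    resolved = resolve_config(config, data.m, data.n)

    if resolved.procedure == "BC":
        scores_vec = direct_contrast_scores(data, kind=resolved.score)
        res = bc_threshold(scores_vec, resolved.q)
        return AnalysisResult(resolved, scores_vec, res, data.feature_ids, plan=None)

    plan = build_plan(data.m, data.n, mode=resolved.mode, h=resolved.h, seed=resolved.seed)
    stats = permuted_statistics(data, plan)
    scores_vec = contrast_from_permutations(stats, kind=resolved.score)
    res = gz_threshold(scores_vec, resolved.q, h=plan.h)
    resolved = replace(resolved, h=plan.h)
    return AnalysisResult(resolved, scores_vec, res, data.feature_ids, plan=plan)


def rescore_paired_qvalues(target_q, decoy_q, q: float = 0.05, feature_ids=None) -> AnalysisResult:
    """Target–decoy rescoring of per-feature q-values (e.g. search-engine PSMs).

    Each feature carries one target and one decoy q-value in (0, 1]; the
    −log10-transformed values become a 1vs1 enrichment pair analyzed with
    the default route (minus contrast score + BC cutoff). Decoy matches act
    as per-feature negative controls.
    """
    target_q = np.asarray(target_q, dtype=float).ravel()
    decoy_q = np.asarray(decoy_q, dtype=float).ravel()
    if target_q.size != decoy_q.size:
        raise ValueError("target and decoy q-value vectors must have equal length")
    for name, v in (("target", target_q), ("decoy", decoy_q)):
        if (v <= 0).any() or (v > 1).any() or np.isnan(v).any():
            raise ValueError(f"{name} q-values must lie in (0, 1]")
    pair = MeasurementPair(
        x=-np.log10(target_q)[:, None],
        y=-np.log10(decoy_q)[:, None],
        feature_ids=feature_ids,
    )
    return run_analysis(pair, mode="enrichment", q=q)
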