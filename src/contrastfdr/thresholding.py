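"""FDR-controlling cutoffs on contrast scores.

Both procedures scan the candidate set C = {|C_j| : C_j != 0} for the
smallest cutoff t whose estimated false discovery proportion falls below
the target q, and discover {j : C_j >= t}:

* BC (Barber–Candès):   (#{C_j <= −t} + 1) / max(#{C_j >= t}, 1) <= q,
  for scores whose null distribution is symmetric about zero (one negative
  control per feature);
* GZ (Gimenez–Zou):     (1/h + #{C_j <= −t}/h) / max(#{C_j >= t}, 1) <= q,
  for scores built from h sampled permutation classes (h negative controls
  per feature), with the 1/h additive correction replacing BC's +1.

If no candidate qualifies the cutoff is +infinity and the discovery set is
empty. Per-feature FDR estimates (the smallest qualifying ratio at or
below a feature's score, clipped to [0, 1]) are an output convenience: for
every q, thresholding them at q reproduces the corresponding cutoff's
discovery set. They are score-based estimates, not p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscoveryResult",
    "bc_threshold",
    "gz_threshold",
    "feature_fdr_estimates",
]


@dataclass
class DiscoveryResult:
    """Cutoff, discovery index set and per-feature FDR estimates."""

    cutoff: float
    discoveries: np.ndarray  # indices j with C_j >= cutoff
    fdr_estimates: np.ndarray
    q: float
    procedure: str
    h: int | None = None

    @property
    def n_discoveries(self) -> int:
        return int(self.discoveries.size)


def _validate(c: np.ndarray, q: float) -> np.ndarray:
    c = np.asarray(c, dtype=float).ravel()
    if np.isnan(c).any():
        raise ValueError("contrast scores must not contain NaN")
    if not 0.0 < q < 1.0:
        raise ValueError(f"target FDR q must lie in (0, 1), got {q}")
    return c


def _ratios(c: np.ndarray, numerator_offset: float, scale: float):
    """FDP-estimate ratio at every candidate cutoff, candidates ascending.

    ratio(t) = (offset + scale * #{C_j <= -t}) / max(#{C_j >= t}, 1).
    BC: offset=1, scale=1. GZ: offset=1/h, scale=1/h.
    """
    cand = np.unique(np.abs(c[c != 0.0]))
    if cand.size == 0:
        return cand, cand
    sorted_c = np.sort(c)
    d = c.size
    # #{C_j <= -t}: -inf scores count at every t (searchsorted 'right' on -t)
    n_neg = np.searchsorted(sorted_c, -cand, side="right")
    # #{C_j >= t}
    n_pos = d - np.searchsorted(sorted_c, cand, side="left")
    ratios = (numerator_offset + scale * n_neg) / np.maximum(n_pos, 1)
    return cand, ratios


def _threshold(c, q, offset, scale, procedure, h=None) -> DiscoveryResult:
    c = _validate(c, q)
    cand, ratios = _ratios(c, offset, scale)
    ok = np.nonzero(ratios <= q)[0]
    if ok.size == 0:
        cutoff = np.inf
        discoveries = np.array([], dtype=int)
    else:
        cutoff = float(cand[ok[0]])
        discoveries = np.nonzero(c >= cutoff)[0]
    est = _estimates_from_ratios(c, cand, ratios)
    return DiscoveryResult(
        cutoff=cutoff,
        discoveries=discoveries,
        fdr_estimates=est,
        q=q,
        procedure=procedure,
        h=h,
    )


def _estimates_from_ratios(c, cand, ratios) -> np.ndarray:
    est = np.ones(c.size)
    if cand.size == 0:
        return est
    running_min = np.minimum.accumulate(ratios)
    pos = c > 0
    idx = np.searchsorted(cand, c[pos], side="right") - 1
    est[pos] = np.clip(running_min[idx], 0.0, 1.0)
    return est


def bc_threshold(c, q: float) -> DiscoveryResult:
    """Barber–Candès cutoff: minimal t with (#{C<=-t}+1)/max(#{C>=t},1) <= q."""
    return _threshold(c, q, offset=1.0, scale=1.0, procedure="BC")


def gz_threshold(c, q: float, h: int) -> DiscoveryResult:
    """Gimenez–Zou cutoff: minimal t with (1/h)(1+#{C<=-t})/max(#{C>=t},1) <= q."""
    h = int(h)
    if h < 1:
        raise ValueError("h must be >= 1")
    return _threshold(c, q, offset=1.0 / h, scale=1.0 / h, procedure="GZ", h=h)


def feature_fdr_estimates(c, procedure: str = "BC", h: int | None = None) -> np.ndarray:
    """Per-feature FDR estimate: min ratio over candidate cutoffs t <= C_j.

    1 for non-positive scores. Thresholding the estimates at any q yields
    exactly the corresponding procedure's discovery set at that q.
    """
    c = np.asarray(c, dtype=float).ravel()
    if np.isnan(c).any():
        raise ValueError("contrast scores must not contain NaN")
    if procedure == "BC":
        offset = scale = 1.0
    elif procedure == "GZ":
        if h is None or int(h) < 1:
            raise ValueError("GZ estimates need h >= 1")
        offset = scale = 1.0 / int(h)
    else:
        raise ValueError(f"unknown procedure {procedure!r}")
    cand, ratios = _ratios(c, offset, scale)
    return _estimates_from_ratios(c, cand, ratios)
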