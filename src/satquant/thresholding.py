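"""Histogram auto-thresholding: mean, Rényi entropy, and Intermodes.

All three methods are pure functions of the 256-bin histogram.  They
return the *last background level* t; binarization takes pixels with
value strictly greater than t as foreground (white objects on black
background, the usual convention for bright fluorescence signal).

Rényi entropy
-------------
For a candidate threshold t, the below-t and above-t intensity
distributions have order-α Rényi entropies

    H_A^α(t) = 1/(1-α) · ln Σ_{i<=t} (P_i / P_A(t))^α
    H_B^α(t) = 1/(1-α) · ln Σ_{i>t}  (P_i / P_B(t))^α

with P_A(t) = Σ_{i<=t} P_i and P_B = 1 - P_A; α = 1 is the Shannon
limit.  Each α in {1/2, 1, 2} contributes its maximizing threshold, and
the three candidates are fused by the weighted rule of the canonical
three-alpha method (Sahoo et al. 1997), matching the widely used
Auto-Threshold "RenyiEntropy" reference implementation.

Intermodes
----------
The histogram is iteratively smoothed with a 3-point running mean until
exactly two local maxima m1 < m2 remain; t = floor((m1 + m2) / 2)
(Prewitt & Mendelsohn).  Histograms that never become bimodal within the
iteration cap raise :class:`NotBimodalError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateHistogramError, NotBimodalError
from .imaging import GRAY_LEVELS, IntensityHistogram, as_gray8

__all__ = [
    "ThresholdResult",
    "threshold_mean",
    "threshold_renyi_entropy",
    "threshold_intermodes",
    "apply_threshold",
]

RENYI_ALPHAS = (0.5, 1.0, 2.0)
INTERMODES_MAX_ITERATIONS = 10_000


@dataclass(frozen=True)
class ThresholdResult:
    """A chosen gray-level threshold with method provenance.

    ``t`` is the last background level: foreground = pixels with value > t.
    ``diagnostics`` carries method-specific intermediates (per-alpha
    candidate thresholds for Rényi, smoothing iteration count for
    Intermodes) so any variant of the decision is reproducible.
    """

    t: int
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.t <= GRAY_LEVELS - 1:
            raise ValueError(f"threshold must lie in [0, 255], got {self.t}")


def _check_nonempty(hist: IntensityHistogram) -> None:
    if hist.total == 0:
        raise DegenerateHistogramError("histogram is empty (total == 0)")


def threshold_mean(hist: IntensityHistogram) -> ThresholdResult:
    """Mean-brightness threshold: t = floor(Σ k·counts[k] / total)."""
    _check_nonempty(hist)
    levels = np.arange(GRAY_LEVELS, dtype=np.float64)
    mean = float(levels @ hist.counts) / hist.total
    return ThresholdResult(t=int(np.floor(mean)), method="mean", diagnostics={"mean": mean})


def _renyi_candidate(p: np.ndarray, alpha: float) -> int:
    """Threshold maximizing H_A^alpha(t) + H_B^alpha(t); smallest argmax wins.

    Candidates with an empty below- or above-class are skipped.
    """
    p1 = np.cumsum(p)
    p2 = 1.0 - p1
    # Validity must be decided on class mass, not float residue: cumsum
    # rounding can leave p2 ~ 1e-16 where the above-t class is empty.
    eps = 1e-12
    valid = (p1 > eps) & (p2 > eps)
    obj = np.full(GRAY_LEVELS, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        if alpha == 1.0:
            # Shannon limit: H_A = ln P_A - S(t)/P_A with S(t) = Σ p_i ln p_i
            plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
            s = np.cumsum(plogp)
            s_total = s[-1]
            ha = np.log(p1) - s / p1
            hb = np.log(p2) - (s_total - s) / p2
        else:
            pa = np.cumsum(p**alpha)
            tail = np.maximum(pa[-1] - pa, 0.0)
            ha = (1.0 / (1.0 - alpha)) * (np.log(pa) - alpha * np.log(p1))
            hb = (1.0 / (1.0 - alpha)) * (np.log(tail) - alpha * np.log(p2))
        total = np.nan_to_num(ha + hb, nan=-np.inf, posinf=-np.inf, neginf=-np.inf)
    obj[valid] = total[valid]
    return int(np.argmax(obj))  # argmax returns the smallest maximizing index


def threshold_renyi_entropy(hist: IntensityHistogram) -> ThresholdResult:
    """Three-alpha Rényi entropy threshold with the Sahoo combination rule."""
    _check_nonempty(hist)
    if int((hist.counts > 0).sum()) < 2:
        raise DegenerateHistogramError(
            "Rényi entropy threshold needs at least two occupied gray levels"
        )
    p = hist.probabilities
    t_by_alpha = {alpha: _renyi_candidate(p, alpha) for alpha in RENYI_ALPHAS}

    # Sort the three candidates ascending, then weight them by how far
    # apart they fall (the canonical three-alpha fusion rule).
    t1, t2, t3 = sorted((t_by_alpha[0.5], t_by_alpha[1.0], t_by_alpha[2.0]))
    if abs(t1 - t2) <= 5:
        if abs(t2 - t3) <= 5:
            beta = (1, 2, 1)
        else:
            beta = (0, 1, 3)
    else:
        if abs(t2 - t3) <= 5:
            beta = (3, 1, 0)
        else:
            beta = (1, 2, 1)
    p1 = np.cumsum(p)
    p2 = 1.0 - p1
    omega = p1[t3] - p1[t1]
    t_opt = int(
        t1 * (p1[t1] + 0.25 * omega * beta[0])
        + 0.25 * t2 * omega * beta[1]
        + t3 * (p2[t3] + 0.25 * omega * beta[2])
    )
    return ThresholdResult(
        t=t_opt,
        method="renyi_entropy",
        diagnostics={
            "t_alpha": {str(a): t_by_alpha[a] for a in RENYI_ALPHAS},
            "beta": beta,
            "omega": float(omega),
        },
    )


def _smooth3(h: np.ndarray) -> np.ndarray:
    """One pass of the 3-point running mean with edge replication."""
    padded = np.concatenate(([h[0]], h, [h[-1]]))
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _local_maxima(h: np.ndarray) -> np.ndarray:
    """Mode locations: bins strictly greater than every existing neighbor.

    End bins count as modes too (a background lobe that drifts onto bin 0
    under repeated smoothing must keep registering as a mode, or heavily
    skewed fluorescence histograms mislead the bimodality test).
    """
    interior = np.flatnonzero((h[1:-1] > h[:-2]) & (h[1:-1] > h[2:])) + 1
    ends = [k for k in (0, len(h) - 1) if h[k] > h[k - 1 if k else 1]]
    return np.sort(np.concatenate([interior, np.array(ends, dtype=np.int64)]))


def threshold_intermodes(hist: IntensityHistogram) -> ThresholdResult:
    """Intermodes threshold: smooth until bimodal, then split the modes."""
    _check_nonempty(hist)
    h = hist.counts.astype(np.float64)
    for iteration in range(INTERMODES_MAX_ITERATIONS + 1):
        maxima = _local_maxima(h)
        if len(maxima) == 2:
            m1, m2 = int(maxima[0]), int(maxima[1])
            return ThresholdResult(
                t=(m1 + m2) // 2,
                method="intermodes",
                diagnostics={"modes": (m1, m2), "iterations": iteration},
            )
        h = _smooth3(h)
    raise NotBimodalError(
        f"histogram did not become bimodal within {INTERMODES_MAX_ITERATIONS} "
        "smoothing iterations (extremely skewed or single-mode data)"
    )


def apply_threshold(image: np.ndarray, result: ThresholdResult | int) -> np.ndarray:
    """Binarize: foreground (True) exactly where pixel value > t."""
    arr = as_gray8(image)
    t = result.t if isinstance(result, ThresholdResult) else int(result)
    return arr > t
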