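"""Model selection across fitted architectures.

Competing architectures are compared on their best refined SSE via the
Gaussian-residual Bayesian Information Criterion,

    BIC = n ln(SSE/n) + k ln(n),

with ``n`` the number of fitted data points across both conditions and
``k`` the architecture's active parameter count.  Bayes weights,
``w_i = exp(-dBIC_i/2) / sum_j exp(-dBIC_j/2)``, give a normalized score
over the compared models; the highest weight marks the preferred model.
Top-k SSE distributions can additionally be compared pairwise with a
paired t test or the two-tailed Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .models import ConfigurationError, ModelArchitecture

__all__ = [
    "ModelScore",
    "compute_bic",
    "bayes_weights",
    "compare_sse_distributions",
    "score_models",
]


@dataclass(frozen=True)
class ModelScore:
    arch: ModelArchitecture
    sse_top: tuple[float, ...]
    n_points: int
    n_params: int
    bic: float
    bayes_weight: float

    @property
    def best_sse(self) -> float:
        return min(self.sse_top)


def compute_bic(sse: float, n_points: int, n_params: int) -> float:
    """Gaussian-error BIC from an SSE at the fitted optimum.

    ``sse = 0`` returns ``-inf`` with a warning (a perfect fit dominates
    any comparison).
    """
    if n_params < 1 or n_points <= n_params:
        raise ConfigurationError(
            "need n_points > n_params >= 1 "
            f"(got n_points={n_points}, n_params={n_params})")
    if sse < 0:
        raise ConfigurationError("sse must be >= 0")
    if sse == 0:
        warnings.warn("SSE of 0: BIC is -inf", RuntimeWarning, stacklevel=2)
        return -math.inf
    return n_points * math.log(sse / n_points) + n_params * math.log(n_points)


def bayes_weights(bics: Sequence[float]) -> np.ndarray:
    """Normalized exp(-dBIC/2) weights over a set of compared models.

    A ``-inf`` BIC (perfect fit) takes weight 1; any other non-finite
    entry is an error.
    """
    b = np.asarray(bics, dtype=float)
    if b.size < 2:
        raise ConfigurationError("need at least 2 BIC values")
    if np.any(np.isnan(b)) or np.any(b == math.inf):
        raise ConfigurationError("BIC values must be finite (or -inf sentinel)")
    neg_inf = b == -math.inf
    if np.any(neg_inf):
        w = neg_inf.astype(float)
        return w / w.sum()
    d = b - b.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def compare_sse_distributions(
    scoresA: Sequence[float],
    scoresB: Sequence[float],
    method: str = "wilcoxon",
) -> float:
    """Two-tailed p-value for paired SSE score comparisons.

    ``method`` is ``"wilcoxon"`` (signed-rank, default) or ``"paired_t"``.
    All-zero differences are degenerate and return p = 1 with a warning.
    """
    a = np.asarray(scoresA, dtype=float)
    b = np.asarray(scoresB, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ConfigurationError("scores must be equal-length 1-D, n >= 2")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p = 1",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    if method == "paired_t":
        return float(stats.ttest_rel(a, b).pvalue)
    if method == "wilcoxon":
        return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    raise ConfigurationError(f"unknown method {method!r}")


def score_models(
    sse_by_arch: dict[ModelArchitecture | str, Sequence[float]],
    n_points: int,
) -> list[ModelScore]:
    """Score competing architectures from their top-k SSE values.

    BIC uses each architecture's single best (lowest) refined SSE — the
    proxy for its maximized likelihood — and its active parameter count.
    """
    archs = [ModelArchitecture.coerce(a) for a in sse_by_arch]
    tops = [tuple(float(s) for s in v) for v in sse_by_arch.values()]
    bics = [compute_bic(min(t), n_points, a.n_params)
            for a, t in zip(archs, tops)]
    weights = bayes_weights(bics)
    return [
        ModelScore(arch=a, sse_top=t, n_points=n_points,
                   n_params=a.n_params, bic=bic, bayes_weight=float(w))
        for a, t, bic, w in zip(archs, tops, bics, weights)
    ]
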