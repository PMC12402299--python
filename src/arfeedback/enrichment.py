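"""Rank-overlap and overrepresentation statistics.

Two ranked gene lists (e.g. genes ordered by a Wald statistic in two
differential-expression comparisons) are compared by the step function
O(k) = |top-k(A) ∩ top-k(B)|, against an empirical null obtained by
permuting one list's ranks over the shared gene universe.  Module
overrepresentation in a study set uses fold enrichment
``overlap / expected`` with ``expected = module_size / background_size *
study_size``, a one-tailed hypergeometric test, and Benjamini–Hochberg
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ConfigurationError

__all__ = [
    "OverlapCurve",
    "EnrichmentResult",
    "rank_overlap_curve",
    "subsampled_null",
    "overlap_curve_with_null",
    "ora_fold_enrichment",
    "hypergeom_test",
    "bh_adjust",
    "enrich_modules",
    "read_ranked_list",
    "read_gmt",
]

#: adjusted-p cutoff used to flag significant modules
SIGNIFICANCE_CUTOFF = 0.001


@dataclass(frozen=True)
class OverlapCurve:
    k: np.ndarray
    observed: np.ndarray
    null_mean: np.ndarray
    null_lo: np.ndarray
    null_hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k, "observed": self.observed,
            "null_mean": self.null_mean,
            "null_lo": self.null_lo, "null_hi": self.null_hi,
        })


@dataclass(frozen=True)
class EnrichmentResult:
    module: str
    module_size: int
    overlap: int
    expected: float
    fold_enrichment: float
    p_value: float
    p_adj: float

    @property
    def significant(self) -> bool:
        return self.p_adj < SIGNIFICANCE_CUTOFF


def _check_ranked(seq: Sequence[str], name: str) -> list[str]:
    items = list(seq)
    if not items:
        raise ConfigurationError(f"{name} is empty")
    if len(set(items)) != len(items):
        raise ConfigurationError(f"{name} contains duplicate identifiers")
    return items


def rank_overlap_curve(
    listA: Sequence[str],
    listB: Sequence[str],
    kmax: int,
    direction: str = "top",
) -> np.ndarray:
    """O(k) = size of the intersection of the first k entries of the two
    ranked lists, for k = 1..kmax.

    ``direction="bottom"`` reverses both lists first, so the curve walks
    in from the other tail of the ranking.
    """
    a = _check_ranked(listA, "listA")
    b = _check_ranked(listB, "listB")
    if direction not in ("top", "bottom"):
        raise ConfigurationError("direction must be 'top' or 'bottom'")
    if direction == "bottom":
        a = a[::-1]
        b = b[::-1]
    if not 1 <= kmax <= min(len(a), len(b)):
        raise ConfigurationError("kmax must be in [1, min(|A|, |B|)]")

    pos_b = {g: i for i, g in enumerate(b)}
    # O(k) counts genes whose rank is < k in both lists; a gene at rank i
    # in A and j in B first enters the curve at k = max(i, j) + 1
    entry = np.full(kmax, 0, dtype=np.int64)
    for i, g in enumerate(a[:kmax]):
        j = pos_b.get(g)
        if j is not None and j < kmax:
            entry[max(i, j)] += 1
    return np.cumsum(entry)


def subsampled_null(
    N: int,
    kmax: int,
    n_subsamples: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical null for the overlap curve over an N-gene universe.

    Each subsample permutes one list's ranks uniformly at random and
    recomputes O(k); returns (mean, 2.5th, 97.5th percentile) per k.  The
    null mean approaches the hypergeometric expectation k^2/N.
    """
    if not 1 <= kmax <= N:
        raise ConfigurationError("kmax must be in [1, N]")
    if n_subsamples < 100:
        raise ConfigurationError("n_subsamples must be >= 100")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_subsamples, kmax), dtype=np.int64)
    for s in range(n_subsamples):
        perm = rng.permutation(N)
        # identity list vs permuted list: item perm[i] sits at rank i in B
        # and rank perm[i] in A, entering the curve at max(i, perm[i]) + 1
        m = np.maximum(np.arange(N), perm)
        counts = np.bincount(m[m < kmax], minlength=kmax)
        curves[s] = np.cumsum(counts)
    return (curves.mean(axis=0),
            np.percentile(curves, 2.5, axis=0),
            np.percentile(curves, 97.5, axis=0))


def overlap_curve_with_null(
    listA: Sequence[str],
    listB: Sequence[str],
    kmax: int,
    direction: str = "top",
    N: int | None = None,
    n_subsamples: int = 1000,
    seed: int = 0,
) -> OverlapCurve:
    """Observed overlap curve together with its subsampled null band."""
    observed = rank_overlap_curve(listA, listB, kmax, direction)
    if N is None:
        N = min(len(listA), len(listB))
    mean, lo, hi = subsampled_null(N, kmax, n_subsamples, seed)
    return OverlapCurve(k=np.arange(1, kmax + 1), observed=observed,
                        null_mean=mean, null_lo=lo, null_hi=hi)


def _check_counts(overlap, module_size, background_size, study_size) -> None:
    if module_size > background_size or study_size > background_size:
        raise ConfigurationError(
            "module and study sets must fit in the background")
    if not 0 <= overlap <= min(module_size, study_size):
        raise ConfigurationError(
            "overlap must be in [0, min(module_size, study_size)]")


def ora_fold_enrichment(
    overlap: int,
    module_size: int,
    background_size: int,
    study_size: int,
) -> tuple[float, float]:
    """Expected overlap and fold enrichment.

    ``expected = module_size / background_size * study_size``;
    ``fold = overlap / expected``.
    """
    _check_counts(overlap, module_size, background_size, study_size)
    expected = module_size / background_size * study_size
    if expected == 0:
        raise ConfigurationError("expected overlap is 0; fold undefined")
    return expected, overlap / expected


def hypergeom_test(
    overlap: int,
    module_size: int,
    background_size: int,
    study_size: int,
) -> float:
    """One-tailed enrichment p-value, P(X >= overlap) for X hypergeometric
    with ``module_size`` marked genes among ``background_size`` and a draw
    of ``study_size``."""
    _check_counts(overlap, module_size, background_size, study_size)
    return float(stats.hypergeom.sf(overlap - 1, background_size,
                                    module_size, study_size))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() <= 0 or p.max() > 1:
        raise ConfigurationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_modules(
    modules: Mapping[str, Sequence[str]],
    study: Sequence[str],
    background_size: int,
) -> list[EnrichmentResult]:
    """Overrepresentation of each module gene set in a study set.

    Returns one result per module with fold enrichment, hypergeometric p,
    and BH-adjusted p across all tested modules.
    """
    study_set = set(study)
    if len(study_set) != len(list(study)):
        raise ConfigurationError("study set contains duplicates")
    rows = []
    for name, members in modules.items():
        mset = set(members)
        overlap = len(mset & study_set)
        expected, fold = ora_fold_enrichment(
            overlap, len(mset), background_size, len(study_set))
        p = hypergeom_test(overlap, len(mset), background_size, len(study_set))
        rows.append((name, len(mset), overlap, expected, fold, p))
    p_adj = bh_adjust([r[5] for r in rows])
    return [
        EnrichmentResult(module=n, module_size=ms, overlap=ov, expected=ex,
                         fold_enrichment=f, p_value=p, p_adj=float(q))
        for (n, ms, ov, ex, f, p), q in zip(rows, p_adj)
    ]


def read_ranked_list(path) -> list[str]:
    """Read a 2-column TSV (gene_id, statistic) ranked by the statistic,
    descending; ties keep input order."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene_id", "statistic"])
    df = df.sort_values("statistic", ascending=False, kind="stable")
    genes = df["gene_id"].astype(str).tolist()
    return _check_ranked(genes, path if isinstance(path, str) else "ranked list")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    from gseapy.parser import read_gmt as _read_gmt  # deferred: heavy import

    sets = {name: list(members)
            for name, members in _read_gmt(str(path)).items()}
    if not sets:
        raise ConfigurationError(f"no gene sets parsed from {path}")
    return sets
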