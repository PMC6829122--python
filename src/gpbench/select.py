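"""Marker feature selection and the random-overlap null.

Markers are ranked on training lines only, by one of three scorers: Random
Forest impurity importances, Elastic Net absolute coefficients (with the
L1:L2 ratio searched downward from 0.10 in steps of 0.02 until at least the
target number of markers survives), or BayesA absolute posterior-mean
effects.  The top k markers (k in a configurable grid, canonically
10...8000) feed downstream models.

:func:`overlap_null_percentile` quantifies how much overlap between
independently selected marker sets is expected by chance: draw several
uniform k-subsets of the p markers, record the size of their common
intersection, repeat, and report a percentile of the null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet

from .datatypes import GenotypeMatrix
from .kernels_trees import fit_tree_ensemble
from .linear import fit_bayesian_regression

__all__ = [
    "MarkerRanking",
    "OverlapNullResult",
    "DEFAULT_K_GRID",
    "rank_markers",
    "elastic_net_ratio_search",
    "select_top_k",
    "overlap_null_percentile",
]

DEFAULT_K_GRID = (10, 50, 100, 250, 500, 1000, 2000, 4000, 8000)

RANKING_METHODS = ("RF", "EN", "BA")


@dataclass
class MarkerRanking:
    """Per-marker scores from one ranking method, training lines only."""

    method: str
    scores: np.ndarray  # (p,), higher = more important
    marker_ids: list[str]
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.marker_ids):
            raise ValueError("scores and marker_ids lengths differ")

    @property
    def order(self) -> np.ndarray:
        """Marker indices sorted by descending score; ties keep original
        marker order (stable sort on negated scores)."""
        return np.argsort(-self.scores, kind="stable")

    @property
    def ranked_marker_ids(self) -> list[str]:
        return [self.marker_ids[i] for i in self.order]


@dataclass
class OverlapNullResult:
    """Null distribution of the common overlap of random marker sets."""

    p_total: int
    k: int
    n_sets: int
    n_permutations: int
    seed: int | None
    overlap_counts: np.ndarray
    percentiles: dict[float, float]

    @property
    def mean(self) -> float:
        return float(self.overlap_counts.mean())

    def analytic_mean(self) -> float:
        """Expected intersection size: p * (k/p)^n_sets."""
        return self.p_total * (self.k / self.p_total) ** self.n_sets

    def to_dict(self) -> dict:
        return {
            "p_total": self.p_total,
            "k": self.k,
            "n_sets": self.n_sets,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "mean_overlap": self.mean,
            "analytic_mean": self.analytic_mean(),
            "percentiles": {str(q): v for q, v in self.percentiles.items()},
        }


def rank_markers(
    G_train,
    y_train,
    method: str = "RF",
    seed: int | None = None,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    rf_settings: dict | None = None,
    en_k_target: int | None = None,
    ba_iterations: int = 4000,
    ba_burn_in: int = 1000,
) -> MarkerRanking:
    """Score every marker on training data with RF, EN or BA.

    RF uses impurity importances from a seeded forest; EN uses absolute
    coefficients of the ratio-searched elastic net; BA uses absolute
    posterior-mean marker effects.  The caller's contract is to pass
    training lines only — test lines must never reach a ranking.
    """
    if method not in RANKING_METHODS:
        raise ValueError(f"method must be one of {RANKING_METHODS}")
    X = np.asarray(
        G_train.X() if isinstance(G_train, GenotypeMatrix) else G_train, dtype=float
    )
    y = np.asarray(y_train, dtype=float)
    p = X.shape[1]
    marker_ids = (
        list(G_train.marker_ids)
        if isinstance(G_train, GenotypeMatrix)
        else [f"m{j}" for j in range(p)]
    )
    k_grid = tuple(k for k in k_grid if k <= p) or (p,)
    if max(k_grid) < max(DEFAULT_K_GRID) and p < max(DEFAULT_K_GRID):
        pass  # grid silently truncated to the available markers
    metadata: dict = {}

    if method == "RF":
        rf_settings = {
            "n_trees": 256,
            "max_depth": None,
            "max_features": 0.25,
            **(rf_settings or {}),
        }
        fit = fit_tree_ensemble(X, y, family="RF", seed=seed, **rf_settings)
        scores = np.asarray(fit.importances, dtype=float)
    elif method == "EN":
        k_target = en_k_target if en_k_target is not None else min(max(k_grid), p)
        est, ratio = elastic_net_ratio_search(X, y, k_target=k_target, seed=seed)
        scores = np.abs(est.coef_)
        metadata["l1_ratio"] = ratio
    else:  # BA
        fit = fit_bayesian_regression(
            X, y, model="BA", iterations=ba_iterations, burn_in=ba_burn_in, seed=seed
        )
        scores = np.abs(fit.marker_effects)

    return MarkerRanking(
        method=method,
        scores=scores,
        marker_ids=marker_ids,
        k_grid=k_grid,
        metadata=metadata,
    )


def elastic_net_ratio_search(
    G_train,
    y_train,
    k_target: int = 8000,
    start_ratio: float = 0.10,
    step: float = 0.02,
    ratio_floor: float = 0.02,
    alpha: float | None = None,
    seed: int | None = None,
) -> tuple[ElasticNet, float]:
    """Walk the L1:L2 ratio down until enough markers survive selection.

    Fits an elastic net at ratios 0.10, 0.08, 0.06, ... and returns the
    first fit keeping at least ``k_target`` nonzero coefficients.  The
    overall penalty strength ``alpha`` is chosen once by internal
    cross-validation at the starting ratio and then frozen during the loop;
    pass ``alpha`` to skip that step.  If the floor ratio still keeps too
    few markers the floor fit is returned with a warning (pure ridge keeps
    everything, so in practice the loop terminates).
    """
    if start_ratio <= 0:
        raise ValueError("start_ratio must be > 0")
    X = np.asarray(
        G_train.X() if isinstance(G_train, GenotypeMatrix) else G_train, dtype=float
    )
    y = np.asarray(y_train, dtype=float)
    if k_target > X.shape[1]:
        raise ValueError("k_target cannot exceed the number of markers")

    if alpha is None:
        from sklearn.linear_model import ElasticNetCV

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = ElasticNetCV(
                l1_ratio=start_ratio, cv=5, alphas=30, random_state=seed,
                max_iter=2000,
            )
            cv.fit(X, y)
        alpha = float(cv.alpha_)

    ratio = start_ratio
    last_fit = None
    while True:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ElasticNet(alpha=alpha, l1_ratio=ratio, max_iter=5000)
            est.fit(X, y)
        last_fit = est
        if int(np.sum(est.coef_ != 0)) >= k_target:
            return est, ratio
        next_ratio = round(ratio - step, 10)
        if next_ratio < ratio_floor - 1e-12:
            warnings.warn(
                f"ratio floor {ratio_floor} reached with only "
                f"{int(np.sum(est.coef_ != 0))} nonzero coefficients "
                f"(target {k_target}); returning the floor fit"
            )
            return last_fit, ratio
        ratio = next_ratio


def select_top_k(
    ranking: MarkerRanking, k: int, genotypes: GenotypeMatrix | None = None
):
    """The k highest-scored markers (stable original order breaks ties).

    Returns ``(marker_indices, marker_ids)`` — plus the reduced
    :class:`GenotypeMatrix` view when ``genotypes`` is given.
    """
    p = len(ranking.scores)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > p:
        raise ValueError(f"k={k} exceeds the {p} available markers")
    idx = np.sort(ranking.order[:k])
    ids = [ranking.marker_ids[i] for i in idx]
    if genotypes is None:
        return idx, ids
    return idx, ids, genotypes.subset_markers(idx)


def _chained_hypergeometric_overlaps(
    rng: np.random.Generator, p: int, k: int, n_sets: int, n_perm: int
) -> np.ndarray:
    """Sample intersection sizes of ``n_sets`` uniform k-subsets of p items.

    By exchangeability, |S1 ∩ S2| ~ Hypergeometric(p, k, k), and the running
    intersection after each further set is hypergeometric given the previous
    size — so the full joint can be sampled without materialising any
    subsets.  Exact in distribution and O(n_sets) per permutation.
    """
    inter = np.full(n_perm, k, dtype=np.int64)
    for _ in range(n_sets - 1):
        nonzero = inter > 0
        out = np.zeros(n_perm, dtype=np.int64)
        if nonzero.any():
            out[nonzero] = rng.hypergeometric(
                inter[nonzero], p - inter[nonzero], k
            )
        inter = out
    return inter


def _direct_overlaps(
    rng: np.random.Generator, p: int, k: int, n_sets: int, n_perm: int
) -> np.ndarray:
    counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        common: np.ndarray | None = None
        for _ in range(n_sets):
            subset = rng.choice(p, size=k, replace=False)
            common = subset if common is None else np.intersect1d(common, subset)
        counts[i] = len(common)
    return counts


def overlap_null_percentile(
    p_total: int,
    k: int,
    n_sets: int = 3,
    n_permutations: int = 10_000,
    percentile: float | tuple[float, ...] = 99.0,
    seed: int | None = None,
    method: str = "hypergeometric",
) -> OverlapNullResult:
    """Null distribution of the common overlap of random top-k marker sets.

    Each permutation draws ``n_sets`` uniform k-subsets of the ``p_total``
    markers without replacement and records the size of their common
    intersection.  ``method="hypergeometric"`` (default) samples the
    intersection sizes exactly via chained hypergeometric draws, which makes
    genome-scale inputs (hundreds of thousands of markers) instant;
    ``method="direct"`` materialises the subsets.  Percentiles use the
    lower (inverted-CDF) convention so the reported value is an attained
    overlap count.
    """
    if not (0 < k <= p_total):
        raise ValueError("need 0 < k <= p_total")
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    if method == "hypergeometric":
        counts = _chained_hypergeometric_overlaps(
            rng, p_total, k, n_sets, n_permutations
        )
    elif method == "direct":
        counts = _direct_overlaps(rng, p_total, k, n_sets, n_permutations)
    else:
        raise ValueError("method must be 'hypergeometric' or 'direct'")

    qs = (percentile,) if np.isscalar(percentile) else tuple(percentile)
    percentiles = {
        float(q): float(
            np.percentile(counts, q, method="inverted_cdf")
        )
        for q in qs
    }
    return OverlapNullResult(
        p_total=p_total,
        k=k,
        n_sets=n_sets,
        n_permutations=n_permutations,
        seed=seed,
        overlap_counts=counts,
        percentiles=percentiles,
    )
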