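"""Covariate-driven heterogeneity detection for ranking data.

A Plackett-Luce tree recursively splits the rankings on participant-level
covariates wherever two worth vectors explain the data significantly better
than one. Splits are scored by the likelihood-ratio statistic

    LR = 2 * (loglik_left + loglik_right - loglik_pooled)

referred to a chi-square with t-1 degrees of freedom (one worth vector per
side, minus the identifiability constraint), Bonferroni-adjusted over the
number of candidate covariates. The df are approximate: threshold search
inflates the statistic, which the Bonferroni correction partially offsets.

Covariate screening uses greedy forward selection scored by k-fold
cross-validated held-out log-likelihood at the package level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .plackett import PLFit, fit_plackett_luce, pl_log_likelihood
from .rankings import RankingSet

__all__ = [
    "CovariateTable",
    "PLTreeNode",
    "split_statistic",
    "fit_pl_tree",
    "forward_select_covariates",
    "INFEASIBLE",
]

#: sentinel returned by split_statistic when a side is too small
INFEASIBLE = None

_MAX_THRESHOLDS = 50


@dataclass(frozen=True)
class CovariateTable:
    """Per-package covariates, joinable to rankings by package_id."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "package_id" not in self.table.columns:
            raise ValueError("covariate table must have a package_id column")
        if self.table["package_id"].duplicated().any():
            dupes = self.table["package_id"][
                self.table["package_id"].duplicated()
            ].tolist()
            raise ValueError(f"duplicate package_ids in covariate table: {dupes}")
        object.__setattr__(
            self, "table", self.table.set_index("package_id", drop=False)
        )

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c != "package_id"]

    def values_for(self, name: str, package_ids: Sequence[int]) -> np.ndarray:
        missing = [p for p in package_ids if p not in self.table.index]
        if missing:
            raise KeyError(
                f"package_ids missing from covariate table: {sorted(set(missing))}"
            )
        return self.table.loc[list(package_ids), name].to_numpy()


@dataclass(frozen=True)
class PLTreeNode:
    """Leaf (a PLFit) or internal node (a binary covariate split)."""

    fit: PLFit | None = None
    n_rankings: int = 0
    covariate: str | None = None
    threshold: float | None = None
    categories: frozenset | None = None
    left: "PLTreeNode | None" = None
    right: "PLTreeNode | None" = None
    lr_statistic: float | None = None
    p_value: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.covariate is None

    def leaves(self) -> list["PLTreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def route(self, covariates: dict[str, object]) -> "PLTreeNode":
        """Follow splits to the leaf matching a covariate record."""
        if self.is_leaf:
            return self
        value = covariates[self.covariate]
        if self.categories is not None:
            goes_left = value in self.categories
        else:
            goes_left = value <= self.threshold
        return (self.left if goes_left else self.right).route(covariates)

    def total_loglik(self) -> float:
        return sum(leaf.fit.loglik for leaf in self.leaves())


def _subset(rankings: RankingSet, mask: np.ndarray) -> RankingSet:
    kept = tuple(r for r, keep in zip(rankings.rankings, mask) if keep)
    return RankingSet(universe=rankings.universe, rankings=kept)


def _fit_side(rankings: RankingSet, regularization: float) -> PLFit:
    return fit_plackett_luce(
        rankings, regularization=regularization, compute_stderr=False
    )


def split_statistic(
    rankings: RankingSet,
    covariates: CovariateTable,
    covariate: str,
    threshold: float,
    min_node_size: int = 30,
    regularization: float = 0.5,
) -> float | None:
    """Likelihood-ratio statistic of splitting at ``covariate <= threshold``.

    Returns the INFEASIBLE sentinel (None) when either side would fall below
    ``min_node_size``. Both sides and the pooled set are fitted with the same
    settings; the statistic is nonnegative up to numerical tolerance.
    """
    pids = [r.package_id for r in rankings.rankings]
    values = covariates.values_for(covariate, pids)
    left_mask = values <= threshold
    n_left = int(left_mask.sum())
    n_right = len(values) - n_left
    if n_left < min_node_size or n_right < min_node_size:
        return INFEASIBLE
    pooled = _fit_side(rankings, regularization)
    left = _fit_side(_subset(rankings, left_mask), regularization)
    right = _fit_side(_subset(rankings, ~left_mask), regularization)
    return 2.0 * (left.loglik + right.loglik - pooled.loglik)


def _candidate_splits(values: np.ndarray) -> list[tuple[str, object]]:
    """Candidate splits for one covariate column.

    Numeric: midpoints of sorted unique values, quantile-thinned past 50.
    Categorical: one category vs the rest.
    """
    if values.dtype.kind in "OUSb":
        cats = sorted(set(values.tolist()))
        if len(cats) < 2:
            return []
        return [("cat", c) for c in cats[:-1]] if len(cats) == 2 else [
            ("cat", c) for c in cats
        ]
    uniq = np.unique(values[~pd.isna(values)])
    if len(uniq) < 2:
        return []
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    if len(mids) > _MAX_THRESHOLDS:
        qs = np.linspace(0, 1, _MAX_THRESHOLDS + 2)[1:-1]
        mids = np.unique(np.quantile(mids, qs))
    return [("num", float(m)) for m in mids]


def _best_split(
    rankings: RankingSet,
    covariates: CovariateTable,
    names: Sequence[str],
    min_node_size: int,
    regularization: float,
    pooled_loglik: float,
):
    """Maximal-LR feasible split over all covariates and thresholds."""
    pids = [r.package_id for r in rankings.rankings]
    best = None
    for name in names:
        values = covariates.values_for(name, pids)
        for kind, cut in _candidate_splits(values):
            if kind == "num":
                left_mask = values <= cut
            else:
                left_mask = np.array([v == cut for v in values])
            n_left = int(left_mask.sum())
            if n_left < min_node_size or len(values) - n_left < min_node_size:
                continue
            left = _fit_side(_subset(rankings, left_mask), regularization)
            right = _fit_side(_subset(rankings, ~left_mask), regularization)
            lr = 2.0 * (left.loglik + right.loglik - pooled_loglik)
            if best is None or lr > best[0]:
                best = (lr, name, kind, cut, left_mask, left, right)
    return best


def fit_pl_tree(
    rankings: RankingSet,
    covariates: CovariateTable,
    alpha: float = 0.05,
    min_node_size: int = 30,
    max_depth: int = 3,
    covariate_names: Sequence[str] | None = None,
    regularization: float = 0.5,
) -> PLTreeNode:
    """Recursively partition rankings by covariates.

    At each node the maximal-LR feasible split is accepted iff its
    Bonferroni-adjusted chi-square(t-1) p-value is <= alpha; otherwise the
    node becomes a leaf holding a Plackett-Luce fit.
    """
    names = (
        list(covariate_names)
        if covariate_names is not None
        else covariates.covariate_names
    )
    pids = [r.package_id for r in rankings.rankings]
    missing = [p for p in pids if p not in covariates.table.index]
    if missing:
        raise KeyError(
            f"rankings reference package_ids absent from the covariate table: "
            f"{sorted(set(missing))}"
        )
    t = len(rankings.universe)

    def grow(rset: RankingSet, depth: int) -> PLTreeNode:
        pooled = _fit_side(rset, regularization)
        leaf = PLTreeNode(fit=pooled, n_rankings=len(rset))
        if depth >= max_depth or len(rset) < 2 * min_node_size or not names:
            return leaf
        best = _best_split(
            rset, covariates, names, min_node_size, regularization, pooled.loglik
        )
        if best is None:
            return leaf
        lr, name, kind, cut, left_mask, _left_fit, _right_fit = best
        p = stats.chi2.sf(max(lr, 0.0), df=t - 1)
        p_adj = min(1.0, p * len(names))
        if p_adj > alpha:
            return leaf
        left_node = grow(_subset(rset, left_mask), depth + 1)
        right_node = grow(_subset(rset, ~left_mask), depth + 1)
        return PLTreeNode(
            n_rankings=len(rset),
            covariate=name,
            threshold=cut if kind == "num" else None,
            categories=frozenset([cut]) if kind == "cat" else None,
            left=left_node,
            right=right_node,
            lr_statistic=float(lr),
            p_value=float(p_adj),
        )

    return grow(rankings, 0)


def _heldout_loglik(
    tree: PLTreeNode, rankings: RankingSet, covariates: CovariateTable
) -> float:
    """Log-likelihood of held-out rankings routed through a fitted tree."""
    total = 0.0
    for r in rankings.rankings:
        record = covariates.table.loc[r.package_id].to_dict()
        leaf = tree.route(record)
        single = RankingSet(universe=rankings.universe, rankings=(r,))
        total += pl_log_likelihood(single, leaf.fit.log_worths)
    return total


@dataclass(frozen=True)
class ForwardSelectionResult:
    selected: tuple[str, ...]
    scores: tuple[float, ...]  # score trajectory, starting at the null model
    candidate_scores: tuple[dict[str, float], ...] = field(default=())


def forward_select_covariates(
    rankings: RankingSet,
    covariates: CovariateTable,
    k_folds: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    min_node_size: int = 30,
    max_depth: int = 3,
    regularization: float = 0.5,
) -> ForwardSelectionResult:
    """Greedy forward selection of splitting covariates by CV log-likelihood.

    Starting from the null (single-leaf) model, each step adds the covariate
    whose availability to the tree most improves the mean held-out
    log-likelihood over k package-level folds; stops when no addition
    improves the score.
    """
    if len(rankings) < k_folds:
        raise ValueError(
            f"need at least k_folds={k_folds} rankings, got {len(rankings)}"
        )
    rng = np.random.default_rng(seed)
    n = len(rankings)
    fold_of = np.repeat(np.arange(k_folds), -(-n // k_folds))[:n]
    rng.shuffle(fold_of)

    def cv_score(names: list[str]) -> float:
        scores = []
        for k in range(k_folds):
            train = _subset(rankings, fold_of != k)
            test = _subset(rankings, fold_of == k)
            if len(train) == 0 or len(test) == 0:
                continue
            tree = fit_pl_tree(
                train,
                covariates,
                alpha=alpha,
                min_node_size=min_node_size,
                max_depth=max_depth,
                covariate_names=names,
                regularization=regularization,
            )
            scores.append(_heldout_loglik(tree, test, covariates))
        return float(np.mean(scores))

    remaining = list(covariates.covariate_names)
    selected: list[str] = []
    current = cv_score([])
    trajectory = [current]
    per_step: list[dict[str, float]] = []
    while remaining:
        step_scores = {
            name: cv_score(selected + [name]) for name in remaining
        }
        per_step.append(step_scores)
        best_name = max(step_scores, key=lambda nm: (step_scores[nm], nm))
        if step_scores[best_name] <= current:
            break
        current = step_scores[best_name]
        selected.append(best_name)
        remaining.remove(best_name)
        trajectory.append(current)
    return ForwardSelectionResult(
        selected=tuple(selected),
        scores=tuple(trajectory),
        candidate_scores=tuple(per_step),
    )
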