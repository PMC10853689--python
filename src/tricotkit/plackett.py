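"""Plackett-Luce worth estimation for triadic rankings.

The model assigns each option a positive worth w_i; a ranking arises by
repeatedly choosing the next-best option with probability proportional to
worth among those remaining. Likelihood contributions:

* strict ranking i > j > k:  (w_i / (w_i+w_j+w_k)) * (w_j / (w_j+w_k))
* best-only i > {j, k}:       w_i / (w_i+w_j+w_k)   (exact marginal)
* worst-only {i, j} > k:      P(k ranked last), the exact marginal obtained
  by summing the two compatible strict orders.

Fitting uses a minorization-maximization (MM) update on the worths; the
worst-only marginals are handled by an expectation step that distributes
each such ranking over its two compatible strict orders, so every iteration
is monotone in the observed log-likelihood.

When the win graph is not strongly connected the MLE diverges; a
pseudo-comparison regularization (weight ``regularization`` of a win and a
loss against a hypothetical reference item, per option) keeps estimates
finite. Weight 0 disables it and enforces a strict estimability check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import TrialDesign
from .rankings import Ranking, RankingSet, TricotResponse, win_graph_connectivity

__all__ = [
    "PLFit",
    "SimulationSpec",
    "EstimabilityError",
    "pl_log_likelihood",
    "fit_plackett_luce",
    "win_probability",
    "simulate_tricot_responses",
]


class EstimabilityError(ValueError):
    """MLE does not exist: the win graph is not strongly connected."""


@dataclass(frozen=True)
class PLFit:
    universe: tuple[str, ...]
    log_worths: np.ndarray  # sum-to-zero
    loglik: float
    n_rankings: int
    converged: bool
    iterations: int
    stderr: np.ndarray | None = None
    loglik_path: tuple[float, ...] = ()

    @property
    def worths(self) -> np.ndarray:
        return np.exp(self.log_worths)

    def log_worth(self, option: str) -> float:
        try:
            return float(self.log_worths[self.universe.index(option)])
        except ValueError:
            raise KeyError(f"unknown option {option!r}") from None

    def as_dict(self) -> dict[str, float]:
        return {o: float(lw) for o, lw in zip(self.universe, self.log_worths)}


@dataclass(frozen=True)
class SimulationSpec:
    design: TrialDesign
    log_worths: np.ndarray
    seed: int
    response_rate: float = 1.0
    trait: str = "overall"

    def __post_init__(self) -> None:
        lw = np.asarray(self.log_worths, dtype=float)
        object.__setattr__(self, "log_worths", lw)
        if len(lw) != len(self.design.option_names):
            raise ValueError(
                f"log_worths length {len(lw)} does not match "
                f"{len(self.design.option_names)} options"
            )
        if not 0 < self.response_rate <= 1:
            raise ValueError("response_rate must be in (0, 1]")


def _ranking_kind(r: Ranking) -> str:
    sizes = tuple(len(g) for g in r.groups)
    if all(s == 1 for s in sizes):
        return "strict"
    if sizes == (1, 2):
        return "best_only"
    if sizes == (2, 1):
        return "worst_only"
    raise ValueError(f"unsupported ranking shape {sizes}")


def _ranking_loglik(r: Ranking, idx: dict[str, int], w: np.ndarray) -> float:
    kind = _ranking_kind(r)
    if kind == "strict":
        order = [idx[o] for g in r.groups for o in g]
        total = w[order].sum()
        ll = 0.0
        for i in order[:-1]:
            ll += np.log(w[i]) - np.log(total)
            total -= w[i]
        return ll
    if kind == "best_only":
        best = idx[r.groups[0][0]]
        total = w[best] + sum(w[idx[o]] for o in r.groups[1])
        return float(np.log(w[best]) - np.log(total))
    # worst_only: P(last) = sum of both compatible strict orders
    (a, b), (z,) = r.groups
    ia, ib, iz = idx[a], idx[b], idx[z]
    total = w[ia] + w[ib] + w[iz]
    p = (w[ia] / total) * (w[ib] / (w[ib] + w[iz])) + (w[ib] / total) * (
        w[ia] / (w[ia] + w[iz])
    )
    return float(np.log(p))


def pl_log_likelihood(rankings: RankingSet, log_worths: np.ndarray) -> float:
    """Exact log-likelihood of a ranking set at the given log-worths.

    ``log_worths`` is aligned to ``rankings.universe``.
    """
    log_worths = np.asarray(log_worths, dtype=float)
    if len(log_worths) != len(rankings.universe):
        raise ValueError(
            f"worth vector length {len(log_worths)} does not match universe "
            f"size {len(rankings.universe)}"
        )
    idx = {o: i for i, o in enumerate(rankings.universe)}
    w = np.exp(log_worths)
    return float(sum(_ranking_loglik(r, idx, w) for r in rankings.rankings))


def _build_events(
    rankings: RankingSet, idx: dict[str, int], n_params: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int, int]]]:
    """Choice events (membership matrix, chosen index, weight) plus the
    index triples (a, b, z) of worst-only rankings handled by EM."""
    rows: list[np.ndarray] = []
    chosen: list[int] = []
    weights: list[float] = []
    worst_only: list[tuple[int, int, int]] = []

    def add_event(choice: int, members: list[int], weight: float = 1.0) -> None:
        row = np.zeros(n_params)
        row[members] = 1.0
        rows.append(row)
        chosen.append(choice)
        weights.append(weight)

    for r in rankings.rankings:
        kind = _ranking_kind(r)
        if kind == "strict":
            order = [idx[o] for g in r.groups for o in g]
            remaining = list(order)
            for i in order[:-1]:
                add_event(i, remaining)
                remaining.remove(i)
        elif kind == "best_only":
            members = [idx[o] for g in r.groups for o in g]
            add_event(idx[r.groups[0][0]], members)
        else:
            (a, b), (z,) = r.groups
            worst_only.append((idx[a], idx[b], idx[z]))
    M = (
        np.array(rows)
        if rows
        else np.zeros((0, n_params))
    )
    return M, np.array(chosen, dtype=int), np.array(weights), worst_only


def fit_plackett_luce(
    rankings: RankingSet,
    regularization: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    compute_stderr: bool = True,
    track_loglik_path: bool = False,
) -> PLFit:
    """Maximize the (optionally regularized) Plackett-Luce likelihood.

    Parameters
    ----------
    rankings
        Non-empty ranking set over a fixed universe.
    regularization
        Weight of the pseudo-comparisons against a hypothetical reference
        item (one win and one loss per option). 0 disables regularization
        and requires a strongly connected win graph.
    tol
        Convergence threshold on the max-norm of the (penalized)
        log-likelihood gradient with respect to the log-worths.
    max_iter
        Iteration cap; exceeding it sets ``converged=False`` with a warning.
    """
    if len(rankings) == 0:
        raise ValueError("cannot fit a Plackett-Luce model to zero rankings")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    if regularization == 0:
        report = win_graph_connectivity(rankings)
        if not report.strongly_connected:
            comps = [sorted(c) for c in report.components]
            raise EstimabilityError(
                "win graph is not strongly connected; worth estimates would "
                f"diverge. Components: {comps}. Use regularization > 0 or "
                "collect more comparisons."
            )

    universe = rankings.universe
    t = len(universe)
    ghost = regularization > 0
    n_params = t + 1 if ghost else t
    idx = {o: i for i, o in enumerate(universe)}

    M, chosen, weights, worst_only = _build_events(rankings, idx, n_params)
    if ghost:
        extra_rows, extra_chosen, extra_w = [], [], []
        for i in range(t):
            row = np.zeros(n_params)
            row[[i, t]] = 1.0
            extra_rows.extend([row, row])
            extra_chosen.extend([i, t])
            extra_w.extend([regularization, regularization])
        M = np.vstack([M, np.array(extra_rows)]) if M.size else np.array(extra_rows)
        chosen = np.concatenate([chosen, np.array(extra_chosen, dtype=int)])
        weights = np.concatenate([weights, np.array(extra_w)])

    w = np.ones(n_params)

    def observed_loglik(wvec: np.ndarray) -> float:
        lw = np.log(wvec[:t])
        lw = lw - lw.mean()
        ll = pl_log_likelihood(rankings, lw)
        if ghost:
            # penalty term from the pseudo-comparisons
            for i in range(t):
                pair = wvec[i] + wvec[t]
                ll += regularization * (
                    np.log(wvec[i] / pair) + np.log(wvec[t] / pair)
                )
        return ll

    def em_expand(wvec: np.ndarray):
        """Expected event weights for worst-only rankings at current worths."""
        rows, ch, ww = [], [], []
        for ia, ib, iz in worst_only:
            total = wvec[ia] + wvec[ib] + wvec[iz]
            p1 = (wvec[ia] / total) * (wvec[ib] / (wvec[ib] + wvec[iz]))
            p2 = (wvec[ib] / total) * (wvec[ia] / (wvec[ia] + wvec[iz]))
            g1 = p1 / (p1 + p2)
            for gamma, first, second in ((g1, ia, ib), (1 - g1, ib, ia)):
                row = np.zeros(n_params)
                row[[ia, ib, iz]] = 1.0
                rows.append(row)
                ch.append(first)
                ww.append(gamma)
                row2 = np.zeros(n_params)
                row2[[second, iz]] = 1.0
                rows.append(row2)
                ch.append(second)
                ww.append(gamma)
        if not rows:
            return (
                np.zeros((0, n_params)),
                np.zeros(0, dtype=int),
                np.zeros(0),
            )
        return np.array(rows), np.array(ch, dtype=int), np.array(ww)

    converged = False
    iterations = 0
    path = [observed_loglik(w)] if track_loglik_path else []
    wins_fixed = np.zeros(n_params)
    np.add.at(wins_fixed, chosen, weights)

    for iterations in range(1, max_iter + 1):
        Me, ce, we = em_expand(w)
        if Me.shape[0]:
            M_all = np.vstack([M, Me]) if M.size else Me
            weights_all = np.concatenate([weights, we])
            wins = wins_fixed.copy()
            np.add.at(wins, ce, we)
        else:
            M_all, weights_all, wins = M, weights, wins_fixed

        denom_events = M_all @ w  # per-event total worth
        denom = (M_all * (weights_all / denom_events)[:, None]).sum(axis=0)
        # gradient of the (penalized) loglik wrt log-worths
        grad = wins - w * denom
        if np.abs(grad).max() <= tol:
            converged = True
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            w_new = np.where(denom > 0, wins / denom, w)
        w_new = np.maximum(w_new, 1e-300)
        w = w_new / np.exp(np.mean(np.log(w_new)))
        if track_loglik_path:
            path.append(observed_loglik(w))

    if not converged:
        warnings.warn(
            f"Plackett-Luce fit did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    log_worths = np.log(w[:t])
    log_worths = log_worths - log_worths.mean()
    loglik = pl_log_likelihood(rankings, log_worths)

    stderr = None
    if compute_stderr:
        if regularization > 0:
            warnings.warn(
                "standard errors are omitted when regularization > 0",
                UserWarning,
                stacklevel=2,
            )
        else:
            stderr = _numeric_stderr(rankings, log_worths)

    return PLFit(
        universe=universe,
        log_worths=log_worths,
        loglik=loglik,
        n_rankings=len(rankings),
        converged=converged,
        iterations=iterations,
        stderr=stderr,
        loglik_path=tuple(path),
    )


def _numeric_stderr(rankings: RankingSet, log_worths: np.ndarray) -> np.ndarray | None:
    """Observed-information standard errors on the sum-to-zero scale.

    The Hessian of the log-likelihood is differentiated numerically in the
    reduced (t-1)-parameter coordinates theta_1..theta_{t-1}, with
    theta_t = -sum(theta). Returns None when the information matrix is
    singular.
    """
    t = len(log_worths)
    theta0 = log_worths[:-1]

    def nll(theta: np.ndarray) -> float:
        full = np.append(theta, -theta.sum())
        return -pl_log_likelihood(rankings, full)

    h = 1e-5
    k = t - 1
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                nll(theta0 + ei + ej)
                - nll(theta0 + ei - ej)
                - nll(theta0 - ei + ej)
                + nll(theta0 - ei - ej)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(cov) < 0):
        return None
    var = np.append(np.diag(cov), np.ones(k) @ cov @ np.ones(k))
    return np.sqrt(var)


def win_probability(fit: PLFit, i: str, j: str) -> float:
    """Probability that option i outperforms option j: w_i / (w_i + w_j)."""
    if i == j:
        raise ValueError("options must differ")
    wi = np.exp(fit.log_worth(i))
    wj = np.exp(fit.log_worth(j))
    return float(wi / (wi + wj))


def simulate_tricot_responses(spec: SimulationSpec) -> list[TricotResponse]:
    """Simulate best/worst responses from known worths, seeded.

    Each package responds with probability ``response_rate``; a responding
    package ranks its three options by Gumbel-perturbed log-worths, which is
    exactly sequential Plackett-Luce sampling. Non-responders yield empty
    responses (best and worst missing).
    """
    rng = np.random.default_rng(spec.seed)
    name_to_idx = {o: i for i, o in enumerate(spec.design.option_names)}
    responses = []
    for pkg in spec.design.packages:
        u = rng.random()
        gumbels = rng.gumbel(size=3)
        if u > spec.response_rate:
            responses.append(
                TricotResponse(package_id=pkg.package_id, trait=spec.trait)
            )
            continue
        scores = (
            np.array([spec.log_worths[name_to_idx[o]] for o in pkg.options]) + gumbels
        )
        order = np.argsort(-scores)  # descending: best first
        responses.append(
            TricotResponse(
                package_id=pkg.package_id,
                trait=spec.trait,
                best="ABC"[order[0]],
                worst="ABC"[order[-1]],
            )
        )
    return responses
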