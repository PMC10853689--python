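"""Incomplete block designs of size three for triadic comparison trials.

Designs are built to satisfy four criteria simultaneously:

* every block holds three distinct options;
* replication counts differ by at most one across options;
* consecutive blocks stay near-balanced (max prefix imbalance <= 2), so
  handing out consecutive package numbers balances options over space/time;
* the concurrence graph is as well connected as a local search can make it,
  measured by the Kirchhoff index (approximate A-optimality).

Positions A/B/C within each block are balanced separately, so that each
option appears with near-equal frequency in each position.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DesignSpec",
    "Package",
    "TrialDesign",
    "ConcurrenceGraph",
    "DesignDiagnostics",
    "concurrence_graph",
    "kirchhoff_index",
    "generate_design",
    "validate_design",
]

#: eigenvalues below this (relative to the largest) count as structural zeros
_ZERO_TOL = 1e-9


class DesignError(ValueError):
    """Raised for invalid design specifications or malformed designs."""


@dataclass(frozen=True)
class DesignSpec:
    """Specification of a trial: option universe, size and randomization seed."""

    n_options: int
    n_packages: int
    option_names: tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "option_names", tuple(self.option_names))
        if self.n_options < 3:
            raise DesignError(f"need at least 3 options, got {self.n_options}")
        if self.n_packages < 1:
            raise DesignError(f"need at least 1 package, got {self.n_packages}")
        if len(self.option_names) != self.n_options:
            raise DesignError(
                f"expected {self.n_options} option names, got {len(self.option_names)}"
            )
        if len(set(self.option_names)) != self.n_options:
            raise DesignError("option names must be unique")
        if any(not name for name in self.option_names):
            raise DesignError("option names must be non-empty")


@dataclass(frozen=True)
class Package:
    """One participant's blind package: three distinct options at positions A/B/C."""

    package_id: int
    options: tuple[str, str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "options", tuple(self.options))
        if self.package_id < 1:
            raise DesignError(f"package_id must be >= 1, got {self.package_id}")
        if len(self.options) != 3:
            raise DesignError(
                f"package {self.package_id}: expected 3 options, got {len(self.options)}"
            )
        if len(set(self.options)) != 3:
            raise DesignError(
                f"package {self.package_id}: options repeat within the block: "
                f"{self.options}"
            )

    def option_at(self, position: str) -> str:
        """Option label at position 'A', 'B' or 'C'."""
        idx = "ABC".index(position)
        return self.options[idx]


@dataclass(frozen=True)
class TrialDesign:
    spec: DesignSpec
    packages: tuple[Package, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "packages", tuple(self.packages))
        ids = [p.package_id for p in self.packages]
        if ids != list(range(1, len(ids) + 1)):
            raise DesignError("package ids must be 1..n consecutive")
        universe = set(self.spec.option_names)
        for p in self.packages:
            unknown = set(p.options) - universe
            if unknown:
                raise DesignError(
                    f"package {p.package_id} uses unknown options: {sorted(unknown)}"
                )

    @property
    def option_names(self) -> tuple[str, ...]:
        return self.spec.option_names

    @property
    def n_packages(self) -> int:
        return len(self.packages)

    def package(self, package_id: int) -> Package:
        if not 1 <= package_id <= len(self.packages):
            raise DesignError(f"unknown package_id {package_id}")
        return self.packages[package_id - 1]


@dataclass(frozen=True)
class ConcurrenceGraph:
    """Weighted co-occurrence graph: w[i, j] = number of blocks holding both."""

    nodes: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise DesignError("weight matrix shape does not match node count")
        if not np.array_equal(w, w.T):
            raise DesignError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise DesignError("weight matrix must have zero diagonal")
        if np.any(w < 0):
            raise DesignError("negative edge weight")
        object.__setattr__(self, "weights", w)

    def laplacian(self) -> np.ndarray:
        w = self.weights.astype(float)
        return np.diag(w.sum(axis=1)) - w

    def is_connected(self) -> bool:
        return math.isfinite(kirchhoff_index(self))


@dataclass(frozen=True)
class DesignDiagnostics:
    replication_counts: dict[str, int]
    position_counts: dict[str, tuple[int, int, int]]
    max_position_deviation: int
    max_prefix_imbalance: int
    kirchhoff_index: float
    connected: bool
    no_within_block_repeats: bool
    block_sizes: tuple[int, ...] = field(default=())


def concurrence_graph(design: TrialDesign) -> ConcurrenceGraph:
    """Count, for every option pair, the packages in which both appear."""
    names = design.option_names
    index = {name: i for i, name in enumerate(names)}
    w = np.zeros((len(names), len(names)), dtype=int)
    for pkg in design.packages:
        for a, b in itertools.combinations(pkg.options, 2):
            i, j = index[a], index[b]
            w[i, j] += 1
            w[j, i] += 1
    return ConcurrenceGraph(nodes=names, weights=w)


def kirchhoff_index(graph: ConcurrenceGraph, method: str = "eigen") -> float:
    """Kirchhoff index of a weighted graph; +inf when disconnected.

    ``method='eigen'`` computes t * sum(1/mu_i) over the nonzero Laplacian
    eigenvalues; ``method='resistance'`` sums pairwise effective resistances
    obtained from the Laplacian pseudoinverse. Both agree on connected graphs
    and exist as mutually checking implementations.
    """
    t = len(graph.nodes)
    if t < 2:
        raise DesignError("Kirchhoff index needs at least 2 nodes")
    L = graph.laplacian()
    if method == "eigen":
        mu = np.linalg.eigvalsh(L)
        tol = _ZERO_TOL * max(mu[-1], 1.0)
        nonzero = mu[mu > tol]
        if len(nonzero) < t - 1:  # more than one structural zero
            return math.inf
        return float(t * np.sum(1.0 / nonzero))
    if method == "resistance":
        mu = np.linalg.eigvalsh(L)
        tol = _ZERO_TOL * max(mu[-1], 1.0)
        if np.count_nonzero(mu > tol) < t - 1:
            return math.inf
        pinv = np.linalg.pinv(L)
        d = np.diag(pinv)
        resist = d[:, None] + d[None, :] - 2.0 * pinv
        return float(resist[np.triu_indices(t, k=1)].sum())
    raise ValueError(f"unknown method {method!r}")


def _kirchhoff_from_weights(w: np.ndarray) -> float:
    t = w.shape[0]
    L = np.diag(w.sum(axis=1).astype(float)) - w
    mu = np.linalg.eigvalsh(L)
    tol = _ZERO_TOL * max(mu[-1], 1.0)
    nonzero = mu[mu > tol]
    if len(nonzero) < t - 1:
        return math.inf
    return float(t * np.sum(1.0 / nonzero))


def _prefix_imbalance(blocks: Sequence[tuple[int, ...]], t: int) -> int:
    reps = np.zeros(t, dtype=int)
    worst = 0
    for block in blocks:
        for i in block:
            reps[i] += 1
        worst = max(worst, int(reps.max() - reps.min()))
    return worst


def _greedy_blocks(t: int, n: int, rng: np.random.Generator) -> list[list[int]]:
    """Phase 1: sequentially balanced greedy construction.

    Each block takes the three lowest-replication options, breaking ties by
    lowest concurrence with options already in the block, then randomly.
    """
    reps = np.zeros(t, dtype=int)
    conc = np.zeros((t, t), dtype=int)
    blocks: list[list[int]] = []
    for _ in range(n):
        chosen: list[int] = []
        for _slot in range(3):
            best_key = None
            best_opt = -1
            noise = rng.random(t)
            for o in range(t):
                if o in chosen:
                    continue
                pair_load = sum(conc[o, c] for c in chosen)
                key = (reps[o], pair_load, noise[o])
                if best_key is None or key < best_key:
                    best_key = key
                    best_opt = o
            chosen.append(best_opt)
        for a, b in itertools.combinations(chosen, 2):
            conc[a, b] += 1
            conc[b, a] += 1
        reps[list(chosen)] += 1
        blocks.append(chosen)
    return blocks


def _conc_matrix(blocks: Sequence[Sequence[int]], t: int) -> np.ndarray:
    w = np.zeros((t, t), dtype=int)
    for block in blocks:
        for a, b in itertools.combinations(block, 2):
            w[a, b] += 1
            w[b, a] += 1
    return w


def _apply_exchange(
    w: np.ndarray, blocks: list[list[int]], b1: int, i1: int, b2: int, i2: int
) -> None:
    """Exchange item i1 of block b1 with item i2 of block b2, updating w in place."""
    x, y = blocks[b1][i1], blocks[b2][i2]
    for other in blocks[b1]:
        if other != x:
            w[x, other] -= 1
            w[other, x] -= 1
            w[y, other] += 1
            w[other, y] += 1
    blocks[b1][i1] = y
    for other in blocks[b2]:
        if other != y:
            w[y, other] -= 1
            w[other, y] -= 1
            w[x, other] += 1
            w[other, x] += 1
    blocks[b2][i2] = x


def _components(w: np.ndarray) -> list[set[int]]:
    t = w.shape[0]
    seen = [False] * t
    comps = []
    for s in range(t):
        if seen[s]:
            continue
        stack, comp = [s], set()
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.add(u)
            for v in np.nonzero(w[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        comps.append(comp)
    return comps


def _connect_components(blocks: list[list[int]], w: np.ndarray, t: int) -> None:
    """Merge disconnected components by exchanging items across them."""
    guard = 0
    while len(_components(w)) > 1 and guard < t * len(blocks):
        guard += 1
        comps = _components(w)
        comp_of = {}
        for k, comp in enumerate(comps):
            for node in comp:
                comp_of[node] = k
        done = False
        for b1, b2 in itertools.combinations(range(len(blocks)), 2):
            if done:
                break
            for i1, i2 in itertools.product(range(3), range(3)):
                x, y = blocks[b1][i1], blocks[b2][i2]
                if comp_of[x] == comp_of[y]:
                    continue
                if y in blocks[b1] or x in blocks[b2]:
                    continue
                _apply_exchange(w, blocks, b1, i1, b2, i2)
                if _prefix_imbalance([tuple(b) for b in blocks], t) <= 2:
                    done = True
                    break
                _apply_exchange(w, blocks, b1, i1, b2, i2)  # undo
        if not done:
            break


#: hard cap on local-search evaluations, keeping generation fast at large n
_MAX_SEARCH_EVALS = 25_000


def _local_search(
    blocks: list[list[int]], t: int, n: int, rng: np.random.Generator
) -> None:
    """Phase 2: single-item exchanges between blocks that strictly lower Kf.

    Replication counts are preserved by construction; exchanges that would
    break prefix balance (imbalance > 2) are rejected. Stops after a full
    pass without improvement or after min(500*n, 25000) evaluated exchanges.
    """
    w = _conc_matrix(blocks, t)
    _connect_components(blocks, w, t)
    current = _kirchhoff_from_weights(w)
    evaluations = 0
    budget = min(500 * n, _MAX_SEARCH_EVALS)
    improved = True
    while improved and evaluations < budget:
        improved = False
        order = rng.permutation(len(blocks) * (len(blocks) - 1) // 2)
        pairs = list(itertools.combinations(range(len(blocks)), 2))
        for idx in order:
            if evaluations >= budget:
                break
            b1, b2 = pairs[idx]
            for i1, i2 in itertools.product(range(3), range(3)):
                x, y = blocks[b1][i1], blocks[b2][i2]
                if x == y or y in blocks[b1] or x in blocks[b2]:
                    continue
                evaluations += 1
                _apply_exchange(w, blocks, b1, i1, b2, i2)
                candidate = _kirchhoff_from_weights(w)
                if (
                    candidate < current - 1e-12
                    and _prefix_imbalance([tuple(b) for b in blocks], t) <= 2
                ):
                    current = candidate
                    improved = True
                else:
                    _apply_exchange(w, blocks, b2, i2, b1, i1)  # undo
                if evaluations >= budget:
                    break


def _position_deviation(counts: np.ndarray, reps: np.ndarray) -> int:
    """Max distance of any (option, position) count from its floor/ceil band."""
    lo = reps // 3
    hi = -(-reps // 3)  # ceil
    over = np.maximum(counts - hi[:, None], 0)
    under = np.maximum(lo[:, None] - counts, 0)
    return int(np.maximum(over, under).max()) if counts.size else 0


def _assign_positions(
    blocks: list[list[int]], t: int, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """Phase 3: order each block's options over positions A/B/C.

    Greedy per block (prefer each option's least-used position), followed by
    a best-improvement repair over within-block permutations; randomized
    restarts until max deviation <= 1.
    """
    reps = np.zeros(t, dtype=int)
    for block in blocks:
        reps[block] += 1
    perms = list(itertools.permutations(range(3)))

    best_assign: list[tuple[int, int, int]] | None = None
    best_dev = np.iinfo(np.int64).max
    for _restart in range(50):
        counts = np.zeros((t, 3), dtype=int)
        assigned: list[tuple[int, int, int]] = []
        for block in blocks:
            noise = rng.random(len(perms))
            best_cost, best_perm = None, None
            for k, perm in enumerate(perms):
                cost = sum(counts[block[perm[p]], p] for p in range(3))
                key = (cost, noise[k])
                if best_cost is None or key < best_cost:
                    best_cost, best_perm = key, perm
            ordered = tuple(block[best_perm[p]] for p in range(3))
            for p in range(3):
                counts[ordered[p], p] += 1
            assigned.append(ordered)

        # repair: swap positions within a block when it lowers total squared error
        def sq_err(c: np.ndarray) -> float:
            return float(((c - reps[:, None] / 3.0) ** 2).sum())

        for _pass in range(100):
            if _position_deviation(counts, reps) <= 1:
                break
            improved = False
            for bi, ordered in enumerate(assigned):
                base = list(ordered)
                for p, q in itertools.combinations(range(3), 2):
                    counts[base[p], p] -= 1
                    counts[base[q], q] -= 1
                    counts[base[p], q] += 1
                    counts[base[q], p] += 1
                    before = sq_err(counts)
                    counts[base[p], q] -= 1
                    counts[base[q], p] -= 1
                    counts[base[p], p] += 1
                    counts[base[q], q] += 1
                    if before < sq_err(counts) - 1e-12:
                        counts[base[p], p] -= 1
                        counts[base[q], q] -= 1
                        counts[base[p], q] += 1
                        counts[base[q], p] += 1
                        base[p], base[q] = base[q], base[p]
                        assigned[bi] = tuple(base)
                        improved = True
                if improved:
                    break
            if not improved:
                break
        dev = _position_deviation(counts, reps)
        if dev < best_dev:
            best_dev = dev
            best_assign = list(assigned)
        if best_dev <= 1:
            break
    assert best_assign is not None
    return best_assign


def generate_design(spec: DesignSpec) -> TrialDesign:
    """Generate a sequentially balanced, approximately A-optimal design.

    Deterministic for a given ``spec.seed``. See module docstring for the
    criteria; the construction is greedy build + Kirchhoff local search +
    position balancing.
    """
    t, n = spec.n_options, spec.n_packages
    rng = np.random.default_rng(spec.seed)
    blocks = _greedy_blocks(t, n, rng)
    if t > 3:
        _local_search(blocks, t, n, rng)
    ordered_blocks = _assign_positions(blocks, t, rng)
    packages = tuple(
        Package(
            package_id=i + 1,
            options=tuple(spec.option_names[o] for o in block),
        )
        for i, block in enumerate(ordered_blocks)
    )
    return TrialDesign(spec=spec, packages=packages)


def validate_design(design: TrialDesign) -> DesignDiagnostics:
    """Compute balance and connectivity diagnostics; reports, never raises."""
    names = design.option_names
    index = {name: i for i, name in enumerate(names)}
    t = len(names)
    reps = np.zeros(t, dtype=int)
    pos_counts = np.zeros((t, 3), dtype=int)
    no_repeats = True
    block_sizes = []
    for pkg in design.packages:
        block_sizes.append(len(pkg.options))
        if len(set(pkg.options)) != len(pkg.options):
            no_repeats = False
        for p, name in enumerate(pkg.options):
            reps[index[name]] += 1
            pos_counts[index[name], p] += 1

    prefix = _prefix_imbalance(
        [tuple(index[o] for o in pkg.options) for pkg in design.packages], t
    )
    graph = concurrence_graph(design)
    kf = kirchhoff_index(graph)
    return DesignDiagnostics(
        replication_counts={name: int(reps[i]) for i, name in enumerate(names)},
        position_counts={
            name: tuple(int(c) for c in pos_counts[i]) for i, name in enumerate(names)
        },
        max_position_deviation=_position_deviation(pos_counts, reps),
        max_prefix_imbalance=prefix,
        kirchhoff_index=kf,
        connected=math.isfinite(kf),
        no_within_block_repeats=no_repeats,
        block_sizes=tuple(block_sizes),
    )
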