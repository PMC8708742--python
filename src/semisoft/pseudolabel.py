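"""Pseudo-label estimation as an explicit bounded optimization problem.

Instead of iterative self-labeling, the unknown labels ``y_u`` of a small
unlabeled subsample are treated as decision variables of a single bounded
optimization.  The subsample is partitioned into ``M`` equal subsets, one
per diversely initialized NCLELM learner, and a candidate label vector is
scored by four terms:

O1  sum over learners of the labeled-set MSE after refitting learner i on
    subset i with its candidate labels only;
O2  the same but refitting on labeled ∪ subset i (accuracy after inclusion);
O3  the graph-Laplacian smoothness y^T L y of the joint labeled + candidate
    label vector, with Gaussian affinities over the standardized inputs;
O4  the labeled-set MSE of the simple average of the M subset-refit learners.

The combined objective is F = O1 + g1*O2 + g2*O3 + g3*O4, minimized by a
real-coded genetic algorithm within per-label boxes derived from a GPR
confidence interval.

Because the learners' input layers are frozen, every refit is a linear
solve whose solution is linear in the candidate labels; the problem object
precomputes those linear maps once, so a candidate evaluation reduces to a
few small matrix-vector products.  The uncached reference path refits via
:func:`semisoft.elm.fit_nclelm` and is used as the oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .elm import NCLELMModel, assemble_ncl_system, hidden_matrix, ncl_pseudo_inverse
from .gpr import fit_gpr, pseudo_label_bounds

FITNESS_EPS = 1e-12
_BOUND_TOL = 1e-9


@dataclass(frozen=True)
class GAConfig:
    """Real-coded GA settings: tournament selection, BLX-alpha crossover,
    per-gene Gaussian mutation, clipping to bounds, elitism."""

    npop: int = 50
    ngen: int = 50
    tournament_size: int = 2
    crossover_prob: float = 0.9
    crossover_alpha: float = 0.5
    mutation_prob_per_gene: float | None = None  # default 1/n_genes
    mutation_sigma_fraction: float = 0.1
    elitism_count: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.npop < 2 or self.ngen < 1:
            raise ValueError("npop >= 2 and ngen >= 1 required")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        if not 1 <= self.elitism_count < self.npop:
            raise ValueError("need 1 <= elitism_count < npop")


def partition_unlabeled(n_unlabeled: int, m: int, rng_seed: int) -> list[np.ndarray]:
    """Random disjoint split of ``n_unlabeled`` row indices into m equal subsets."""
    if n_unlabeled % m != 0:
        raise ValueError(
            f"{n_unlabeled} unlabeled rows are not divisible into {m} equal subsets; "
            "truncate the random subsample to a multiple of m first"
        )
    p = n_unlabeled // m
    perm = np.random.default_rng(rng_seed).permutation(n_unlabeled)
    return [np.sort(perm[i * p : (i + 1) * p]) for i in range(m)]


def graph_laplacian(X_all: np.ndarray, delta: float) -> np.ndarray:
    """Dense graph Laplacian L = D − W with w_ij = exp(−||xi−xj||²/(2 δ²))."""
    if delta <= 0:
        raise ValueError(f"bandwidth delta must be positive, got {delta}")
    X_all = np.atleast_2d(np.asarray(X_all, dtype=float))
    W = np.exp(-squareform(pdist(X_all, metric="sqeuclidean")) / (2.0 * delta**2))
    return np.diag(W.sum(axis=1)) - W


def median_bandwidth(X_all: np.ndarray) -> float:
    d = pdist(np.atleast_2d(np.asarray(X_all, dtype=float)))
    med = float(np.median(d)) if d.size else 0.0
    if med <= 0:
        raise ValueError("median pairwise distance is zero; cannot set bandwidth")
    return med


def knn_bandwidth(X_all: np.ndarray, k: int = 7) -> float:
    """Mean distance to the k nearest neighbours — a local graph scale.

    With the global median distance as bandwidth, every pair of points is
    strongly connected and the smoothness quadratic form dwarfs the error
    terms by orders of magnitude, so minimizing it just flattens the
    labels.  A neighbour-scale bandwidth keeps the graph effectively
    local, turning the smoothness term into the label-propagation-style
    pull it is meant to be.
    """
    X_all = np.atleast_2d(np.asarray(X_all, dtype=float))
    D = squareform(pdist(X_all))
    k = min(k, D.shape[0] - 1)
    if k < 1:
        raise ValueError("need at least two points for a neighbour bandwidth")
    D.sort(axis=1)
    bw = float(np.mean(D[:, 1 : k + 1]))
    if bw <= 0:
        raise ValueError("degenerate inputs: zero neighbour distances")
    return bw


class PLOProblem:
    """A fully assembled pseudo-labeling optimization problem.

    Chromosome layout is subset-major: genes ``[i*P:(i+1)*P]`` are the
    candidate labels of subset ``i`` in partition order.  ``gene_rows[g]``
    maps gene ``g`` back to its row in ``unlabeled_X``.
    """

    def __init__(
        self,
        labeled_X: np.ndarray,
        labeled_y: np.ndarray,
        unlabeled_X: np.ndarray,
        models: list[NCLELMModel],
        gammas: tuple[float, float, float],
        partition: list[np.ndarray],
        y_min: np.ndarray,
        y_max: np.ndarray,
        laplacian: np.ndarray,
    ):
        self.labeled_X = np.atleast_2d(np.asarray(labeled_X, dtype=float))
        self.labeled_y = np.asarray(labeled_y, dtype=float).ravel()
        self.unlabeled_X = np.atleast_2d(np.asarray(unlabeled_X, dtype=float))
        self.models = list(models)
        self.gammas = tuple(float(g) for g in gammas)
        if any(g < 0 for g in self.gammas):
            raise ValueError("gamma weights must be non-negative")
        self.partition = [np.asarray(p, dtype=int) for p in partition]
        self.m = len(self.models)
        if len(self.partition) != self.m:
            raise ValueError("one partition subset per model is required")
        self.gene_rows = np.concatenate(self.partition)
        u = self.unlabeled_X.shape[0]
        if sorted(self.gene_rows.tolist()) != list(range(u)):
            raise ValueError("partition must cover every unlabeled row exactly once")
        self.n_genes = u
        self.p = u // self.m
        # bounds arrive in unlabeled-row order; store in gene order
        self.y_min = np.asarray(y_min, dtype=float)[self.gene_rows]
        self.y_max = np.asarray(y_max, dtype=float)[self.gene_rows]
        if not np.all(self.y_min < self.y_max):
            raise ValueError("require y_min < y_max element-wise")
        self.laplacian = np.asarray(laplacian, dtype=float)
        n_all = self.labeled_X.shape[0] + u
        if self.laplacian.shape != (n_all, n_all):
            raise ValueError("laplacian must cover labeled + unlabeled inputs")
        self._build_caches()

    # -- cached linear maps -------------------------------------------------
    def _refit_map(self, model: NCLELMModel, X_train: np.ndarray) -> np.ndarray:
        """Matrix mapping a training label vector to the refit model's
        predictions on the labeled set (min-norm NCL solve baked in)."""
        H_tr = [hidden_matrix(mem, X_train) for mem in model.members]
        G, _ = assemble_ncl_system(H_tr, np.zeros(X_train.shape[0]), model.lam)
        P = ncl_pseudo_inverse(G)
        B = np.vstack([H.T for H in H_tr])           # (N*node, n_train)
        H_l = [hidden_matrix(mem, self.labeled_X) for mem in model.members]
        A = np.hstack(H_l) / model.n_elm             # (L, N*node)
        return A @ (P @ B)                           # (L, n_train)

    def _build_caches(self):
        L = self.labeled_X.shape[0]
        self._map_pl = []       # (L, P): subset labels -> labeled-set predictions
        self._fix_lpl = []      # (L,): labeled-label contribution of the union refit
        self._var_lpl = []      # (L, P): subset-label contribution of the union refit
        for i, model in enumerate(self.models):
            X_sub = self.unlabeled_X[self.partition[i]]
            self._map_pl.append(self._refit_map(model, X_sub))
            M_un = self._refit_map(model, np.vstack([self.labeled_X, X_sub]))
            self._fix_lpl.append(M_un[:, :L] @ self.labeled_y)
            self._var_lpl.append(M_un[:, L:])

    # -- candidate handling -------------------------------------------------
    def check_bounds(self, y_u: np.ndarray) -> np.ndarray:
        y_u = np.asarray(y_u, dtype=float).ravel()
        if y_u.shape[0] != self.n_genes:
            raise ValueError(f"candidate has {y_u.shape[0]} genes, expected {self.n_genes}")
        if np.any(y_u < self.y_min - _BOUND_TOL) or np.any(y_u > self.y_max + _BOUND_TOL):
            raise ValueError("candidate pseudo labels violate the search bounds")
        return y_u

    def subset_labels(self, y_u: np.ndarray, i: int) -> np.ndarray:
        return y_u[i * self.p : (i + 1) * self.p]

    def labels_in_row_order(self, y_u: np.ndarray) -> np.ndarray:
        out = np.empty(self.n_genes)
        out[self.gene_rows] = y_u
        return out

    @property
    def bounds_midpoint(self) -> np.ndarray:
        return 0.5 * (self.y_min + self.y_max)

    # -- objective terms ----------------------------------------------------
    def _pl_predictions(self, y_u: np.ndarray) -> list[np.ndarray]:
        return [
            self._map_pl[i] @ self.subset_labels(y_u, i) for i in range(self.m)
        ]

    def objective_o1(self, y_u: np.ndarray) -> float:
        y_u = self.check_bounds(y_u)
        return float(
            sum(np.mean((p - self.labeled_y) ** 2) for p in self._pl_predictions(y_u))
        )

    def objective_o2(self, y_u: np.ndarray) -> float:
        y_u = self.check_bounds(y_u)
        total = 0.0
        for i in range(self.m):
            pred = self._fix_lpl[i] + self._var_lpl[i] @ self.subset_labels(y_u, i)
            total += np.mean((pred - self.labeled_y) ** 2)
        return float(total)

    def objective_o3(self, y_u: np.ndarray) -> float:
        y_u = self.check_bounds(y_u)
        y = np.concatenate([self.labeled_y, self.labels_in_row_order(y_u)])
        return float(y @ self.laplacian @ y)

    def objective_o4(self, y_u: np.ndarray) -> float:
        y_u = self.check_bounds(y_u)
        ens = np.mean(self._pl_predictions(y_u), axis=0)
        return float(np.mean((ens - self.labeled_y) ** 2))

    def combined_objective(self, y_u: np.ndarray) -> float:
        """F = O1 + g1 O2 + g2 O3 + g3 O4, sharing the subset refits of O1/O4."""
        y_u = self.check_bounds(y_u)
        g1, g2, g3 = self.gammas
        preds = self._pl_predictions(y_u)
        o1 = sum(np.mean((p - self.labeled_y) ** 2) for p in preds)
        o4 = np.mean((np.mean(preds, axis=0) - self.labeled_y) ** 2)
        total = o1 + g3 * o4
        if g1 > 0:
            total += g1 * self.objective_o2(y_u)
        if g2 > 0:
            total += g2 * self.objective_o3(y_u)
        return float(total)


def build_plo_problem(
    labeled_X: np.ndarray,
    labeled_y: np.ndarray,
    unlabeled_X: np.ndarray,
    models: list[NCLELMModel],
    gammas: tuple[float, float, float],
    partition_seed: int,
    delta: float | str = "knn",
    ci_level: float = 0.95,
) -> PLOProblem:
    """Assemble a PLOProblem: partition, GPR bounds, Laplacian, caches.

    Inputs are expected already standardized (the pipeline scales them with
    labeled ∪ unlabeled statistics).  The graph bandwidth ``delta`` may be
    a number, ``'knn'`` (mean 7-nearest-neighbour distance, the default)
    or ``'median'`` (global median pairwise distance).
    """
    labeled_X = np.atleast_2d(np.asarray(labeled_X, dtype=float))
    unlabeled_X = np.atleast_2d(np.asarray(unlabeled_X, dtype=float))
    m = len(models)
    partition = partition_unlabeled(unlabeled_X.shape[0], m, partition_seed)
    gpr = fit_gpr(labeled_X, labeled_y)
    y_min, y_max = pseudo_label_bounds(gpr, unlabeled_X, ci_level)
    X_all = np.vstack([labeled_X, unlabeled_X])
    if delta == "knn":
        bw = knn_bandwidth(X_all)
    elif delta == "median":
        bw = median_bandwidth(X_all)
    else:
        bw = float(delta)
    lap = graph_laplacian(X_all, bw)
    return PLOProblem(
        labeled_X, labeled_y, unlabeled_X, models, gammas, partition,
        y_min, y_max, lap,
    )


# -- objective wrappers matching the functional surface ----------------------

def objective_o1(problem: PLOProblem, y_u) -> float:
    return problem.objective_o1(y_u)


def objective_o2(problem: PLOProblem, y_u) -> float:
    return problem.objective_o2(y_u)


def objective_o3(problem: PLOProblem, y_u) -> float:
    return problem.objective_o3(y_u)


def objective_o4(problem: PLOProblem, y_u) -> float:
    return problem.objective_o4(y_u)


def combined_objective(problem: PLOProblem, y_u) -> float:
    return problem.combined_objective(y_u)


def scale_balanced_gammas(problem: PLOProblem) -> tuple[float, float, float]:
    """Trade-off weights that equalize the four terms at the search-box midpoint.

    The raw terms live on very different scales (the smoothness quadratic
    form grows with the graph size while the MSE terms stay O(noise^2)), so
    a standard scalarization heuristic is applied: gamma_i = O1(mid)/O_i(mid)
    evaluated once at the midpoint candidate, making each weighted term
    start from the same magnitude.
    """
    mid = problem.bounds_midpoint
    o1 = problem.objective_o1(mid)
    terms = (
        problem.objective_o2(mid),
        problem.objective_o3(mid),
        problem.objective_o4(mid),
    )
    return tuple(o1 / t if t > 0 else 0.0 for t in terms)


def fitness(F: float) -> float:
    """Reciprocal fitness 1/(F + eps); larger is better, finite at F = 0."""
    if F < 0:
        raise RuntimeError(f"objective values must be non-negative, got {F}")
    return 1.0 / (F + FITNESS_EPS)


def run_ga(
    problem: PLOProblem, config: GAConfig
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize the combined objective with a bounded real-coded GA.

    Returns the best candidate ever seen, its objective value and the
    per-generation best-so-far history (length ngen + 1, non-increasing by
    elitism).  Fully deterministic under ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    lo, hi = problem.y_min, problem.y_max
    span = hi - lo
    n = problem.n_genes
    p_mut = (
        config.mutation_prob_per_gene
        if config.mutation_prob_per_gene is not None
        else 1.0 / n
    )
    sigma = config.mutation_sigma_fraction * span

    pop = rng.uniform(lo, hi, size=(config.npop, n))
    F = np.array([problem.combined_objective(ind) for ind in pop])
    best_i = int(np.argmin(F))
    best_x, best_F = pop[best_i].copy(), float(F[best_i])
    history = [best_F]

    def tournament() -> int:
        idx = rng.integers(0, config.npop, size=config.tournament_size)
        return int(idx[np.argmin(F[idx])])

    for _ in range(config.ngen):
        elite_idx = np.argsort(F)[: config.elitism_count]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < config.npop:
            p1, p2 = pop[tournament()], pop[tournament()]
            c1, c2 = p1.copy(), p2.copy()
            if rng.random() < config.crossover_prob:
                cmin = np.minimum(p1, p2)
                cmax = np.maximum(p1, p2)
                ext = config.crossover_alpha * (cmax - cmin)
                c1 = rng.uniform(cmin - ext, cmax + ext)
                c2 = rng.uniform(cmin - ext, cmax + ext)
            for c in (c1, c2):
                if len(children) >= config.npop:
                    break
                mask = rng.random(n) < p_mut
                if mask.any():
                    c[mask] += rng.normal(0.0, sigma[mask])
                children.append(np.clip(c, lo, hi))
        pop = np.array(children)
        F = np.array([problem.combined_objective(ind) for ind in pop])
        gen_best = int(np.argmin(F))
        if F[gen_best] < best_F:
            best_x, best_F = pop[gen_best].copy(), float(F[gen_best])
        history.append(best_F)

    return best_x, best_F, np.array(history)
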