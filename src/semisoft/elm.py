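"""Extreme learning machines and their negative-correlation ensembles.

An extreme learning machine (ELM) is a single-hidden-layer network whose
input weights and hidden biases are drawn at random and then frozen; only
the output weights are trained, by a minimum-norm least-squares solve
against the hidden-layer response matrix ``H``.

Negative correlation learning (NCL) trains ``N_ELM`` such networks jointly.
Each member ``n`` minimizes

    e_n(beta_n) = 1/2 ( ||H_n beta_n - y||^2 - lambda ||H_n beta_n - f_ens||^2 )

where ``f_ens`` is the simple average of the member outputs and ``lambda``
in [0, 1] trades training accuracy against decorrelation of the member
errors.  Setting every gradient to zero yields one block linear system over
all output-weight vectors, solved here in closed form: the diagonal blocks
are ``[1 - lambda((N-1)/N)^2] H_n^T H_n`` and the off-diagonal blocks are
``lambda (N-1)/N^2 H_n^T H_m``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Condition-number threshold above which a solve is flagged as ill-conditioned.
COND_LIMIT = 1e12


def _readonly(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class ELMMember:
    """One sigmoid-activation ELM with frozen random input layer.

    ``input_weights`` has shape (d, n_node); ``biases`` has length n_node.
    ``output_weights`` is ``None`` until fitted.  The input layer is
    immutable: refitting only ever replaces ``output_weights``.
    """

    input_weights: np.ndarray
    biases: np.ndarray
    output_weights: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "input_weights", _readonly(self.input_weights))
        object.__setattr__(self, "biases", _readonly(self.biases))
        if self.output_weights is not None:
            object.__setattr__(self, "output_weights", _readonly(self.output_weights))

    @property
    def d(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_node(self) -> int:
        return self.input_weights.shape[1]

    @property
    def is_fitted(self) -> bool:
        return self.output_weights is not None


@dataclass(frozen=True)
class NCLELMModel:
    """An ensemble of ELM members jointly trained by negative correlation.

    Prediction is the simple average of the member outputs.
    """

    members: tuple[ELMMember, ...]
    lam: float = 0.6

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(self.members))
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")
        dims = {(m.d, m.n_node) for m in self.members}
        if len(dims) > 1:
            raise ValueError("all members must share input dimension and node count")

    @property
    def n_elm(self) -> int:
        return len(self.members)

    @property
    def is_fitted(self) -> bool:
        return all(m.is_fitted for m in self.members)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def init_elm(d: int, n_node: int, rng_seed: int) -> ELMMember:
    """Draw a fresh member: weights and biases i.i.d. uniform on [-1, 1]."""
    if d < 1 or n_node < 1:
        raise ValueError(f"d and n_node must be positive, got d={d}, n_node={n_node}")
    rng = np.random.default_rng(rng_seed)
    w = rng.uniform(-1.0, 1.0, size=(d, n_node))
    b = rng.uniform(-1.0, 1.0, size=n_node)
    return ELMMember(input_weights=w, biases=b)


def init_nclelm(d: int, n_node: int, n_elm: int, lam: float, rng_seed: int) -> NCLELMModel:
    """Create an unfitted NCL ensemble of ``n_elm`` fresh members."""
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_elm)
    return NCLELMModel(members=tuple(init_elm(d, n_node, int(s)) for s in seeds), lam=lam)


def hidden_matrix(member: ELMMember, X: np.ndarray) -> np.ndarray:
    """Hidden-layer response ``H`` with entries g(w_i . x_j + b_i) in (0, 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != member.d:
        raise ValueError(
            f"X has {X.shape[1]} columns but member expects {member.d} inputs"
        )
    return sigmoid(X @ member.input_weights + member.biases)


def fit_elm(member: ELMMember, X: np.ndarray, y: np.ndarray) -> ELMMember:
    """Set output weights to the minimum-norm least-squares solution of H beta = y."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} rows of X but {y.shape[0]} targets")
    H = hidden_matrix(member, X)
    beta, *_ = np.linalg.lstsq(H, y, rcond=None)
    return replace(member, output_weights=beta)


def predict_elm(member: ELMMember, X: np.ndarray) -> np.ndarray:
    if not member.is_fitted:
        raise RuntimeError("ELM member has no output weights; fit it first")
    return hidden_matrix(member, X) @ member.output_weights


def ncl_coefficients(n_elm: int, lam: float) -> tuple[float, float]:
    """Diagonal and off-diagonal block coefficients of the NCL system."""
    diag = 1.0 - lam * ((n_elm - 1) / n_elm) ** 2
    off = lam * (n_elm - 1) / n_elm**2
    return diag, off


def assemble_ncl_system(
    H_list: list[np.ndarray], y: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Block matrix ``G`` and right-hand side ``T`` of the joint NCL solve."""
    n_elm = len(H_list)
    diag, off = ncl_coefficients(n_elm, lam)
    blocks = [
        [
            (diag if n == m else off) * (H_list[n].T @ H_list[m])
            for m in range(n_elm)
        ]
        for n in range(n_elm)
    ]
    G = np.block(blocks)
    T = np.concatenate([H.T @ y for H in H_list])
    return G, T


#: Relative singular-value cutoff of the truncated pseudo-inverse.  Directions
#: of the Gram system below this fraction of the largest singular value carry
#: no reliable information (the system is often rank-deficient when the
#: training set is smaller than the total node count) and are dropped rather
#: than jittered — inverting them would amplify numerical null-space noise.
NCL_RCOND = 1e-8


def ncl_pseudo_inverse(G: np.ndarray) -> np.ndarray:
    """Truncated pseudo-inverse of the (symmetric) NCL block matrix.

    Logs a warning when the retained spectrum is still ill-conditioned.
    """
    U, s, Vt = np.linalg.svd(G, hermitian=True)
    keep = s > NCL_RCOND * s[0]
    if s[0] / s[keep][-1] > COND_LIMIT:
        logger.warning(
            "NCL system ill-conditioned (cond=%.3e) after truncation",
            s[0] / s[keep][-1],
        )
    return (Vt.T[:, keep] / s[keep]) @ U[:, keep].T


def solve_ncl_system(G: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum-norm solve of G beta = T via the truncated pseudo-inverse."""
    return ncl_pseudo_inverse(G) @ T


def fit_nclelm(
    members, X: np.ndarray, y: np.ndarray, lam: float
) -> NCLELMModel:
    """Jointly fit all member output weights by the closed-form NCL solve.

    With ``lam = 0`` the blocks decouple and each member receives its
    independent least-squares solution; with a single member the penalty
    vanishes identically.
    """
    if isinstance(members, NCLELMModel):
        members = members.members
    members = tuple(members)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    H_list = [hidden_matrix(m, X) for m in members]
    G, T = assemble_ncl_system(H_list, y, lam)
    beta = solve_ncl_system(G, T)
    n_node = members[0].n_node
    fitted = tuple(
        replace(m, output_weights=beta[i * n_node : (i + 1) * n_node])
        for i, m in enumerate(members)
    )
    return NCLELMModel(members=fitted, lam=lam)


def predict_nclelm(model: NCLELMModel, X: np.ndarray) -> np.ndarray:
    """Simple average of the member predictions."""
    if not model.is_fitted:
        raise RuntimeError("NCLELM model has unfitted members")
    preds = np.stack([predict_elm(m, X) for m in model.members])
    return preds.mean(axis=0)


def refit_output_weights(model: NCLELMModel, X: np.ndarray, y: np.ndarray) -> NCLELMModel:
    """Refit all output weights on new data; the random input layer is untouched."""
    return fit_nclelm(model.members, X, y, model.lam)


def ncl_member_cost(model: NCLELMModel, n: int, X: np.ndarray, y: np.ndarray) -> float:
    """Member cost e_n = 1/2(||H_n b_n - y||^2 - lam ||H_n b_n - f_ens||^2).

    Exposed for gradient/stationarity checks; not used by the solver.
    """
    y = np.asarray(y, dtype=float).ravel()
    outs = np.stack([predict_elm(m, X) for m in model.members])
    f_ens = outs.mean(axis=0)
    fn = outs[n]
    return 0.5 * (np.sum((fn - y) ** 2) - model.lam * np.sum((fn - f_ens) ** 2))
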