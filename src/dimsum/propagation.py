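"""Label diffusion over the damage-weighted interactome.

Node priors Y (normalized GWAS relevance) are spread over the network by the
symmetric-normalized iteration

    F_{t+1} = alpha * W' F_t + (1 - alpha) * Y,      F_0 = Y,

where W' = D^{-1/2} W D^{-1/2} is the degree-normalized edge-weight matrix
and alpha in (0, 1) trades smoothness over the network against fidelity to
the prior (default 0.5).  Because the spectral radius of W' is at most 1,
the iteration contracts with rate alpha and converges to the closed form
F* = (1 - alpha) (I - alpha W')^{-1} Y, which is also provided as an
independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PropagationResult",
    "normalize_adjacency",
    "propagate",
    "closed_form_scores",
]

DEFAULT_ALPHA = 0.5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


def _validate_weight_matrix(m: np.ndarray) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {m.shape}")
    if np.any(m < 0):
        raise ValueError("weight matrix must be nonnegative")
    if not np.allclose(m, m.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(np.diag(m) != 0):
        raise ValueError("weight matrix must have a zero diagonal (no self-loops)")


def normalize_adjacency(m) -> np.ndarray:
    """Symmetric degree normalization W' = D^{-1/2} W D^{-1/2}.

    D(i, i) is the row sum of ``m``.  Rows/columns with zero row sum (isolated
    nodes) map to all-zero rows/columns rather than dividing by zero.  The
    result is symmetric with spectral radius <= 1.

    Accepts dense arrays or scipy sparse matrices; sparse input yields sparse
    output (CSR).
    """
    if sp.issparse(m):
        m = m.tocsr().astype(float)
        if (m != m.T).nnz != 0:
            raise ValueError("weight matrix must be symmetric")
        if m.diagonal().any():
            raise ValueError("weight matrix must have a zero diagonal")
        if m.nnz and m.data.min() < 0:
            raise ValueError("weight matrix must be nonnegative")
        d = np.asarray(m.sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            dinv = np.where(d > 0, 1.0 / np.sqrt(d), 0.0)
        dmat = sp.diags(dinv)
        return (dmat @ m @ dmat).tocsr()
    m = np.asarray(m, dtype=float)
    _validate_weight_matrix(m)
    d = m.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(d), 0.0)
    return dinv[:, None] * m * dinv[None, :]


@dataclass
class PropagationResult:
    """Converged relevance vector with its iteration trace."""

    scores: np.ndarray  # F, one entry per node
    alpha: float
    iterations: int
    converged: bool
    residual_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("propagated scores must be finite")


def propagate(
    w_norm,
    y: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PropagationResult:
    """Iterate F_{t+1} = alpha W' F_t + (1 - alpha) Y until convergence.

    Stops when the L2 norm of the update falls below ``tol`` or after
    ``max_iter`` iterations; in the latter case the result is flagged
    ``converged=False`` rather than raising.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    y = np.asarray(y, dtype=float)
    f = y.copy()
    residuals: list[float] = []
    converged = False
    iterations = 0
    for _ in range(max_iter):
        f_next = alpha * (w_norm @ f) + (1.0 - alpha) * y
        if sp.issparse(f_next):  # pragma: no cover - sparse matvec returns dense
            f_next = np.asarray(f_next).ravel()
        r = float(np.linalg.norm(f_next - f))
        residuals.append(r)
        f = f_next
        iterations += 1
        if r < tol:
            converged = True
            break
    return PropagationResult(
        scores=f, alpha=alpha, iterations=iterations, converged=converged,
        residual_trace=residuals,
    )


def closed_form_scores(w_norm, y: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Fixed point F* = (1 - alpha) (I - alpha W')^{-1} Y via a dense solve.

    Exists whenever alpha < 1 because the spectral radius of W' is <= 1.
    Used as the independent check on the iterative solver.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if sp.issparse(w_norm):
        w_norm = w_norm.toarray()
    w_norm = np.asarray(w_norm, dtype=float)
    n = w_norm.shape[0]
    return np.linalg.solve(np.eye(n) - alpha * w_norm, (1.0 - alpha) * np.asarray(y, dtype=float))
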