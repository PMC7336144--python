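"""Convex nonnegative fitting of streamline contributions.

Solves ``min_{x >= 0} 0.5 ||A x - y||^2`` where A is the stick–zeppelin–
ball system operator and y the stacked, b0-normalised signal.  The fitted
intra-axonal coefficients are per-streamline signal-fraction densities
(1/mm); streamlines whose weight falls at (numerical) zero are judged
unnecessary to explain the signal and are filtered out.

Solver: monotone FISTA (accelerated projected gradient) started at x = 0
with a fixed 1/L step, followed by an optional polish step that re-solves
the unconstrained least-squares problem on the active support and accepts
the refinement only when it is feasible and lowers the objective.  The
whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse

from .errors import ContractError, DataError, ParameterError
from .model import SystemMatrix
from .phantom import Tractogram

__all__ = ["FitResult", "fit_weights", "filter_tractogram"]

#: default cut below which a fitted streamline is considered filtered out
DEFAULT_WEIGHT_THRESHOLD = 1e-10


@dataclass
class FitResult:
    """Outcome of the nonnegative fit.

    ``objective_history`` holds 0.5||Ax-y||^2 per accepted iterate and is
    non-increasing by construction.
    """

    streamline_weights: np.ndarray
    ec_weights: np.ndarray
    iso_weights: np.ndarray
    residual_norm: float
    n_iterations: int
    converged: bool
    objective_history: np.ndarray = field(repr=False,
                                          default_factory=lambda: np.empty(0))

    @property
    def x(self) -> np.ndarray:
        return np.concatenate([self.streamline_weights, self.ec_weights,
                               self.iso_weights])


def _operator_norm_sq(A, n_iter: int = 30, seed_vec=None) -> float:
    """||A||_2^2 by power iteration on A^T A (deterministic start)."""
    n = A.shape[1]
    v = np.ones(n) / np.sqrt(n) if seed_vec is None else seed_vec
    lam = 0.0
    for _ in range(n_iter):
        w = A.T @ (A @ v)
        lam = float(np.linalg.norm(w))
        if lam == 0:
            return 0.0
        v = w / lam
    return lam


def _polish(A, y, x: np.ndarray) -> np.ndarray:
    """Least-squares refit on the active support; returns a candidate
    that is accepted by the caller only if feasible and better."""
    support = np.flatnonzero(x > 0)
    if support.size == 0:
        return x
    As = A[:, support]
    if sparse.issparse(As):
        gram = (As.T @ As).toarray()
        rhs = As.T @ y
    else:
        gram = As.T @ As
        rhs = As.T @ y
    try:
        z = linalg.solve(gram, rhs, assume_a="pos")
    except linalg.LinAlgError:
        z, *_ = linalg.lstsq(gram, rhs)
    z = np.clip(z, 0.0, None)
    out = np.zeros_like(x)
    out[support] = z
    return out


def fit_weights(system_matrix, signal, max_iter: int = 1000,
                tol: float = 1e-8, polish: bool = True) -> FitResult:
    """Fit nonnegative compartment coefficients to a signal vector.

    Parameters
    ----------
    system_matrix:
        A :class:`~tractofit.model.SystemMatrix`, or any 2-D matrix /
        sparse matrix (then all coefficients are reported in
        ``streamline_weights`` and the other blocks are empty).
    signal:
        Stacked signal; a 4-D volume is flattened in the system matrix's
        row order (voxel-major, measurement-minor).
    tol:
        Convergence threshold on the relative objective decrease.
    """
    if isinstance(system_matrix, SystemMatrix):
        A = system_matrix.A
        slices = system_matrix.block_slices()
    else:
        A = system_matrix if sparse.issparse(system_matrix) else \
            np.asarray(system_matrix, dtype=float)
        n = A.shape[1]
        slices = (slice(0, n), slice(n, n), slice(n, n))
    y = np.asarray(signal, dtype=float).ravel()
    if A.shape[0] != y.size:
        raise ContractError(
            f"matrix rows {A.shape[0]} != signal length {y.size}")
    if not np.all(np.isfinite(y)):
        raise DataError("signal contains non-finite values")
    if max_iter < 1 or tol <= 0:
        raise ParameterError("max_iter >= 1 and tol > 0 required")

    n = A.shape[1]
    x = np.zeros(n)
    f = 0.5 * float(y @ y)
    history = [f]
    converged = False
    it = 0
    if n > 0 and f > 0:
        L = _operator_norm_sq(A)
        if L == 0:
            converged = True
        else:
            step = 1.0 / L
            w = x.copy()
            t = 1.0
            for it in range(1, max_iter + 1):
                grad = A.T @ (A @ w - y)
                zeta = np.clip(w - step * grad, 0.0, None)
                r = A @ zeta - y
                f_zeta = 0.5 * float(r @ r)
                # monotone acceptance: keep the better of zeta and x_{k-1};
                # a rejected step restarts the momentum (classical restart)
                if f_zeta <= f:
                    rel = (f - f_zeta) / max(f_zeta, 1e-300)
                    t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
                    w = zeta + ((t - 1.0) / t_next) * (zeta - x)
                    x, f, t = zeta, f_zeta, t_next
                    history.append(f)
                    if rel < tol:
                        converged = True
                        break
                else:
                    w = x.copy()
                    t = 1.0
                    history.append(f)
            if polish:
                cand = _polish(A, y, x)
                r = A @ cand - y
                f_cand = 0.5 * float(r @ r)
                if f_cand <= history[-1] + 1e-15:
                    x, f = cand, f_cand
                    history.append(f_cand)
    else:
        converged = True

    resid = float(np.linalg.norm(A @ x - y)) if n > 0 else float(np.linalg.norm(y))
    return FitResult(
        streamline_weights=x[slices[0]].copy(),
        ec_weights=x[slices[1]].copy(),
        iso_weights=x[slices[2]].copy(),
        residual_norm=resid,
        n_iterations=it,
        converged=converged,
        objective_history=np.asarray(history),
    )


def filter_tractogram(tractogram: Tractogram, fit_result: FitResult,
                      weight_threshold: float = DEFAULT_WEIGHT_THRESHOLD
                      ) -> tuple[Tractogram, np.ndarray]:
    """Keep streamlines whose fitted weight exceeds the threshold.

    Returns the filtered tractogram (ground-truth metadata re-indexed
    consistently) and the aligned kept weights."""
    if weight_threshold < 0:
        raise ParameterError("weight_threshold must be nonnegative")
    w = np.asarray(fit_result.streamline_weights, dtype=float)
    if w.size != len(tractogram):
        raise ContractError("weights not aligned with tractogram")
    keep = np.flatnonzero(w > weight_threshold)
    out = Tractogram(
        streamlines=[tractogram.streamlines[i] for i in keep],
        true_weights=tractogram.true_weights[keep],
        spurious=tractogram.spurious[keep],
        endpoint_nodes=[tractogram.endpoint_nodes[i] for i in keep],
    )
    return out, w[keep]
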