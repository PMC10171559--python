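"""Principal component pursuit: low-rank + sparse matrix decomposition.

Solves

    minimize  ||L||_* + lam * ||S||_1   subject to  Y = L + S

by the inexact augmented Lagrangian method (singular-value thresholding
for L, soft thresholding for S, growing penalty). With the default
lam = 1 / sqrt(max(m, n)) the program provably recovers a planted
low-rank matrix corrupted in a small fraction of entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConvergenceError", "PcpResult", "principal_component_pursuit", "default_pcp_weight"]


class ConvergenceError(RuntimeError):
    """Iteration budget exhausted before the feasibility tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class PcpResult:
    low_rank: np.ndarray
    sparse: np.ndarray
    n_iter: int
    residual: float


def default_pcp_weight(shape: tuple[int, int]) -> float:
    """The standard sparsity weight 1/sqrt(max dimension)."""
    return 1.0 / np.sqrt(max(shape))


def _soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def _svt(x: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft thresholding."""
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    sv = np.maximum(sv - tau, 0.0)
    keep = sv > 0
    return (u[:, keep] * sv[keep]) @ vt[keep]


def principal_component_pursuit(
    y: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> PcpResult:
    """Decompose ``y`` into low-rank plus sparse parts.

    Parameters
    ----------
    y
        Finite real matrix.
    lam
        Entrywise-l1 weight; defaults to 1/sqrt(max(m, n)).
    tol
        Relative Frobenius feasibility tolerance ||Y-L-S||_F / ||Y||_F.
    max_iter
        Iteration budget; exceeding it raises :class:`ConvergenceError`
        carrying the final residual.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("PCP input must be a matrix")
    if not np.all(np.isfinite(y)):
        raise ValueError("PCP input must be finite")
    if lam is None:
        lam = default_pcp_weight(y.shape)
    if lam <= 0:
        raise ValueError("lam must be positive")
    norm_y = np.linalg.norm(y)
    if norm_y == 0:
        return PcpResult(np.zeros_like(y), np.zeros_like(y), 0, 0.0)

    # dual initialization and penalty schedule of the inexact ALM
    norm_two = np.linalg.norm(y, 2)
    norm_inf = np.abs(y).max() / lam
    dual = y / max(norm_two, norm_inf)
    mu = 1.25 / norm_two
    mu_bar = mu * 1e7
    rho = 1.5

    sparse = np.zeros_like(y)
    low_rank = np.zeros_like(y)
    residual = np.inf
    for it in range(1, max_iter + 1):
        low_rank = _svt(y - sparse + dual / mu, 1.0 / mu)
        sparse = _soft_threshold(y - low_rank + dual / mu, lam / mu)
        gap = y - low_rank - sparse
        dual = dual + mu * gap
        mu = min(mu * rho, mu_bar)
        residual = np.linalg.norm(gap) / norm_y
        if residual < tol:
            return PcpResult(low_rank, sparse, it, residual)
    raise ConvergenceError(
        f"PCP did not reach tol={tol} in {max_iter} iterations "
        f"(residual {residual:.3e})",
        residual=float(residual),
    )
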