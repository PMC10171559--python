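"""FC normalizations: Fisher Z, degree normalization, or none.

Fisher Z, z = 0.5*[ln(1+r) - ln(1-r)], is the variance-stabilizing
transform of a Pearson correlation; it is elementwise, odd, and
strictly increasing, so it preserves the rank order of FC entries.

Degree normalization treats |A| (absolute correlations, self-loops
removed) as a weighted adjacency matrix and rescales it symmetrically
by node strength: A_degree = B^(-1/2) |A| B^(-1/2) with
b_i = sum_j |A_ij| (j != i). Every normalized entry lies in [0, 1]
because b_i >= |A_ij| for all j; note that the sign of the original
correlations is deliberately discarded.

Both operate on the n x n matrix; vectorization comes afterwards (for
the elementwise Fisher Z the order would not matter, for degree
normalization it does).
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortError, FcMatrix

__all__ = ["fisher_z", "degree_normalize", "apply_normalization", "NORMALIZATIONS"]

#: clipping applied to |r| before the log, so r = +/-1 maps to a large
#: finite value instead of +/-inf without affecting ordering
FISHER_CLIP_EPS = 1e-7

NORMALIZATIONS = ("none", "fisher_z", "degree")


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Elementwise Fisher Z transform of correlation values.

    Values with |r| > 1 beyond numerical tolerance are rejected; exact
    +/-1 is clipped to 1 - 1e-7 first.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-9):
        bad = float(np.max(np.abs(arr)))
        raise CohortError(f"correlation magnitude {bad} exceeds 1")
    clipped = np.clip(arr, -1.0 + FISHER_CLIP_EPS, 1.0 - FISHER_CLIP_EPS)
    out = 0.5 * (np.log1p(clipped) - np.log1p(-clipped))
    if np.isscalar(r):
        return float(out)
    return out


def degree_normalize(fc: FcMatrix) -> FcMatrix:
    """Degree-normalize a raw FC matrix: B^(-1/2) |A| B^(-1/2), zero diagonal.

    Raises
    ------
    CohortError
        If any node has degree zero (all its off-diagonal correlations
        exactly 0); the node is named in the message.
    """
    if fc.normalization != "raw":
        raise CohortError(
            f"degree normalization expects a raw FC matrix, got "
            f"{fc.normalization!r}"
        )
    a = np.abs(fc.values).astype(float)
    np.fill_diagonal(a, 0.0)
    degree = a.sum(axis=1)
    dead = np.flatnonzero(degree == 0)
    if dead.size:
        names = [fc.node_ids[i] for i in dead]
        raise CohortError(
            f"node(s) {names} have zero degree; degree normalization "
            "is undefined"
        )
    inv_sqrt = 1.0 / np.sqrt(degree)
    out = a * inv_sqrt[:, None] * inv_sqrt[None, :]
    out = (out + out.T) / 2.0
    return FcMatrix(values=out, node_ids=fc.node_ids, normalization="degree")


def apply_normalization(fc: FcMatrix, method: str) -> FcMatrix:
    """Dispatch on the normalization method; ``none`` is the identity.

    Re-normalizing an already-normalized matrix is an error: the
    transforms are defined on raw Pearson correlations only.
    """
    if method not in NORMALIZATIONS:
        raise CohortError(
            f"unknown normalization {method!r}; choose from {NORMALIZATIONS}"
        )
    if method == "none":
        return fc
    if fc.normalization != "raw":
        raise CohortError(
            f"matrix is already {fc.normalization!r}-normalized"
        )
    if method == "fisher_z":
        values = fc.values.copy()
        n = values.shape[0]
        off = ~np.eye(n, dtype=bool)
        values[off] = fisher_z(values[off])
        return FcMatrix(
            values=values, node_ids=fc.node_ids, normalization="fisher_z"
        )
    return degree_normalize(fc)
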