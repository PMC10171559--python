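"""Identifiability scoring: Idiff, Overlap and their ratio.

Differential identifiability
    For every unordered session pair (i, j) build the p x p
    identifiability matrix C^{i,j} whose (a, b) entry is the Pearson
    correlation between subject a's session-i vector and subject b's
    session-j vector. Iself^{i,j} is the mean of the diagonal (same
    subject, different sessions), Iothers^{i,j} the mean off-diagonal
    (different subjects); Idiff^{i,j} = 100 * (Iself - Iothers). The
    reported Idiff is the average over all s̃ = s(s-1)/2 pairs. A
    perfectly separable cohort scores 100; the theoretical range is
    [-200, 200].

Overlap
    Pool the within-subject and between-subject Pearson correlations of
    all p*s scan vectors (strict upper triangles of the diagonal s x s
    blocks of the ps x ps correlation matrix, and the full blocks above
    the block diagonal, respectively — the trivial unit
    self-correlations are excluded and each unordered scan pair counts
    once). The overlap count is the minimal number of misclassified
    values over all thresholds t under the rule "value >= t is
    within-subject". The optimal threshold is learned on training data
    and reused, fixed, at test time. Ideal value: 0.

Ratio
    Idiff / max(Overlap, 1). Overlap is an integer count, so flooring
    the denominator at 1 keeps the ratio finite on perfectly separated
    cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortError, CohortMatrix

__all__ = [
    "IdiffResult",
    "OverlapResult",
    "IdentifiabilityReport",
    "identifiability_matrix",
    "idiff",
    "within_between_values",
    "overlap_train",
    "overlap_test",
    "ratio",
    "evaluate_train",
    "evaluate_test",
]


@dataclass(frozen=True)
class IdiffResult:
    iself: float
    iothers: float
    idiff: float
    n_session_pairs: int


@dataclass(frozen=True)
class OverlapResult:
    threshold: float
    overlap: int
    within: np.ndarray
    between: np.ndarray


@dataclass(frozen=True)
class IdentifiabilityReport:
    """One scored (network, normalization, extractor, parameters) cell."""

    iself: float
    iothers: float
    idiff: float
    overlap: int
    threshold: float
    ratio: float
    phase: str  # "train" or "test"
    n_session_pairs: int

    def as_dict(self) -> dict:
        return {
            "iself": self.iself,
            "iothers": self.iothers,
            "idiff": self.idiff,
            "overlap": self.overlap,
            "threshold": self.threshold,
            "ratio": self.ratio,
            "phase": self.phase,
            "n_session_pairs": self.n_session_pairs,
        }


def _standardize_columns(mat: np.ndarray, what: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    centered = mat - mat.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise CohortError(
            f"zero-variance column(s) {dead.tolist()} in {what}; "
            "Pearson correlation undefined"
        )
    return centered / norms


def identifiability_matrix(
    session_i: np.ndarray, session_j: np.ndarray
) -> np.ndarray:
    """p x p matrix of cross-session Pearson correlations.

    Entry (a, b) correlates subject a's session-i vector with subject
    b's session-j vector; both inputs are ñ x p with subjects in the
    same column order.
    """
    session_i = np.asarray(session_i, dtype=float)
    session_j = np.asarray(session_j, dtype=float)
    if session_i.shape != session_j.shape:
        raise CohortError(
            f"session matrices differ in shape: "
            f"{session_i.shape} vs {session_j.shape}"
        )
    zi = _standardize_columns(session_i, "session i")
    zj = _standardize_columns(session_j, "session j")
    return np.clip(zi.T @ zj, -1.0, 1.0)


def idiff(sub: CohortMatrix) -> IdiffResult:
    """Pair-averaged Iself, Iothers and Idiff of a (subject-specific) cohort."""
    if sub.p < 2:
        raise CohortError("Idiff needs at least 2 subjects")
    if sub.s < 2:
        raise CohortError("Idiff needs at least 2 sessions (no session pairs)")
    sessions = sub.sessions
    p = sub.p
    off_mask = ~np.eye(p, dtype=bool)
    iselfs, iothers_ = [], []
    for i in range(len(sessions)):
        mat_i = sub.session_matrix(sessions[i])
        for j in range(i + 1, len(sessions)):
            c = identifiability_matrix(mat_i, sub.session_matrix(sessions[j]))
            iselfs.append(float(np.mean(np.diag(c))))
            iothers_.append(float(np.mean(c[off_mask])))
    iself = float(np.mean(iselfs))
    iothers = float(np.mean(iothers_))
    return IdiffResult(
        iself=iself,
        iothers=iothers,
        idiff=100.0 * (iself - iothers),
        n_session_pairs=len(iselfs),
    )


def within_between_values(sub: CohortMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-subject and between-subject scan correlations.

    Within: strict upper triangles of the diagonal s x s blocks of the
    ps x ps scan correlation matrix (p * s(s-1)/2 values). Between: all
    entries of the blocks above the block diagonal (C(p,2) * s^2
    values) — each unordered scan pair exactly once, self-correlations
    never.
    """
    if sub.p < 2 or sub.s < 2:
        raise CohortError("need p >= 2 and s >= 2")
    z = _standardize_columns(sub.values, "cohort")
    corr = np.clip(z.T @ z, -1.0, 1.0)
    s = sub.s
    p = sub.p
    within = []
    between = []
    for a in range(p):
        block_a = slice(a * s, (a + 1) * s)
        iu = np.triu_indices(s, k=1)
        within.append(corr[block_a, block_a][iu])
        for b in range(a + 1, p):
            block_b = slice(b * s, (b + 1) * s)
            between.append(corr[block_a, block_b].ravel())
    return np.concatenate(within), np.concatenate(between)


def _classification_error(
    t: float, within_sorted: np.ndarray, between_sorted: np.ndarray
) -> int:
    """Misclassifications at threshold t under the rule '>= t is within'."""
    miss_within = int(np.searchsorted(within_sorted, t, side="left"))
    miss_between = between_sorted.size - int(
        np.searchsorted(between_sorted, t, side="left")
    )
    return miss_within + miss_between


def optimal_threshold(
    within: np.ndarray, between: np.ndarray
) -> tuple[float, int]:
    """Exhaustive threshold search minimizing the misclassification count.

    Candidates are the midpoints of consecutive distinct pooled values
    plus one point below the minimum and one above the maximum; this
    set realizes every achievable error value. Ties in the minimal
    error are broken toward the smallest threshold.
    """
    within_sorted = np.sort(np.asarray(within, dtype=float).ravel())
    between_sorted = np.sort(np.asarray(between, dtype=float).ravel())
    pooled = np.unique(np.concatenate([within_sorted, between_sorted]))
    candidates = np.concatenate(
        [[pooled[0] - 1.0], (pooled[:-1] + pooled[1:]) / 2.0, [pooled[-1] + 1.0]]
    )
    best_t, best_err = None, None
    for t in candidates:  # increasing, so strict < keeps the smallest tie
        err = _classification_error(float(t), within_sorted, between_sorted)
        if best_err is None or err < best_err:
            best_t, best_err = float(t), err
    return best_t, best_err


def overlap_train(sub: CohortMatrix) -> OverlapResult:
    """Learn the optimal threshold and its overlap count on training data."""
    within, between = within_between_values(sub)
    threshold, overlap = optimal_threshold(within, between)
    return OverlapResult(
        threshold=threshold, overlap=overlap, within=within, between=between
    )


def overlap_test(sub: CohortMatrix, threshold: float) -> int:
    """Overlap count at a fixed (train-learned) threshold; no re-optimization."""
    if not np.isfinite(threshold):
        raise CohortError("threshold must be finite")
    within, between = within_between_values(sub)
    return _classification_error(
        float(threshold), np.sort(within), np.sort(between)
    )


def ratio(idiff_value: float, overlap_count: int) -> float:
    """Idiff / max(Overlap, 1): the joint selection criterion."""
    if overlap_count < 0:
        raise CohortError("overlap count cannot be negative")
    return float(idiff_value) / max(int(overlap_count), 1)


def evaluate_train(sub: CohortMatrix) -> IdentifiabilityReport:
    """Score a training-phase subject-specific matrix (threshold learned)."""
    d = idiff(sub)
    ov = overlap_train(sub)
    return IdentifiabilityReport(
        iself=d.iself,
        iothers=d.iothers,
        idiff=d.idiff,
        overlap=ov.overlap,
        threshold=ov.threshold,
        ratio=ratio(d.idiff, ov.overlap),
        phase="train",
        n_session_pairs=d.n_session_pairs,
    )


def evaluate_test(sub: CohortMatrix, threshold: float) -> IdentifiabilityReport:
    """Score a test-phase matrix at the threshold learned in training."""
    d = idiff(sub)
    ov = overlap_test(sub, threshold)
    return IdentifiabilityReport(
        iself=d.iself,
        iothers=d.iothers,
        idiff=d.idiff,
        overlap=ov,
        threshold=float(threshold),
        ratio=ratio(d.idiff, ov),
        phase="test",
        n_session_pairs=d.n_session_pairs,
    )
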