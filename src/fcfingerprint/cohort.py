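"""Core containers for multi-subject, multi-session functional-connectivity data.

Three containers travel through the whole pipeline:

``RoiTimeSeries``
    one scan's T x n ROI signal matrix, with subject/session identity,
    the sampling interval (TR) and a node-to-network label vector;
``FcMatrix``
    one scan's n x n Pearson correlation matrix (possibly normalized);
``CohortMatrix``
    the global feature matrix Y whose columns are the upper-triangle FC
    vectors of every scan, ordered so that the sessions of each subject
    are contiguous.

``SubjectSpecificMatrix`` is a ``CohortMatrix`` produced by an extractor;
it keeps the same shape and column index as its source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CohortError",
    "RoiTimeSeries",
    "FcMatrix",
    "CohortMatrix",
    "SubjectSpecificMatrix",
]


class CohortError(ValueError):
    """Structural problem with a cohort, scan or FC container."""


@dataclass
class RoiTimeSeries:
    """One scan: a T x n matrix of ROI signals plus identity and labels.

    Parameters
    ----------
    data
        T x n real matrix, rows are time points, columns are ROIs. The
        signal units are arbitrary; Pearson correlation is affine
        invariant per column.
    subject_id, session_id
        Identity of the scan within the cohort.
    dt
        Sampling interval (repetition time) in seconds.
    labels
        Length-n sequence assigning each node to a named network.
    node_ids
        Optional node names; defaults to ``roi000, roi001, ...``.
    """

    data: np.ndarray
    subject_id: str
    session_id: str
    dt: float
    labels: tuple[str, ...]
    node_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise CohortError("time-series data must be a 2-D (T x n) matrix")
        t, n = self.data.shape
        if t < 3:
            raise CohortError(
                f"scan {self.subject_id}/{self.session_id}: T={t} < 3, "
                "correlation is degenerate"
            )
        if self.dt <= 0:
            raise CohortError("sampling interval dt must be positive")
        self.labels = tuple(self.labels)
        if len(self.labels) != n:
            raise CohortError(
                f"labels length {len(self.labels)} != number of ROIs {n}"
            )
        if self.node_ids is None:
            self.node_ids = tuple(f"roi{i:03d}" for i in range(n))
        else:
            self.node_ids = tuple(self.node_ids)
            if len(self.node_ids) != n:
                raise CohortError("node_ids length mismatch")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        return replace(self, data=data)


@dataclass
class FcMatrix:
    """An n x n functional-connectivity matrix with a normalization tag.

    ``normalization`` is one of ``raw`` (Pearson correlations, unit
    diagonal), ``fisher_z`` or ``degree``.
    """

    values: np.ndarray
    node_ids: tuple[str, ...] | None = None
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise CohortError("FC matrix must be square")
        n = self.values.shape[0]
        if n < 2:
            raise CohortError("FC matrix needs at least 2 nodes")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise CohortError("FC matrix must be symmetric")
        if self.normalization == "raw" and not np.allclose(
            np.diag(self.values), 1.0, atol=1e-8
        ):
            raise CohortError("raw FC matrix must have unit diagonal")
        if self.node_ids is None:
            self.node_ids = tuple(f"roi{i:03d}" for i in range(n))
        else:
            self.node_ids = tuple(self.node_ids)
            if len(self.node_ids) != n:
                raise CohortError("node_ids length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def _validate_index(
    index: Sequence[tuple[str, str]], n_cols: int
) -> tuple[tuple[str, str], ...]:
    index = tuple((str(a), str(b)) for a, b in index)
    if len(index) != n_cols:
        raise CohortError(
            f"index has {len(index)} entries for {n_cols} columns"
        )
    if len(set(index)) != len(index):
        raise CohortError("duplicate (subject, session) pairs in index")
    # sessions of each subject must be contiguous and equally many,
    # mirroring the concatenation Y = [Y_1 Y_2 ... Y_p]
    subjects: list[str] = []
    sessions: dict[str, list[str]] = {}
    for sub, ses in index:
        if sub not in sessions:
            subjects.append(sub)
            sessions[sub] = []
        elif subjects[-1] != sub:
            raise CohortError(
                f"sessions of subject {sub!r} are not contiguous in the index"
            )
        sessions[sub].append(ses)
    counts = {len(v) for v in sessions.values()}
    if len(counts) != 1:
        raise CohortError(
            "unbalanced cohort: subjects have unequal session counts "
            f"({sorted((k, len(v)) for k, v in sessions.items())})"
        )
    session_lists = {tuple(v) for v in sessions.values()}
    if len(session_lists) != 1:
        raise CohortError(
            "subjects must share the same ordered session identifiers"
        )
    return index


@dataclass
class CohortMatrix:
    """Global matrix Y: one FC vector per column, subjects contiguous.

    ``values`` is an ñ x (p·s) matrix; ``index`` pairs each column with
    its (subject_id, session_id). Columns belonging to one subject are
    contiguous, all subjects share the same ordered session list.
    """

    values: np.ndarray
    index: tuple[tuple[str, str], ...]
    network: str = "all"
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CohortError("cohort values must be a 2-D matrix")
        self.index = _validate_index(self.index, self.values.shape[1])

    # -- structure -----------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_scans(self) -> int:
        return self.values.shape[1]

    @property
    def subjects(self) -> tuple[str, ...]:
        out: list[str] = []
        for sub, _ in self.index:
            if not out or out[-1] != sub:
                out.append(sub)
        return tuple(out)

    @property
    def sessions(self) -> tuple[str, ...]:
        """Ordered session ids (identical for every subject)."""
        first = self.subjects[0]
        return tuple(ses for sub, ses in self.index if sub == first)

    @property
    def p(self) -> int:
        return len(self.subjects)

    @property
    def s(self) -> int:
        return len(self.sessions)

    # -- views ---------------------------------------------------------
    def columns_of(self, subject: str) -> np.ndarray:
        idx = [i for i, (sub, _) in enumerate(self.index) if sub == subject]
        if not idx:
            raise CohortError(f"unknown subject {subject!r}")
        return np.asarray(idx)

    def subject_blocks(self) -> dict[str, np.ndarray]:
        """Per-subject blocks Y_i (ñ x s), in subject order."""
        return {sub: self.values[:, self.columns_of(sub)] for sub in self.subjects}

    def session_matrix(self, session: str) -> np.ndarray:
        """ñ x p matrix holding one session of every subject."""
        cols = [
            i for i, (_, ses) in enumerate(self.index) if ses == str(session)
        ]
        if len(cols) != self.p:
            raise CohortError(f"session {session!r} missing for some subject")
        return self.values[:, cols]

    def select_sessions(self, sessions: Sequence[str]) -> "CohortMatrix":
        """Sub-cohort restricted to the given session ids (subject grouping kept)."""
        wanted = [str(s) for s in sessions]
        missing = set(wanted) - set(self.sessions)
        if missing:
            raise CohortError(f"unknown sessions: {sorted(missing)}")
        cols = [
            i
            for i, (_, ses) in enumerate(self.index)
            if ses in wanted
        ]
        return replace(
            self,
            values=self.values[:, cols],
            index=tuple(self.index[i] for i in cols),
        )

    def with_values(self, values: np.ndarray) -> "CohortMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise CohortError(
                f"replacement values shape {values.shape} != {self.values.shape}"
            )
        return replace(self, values=values)


@dataclass
class SubjectSpecificMatrix(CohortMatrix):
    """Extractor output; same shape and index as its source cohort."""

    extractor: str = "none"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_cohort(
        cls,
        cohort: CohortMatrix,
        values: np.ndarray,
        extractor: str,
        params: dict | None = None,
    ) -> "SubjectSpecificMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != cohort.values.shape:
            raise CohortError(
                "subject-specific matrix must keep the cohort shape: "
                f"{values.shape} != {cohort.values.shape}"
            )
        return cls(
            values=values,
            index=cohort.index,
            network=cohort.network,
            normalization=cohort.normalization,
            extractor=extractor,
            params=dict(params or {}),
        )
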