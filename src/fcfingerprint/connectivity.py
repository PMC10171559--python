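"""From ROI time series to network-restricted FC vectors and cohort matrices.

The FC matrix of a scan is the Pearson correlation matrix of its ROI
time courses. It can be restricted to the nodes of one resting-state
network, normalized (see :mod:`fcfingerprint.normalization`) and then
vectorized by taking the strict upper triangle in row-major order; the
resulting vector of length ñ = n(n-1)/2 is one column of the cohort
matrix Y.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np

from .cohort import CohortError, CohortMatrix, FcMatrix, RoiTimeSeries

__all__ = [
    "compute_fc_matrix",
    "select_network",
    "vectorize_upper",
    "devectorize_upper",
    "truncate_scan",
    "assemble_cohort",
    "scan_to_fc_vector",
]


def compute_fc_matrix(ts: RoiTimeSeries) -> FcMatrix:
    """Pearson correlation matrix of the scan's ROI time courses.

    Raises
    ------
    CohortError
        If T < 3 or any ROI has zero variance (the offending node is
        named in the message).
    """
    data = ts.data
    if data.shape[0] < 3:
        raise CohortError("T < 3: correlation is degenerate")
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.node_ids[i] for i in dead]
        raise CohortError(
            f"zero-variance ROI(s) {names} in scan "
            f"{ts.subject_id}/{ts.session_id}: correlation undefined"
        )
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return FcMatrix(values=r, node_ids=ts.node_ids, normalization="raw")


def _network_node_indices(
    labels: Sequence[str], network_name: str
) -> np.ndarray:
    labels = [str(x) for x in labels]
    if network_name not in labels:
        raise CohortError(f"unknown network {network_name!r}")
    idx = np.flatnonzero(np.asarray(labels, dtype=object) == network_name)
    if idx.size < 2:
        raise CohortError(
            f"network {network_name!r} has {idx.size} node(s); "
            "FC needs at least 2"
        )
    return idx


def select_network(
    obj: RoiTimeSeries | FcMatrix,
    network_name: str,
    labels: Sequence[str] | None = None,
) -> RoiTimeSeries | FcMatrix:
    """Restrict a scan or an FC matrix to the nodes of one network.

    For a :class:`RoiTimeSeries` the labels carried by the scan are
    used; for an :class:`FcMatrix` an explicit ``labels`` sequence of
    the same length must be supplied. Node order is preserved.
    """
    if isinstance(obj, RoiTimeSeries):
        lab = obj.labels if labels is None else tuple(labels)
        if len(lab) != obj.n_rois:
            raise CohortError("labels length mismatch")
        idx = _network_node_indices(lab, network_name)
        return replace(
            obj,
            data=obj.data[:, idx],
            labels=tuple(lab[i] for i in idx),
            node_ids=tuple(obj.node_ids[i] for i in idx),
        )
    if isinstance(obj, FcMatrix):
        if labels is None:
            raise CohortError("labels are required to restrict an FC matrix")
        if len(labels) != obj.n_nodes:
            raise CohortError("labels length mismatch")
        idx = _network_node_indices(labels, network_name)
        return FcMatrix(
            values=obj.values[np.ix_(idx, idx)],
            node_ids=tuple(obj.node_ids[i] for i in idx),
            normalization=obj.normalization,
        )
    raise TypeError(f"cannot restrict object of type {type(obj).__name__}")


def vectorize_upper(fc: FcMatrix | np.ndarray) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major order.

    Row-major means the pairs of row 0 come first: (0,1), (0,2), ...,
    (1,2), ... The length is ñ = n(n-1)/2. This fixed bijection is a
    package convention; every downstream metric is invariant to it.
    """
    values = fc.values if isinstance(fc, FcMatrix) else np.asarray(fc, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise CohortError("input must be a square matrix")
    n = values.shape[0]
    if n < 2:
        raise CohortError("vectorization needs at least 2 nodes")
    if not np.allclose(values, values.T, atol=1e-10):
        raise CohortError("input must be symmetric")
    iu = np.triu_indices(n, k=1)
    return values[iu].copy()


def devectorize_upper(
    vec: np.ndarray,
    diag: float = 1.0,
    node_ids: Sequence[str] | None = None,
    normalization: str = "raw",
) -> FcMatrix:
    """Rebuild the symmetric matrix whose strict upper triangle is ``vec``."""
    vec = np.asarray(vec, dtype=float).ravel()
    # invert ñ = n(n-1)/2
    n = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if n * (n - 1) // 2 != vec.size:
        raise CohortError(
            f"vector length {vec.size} is not a triangular number"
        )
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out = out + out.T
    np.fill_diagonal(out, diag)
    return FcMatrix(values=out, node_ids=node_ids, normalization=normalization)


def truncate_scan(ts: RoiTimeSeries, minutes: float) -> RoiTimeSeries:
    """Keep the first ``floor(minutes*60/dt)`` time points of a scan.

    Emulates recomputing FC from a shorter acquisition. Requesting more
    than the scan contains, or fewer than 3 points, is an error.
    """
    if minutes <= 0:
        raise CohortError("duration must be positive")
    n_keep = int(np.floor(minutes * 60.0 / ts.dt))
    if n_keep > ts.n_timepoints:
        raise CohortError(
            f"requested {minutes} min = {n_keep} points, scan has only "
            f"{ts.n_timepoints}"
        )
    if n_keep < 3:
        raise CohortError(
            f"requested duration keeps {n_keep} < 3 time points"
        )
    return ts.with_data(ts.data[:n_keep])


def assemble_cohort(
    entries: Iterable[tuple[str, str, np.ndarray]],
    network: str = "all",
    normalization: str = "raw",
) -> CohortMatrix:
    """Stack (subject_id, session_id, fc_vector) triples into a cohort matrix.

    Input order is irrelevant: columns are sorted canonically by
    (subject, session), which also groups each subject's sessions
    contiguously. Ragged session counts, mixed vector lengths and
    duplicate (subject, session) pairs are rejected.
    """
    rows = [(str(sub), str(ses), np.asarray(v, dtype=float).ravel()) for sub, ses, v in entries]
    if not rows:
        raise CohortError("no scans to assemble")
    lengths = {v.size for _, _, v in rows}
    if len(lengths) != 1:
        raise CohortError(f"FC vectors have mixed lengths: {sorted(lengths)}")
    rows.sort(key=lambda r: (r[0], r[1]))
    index = tuple((sub, ses) for sub, ses, _ in rows)
    values = np.column_stack([v for _, _, v in rows])
    return CohortMatrix(
        values=values, index=index, network=network, normalization=normalization
    )


def scan_to_fc_vector(
    ts: RoiTimeSeries,
    network: str | None = None,
    normalization: str = "none",
) -> np.ndarray:
    """Convenience: restrict, correlate, normalize and vectorize one scan."""
    from .normalization import apply_normalization

    if network is not None and network != "all":
        ts = select_network(ts, network)
    fc = compute_fc_matrix(ts)
    fc = apply_normalization(fc, normalization)
    return vectorize_upper(fc)
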