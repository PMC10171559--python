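"""Synthetic multi-subject, multi-session cohorts.

Two generative modes emulate the statistical structure the analysis
assumes of resting-state FC data:

FC-vector mode (:func:`generate_fc_cohort`)
    each scan's FC vector is an additive mixture

        y_{i,j} = sqrt(a) g + sqrt(b) u_i + sqrt(c) e_{i,j}

    of a shared vector ``g``, a subject-stable vector ``u_i`` and
    session noise ``e_{i,j}`` (all iid standard normal of length ñ),
    with variance shares a = rho_between, b = rho_within - rho_between,
    c = 1 - rho_within. Under this parameterization the expected
    Pearson correlation between two scans is exactly ``rho_within``
    within a subject and ``rho_between`` between subjects, so metric
    recovery is analytically checkable.

ROI-time-series mode (:func:`generate_timeseries_cohort`)
    each scan is a latent-factor mixture with one factor per labeled
    network: every ROI loads on its network's factor with a loading
    shared by all subjects, perturbed by a subject-stable random
    offset, plus white observation noise. Downstream Pearson FC
    matrices then show block structure by network and subject-stable
    deviations, so the correlation stage of the pipeline is exercised
    too.

:func:`make_separable_cohort` builds the deterministic ideal case used
by the metric definitions: identical sessions within a subject and
exactly zero correlation between subjects, for which differential
identifiability is 100 and the overlap count is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hadamard, helmert

from .cohort import CohortError, CohortMatrix, RoiTimeSeries

__all__ = [
    "SyntheticSpec",
    "generate_fc_cohort",
    "generate_timeseries_cohort",
    "make_separable_cohort",
]

#: default node-to-network labels used when a time-series spec does not
#: provide any: four named networks of equal size
DEFAULT_NETWORKS = ("visual", "somatomotor", "frontoparietal", "default")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    p, s
        Subject count (>= 2) and sessions per subject (>= 2), with
        p*s >= 4.
    n_features
        FC-vector length ñ (FC-vector mode; >= 3).
    n_rois, n_timepoints
        Node and time-point counts (time-series mode).
    rho_within, rho_between
        Target expected Pearson correlation between two sessions of the
        same subject and between scans of different subjects, with
        0 <= rho_between <= rho_within < 1.
    subject_scale
        Time-series mode: standard deviation of the subject-stable
        loading perturbation (0.3 by default — strong enough to make
        subjects identifiable from a few hundred time points without
        dominating the shared network structure).
    noise_scale
        Time-series mode: standard deviation of the white observation
        noise added on top of the factor mixture.
    dt
        Sampling interval in seconds (2.0 s, a typical fMRI TR).
    network_labels
        Node-to-network assignment (time-series mode); defaults to four
        equal-sized blocks over ``DEFAULT_NETWORKS``.
    seed
        RNG seed; all generators are pure functions of (spec, seed).
    """

    p: int
    s: int
    n_features: int | None = None
    n_rois: int | None = None
    n_timepoints: int | None = None
    rho_within: float = 0.6
    rho_between: float = 0.2
    subject_scale: float = 0.3
    noise_scale: float = 1.0
    dt: float = 2.0
    network_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise CohortError("need p >= 2 subjects")
        if self.s < 2:
            raise CohortError("need s >= 2 sessions per subject")
        if self.p * self.s < 4:
            raise CohortError("need p*s >= 4 scans")
        if not 0.0 <= self.rho_between:
            raise CohortError("violated: 0 <= rho_between")
        if self.rho_between > self.rho_within:
            raise CohortError("violated: rho_between <= rho_within")
        if not self.rho_within < 1.0:
            raise CohortError("violated: rho_within < 1")
        if self.n_features is not None and self.n_features < 3:
            raise CohortError("need n_features >= 3")

    # -- derived variance shares (FC-vector mode) ----------------------
    @property
    def variance_shares(self) -> tuple[float, float, float]:
        """(a, b, c): shared, subject-stable and session-noise shares."""
        a = self.rho_between
        b = self.rho_within - self.rho_between
        c = 1.0 - self.rho_within
        return a, b, c

    def labels(self) -> tuple[str, ...]:
        if self.network_labels is not None:
            if self.n_rois is not None and len(self.network_labels) != self.n_rois:
                raise CohortError("network_labels length != n_rois")
            return tuple(self.network_labels)
        if self.n_rois is None:
            raise CohortError("time-series mode needs n_rois")
        k = len(DEFAULT_NETWORKS)
        return tuple(
            DEFAULT_NETWORKS[(i * k) // self.n_rois] for i in range(self.n_rois)
        )


def _ids(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    subjects = [f"sub{i + 1:03d}" for i in range(spec.p)]
    sessions = [f"ses{j + 1:02d}" for j in range(spec.s)]
    return subjects, sessions


def generate_fc_cohort(spec: SyntheticSpec) -> CohortMatrix:
    """Draw a cohort of FC vectors with the additive three-part structure."""
    if spec.n_features is None:
        raise CohortError("FC-vector mode needs n_features")
    a, b, c = spec.variance_shares
    if b < 0:
        raise CohortError("violated: rho_between <= rho_within")
    if c <= 0:
        raise CohortError("violated: rho_within < 1")
    rng = np.random.default_rng(spec.seed)
    nf = spec.n_features
    shared = rng.standard_normal(nf)
    subjects, sessions = _ids(spec)
    cols = []
    index = []
    for sub in subjects:
        stable = rng.standard_normal(nf)
        for ses in sessions:
            noise = rng.standard_normal(nf)
            cols.append(
                np.sqrt(a) * shared + np.sqrt(b) * stable + np.sqrt(c) * noise
            )
            index.append((sub, ses))
    return CohortMatrix(
        values=np.column_stack(cols),
        index=tuple(index),
        network="synthetic",
        normalization="raw",
    )


def generate_timeseries_cohort(spec: SyntheticSpec) -> list[RoiTimeSeries]:
    """Draw one latent-factor ROI time-series scan per (subject, session).

    Every scan of subject i is F @ (W0 + dW_i).T + noise, where F is a
    fresh T x K matrix of standard-normal factor time courses (one
    factor per network), W0 puts unit loading of each ROI on its own
    network's factor, and dW_i is the subject-stable dense perturbation
    with standard deviation ``subject_scale``.
    """
    if spec.n_rois is None or spec.n_timepoints is None:
        raise CohortError("time-series mode needs n_rois and n_timepoints")
    if spec.n_timepoints < 3:
        raise CohortError("need n_timepoints >= 3 (correlation degenerate)")
    labels = spec.labels()
    networks = list(dict.fromkeys(labels))
    k = len(networks)
    n, t = spec.n_rois, spec.n_timepoints
    w0 = np.zeros((n, k))
    for r, lab in enumerate(labels):
        w0[r, networks.index(lab)] = 1.0
    rng = np.random.default_rng(spec.seed)
    subjects, sessions = _ids(spec)
    scans: list[RoiTimeSeries] = []
    for sub in subjects:
        w_i = w0 + spec.subject_scale * rng.standard_normal((n, k))
        for ses in sessions:
            factors = rng.standard_normal((t, k))
            noise = spec.noise_scale * rng.standard_normal((t, n))
            scans.append(
                RoiTimeSeries(
                    data=factors @ w_i.T + noise,
                    subject_id=sub,
                    session_id=ses,
                    dt=spec.dt,
                    labels=labels,
                )
            )
    return scans


def _orthogonal_mean_centered_vectors(p: int, n_features: int) -> np.ndarray:
    """p mutually orthogonal, mean-zero vectors of length n_features.

    Prefers sign-pattern columns of a Hadamard matrix (orthogonality
    exact in integer arithmetic), zero-padded to n_features; falls back
    to Helmert rows (orthonormal and mean-zero to float precision) when
    no power-of-two block is large enough.
    """
    if n_features < p + 1:
        raise CohortError(
            f"cannot host {p} orthogonal mean-centered vectors in "
            f"{n_features} features (need at least p+1)"
        )
    m = 1 << int(np.log2(n_features))
    if m - 1 >= p:
        h = hadamard(m).astype(float)
        vecs = np.zeros((n_features, p))
        vecs[:m, :] = h[:, 1 : p + 1]  # skip the constant column
        return vecs
    return helmert(n_features, full=False)[:p].T.copy()


def make_separable_cohort(p: int, s: int, n_features: int) -> CohortMatrix:
    """Deterministic ideal cohort: within-correlation 1, between 0.

    Each subject's s session vectors are identical copies of one
    subject vector; subject vectors are mean-centered and pairwise
    orthogonal, hence pairwise Pearson correlation 0. On this cohort
    Idiff is 100 and the overlap count is 0.
    """
    if p < 2:
        raise CohortError("need p >= 2 (between-subject set empty for p=1)")
    if s < 2:
        raise CohortError("need s >= 2 sessions")
    vecs = _orthogonal_mean_centered_vectors(p, n_features)
    subjects = [f"sub{i + 1:03d}" for i in range(p)]
    sessions = [f"ses{j + 1:02d}" for j in range(s)]
    values = np.column_stack(
        [vecs[:, i] for i in range(p) for _ in sessions]
    )
    index = tuple((sub, ses) for sub in subjects for ses in sessions)
    return CohortMatrix(
        values=values,
        index=index,
        network="separable",
        normalization="raw",
    )
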