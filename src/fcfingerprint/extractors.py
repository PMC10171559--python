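"""Subject-specific component extractors with a uniform fit/transform contract.

Each extractor is fitted on the training cohort only and then applied
to any cohort with matching feature dimension; ``transform`` always
returns a :class:`~fcfingerprint.cohort.SubjectSpecificMatrix` with
exactly the input's shape and column index.

pca
    Learn the per-feature training mean and the top-m̃ eigenvectors of
    the centered training covariance; the subject-specific component of
    a scan is its reconstruction D D^T (y - ȳ) within that subspace.
pca / rpca keep the individual variability *inside* a learned
subspace, ksvd / cobe return the *residual* after removing a learned
shared reconstruction:

rpca
    Split the training matrix into low-rank plus sparse parts by
    principal component pursuit, z-score the sparse "connectivity
    traits" per feature, learn a k-atom l1-sparse dictionary on it
    (online/batch dictionary learning), and at test time project the
    raw test matrix onto the dictionary span by least squares.
ksvd
    Learn a k-atom dictionary with OMP sparsity s0 on the training
    matrix; at test time code the test matrix by unconstrained least
    squares and keep the residual Y - D X.
cobe
    Common orthogonal basis extraction: find the C orthonormal
    directions most shared by the per-subject blocks (top eigenvectors
    of the summed block projectors) and keep the residual after
    projecting them out. COBE is the only supervised extractor — its
    fit consumes per-subject blocks, not the pooled matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import orth
from sklearn.decomposition import DictionaryLearning

from .cohort import CohortError, CohortMatrix, SubjectSpecificMatrix
from .ksvd import fix_signs, ksvd, omp_encode
from .pcp import principal_component_pursuit

logger = logging.getLogger(__name__)

__all__ = [
    "BaseExtractor",
    "RawExtractor",
    "PcaExtractor",
    "RpcaExtractor",
    "KsvdExtractor",
    "CobeExtractor",
    "cobe_fit",
    "CobeModel",
    "make_extractor",
    "EXTRACTORS",
    "save_model",
    "load_model",
]


class NotFittedError(RuntimeError):
    pass


class BaseExtractor:
    """fit(train) -> self; transform(cohort) -> SubjectSpecificMatrix."""

    name: str = "base"

    def fit(self, train: CohortMatrix) -> "BaseExtractor":
        raise NotImplementedError

    def transform(self, cohort: CohortMatrix) -> SubjectSpecificMatrix:
        raise NotImplementedError

    def fit_transform(self, train: CohortMatrix) -> SubjectSpecificMatrix:
        return self.fit(train).transform(train)

    def params(self) -> dict:
        return {}

    def _check_features(self, cohort: CohortMatrix, n_features: int) -> None:
        if cohort.n_features != n_features:
            raise CohortError(
                f"feature dimension mismatch: model has {n_features}, "
                f"cohort has {cohort.n_features}"
            )


class RawExtractor(BaseExtractor):
    """Pass-through baseline: the 'subject-specific' matrix is the input."""

    name = "none"

    def fit(self, train: CohortMatrix) -> "RawExtractor":
        self.n_features_ = train.n_features
        return self

    def transform(self, cohort: CohortMatrix) -> SubjectSpecificMatrix:
        self._check_features(cohort, getattr(self, "n_features_", cohort.n_features))
        return SubjectSpecificMatrix.from_cohort(
            cohort, cohort.values.copy(), extractor=self.name, params={}
        )


class PcaExtractor(BaseExtractor):
    """Reconstruction within the top-m̃ principal subspace of the training set.

    Attributes after fit: ``mean_`` (per-feature training mean),
    ``basis_`` (ñ x m̃, orthonormal), ``explained_variance_ratio_``
    (all singular directions, non-increasing).
    """

    name = "pca"

    def __init__(self, n_components: int):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = int(n_components)

    def params(self) -> dict:
        return {"n_components": self.n_components}

    def fit(self, train: CohortMatrix) -> "PcaExtractor":
        y = train.values
        self.mean_ = y.mean(axis=1)
        centered = y - self.mean_[:, None]
        u, sv, _ = np.linalg.svd(centered, full_matrices=False)
        tol = sv[0] * max(centered.shape) * np.finfo(float).eps if sv.size else 0.0
        rank = int(np.sum(sv > tol))
        if self.n_components > rank:
            raise CohortError(
                f"n_components={self.n_components} exceeds the rank "
                f"({rank}) of the centered training matrix"
            )
        self.basis_ = fix_signs(u[:, : self.n_components])
        total = float(np.sum(sv**2))
        self.explained_variance_ratio_ = (
            sv**2 / total if total > 0 else np.zeros_like(sv)
        )
        self.n_features_ = train.n_features
        return self

    def transform(self, cohort: CohortMatrix) -> SubjectSpecificMatrix:
        if not hasattr(self, "basis_"):
            raise NotFittedError("fit the extractor first")
        self._check_features(cohort, self.n_features_)
        centered = cohort.values - self.mean_[:, None]
        sub = self.basis_ @ (self.basis_.T @ centered)
        return SubjectSpecificMatrix.from_cohort(
            cohort, sub, extractor=self.name, params=self.params()
        )


def learn_sparse_dictionary(
    z: np.ndarray, k: int, lam: float, n_iter: int = 100, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """l1-penalized dictionary learning on a feature x sample matrix.

    Minimizes 0.5*||z - D a||_F^2 + lam*||a||_1 by alternating sparse
    coding and dictionary updates with unit-norm-bounded atoms.
    Returns (dictionary ñ x k, codes k x samples, per-iteration
    objective values).
    """
    dl = DictionaryLearning(
        n_components=k,
        alpha=lam,
        max_iter=n_iter,
        fit_algorithm="cd",
        transform_algorithm="lasso_cd",
        random_state=seed,
        tol=1e-8,
    )
    codes = dl.fit_transform(z.T)
    return dl.components_.T, codes.T, list(np.asarray(dl.error_, dtype=float))


class RpcaExtractor(BaseExtractor):
    """PCP split, per-feature z-scoring of the sparse part, l1 dictionary.

    Parameters
    ----------
    k
        Number of dictionary atoms (must satisfy k < ñ).
    lam
        l1 sparse-coding weight of the dictionary-learning step (> 0).
    lam_pcp
        PCP sparsity weight; defaults to 1/sqrt(max dimension).
    n_iter
        Dictionary-learning iteration budget (100 — the learning curve
        is flat well before that on cohort-sized problems).
    standardize_test
        If True, apply the stored training z-score to the test matrix
        before least squares; the default (False) codes the raw test
        matrix, following the literal test-phase rule.
    """

    name = "rpca"

    def __init__(
        self,
        k: int,
        lam: float,
        lam_pcp: float | None = None,
        pcp_tol: float = 1e-7,
        pcp_max_iter: int = 500,
        n_iter: int = 100,
        seed: int = 0,
        standardize_test: bool = False,
    ):
        if lam <= 0:
            raise ValueError("lam must be positive")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = int(k)
        self.lam = float(lam)
        self.lam_pcp = lam_pcp
        self.pcp_tol = pcp_tol
        self.pcp_max_iter = pcp_max_iter
        self.n_iter = int(n_iter)
        self.seed = int(seed)
        self.standardize_test = bool(standardize_test)

    def params(self) -> dict:
        return {
            "k": self.k,
            "lam": self.lam,
            "seed": self.seed,
            "standardize_test": self.standardize_test,
        }

    def fit(self, train: CohortMatrix) -> "RpcaExtractor":
        y = train.values
        if self.k >= train.n_features:
            raise CohortError(
                f"k={self.k} must be smaller than the feature dimension "
                f"{train.n_features}"
            )
        res = principal_component_pursuit(
            y, lam=self.lam_pcp, tol=self.pcp_tol, max_iter=self.pcp_max_iter
        )
        self.low_rank_, self.sparse_ = res.low_rank, res.sparse
        self.feature_mean_ = self.sparse_.mean(axis=1)
        sd = self.sparse_.std(axis=1)
        self.feature_sd_ = np.where(sd > 0, sd, 1.0)  # constant features -> 0
        z = (self.sparse_ - self.feature_mean_[:, None]) / self.feature_sd_[:, None]
        self.dictionary_, self.codes_, self.objective_history_ = (
            learn_sparse_dictionary(
                z, k=self.k, lam=self.lam, n_iter=self.n_iter, seed=self.seed
            )
        )
        self.n_features_ = train.n_features
        return self

    def transform(self, cohort: CohortMatrix) -> SubjectSpecificMatrix:
        if not hasattr(self, "dictionary_"):
            raise NotFittedError("fit the extractor first")
        self._check_features(cohort, self.n_features_)
        y = cohort.values
        if self.standardize_test:
            y = (y - self.feature_mean_[:, None]) / self.feature_sd_[:, None]
        d = self.dictionary_
        rank = np.linalg.matrix_rank(d)
        if rank < d.shape[1]:
            logger.warning(
                "rpca dictionary is rank deficient (%d < %d); using the "
                "minimum-norm least-squares solution",
                rank,
                d.shape[1],
            )
        alpha, *_ = np.linalg.lstsq(d, y, rcond=None)
        return SubjectSpecificMatrix.from_cohort(
            cohort, d @ alpha, extractor=self.name, params=self.params()
        )


class KsvdExtractor(BaseExtractor):
    """K-SVD shared dictionary; subject-specific part is the coding residual.

    ``test_coding`` selects the test-phase coder: ``"lstsq"``
    (unconstrained least squares, the default) or ``"omp"`` (sparse
    coding with the training sparsity budget, for sensitivity checks).
    """

    name = "ksvd"

    def __init__(
        self,
        k: int,
        s0: int,
        n_iter: int = 30,
        seed: int = 0,
        test_coding: str = "lstsq",
    ):
        if s0 > k:
            raise ValueError(f"sparsity s0={s0} cannot exceed k={k}")
        if test_coding not in ("lstsq", "omp"):
            raise ValueError("test_coding must be 'lstsq' or 'omp'")
        self.k = int(k)
        self.s0 = int(s0)
        self.n_iter = int(n_iter)
        self.seed = int(seed)
        self.test_coding = test_coding

    def params(self) -> dict:
        return {
            "k": self.k,
            "s0": self.s0,
            "seed": self.seed,
            "test_coding": self.test_coding,
        }

    def fit(self, train: CohortMatrix) -> "KsvdExtractor":
        res = ksvd(
            train.values, k=self.k, s0=self.s0, n_iter=self.n_iter, seed=self.seed
        )
        self.dictionary_ = res.dictionary
        self.train_codes_ = res.codes
        self.objective_history_ = res.objective
        self.n_features_ = train.n_features
        return self

    def transform(self, cohort: CohortMatrix) -> SubjectSpecificMatrix:
        if not hasattr(self, "dictionary_"):
            raise NotFittedError("fit the extractor first")
        self._check_features(cohort, self.n_features_)
        y = cohort.values
        if self.test_coding == "omp":
            codes = omp_encode(self.dictionary_, y, self.s0)
        else:
            codes, *_ = np.linalg.lstsq(self.dictionary_, y, rcond=None)
        sub = y - self.dictionary_ @ codes
        return SubjectSpecificMatrix.from_cohort(
            cohort, sub, extractor=self.name, params=self.params()
        )


@dataclass(frozen=True)
class CobeModel:
    """Fitted common orthogonal basis: ñ x C, orthonormal columns."""

    basis: np.ndarray
    commonality: np.ndarray  # eigenvalues of the summed block projectors

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]


def cobe_fit(blocks: Sequence[np.ndarray], n_components: int) -> CobeModel:
    """Orthonormal directions most shared by the blocks' column spaces.

    The basis maximizes the summed squared projection onto each block's
    column space, i.e. it consists of the top-C eigenvectors of
    sum_i Q_i Q_i^T with Q_i an orthonormal basis of span(Y_i)
    (computed via an SVD of the stacked Q_i). An eigenvalue near the
    number of blocks signals a genuinely common direction; a top
    eigenvalue <= 1 + delta means no direction is shared and is logged.
    """
    if len(blocks) < 2:
        raise CohortError("COBE needs at least 2 blocks")
    blocks = [np.asarray(b, dtype=float) for b in blocks]
    n_feat = blocks[0].shape[0]
    for i, b in enumerate(blocks):
        if b.ndim != 2 or b.shape[0] != n_feat:
            raise CohortError("blocks must share the feature dimension")
        if not np.any(b):
            raise CohortError(f"block {i} is identically zero")
    min_cols = min(b.shape[1] for b in blocks)
    if not 1 <= n_components <= min_cols:
        raise CohortError(
            f"n_components={n_components} must be in [1, {min_cols}] "
            "(the smallest block column count)"
        )
    stacked = np.hstack([orth(b) for b in blocks])
    u, sv, _ = np.linalg.svd(stacked, full_matrices=False)
    eigenvalues = sv**2  # of sum_i Q_i Q_i^T
    if eigenvalues[0] <= 1.0 + 1e-6:
        logger.warning(
            "COBE: top commonality eigenvalue %.4f <= 1; the blocks share "
            "no genuinely common direction",
            eigenvalues[0],
        )
    basis = fix_signs(u[:, :n_components])
    return CobeModel(basis=basis, commonality=eigenvalues)


class CobeExtractor(BaseExtractor):
    """Residual after removing the common orthogonal basis component.

    Supervised: ``fit`` splits the training cohort into per-subject
    blocks using the column index, so the algorithm knows which scans
    belong together. Since the basis is orthonormal, the test-phase
    least squares reduces to the orthogonal projection
    Sub = Y - D (D^T Y), applied columnwise.
    """

    name = "cobe"

    def __init__(self, n_components: int):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = int(n_components)

    def params(self) -> dict:
        return {"n_components": self.n_components}

    def fit(self, train: CohortMatrix) -> "CobeExtractor":
        blocks = list(train.subject_blocks().values())
        self.model_ = cobe_fit(blocks, self.n_components)
        self.n_features_ = train.n_features
        return self

    def transform(self, cohort: CohortMatrix) -> SubjectSpecificMatrix:
        if not hasattr(self, "model_"):
            raise NotFittedError("fit the extractor first")
        self._check_features(cohort, self.n_features_)
        d = self.model_.basis
        y = cohort.values
        sub = y - d @ (d.T @ y)
        return SubjectSpecificMatrix.from_cohort(
            cohort, sub, extractor=self.name, params=self.params()
        )


EXTRACTORS = {
    "none": RawExtractor,
    "pca": PcaExtractor,
    "rpca": RpcaExtractor,
    "ksvd": KsvdExtractor,
    "cobe": CobeExtractor,
}


def make_extractor(name: str, **params) -> BaseExtractor:
    """Instantiate an extractor by name with its hyper-parameters."""
    if name not in EXTRACTORS:
        raise CohortError(
            f"unknown extractor {name!r}; choose from {sorted(EXTRACTORS)}"
        )
    return EXTRACTORS[name](**params)


# -- serialization -----------------------------------------------------

_ARRAY_ATTRS = (
    "mean_",
    "basis_",
    "explained_variance_ratio_",
    "dictionary_",
    "feature_mean_",
    "feature_sd_",
)


def save_model(extractor: BaseExtractor, path: str | Path, threshold: float | None = None) -> None:
    """Persist a fitted extractor (arrays + JSON metadata sidecar)."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for attr in _ARRAY_ATTRS:
        if hasattr(extractor, attr):
            arrays[attr] = getattr(extractor, attr)
    if isinstance(extractor, CobeExtractor) and hasattr(extractor, "model_"):
        arrays["basis_"] = extractor.model_.basis
        arrays["commonality_"] = extractor.model_.commonality
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "extractor": extractor.name,
        "params": extractor.params(),
        "n_features": getattr(extractor, "n_features_", None),
        "threshold": threshold,
        "format_version": 1,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> tuple[BaseExtractor, float | None]:
    """Load a fitted extractor saved by :func:`save_model`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))
    ex = make_extractor(meta["extractor"], **meta["params"])
    for key in data.files:
        setattr(ex, key.rstrip("_") + "_", data[key])
    if isinstance(ex, CobeExtractor):
        ex.model_ = CobeModel(
            basis=data["basis_"], commonality=data["commonality_"]
        )
    ex.n_features_ = meta["n_features"]
    return ex, meta.get("threshold")
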