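"""K-SVD dictionary learning with OMP sparse coding.

Alternates two steps: (1) code every training column with at most s0
nonzeros by orthogonal matching pursuit over the current dictionary;
(2) update the atoms one at a time with a rank-1 SVD of the residual
restricted to the columns that use the atom, re-fitting those columns'
coefficients in the same step. Atoms that no training column uses, and
atoms that have collapsed onto a near-duplicate of another atom, are
replaced by the currently worst-represented column — the usual guard
against the local minima of the alternation. The dictionary is
initialized from randomly chosen training columns, so the whole run is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import orthogonal_mp

__all__ = ["KsvdResult", "ksvd", "omp_encode", "fix_signs"]


@dataclass(frozen=True)
class KsvdResult:
    dictionary: np.ndarray  # ñ x k, unit-norm atoms
    codes: np.ndarray  # k x q, at most s0 nonzeros per column
    objective: list[float]  # ||Y - D X||_F after each iteration


def fix_signs(basis: np.ndarray) -> np.ndarray:
    """Make the first coordinate of largest magnitude positive, per column.

    Resolves the sign ambiguity of SVD/eigendecompositions so repeated
    runs are bit-identical.
    """
    basis = np.array(basis, dtype=float)
    for j in range(basis.shape[1]):
        col = basis[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            basis[:, j] = -col
    return basis


def omp_encode(dictionary: np.ndarray, y: np.ndarray, s0: int) -> np.ndarray:
    """OMP codes with at most s0 nonzeros per column of ``y``."""
    codes = orthogonal_mp(dictionary, y, n_nonzero_coefs=s0)
    # orthogonal_mp squeezes singleton dimensions; restore (k, n_targets)
    return codes.reshape(dictionary.shape[1], -1)


def ksvd(
    y: np.ndarray,
    k: int,
    s0: int,
    n_iter: int = 30,
    seed: int = 0,
) -> KsvdResult:
    """Learn a k-atom dictionary with sparsity budget s0.

    Raises
    ------
    ValueError
        If s0 > k, or there are fewer training columns than atoms to
        initialize from.
    """
    y = np.asarray(y, dtype=float)
    n_feat, n_cols = y.shape
    if not 1 <= s0 <= k:
        raise ValueError(f"need 1 <= s0 <= k, got s0={s0}, k={k}")
    if k > n_cols:
        raise ValueError(
            f"cannot initialize {k} atoms from {n_cols} training columns"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_cols, size=k, replace=False)
    dictionary = y[:, chosen].copy()
    norms = np.linalg.norm(dictionary, axis=0)
    for j in np.flatnonzero(norms == 0):  # guard against zero columns
        dictionary[:, j] = rng.standard_normal(n_feat)
    dictionary /= np.linalg.norm(dictionary, axis=0)
    dictionary = fix_signs(dictionary)

    objective: list[float] = []
    codes = np.zeros((k, n_cols))
    for _ in range(n_iter):
        codes = omp_encode(dictionary, y, s0)
        for j in range(k):
            users = np.flatnonzero(codes[j])
            if users.size == 0:
                resid_norms = np.linalg.norm(y - dictionary @ codes, axis=0)
                worst = int(np.argmax(resid_norms))
                atom = y[:, worst]
                nrm = np.linalg.norm(atom)
                if nrm > 0:
                    dictionary[:, j] = atom / nrm
                continue
            codes[j, users] = 0.0
            residual = y[:, users] - dictionary @ codes[:, users]
            u, sv, vt = np.linalg.svd(residual, full_matrices=False)
            atom = u[:, 0]
            coef = sv[0] * vt[0]
            nz = np.flatnonzero(np.abs(atom) > 1e-12)
            if nz.size and atom[nz[0]] < 0:
                atom, coef = -atom, -coef
            dictionary[:, j] = atom
            codes[j, users] = coef
        _replace_degenerate_atoms(y, dictionary, codes)
        objective.append(float(np.linalg.norm(y - dictionary @ codes)))
    return KsvdResult(dictionary=dictionary, codes=codes, objective=objective)


def _replace_degenerate_atoms(
    y: np.ndarray, dictionary: np.ndarray, codes: np.ndarray, coherence: float = 0.99
) -> None:
    """Swap near-duplicate atoms for the worst-represented columns, in place.

    Only atoms whose replacement cannot increase the objective are
    swapped: the duplicate's coefficient mass is first folded into its
    twin (they are the same direction up to ``coherence``), keeping the
    training objective monotone.
    """
    k = dictionary.shape[1]
    gram = np.abs(dictionary.T @ dictionary)
    np.fill_diagonal(gram, 0.0)
    for j in range(k):
        twins = np.flatnonzero(gram[j, :j] > coherence)
        if twins.size == 0:
            continue
        twin = int(twins[0])
        sign = np.sign(dictionary[:, twin] @ dictionary[:, j]) or 1.0
        codes[twin] += sign * codes[j]
        codes[j] = 0.0
        resid_norms = np.linalg.norm(y - dictionary @ codes, axis=0)
        worst = int(np.argmax(resid_norms))
        nrm = np.linalg.norm(y[:, worst])
        if nrm > 0:
            dictionary[:, j] = y[:, worst] / nrm
        gram[j, :] = 0.0
        gram[:, j] = 0.0
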