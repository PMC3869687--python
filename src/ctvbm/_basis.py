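"""Separable low-frequency cosine (DCT-II) bases.

Used both for the multiplicative MR bias field (segmentation) and for the
nonlinear deformation field (spatial normalization).  Basis functions are
evaluated at arbitrary, possibly fractional, voxel coordinates so that
fields estimated on one grid can be evaluated on another.
"""

from __future__ import annotations

import numpy as np


def dct_basis(n_points: int, n_funcs: int, coords: np.ndarray | None = None) -> np.ndarray:
    """DCT-II basis matrix of shape ``(len(coords), n_funcs)``.

    ``coords`` defaults to the integer voxel positions ``0..n_points-1``.
    Columns are orthonormal over the default coordinates; the first column
    is the constant function.
    """
    if coords is None:
        coords = np.arange(n_points, dtype=float)
    coords = np.asarray(coords, dtype=float)
    k = np.arange(n_funcs)
    B = np.cos(np.pi * np.outer(coords + 0.5, k) / n_points)
    B[:, 0] *= 1.0 / np.sqrt(2.0)
    B *= np.sqrt(2.0 / n_points)
    return B


def separable_field(coeffs: np.ndarray, bases: list[np.ndarray]) -> np.ndarray:
    """Evaluate ``sum_ijk c[i,j,k] B0[:,i] B1[:,j] B2[:,k]`` on the grid.

    ``coeffs`` has shape ``(n0, n1, n2)``; ``bases[a]`` has shape
    ``(N_a, n_a)``.  Returns an array of shape ``(N0, N1, N2)``.
    """
    f = np.tensordot(bases[0], coeffs, axes=(1, 0))        # (N0, n1, n2)
    f = np.tensordot(f, bases[1], axes=([1], [1]))         # (N0, n2, N1)
    f = np.tensordot(f, bases[2], axes=([1], [1]))         # (N0, N1, N2)
    return f


def design_matrix(bases: list[np.ndarray]) -> np.ndarray:
    """Flattened separable design: shape ``(N0*N1*N2, n0*n1*n2)``.

    Row order is C order of the evaluation grid; column order is C order of
    the coefficient array, matching :func:`separable_field`.
    """
    B0, B1, B2 = bases
    out = np.einsum("ai,bj,ck->abcijk", B0, B1, B2, optimize=True)
    return out.reshape(B0.shape[0] * B1.shape[0] * B2.shape[0], -1)
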