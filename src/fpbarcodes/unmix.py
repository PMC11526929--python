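"""Spectral unmixing by non-negative least squares.

Each cell's C-channel intensity vector b is decomposed against the C x R
reference basis A by solving

    min_x ||A x - b||_2   subject to  x >= 0,

yielding R nonnegative abundances (18 FPs + autofluorescence by default),
each interpretable as a relative concentration in peak-channel AU. The
solver is Lawson–Hanson active-set NNLS; optimality is characterized by the
KKT conditions: the gradient g = A'(Ax - b) satisfies |g_j| <= tol on the
active support (x_j > 0) and g_j >= -tol where x_j = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .io import EventTable
from .reference import ReferenceMatrix

__all__ = ["AbundanceVector", "nnls", "unmix_table", "kkt_violation"]


@dataclass(frozen=True)
class AbundanceVector:
    """Nonnegative abundances of one cell over the basis columns."""

    values: np.ndarray
    residual_norm: float
    cell_index: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if (v < 0).any() or self.residual_norm < 0:
            raise ValueError("abundances and residual must be nonnegative")


def _check_basis(A: np.ndarray) -> None:
    if not np.isfinite(A).all():
        raise ValueError("basis contains non-finite values")
    if (A < 0).any():
        raise ValueError("basis columns must be nonnegative")
    if (np.abs(A).sum(axis=0) == 0).any():
        raise ValueError("basis contains an all-zero column")


def nnls(
    basis: ReferenceMatrix | np.ndarray,
    cell: np.ndarray,
    *,
    cell_index: int | None = None,
) -> AbundanceVector:
    """Solve one cell's NNLS problem against the basis.

    Raises on dimension mismatch or non-finite input; solver failures
    propagate rather than being silently zeroed.
    """
    A = basis.basis if isinstance(basis, ReferenceMatrix) else np.asarray(basis, float)
    b = np.asarray(cell, dtype=float)
    _check_basis(A)
    if b.ndim != 1 or b.size != A.shape[0]:
        raise ValueError(f"cell vector length {b.size} != basis rows {A.shape[0]}")
    if not np.isfinite(b).all():
        raise ValueError("cell vector contains non-finite values")
    x, rnorm = scipy.optimize.nnls(A, b)
    return AbundanceVector(values=x, residual_norm=float(rnorm), cell_index=cell_index)


def kkt_violation(A: np.ndarray, b: np.ndarray, x: np.ndarray) -> float:
    """Worst-case KKT violation of a candidate NNLS solution.

    Returns max( |g_j| over x_j > 0, max(-g_j, 0) over x_j = 0 ) where
    g = A'(Ax - b); zero (within tolerance) certifies optimality.
    """
    g = A.T @ (A @ x - b)
    active = x > 0
    v = 0.0
    if active.any():
        v = float(np.abs(g[active]).max())
    if (~active).any():
        v = max(v, float(np.maximum(-g[~active], 0.0).max()))
    return v


def unmix_table(basis: ReferenceMatrix, events: EventTable) -> pd.DataFrame:
    """Unmix every cell; rows align with the event table.

    Returns a DataFrame with one column per basis label plus ``residual``
    (the residual 2-norm). Channel names must match the basis rows; the
    basis is stored channels x references with rows in the order the
    reference spectra were estimated, so tables are aligned by name.
    """
    if events.n_channels != basis.n_channels:
        raise ValueError(
            f"event table has {events.n_channels} channels, basis {basis.n_channels}"
        )
    intensities = events.intensities
    if basis.channel_names is not None:
        if set(events.channel_names) != set(basis.channel_names):
            raise ValueError("event table channel names do not match basis")
        order = [events.channel_names.index(c) for c in basis.channel_names]
        intensities = intensities[:, order]
    n = events.n_cells
    out = np.zeros((n, len(basis.column_labels) + 1))
    for i in range(n):
        av = nnls(basis, intensities[i], cell_index=i)
        out[i, :-1] = av.values
        out[i, -1] = av.residual_norm
    return pd.DataFrame(out, columns=list(basis.column_labels) + ["residual"])
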