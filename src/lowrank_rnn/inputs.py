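"""Stochastic-input ensembles of prescribed dimensionality.

The network is driven by temporally white, unit-spectral-density Gaussian
noise fed through an input weight matrix U whose C non-vanishing columns are
orthonormal. C is the input dimensionality: C = 1 broadcasts a single signal
along a vector u, C = N (U = I) drives every unit with an independent signal.
The static input covariance is Sigma_inp = U U^T.

The geometry quantities that enter the covariance formulas are d^r =
Sigma_inp n^r (the projection of each left connectivity vector onto the input
subspace) and sigma_rr' = n^r . Sigma_inp n^r'.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivitySpec, orthonormal_scaffold

__all__ = ["InputEnsemble", "InputGeometry", "make_input", "ei_input", "input_geometry"]


@dataclass(frozen=True)
class InputEnsemble:
    """Input weights U (N x N, C orthonormal non-vanishing columns)."""

    U: np.ndarray
    mode: str  # one_d | intermediate | high_d
    seed: int | None = None

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        if U.ndim != 2 or U.shape[0] != U.shape[1]:
            raise ValueError("U must be a square N x N matrix")
        object.__setattr__(self, "U", U)
        live = self._live_columns()
        gram = U[:, live].T @ U[:, live]
        if not np.allclose(gram, np.eye(live.size), atol=1e-10):
            raise ValueError("non-vanishing columns of U must be orthonormal")

    def _live_columns(self) -> np.ndarray:
        return np.flatnonzero(np.linalg.norm(self.U, axis=0) > 1e-14)

    @property
    def N(self) -> int:
        return self.U.shape[0]

    @property
    def C(self) -> int:
        return int(self._live_columns().size)

    @property
    def columns(self) -> np.ndarray:
        """The C non-vanishing columns, shape (N, C)."""
        return self.U[:, self._live_columns()]

    @property
    def u(self) -> np.ndarray:
        """The single input vector (one-dimensional ensembles only)."""
        if self.C != 1:
            raise ValueError(f"u is defined only for C = 1 ensembles, got C = {self.C}")
        return self.columns[:, 0]

    @property
    def sigma_inp(self) -> np.ndarray:
        """Static input covariance Sigma_inp = U U^T (rank C)."""
        return self.U @ self.U.T


@dataclass(frozen=True)
class InputGeometry:
    """Input-connectivity geometry entering the covariance formulas."""

    d_vectors: np.ndarray  # (R, N): d^r = Sigma_inp n^r
    sigma_matrix: np.ndarray  # (R, R): n^r . Sigma_inp n^r'
    rho_nu: np.ndarray  # (R, C): overlaps n^r . u_c
    rho_mu: np.ndarray  # (R, C): overlaps m^r . u_c


def make_input(
    N: int,
    mode: str,
    C: int | None = None,
    u: np.ndarray | None = None,
    seed: int | None = None,
) -> InputEnsemble:
    """Build an ensemble of the requested dimensionality.

    mode='one_d' uses the supplied u (normalized with a warning if needed) or
    a seeded random unit vector; mode='high_d' sets U = I; mode='intermediate'
    places C seeded random orthonormal columns (or the columns of u, if given
    as an (N, C) array).
    """
    if mode == "high_d":
        return InputEnsemble(U=np.eye(N), mode=mode, seed=seed)

    if mode == "one_d":
        C = 1
        if u is None:
            u = orthonormal_scaffold(N, 1, seed)[0]
        u = np.asarray(u, dtype=float)
        norm = np.linalg.norm(u)
        if norm == 0:
            raise ValueError("input vector u must be nonzero")
        if abs(norm - 1.0) > 1e-10:
            warnings.warn(f"input vector u had norm {norm:.6g}; normalizing", stacklevel=2)
            u = u / norm
        U = np.zeros((N, N))
        U[:, 0] = u
        return InputEnsemble(U=U, mode=mode, seed=seed)

    if mode == "intermediate":
        if C is None or not (1 <= C <= N):
            raise ValueError(f"intermediate mode needs 1 <= C <= N, got C = {C}")
        if u is not None:
            cols = np.atleast_2d(np.asarray(u, dtype=float))
            cols = cols.T if cols.shape[0] != N else cols
        else:
            cols = orthonormal_scaffold(N, C, seed).T
        U = np.zeros((N, N))
        U[:, :C] = cols[:, :C]
        return InputEnsemble(U=U, mode=mode, seed=seed)

    raise ValueError(f"unknown input mode {mode!r}")


def ei_input(theta: float) -> InputEnsemble:
    """One-dimensional input to the two-unit E-I circuit.

    u = (cos theta, sin theta) with theta in [0, pi]: theta = 0 drives only E,
    pi/2 only I, pi/4 the sum direction and 3 pi/4 the difference direction.
    """
    if not 0.0 <= theta <= np.pi:
        raise ValueError(f"theta must lie in [0, pi], got {theta}")
    u = np.array([np.cos(theta), np.sin(theta)])
    U = np.zeros((2, 2))
    U[:, 0] = u
    return InputEnsemble(U=U, mode="one_d")


def input_geometry(ensemble: InputEnsemble, spec: ConnectivitySpec) -> InputGeometry:
    """d^r, sigma_rr' and the per-column overlaps for a spec/ensemble pair."""
    if ensemble.N != spec.N:
        raise ValueError(f"dimension mismatch: ensemble N = {ensemble.N}, spec N = {spec.N}")
    sigma_inp = ensemble.sigma_inp
    d = spec.n_vectors @ sigma_inp.T  # (R, N); sigma_inp symmetric
    sigma = spec.n_vectors @ sigma_inp @ spec.n_vectors.T
    cols = ensemble.columns
    return InputGeometry(
        d_vectors=d,
        sigma_matrix=sigma,
        rho_nu=spec.n_vectors @ cols,
        rho_mu=spec.m_vectors @ cols,
    )


def ensemble_to_json(ensemble: InputEnsemble) -> str:
    return json.dumps(
        {"N": ensemble.N, "C": ensemble.C, "mode": ensemble.mode, "seed": ensemble.seed}
    )


def columns_to_csv(ensemble: InputEnsemble, path) -> None:
    """CSV export of the non-vanishing input columns."""
    import pandas as pd

    cols = {f"u{c + 1}": ensemble.columns[:, c] for c in range(ensemble.C)}
    pd.DataFrame(cols).to_csv(path, index=False)
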