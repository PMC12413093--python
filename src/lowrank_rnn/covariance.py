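"""Analytic stationary covariance of low-rank linear networks.

The dynamics dx/dt = -x + W x + U chi(t), with W = k sum_r m^r (n^r)^T and
unit-spectral-density white noise chi, settle into a stationary multivariate
Ornstein-Uhlenbeck process. Its equal-time covariance has the closed form

    Sigma = 1/2 { Sigma_inp
                  + sum_r k/(2 - l_r) [d^r (m^r)^T + m^r (d^r)^T]
                  + sum_{r,r'} sigma_rr' k^2 (4 - l_r - l_r')
                    / [(2 - l_r - l_r')(2 - l_r)(2 - l_r')] m^r (m^r')^T }

with l_r = k (m^r . n^r), d^r = Sigma_inp n^r and sigma_rr' =
n^r . Sigma_inp n^r'.  The three groups of terms are the local-input
covariance, the local/recurrent cross covariance and the recurrent
covariance; they are retained separately so variance can be attributed.

Time-lagged covariances Sigma(t, s) = <x(t) x(s)^T> in the stationary limit
are assembled from scalar coefficients c1..c4 that depend only on |t - s|,
k and the connectivity eigenvalues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivitySpec
from .inputs import InputEnsemble, input_geometry

__all__ = [
    "StationaryCovariance",
    "stationary_covariance",
    "lagged_covariance",
    "lagged_coefficients",
    "c4_cross",
    "lyapunov_residual",
]


@dataclass(frozen=True)
class StationaryCovariance:
    """Equal-time covariance Sigma with its additive component terms."""

    sigma: np.ndarray
    formula_tag: str
    term_input: np.ndarray
    term_cross: np.ndarray
    term_recurrent: np.ndarray

    def __post_init__(self) -> None:
        s = self.sigma
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        evals = np.linalg.eigvalsh(s)
        if evals.min() < -1e-10 * max(np.trace(s), 1.0):
            raise ValueError(f"covariance must be PSD; min eigenvalue {evals.min():.3e}")

    @property
    def N(self) -> int:
        return self.sigma.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.sigma).to_csv(path, index=False, header=False)

    def to_hdf5(self, path, metadata: dict | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("sigma", data=self.sigma)
            f.create_dataset("term_input", data=self.term_input)
            f.create_dataset("term_cross", data=self.term_cross)
            f.create_dataset("term_recurrent", data=self.term_recurrent)
            f.attrs["formula_tag"] = self.formula_tag
            if metadata:
                f.attrs["metadata"] = json.dumps(metadata)


def _recurrent_coefficients(k: float, lams: np.ndarray) -> np.ndarray:
    """R x R table k^2 (4 - l_r - l_s) / [(2 - l_r - l_s)(2 - l_r)(2 - l_s)]."""
    lr = lams[:, None]
    ls = lams[None, :]
    return k**2 * (4.0 - lr - ls) / ((2.0 - lr - ls) * (2.0 - lr) * (2.0 - ls))


def stationary_covariance(
    spec: ConnectivitySpec, ensemble: InputEnsemble, formula: str = "auto"
) -> StationaryCovariance:
    """Closed-form equal-time covariance for a stable spec/ensemble pair.

    ``formula`` selects the closed form used ('auto' picks the most
    specialized one); all routes agree to floating-point accuracy, the tag
    records provenance.
    """
    spec.require_stable()
    if ensemble.N != spec.N:
        raise ValueError("spec and ensemble dimensions differ")

    if formula == "auto":
        rank_part = "rank1" if spec.R == 1 else "rankR"
        mode_part = {"one_d": "1d", "high_d": "hd"}.get(ensemble.mode, "general")
        formula = f"{rank_part}-{mode_part}"

    k = spec.k
    lams = spec.eigenvalues
    geom = input_geometry(ensemble, spec)
    m = spec.m_vectors
    beta = _recurrent_coefficients(k, lams)

    if formula in ("rank1-general", "rankR-general"):
        term_input = 0.5 * ensemble.sigma_inp
        d = geom.d_vectors
        term_cross = np.zeros((spec.N, spec.N))
        for r in range(spec.R):
            a = 0.5 * k / (2.0 - lams[r])
            term_cross += a * (np.outer(d[r], m[r]) + np.outer(m[r], d[r]))
        term_rec = 0.5 * m.T @ (geom.sigma_matrix * beta) @ m
    elif formula in ("rank1-1d", "rankR-1d"):
        if ensemble.mode != "one_d":
            raise ValueError(f"formula {formula!r} requires a one-dimensional ensemble")
        u = ensemble.u
        rho_nu = geom.rho_nu[:, 0]
        term_input = 0.5 * np.outer(u, u)
        term_cross = np.zeros((spec.N, spec.N))
        for r in range(spec.R):
            a = 0.5 * rho_nu[r] * k / (2.0 - lams[r])
            term_cross += a * (np.outer(u, m[r]) + np.outer(m[r], u))
        term_rec = 0.5 * m.T @ (np.outer(rho_nu, rho_nu) * beta) @ m
    elif formula in ("rank1-hd", "rankR-hd"):
        if ensemble.mode != "high_d":
            raise ValueError(f"formula {formula!r} requires a high-dimensional ensemble")
        n = spec.n_vectors
        term_input = 0.5 * np.eye(spec.N)
        term_cross = np.zeros((spec.N, spec.N))
        for r in range(spec.R):
            a = 0.5 * k / (2.0 - lams[r])
            term_cross += a * (np.outer(n[r], m[r]) + np.outer(m[r], n[r]))
        term_rec = 0.5 * m.T @ (spec.rho_nn * beta) @ m
    else:
        raise ValueError(f"unknown formula tag {formula!r}")

    sigma = term_input + term_cross + term_rec
    return StationaryCovariance(
        sigma=sigma,
        formula_tag=formula,
        term_input=term_input,
        term_cross=term_cross,
        term_recurrent=term_rec,
    )


# ---------------------------------------------------------------------------
# lagged coefficients

_SMALL_LAMBDA = 1e-6
_CSTEP = 1e-150


def _divided_difference(f, lam: float) -> float:
    """(f(lam) - f(0)) / lam, complex-step midpoint derivative for small lam.

    The coefficients c2..c4 all carry a 1/lambda prefactor whose pole cancels
    analytically; evaluating the divided difference as f'(lam/2) via a complex
    step keeps full precision through lambda = 0.
    """
    if abs(lam) < _SMALL_LAMBDA:
        return float(f(0.5 * lam + 1j * _CSTEP).imag / _CSTEP)
    return float((np.real(f(lam)) - np.real(f(0.0))) / lam)


def _c2_pair(k: float, lam: float, dt: float) -> float:
    """c2 for dt = t - s < 0 (equivalently c3 for dt > 0, with dt -> -|dt|)."""
    def f(z):
        return np.exp((1.0 - z) * dt) / (2.0 - z)

    return k * _divided_difference(f, lam)


def c4_cross(k: float, lam_r: float, lam_rp: float, t: float, s: float) -> float:
    """Cross-rank recurrent coefficient c4^{rr'}(t, s) in the stationary limit.

    Continuous in both eigenvalues (including zero and coincident values) and
    symmetric under (t, s) -> (s, t) together with r <-> r'.
    """
    if t <= s:
        dt = t - s

        def f(z):
            return np.exp((1.0 - z) * dt) / ((2.0 - lam_r - z) * (2.0 - z))

        return k**2 * _divided_difference(f, lam_rp)
    return c4_cross(k, lam_rp, lam_r, s, t)


def lagged_coefficients(k: float, lam: float, t: float, s: float) -> tuple[float, float, float, float]:
    """(c1, c2, c3, c4) for a single rank-one component, stationary limit."""
    dt = t - s
    c1 = 0.5 * np.exp(-abs(dt))
    if dt <= 0:  # t < s
        c2 = _c2_pair(k, lam, dt)
        c3 = 0.5 * k * np.exp(dt) / (2.0 - lam)
    else:
        c2 = 0.5 * k * np.exp(-dt) / (2.0 - lam)
        c3 = _c2_pair(k, lam, -dt)
    c4 = c4_cross(k, lam, lam, t, s)
    return float(c1), float(c2), float(c3), float(c4)


def lagged_covariance(
    spec: ConnectivitySpec, ensemble: InputEnsemble, t: float, s: float
) -> np.ndarray:
    """Stationary two-time covariance Sigma(t, s) = <x(t) x(s)^T>.

    At t = s this reproduces the equal-time covariance exactly.
    """
    spec.require_stable()
    k = spec.k
    lams = spec.eigenvalues
    sigma_inp = ensemble.sigma_inp
    geom = input_geometry(ensemble, spec)
    m, d = spec.m_vectors, geom.d_vectors
    dt = t - s

    out = 0.5 * np.exp(-abs(dt)) * sigma_inp
    for r in range(spec.R):
        if dt <= 0:
            c2 = _c2_pair(k, lams[r], dt)
            c3 = 0.5 * k * np.exp(dt) / (2.0 - lams[r])
        else:
            c2 = 0.5 * k * np.exp(-dt) / (2.0 - lams[r])
            c3 = _c2_pair(k, lams[r], -dt)
        out += c2 * np.outer(d[r], m[r]) + c3 * np.outer(m[r], d[r])
    for r in range(spec.R):
        for rp in range(spec.R):
            c4 = c4_cross(k, lams[r], lams[rp], t, s)
            out += c4 * geom.sigma_matrix[r, rp] * np.outer(m[r], m[rp])
    return out


def lyapunov_residual(
    cov: StationaryCovariance | np.ndarray,
    spec: ConnectivitySpec,
    ensemble: InputEnsemble,
) -> float:
    """Frobenius norm of (W - I) Sigma + Sigma (W - I)^T + Sigma_inp.

    The analytic stationary covariance solves this Lyapunov equation exactly;
    the residual of any candidate covariance measures its violation of
    stationarity.
    """
    sigma = cov.sigma if isinstance(cov, StationaryCovariance) else np.asarray(cov, dtype=float)
    a = spec.matrix() - np.eye(spec.N)
    return float(np.linalg.norm(a @ sigma + sigma @ a.T + ensemble.sigma_inp, ord="fro"))
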