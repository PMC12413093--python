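"""Closed-form spectra of the stationary covariance and dimensionality.

Nonzero eigenvalues of a rank-P matrix sum_p l_p r_p^T coincide with the
eigenvalues of the P x P reduced matrix of inner products — this turns the
covariance eigenproblem into a 2x2 (rank one) or 2R x 2R (rank R) problem
that is solved exactly.

Under one-dimensional input the covariance has two nonzero eigenvalues
mu_+- and activity lives in the plane span{m, u}; under high-dimensional
input N - 2R eigenvalues sit at the reference value mu_ref = 1/2 and 2R are
perturbed by recurrence, with principal components in span{m^r, n^r}.
Dimensionality is summarized by the participation ratio
D = (sum mu)^2 / sum mu^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivitySpec
from .inputs import InputEnsemble, input_geometry

__all__ = [
    "SpectralSummary",
    "WrongRegimeError",
    "reduced_matrix",
    "spectrum_1d",
    "spectrum_hd",
    "spectrum_rank_r_hd",
    "participation_ratio",
    "closed_form_D_1d",
    "participation_ratio_1d",
    "eigenvalues_1d",
    "eigenvalues_hd",
    "gamma_hd",
    "limit_eigenvalues",
]

#: relative tolerance used to classify an eigenvalue as "perturbed away from mu_ref"
PERTURBED_RTOL = 1e-8


class WrongRegimeError(ValueError):
    """A specialized spectrum routine was called outside its regime."""


@dataclass(frozen=True)
class SpectralSummary:
    """Eigen-structure of a stationary covariance.

    ``eigenvalues`` holds all N covariance eigenvalues sorted descending
    (ties keep ascending original index). ``mu_plus``/``mu_minus`` are the
    recurrence-perturbed eigenvalues (scalars for rank one, arrays for higher
    rank); ``mu_ref`` is the value of the unperturbed eigenvalues (1/2 for
    unit-variance high-dimensional input, 0 for one-dimensional input).
    """

    eigenvalues: np.ndarray
    classes: np.ndarray  # per-eigenvalue label: plus | minus | reference | zero
    mu_plus: float | np.ndarray
    mu_minus: float | np.ndarray
    mu_ref: float
    gamma_plus: float | None
    gamma_minus: float | None
    v_plus: np.ndarray | None
    v_minus: np.ndarray | None
    participation_ratio: float
    alpha: float | None = None
    beta: float | None = None
    block_matrix: np.ndarray | None = field(default=None, repr=False)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "index": np.arange(self.eigenvalues.size),
                "mu": self.eigenvalues,
                "class": self.classes,
            }
        ).to_csv(path, index=False)

    def to_json(self) -> str:
        def _tolist(x):
            return np.asarray(x).tolist() if x is not None else None

        return json.dumps(
            {
                "mu_plus": _tolist(self.mu_plus),
                "mu_minus": _tolist(self.mu_minus),
                "mu_ref": self.mu_ref,
                "gamma_plus": self.gamma_plus,
                "gamma_minus": self.gamma_minus,
                "participation_ratio": self.participation_ratio,
                "alpha": self.alpha,
                "beta": self.beta,
            }
        )


def reduced_matrix(factor_pairs: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """P x P reduced matrix of M = sum_p left_p right_p^T.

    Entry (r, s) = left_r . right_s; the nonzero eigenvalues of M coincide
    with the eigenvalues of this matrix.
    """
    if not factor_pairs:
        raise ValueError("factor_pairs must be non-empty")
    lefts = np.stack([np.asarray(l, dtype=float) for l, _ in factor_pairs])
    rights = np.stack([np.asarray(r, dtype=float) for _, r in factor_pairs])
    if lefts.shape != rights.shape:
        raise ValueError("left and right vectors must share a common length")
    return lefts @ rights.T


def _sort_descending(mu: np.ndarray, classes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-mu, kind="stable")
    return mu[order], classes[order]


# ---------------------------------------------------------------------------
# one-dimensional input, rank one

def _alpha_beta(k, lam):
    return k / (2.0 - lam), k**2 / ((2.0 - lam) * (1.0 - lam))


def eigenvalues_1d(k, rho_mn, rho_nu, rho_mu):
    """Nonzero covariance eigenvalues (mu_plus, mu_minus), vectorized.

    mu_pm = 1/4 [ T +- sqrt(T^2 - 4 rho_nu^2 (1 - rho_mu^2)(beta - alpha^2)) ]
    with T = 1 + 2 alpha rho_mu rho_nu + beta rho_nu^2.
    """
    lam = np.asarray(k) * np.asarray(rho_mn)
    alpha, beta = _alpha_beta(np.asarray(k, dtype=float), lam)
    trace_term = 1.0 + 2.0 * alpha * rho_mu * rho_nu + beta * np.square(rho_nu)
    disc = np.square(trace_term) - 4.0 * np.square(rho_nu) * (1.0 - np.square(rho_mu)) * (
        beta - np.square(alpha)
    )
    root = np.sqrt(np.maximum(disc, 0.0))
    return 0.25 * (trace_term + root), 0.25 * (trace_term - root)


def participation_ratio_1d(k, rho_mn, rho_nu, rho_mu):
    """Closed-form participation ratio under one-dimensional input (in [1, 2])."""
    lam = np.asarray(k) * np.asarray(rho_mn)
    alpha, beta = _alpha_beta(np.asarray(k, dtype=float), lam)
    trace_term = 1.0 + 2.0 * alpha * rho_mu * rho_nu + beta * np.square(rho_nu)
    frac = (
        2.0
        * np.square(rho_nu)
        * (1.0 - np.square(rho_mu))
        * (beta - np.square(alpha))
        / np.square(trace_term)
    )
    return 1.0 / (1.0 - frac)


def closed_form_D_1d(spec: ConnectivitySpec, ensemble: InputEnsemble) -> float:
    """Participation ratio of a rank-one network under one-dimensional input."""
    if spec.R != 1 or ensemble.mode != "one_d":
        raise WrongRegimeError("closed_form_D_1d needs a rank-one spec and a one_d ensemble")
    geom = input_geometry(ensemble, spec)
    return float(
        participation_ratio_1d(
            spec.k, spec.rho_mn[0, 0], geom.rho_nu[0, 0], geom.rho_mu[0, 0]
        )
    )


def _orient(v: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip sign so the overlap with the reference direction is non-negative."""
    return -v if v @ reference < 0 else v


def spectrum_1d(spec: ConnectivitySpec, ensemble: InputEnsemble) -> SpectralSummary:
    """Closed-form spectrum for a rank-one network with one-dimensional input.

    Eigenvector ansatz v_pm = gamma_pm m + u. When rho_nu = 0 recurrence is
    disengaged: mu = (1/2, 0), gamma_pm = 0 and the only PC is u itself.
    """
    if spec.R != 1:
        raise WrongRegimeError("spectrum_1d needs a rank-one spec; use the general machinery")
    if ensemble.mode != "one_d":
        raise WrongRegimeError("spectrum_1d needs a one-dimensional ensemble")
    spec.require_stable()

    k = spec.k
    rho_mn = float(spec.rho_mn[0, 0])
    geom = input_geometry(ensemble, spec)
    rho_nu = float(geom.rho_nu[0, 0])
    rho_mu = float(geom.rho_mu[0, 0])
    lam = k * rho_mn
    alpha, beta = _alpha_beta(k, lam)
    mu_p, mu_m = (float(x) for x in eigenvalues_1d(k, rho_mn, rho_nu, rho_mu))

    denom = rho_mu + alpha * rho_nu
    if abs(rho_nu) < 1e-12 and abs(rho_mu) < 1e-12:
        gamma = {"+": 0.0, "-": 0.0}
    elif abs(denom) > 1e-12:
        trace_term = 1.0 + 2.0 * alpha * rho_mu * rho_nu + beta * rho_nu**2
        disc = trace_term**2 - 4.0 * rho_nu**2 * (1.0 - rho_mu**2) * (beta - alpha**2)
        root = np.sqrt(max(disc, 0.0))
        gamma = {
            "+": (-1.0 + beta * rho_nu**2 + root) / (2.0 * denom),
            "-": (-1.0 + beta * rho_nu**2 - root) / (2.0 * denom),
        }
    else:
        # fall back on the first eigen-equation of the ansatz system
        gamma = {}
        for sign, mu in (("+", mu_p), ("-", mu_m)):
            num = alpha * rho_nu + beta * rho_nu**2 * rho_mu
            den = 2.0 * mu - alpha * rho_nu * rho_mu - beta * rho_nu**2
            gamma[sign] = num / den if abs(den) > 1e-14 else 0.0

    m = spec.m_vectors[0]
    u = ensemble.u
    vs = {}
    for sign in ("+", "-"):
        v = gamma[sign] * m + u
        norm = np.linalg.norm(v)
        vs[sign] = _orient(v / norm, u) if norm > 1e-14 else u.copy()

    mu = np.concatenate([[mu_p, mu_m], np.zeros(spec.N - 2)])
    classes = np.array(["plus", "minus"] + ["zero"] * (spec.N - 2))
    mu, classes = _sort_descending(mu, classes)
    return SpectralSummary(
        eigenvalues=mu,
        classes=classes,
        mu_plus=mu_p,
        mu_minus=mu_m,
        mu_ref=0.0,
        gamma_plus=float(gamma["+"]),
        gamma_minus=float(gamma["-"]),
        v_plus=vs["+"],
        v_minus=vs["-"],
        participation_ratio=participation_ratio(mu),
        alpha=alpha,
        beta=beta,
    )


# ---------------------------------------------------------------------------
# high-dimensional input, rank one

def gamma_hd(k, rho_mn):
    """Ansatz coefficients (gamma_plus, gamma_minus) for v_pm = gamma m + n.

    gamma_pm = 1/2 [ k/(1-lam) +- sqrt((2 rho_mn + k/(1-lam))^2
                                        + 4 (1 - rho_mn^2)) ].
    """
    lam = np.asarray(k) * np.asarray(rho_mn)
    slow = np.asarray(k, dtype=float) / (1.0 - lam)
    root = np.sqrt(np.square(2.0 * np.asarray(rho_mn) + slow) + 4.0 * (1.0 - np.square(rho_mn)))
    return 0.5 * (slow + root), 0.5 * (slow - root)


def eigenvalues_hd(k, rho_mn):
    """Perturbed covariance eigenvalues (mu_plus, mu_minus), vectorized.

    mu_pm = (1 + mu_pm^lr)/2 with mu_pm^lr = k (gamma_pm + rho_mn)/(2 - lam);
    all remaining eigenvalues equal mu_ref = 1/2.
    """
    lam = np.asarray(k) * np.asarray(rho_mn)
    g_p, g_m = gamma_hd(k, rho_mn)
    mu_lr_p = np.asarray(k) * (g_p + rho_mn) / (2.0 - lam)
    mu_lr_m = np.asarray(k) * (g_m + rho_mn) / (2.0 - lam)
    return 0.5 * (1.0 + mu_lr_p), 0.5 * (1.0 + mu_lr_m)


def spectrum_hd(spec: ConnectivitySpec) -> SpectralSummary:
    """Closed-form spectrum for a rank-one network with high-dimensional input.

    N - 2 eigenvalues equal mu_ref = 1/2; the pair mu_pm brackets the
    reference strictly from above and below whenever k > 0.
    """
    if spec.R != 1:
        raise WrongRegimeError("spectrum_hd needs a rank-one spec; see spectrum_rank_r_hd")
    spec.require_stable()
    k = spec.k
    rho_mn = float(spec.rho_mn[0, 0])
    lam = k * rho_mn
    g_p, g_m = (float(x) for x in gamma_hd(k, rho_mn))
    mu_p, mu_m = (float(x) for x in eigenvalues_hd(k, rho_mn))

    m, n = spec.m_vectors[0], spec.n_vectors[0]
    vs = {}
    for g in (g_p, g_m):
        v = g * m + n
        norm = np.linalg.norm(v)
        vs[g] = _orient(v / norm, m) if norm > 1e-14 else m.copy()

    mu = np.concatenate([[mu_p, mu_m], np.full(spec.N - 2, 0.5)])
    classes = np.array(["plus", "minus"] + ["reference"] * (spec.N - 2))
    mu, classes = _sort_descending(mu, classes)
    alpha, beta = _alpha_beta(k, lam)
    return SpectralSummary(
        eigenvalues=mu,
        classes=classes,
        mu_plus=mu_p,
        mu_minus=mu_m,
        mu_ref=0.5,
        gamma_plus=g_p,
        gamma_minus=g_m,
        v_plus=vs[g_p],
        v_minus=vs[g_m],
        participation_ratio=participation_ratio(mu),
        alpha=alpha,
        beta=beta,
    )


# ---------------------------------------------------------------------------
# high-dimensional input, rank R

def _lowrank_factor_pairs(spec: ConnectivitySpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Factor pairs of the low-rank covariance component Sigma_lr (high-D).

    Sigma_lr = sum_r [ n^r (a_r m^r)^T
                       + m^r (a_r n^r + sum_s rho_nn[r,s] b_rs m^s)^T ]
    with a_r = k/(2 - l_r) and b_rs the recurrent coefficient table.
    """
    k = spec.k
    lams = spec.eigenvalues
    rho_nn = spec.rho_nn
    lr = lams[:, None]
    ls = lams[None, :]
    b = k**2 * (4.0 - lr - ls) / ((2.0 - lr - ls) * (2.0 - lr) * (2.0 - ls))
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for r in range(spec.R):
        a_r = k / (2.0 - lams[r])
        pairs.append((spec.n_vectors[r], a_r * spec.m_vectors[r]))
        right = a_r * spec.n_vectors[r] + (rho_nn[r] * b[r]) @ spec.m_vectors
        pairs.append((spec.m_vectors[r], right))
    return pairs


def spectrum_rank_r_hd(spec: ConnectivitySpec) -> SpectralSummary:
    """Spectrum for rank-R connectivity with high-dimensional input.

    Builds the 2R x 2R block-reduced matrix of the low-rank covariance
    component; its eigenvalues give the <= 2R perturbed covariance
    eigenvalues via mu = (1 + mu^lr)/2, the rest equal mu_ref = 1/2. The
    perturbed principal components are recovered as the matching linear
    combinations of {n^r, m^r}.
    """
    spec.require_stable()
    pairs = _lowrank_factor_pairs(spec)
    block = reduced_matrix(pairs)

    # eigenvectors of sum_p left_p right_p^T with eigenvalue mu are L w with
    # (R^T L) w = mu w
    lefts = np.stack([p[0] for p in pairs])
    rights = np.stack([p[1] for p in pairs])
    kmat = rights @ lefts.T
    mu_lr, wvecs = np.linalg.eig(kmat)
    if np.abs(mu_lr.imag).max(initial=0.0) > 1e-8:
        raise ValueError("reduced matrix produced complex eigenvalues; spec outside valid class")
    mu_lr = mu_lr.real

    mu_pert = 0.5 * (1.0 + mu_lr)
    perturbed = np.abs(mu_pert - 0.5) > PERTURBED_RTOL * 0.5
    classes_pert = np.where(mu_pert > 0.5, "plus", "minus")
    classes_pert = np.where(perturbed, classes_pert, "reference")

    vecs = (lefts.T @ wvecs.real).T  # rows: candidate eigenvectors of Sigma_lr
    norms = np.linalg.norm(vecs, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vecs = np.where(norms[:, None] > 1e-12, vecs / norms[:, None], vecs)

    n_ref = spec.N - mu_pert.size
    mu = np.concatenate([mu_pert, np.full(n_ref, 0.5)])
    classes = np.concatenate([classes_pert, np.full(n_ref, "reference")])
    mu, classes = _sort_descending(mu, classes)

    above = np.sort(mu_pert[perturbed & (mu_pert > 0.5)])[::-1]
    below = np.sort(mu_pert[perturbed & (mu_pert < 0.5)])[::-1]
    order = np.argsort(-mu_pert)
    return SpectralSummary(
        eigenvalues=mu,
        classes=classes,
        mu_plus=above,
        mu_minus=below,
        mu_ref=0.5,
        gamma_plus=None,
        gamma_minus=None,
        v_plus=vecs[order[0]] if mu_pert.size else None,
        v_minus=vecs[order[-1]] if mu_pert.size else None,
        participation_ratio=participation_ratio(mu),
        block_matrix=block,
    )


# ---------------------------------------------------------------------------
# dimensionality and limits

def participation_ratio(eigenvalues: np.ndarray) -> float:
    """D = (sum mu)^2 / sum mu^2, between 1 and the number of eigenvalues."""
    mu = np.asarray(eigenvalues, dtype=float)
    if mu.size == 0 or np.any(mu < -1e-12) or np.all(mu == 0):
        raise ValueError("participation ratio needs a non-negative, not-all-zero spectrum")
    mu = np.maximum(mu, 0.0)
    return float(mu.sum() ** 2 / np.square(mu).sum())


@dataclass(frozen=True)
class LimitSpectrum:
    mu_plus: float
    mu_minus: float
    gamma_plus: float
    gamma_minus: float


def limit_eigenvalues(spec: ConnectivitySpec, regime: str) -> LimitSpectrum:
    """Limiting high-dimensional-input eigen-structure of a rank-one network.

    'symmetric' is the line-attractor limit rho_mn -> 1/k (lambda -> 1):
    mu_plus diverges while mu_minus -> 1/2, gamma_plus -> +inf, gamma_minus
    -> 0. 'antisymmetric' is the autoencoder limit rho_mn = -1 (lambda = -k):
    mu_plus = 1/2, mu_minus = 1/(2 (1 + k)), gamma_plus = 1 and
    gamma_minus = -1/(1 + k).
    """
    if spec.R != 1:
        raise WrongRegimeError("limit_eigenvalues is defined for rank-one specs")
    k = spec.k
    if regime == "symmetric":
        return LimitSpectrum(
            mu_plus=np.inf, mu_minus=0.5, gamma_plus=np.inf, gamma_minus=0.0
        )
    if regime == "antisymmetric":
        return LimitSpectrum(
            mu_plus=0.5,
            mu_minus=0.5 / (1.0 + k),
            gamma_plus=1.0,
            gamma_minus=-1.0 / (1.0 + k),
        )
    raise ValueError(f"unknown regime {regime!r}; use 'symmetric' or 'antisymmetric'")
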