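"""Closed-form propagator exp[(W - I) t] for low-rank connectivity.

Because the rank-one components commute under the cross-orthogonality
constraint, the matrix exponential reduces to

    exp[(W - I) t] = exp(-t) [ I + sum_r k (exp(lambda^r t) - 1)/lambda^r
                                        m^r (n^r)^T ]

with the r-th factor replaced by k t m^r (n^r)^T when lambda^r = 0.
"""

from __future__ import annotations

import numpy as np

from .connectivity import ConnectivitySpec

__all__ = ["propagate", "phi"]

#: below this |lambda| the zero-eigenvalue series branch is used
LAMBDA_SWITCH = 1e-8


def phi(lam: float, t: float) -> float:
    """(exp(lam t) - 1)/lam, with a second-order series near lam = 0.

    The series t + lam t^2 / 2 avoids the catastrophic cancellation of
    expm1(lam t)/lam at tiny lam while keeping the branch switch continuous
    to ~1e-16 relative.
    """
    if abs(lam) < LAMBDA_SWITCH:
        return t + 0.5 * lam * t * t
    return float(np.expm1(lam * t) / lam)


def propagate(spec: ConnectivitySpec, t: float) -> np.ndarray:
    """Dense N x N propagator exp[(W - I) t] at time t >= 0."""
    if t < 0:
        raise ValueError(f"propagator time must be non-negative, got {t}")
    lams = spec.eigenvalues
    out = np.eye(spec.N)
    for r in range(spec.R):
        coeff = spec.k * phi(float(lams[r]), t)
        out += coeff * np.outer(spec.m_vectors[r], spec.n_vectors[r])
    return np.exp(-t) * out
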