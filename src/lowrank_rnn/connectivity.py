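"""Low-rank connectivity specifications.

A rank-R synaptic matrix is parameterized as W = k * sum_r m^r (n^r)^T with
unit-norm connectivity vectors m^r, n^r and a positive coupling constant k.
For the subclass handled here, rank-one components acting on mutually
orthogonal subspaces (n^r . m^s = 0 for r != s), the nonzero eigenvalues of W
are real and given by lambda^r = k * (m^r . n^r), each with eigenvector m^r.

The module builds such specifications from prescribed overlaps (seeded,
reproducible), maps the two-unit excitatory-inhibitory circuit onto the
rank-one form, and assembles dense matrices for validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectivitySpec",
    "EICircuitParams",
    "ConstructionError",
    "StabilityError",
    "overlap",
    "orthonormal_scaffold",
    "build_rank_one",
    "build_low_rank",
    "ei_to_rank_one",
    "assemble_connectivity_matrix",
    "spec_to_json",
    "spec_from_json",
    "vectors_to_csv",
]

#: default margin below lambda = 1 under which a spec is still called stable
STABILITY_MARGIN = 1e-6

ORTHO_TOL = 1e-12


class ConstructionError(ValueError):
    """Requested overlap structure is not realizable."""


class StabilityError(ValueError):
    """Operation requires a stable spec (all lambda^r < 1)."""


def overlap(v: np.ndarray, v2: np.ndarray) -> float:
    """Overlap rho = v . v2 between two equal-length vectors.

    For unit-norm vectors this is the cosine of the angle and lies in [-1, 1].
    """
    v = np.asarray(v, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v.shape != v2.shape or v.ndim != 1:
        raise ValueError(
            f"overlap requires two vectors of equal length, got shapes {v.shape} and {v2.shape}"
        )
    return float(v @ v2)


@dataclass(frozen=True)
class ConnectivitySpec:
    """Rank-R low-rank connectivity W = k * sum_r m^r (n^r)^T.

    Vectors are stored row-wise in (R, N) arrays and are unit norm. The
    requested coupling k is never rescaled.
    """

    k: float
    m_vectors: np.ndarray  # (R, N)
    n_vectors: np.ndarray  # (R, N)
    seed: int | None = None
    stability_margin: float = field(default=STABILITY_MARGIN, repr=False)

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.m_vectors, dtype=float))
        n = np.atleast_2d(np.asarray(self.n_vectors, dtype=float))
        if m.shape != n.shape:
            raise ValueError("m_vectors and n_vectors must have identical shapes")
        if self.k < 0:
            # k = 0 (unconnected network) is allowed as a useful degenerate case
            raise ValueError(f"coupling k must be non-negative, got {self.k}")
        object.__setattr__(self, "m_vectors", m)
        object.__setattr__(self, "n_vectors", n)
        norms_m = np.linalg.norm(m, axis=1)
        norms_n = np.linalg.norm(n, axis=1)
        if not (np.allclose(norms_m, 1.0, atol=1e-10) and np.allclose(norms_n, 1.0, atol=1e-10)):
            raise ValueError("connectivity vectors must be unit norm")
        # cross-orthogonality n^r . m^s = 0 (r != s) keeps eigenvalues real and
        # the closed-form propagator/covariance valid
        cross = n @ m.T
        off = cross - np.diag(np.diag(cross))
        if np.abs(off).max(initial=0.0) > 1e-10:
            raise ConstructionError(
                "rank-one components must act on orthogonal subspaces: "
                f"max |n^r . m^s| (r != s) = {np.abs(off).max():.2e}"
            )

    @property
    def N(self) -> int:
        return self.m_vectors.shape[1]

    @property
    def R(self) -> int:
        return self.m_vectors.shape[0]

    @property
    def rho_mn(self) -> np.ndarray:
        """R x R overlap table rho_{m^r n^s} = m^r . n^s."""
        return self.m_vectors @ self.n_vectors.T

    @property
    def rho_mm(self) -> np.ndarray:
        return self.m_vectors @ self.m_vectors.T

    @property
    def rho_nn(self) -> np.ndarray:
        return self.n_vectors @ self.n_vectors.T

    @property
    def eigenvalues(self) -> np.ndarray:
        """Nonzero eigenvalues lambda^r = k * (m^r . n^r) of W."""
        return self.k * np.einsum("ri,ri->r", self.m_vectors, self.n_vectors)

    @property
    def stable(self) -> bool:
        return bool(self.eigenvalues.max() < 1.0 - self.stability_margin)

    def require_stable(self) -> None:
        if not self.stable:
            raise StabilityError(
                f"spec is unstable: max lambda^r = {self.eigenvalues.max():.6g} >= "
                f"{1.0 - self.stability_margin:.6g}"
            )

    def matrix(self) -> np.ndarray:
        return assemble_connectivity_matrix(self)


@dataclass(frozen=True)
class EICircuitParams:
    """Two-unit excitatory-inhibitory circuit, W = w * [[1, -g], [1, -g]].

    w is the overall connection strength, g the relative dominance of
    inhibition over excitation (g > 1: inhibition-dominated).
    """

    w: float
    g: float

    def __post_init__(self) -> None:
        if self.w < 0 or self.g < 0:
            raise ValueError("E-I parameters w and g must be non-negative")


def orthonormal_scaffold(N: int, count: int, seed: int | None) -> np.ndarray:
    """`count` seeded random orthonormal N-vectors, shape (count, N).

    QR factorization of a standard-normal matrix; each column's sign is fixed
    so that its first nonzero entry is positive, making the scaffold a pure
    function of the seed.
    """
    if count > N:
        raise ValueError(f"cannot draw {count} orthonormal vectors in dimension {N}")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((N, count)))
    for j in range(count):
        col = q[:, j]
        lead = col[np.flatnonzero(np.abs(col) > 1e-14)[0]]
        if lead < 0:
            q[:, j] = -col
    return q.T


def build_rank_one(
    N: int, k: float, rho_mn: float, seed: int | None = None
) -> ConnectivitySpec:
    """Rank-one spec with prescribed overlap m . n = rho_mn.

    m = z1 and n = rho_mn z1 + sqrt(1 - rho_mn^2) z2 for a seeded random
    orthonormal pair {z1, z2}.
    """
    if N < 2:
        raise ValueError("need N >= 2")
    if abs(rho_mn) > 1:
        raise ValueError(f"|rho_mn| must be <= 1, got {rho_mn}")
    z = orthonormal_scaffold(N, 2, seed)
    m = z[0]
    n = rho_mn * z[0] + np.sqrt(max(1.0 - rho_mn**2, 0.0)) * z[1]
    return ConnectivitySpec(k=k, m_vectors=m[None, :], n_vectors=n[None, :], seed=seed)


def build_low_rank(
    N: int,
    k: float,
    *,
    rho_mn: float | list[float] | np.ndarray | None = None,
    rho_m1m2: float | None = None,
    rho_n1n2: float | None = None,
    seed: int | None = None,
) -> ConnectivitySpec:
    """Rank-R spec in one of two parametrizations.

    Orthogonal-subspace (pass ``rho_mn``, one internal overlap per rank):
    m^r = z_r, n^r = rho_r z_r + sqrt(1 - rho_r^2) z_{R+r} with 2R orthonormal
    scaffold vectors; all cross overlaps vanish and lambda^r = k rho_r.

    Cross-overlap (pass ``rho_m1m2`` and/or ``rho_n1n2``, rank two): the m-span
    and n-span are orthogonal, so all rho_{m^r n^s} = 0 and both eigenvalues of
    W vanish, while m^1 . m^2 and n^1 . n^2 take the prescribed values.
    """
    if rho_mn is not None:
        if rho_m1m2 is not None or rho_n1n2 is not None:
            raise ValueError("choose either the rho_mn or the cross-overlap parametrization")
        rho = np.atleast_1d(np.asarray(rho_mn, dtype=float))
        if np.abs(rho).max() > 1:
            raise ValueError("all |rho_{m^r n^r}| must be <= 1")
        R = rho.size
        if R == 1:
            return build_rank_one(N, k, float(rho[0]), seed)
        if N < 2 * R:
            raise ConstructionError(f"orthogonal-subspace rank {R} needs N >= {2 * R}")
        z = orthonormal_scaffold(N, 2 * R, seed)
        m = z[:R].copy()
        n = rho[:, None] * z[:R] + np.sqrt(np.maximum(1.0 - rho**2, 0.0))[:, None] * z[R:]
        return ConnectivitySpec(k=k, m_vectors=m, n_vectors=n, seed=seed)

    rm = 0.0 if rho_m1m2 is None else float(rho_m1m2)
    rn = 0.0 if rho_n1n2 is None else float(rho_n1n2)
    if rho_m1m2 is None and rho_n1n2 is None:
        raise ValueError("specify rho_mn, or rho_m1m2/rho_n1n2 for the rank-two parametrization")
    if abs(rm) > 1 or abs(rn) > 1:
        raise ValueError("cross overlaps must have magnitude <= 1")
    if N < 4:
        raise ConstructionError("cross-overlap rank-two parametrization needs N >= 4")
    z = orthonormal_scaffold(N, 4, seed)
    m = np.stack([z[0], rm * z[0] + np.sqrt(max(1 - rm**2, 0.0)) * z[1]])
    n = np.stack([z[2], rn * z[2] + np.sqrt(max(1 - rn**2, 0.0)) * z[3]])
    return ConnectivitySpec(k=k, m_vectors=m, n_vectors=n, seed=seed)


def ei_to_rank_one(params: EICircuitParams) -> ConnectivitySpec:
    """Map the E-I circuit onto the rank-one form.

    m = (1, 1)/sqrt(2) (sum direction), n = (1, -g)/sqrt(g^2 + 1),
    k = w sqrt(2 (g^2 + 1)); the nonzero eigenvalue is w (1 - g).
    """
    if params.w == 0:
        raise ValueError("w = 0 gives a degenerate (zero) connectivity with no rank-one form")
    g = params.g
    m = np.array([1.0, 1.0]) / np.sqrt(2.0)
    n = np.array([1.0, -g]) / np.sqrt(g**2 + 1.0)
    k = params.w * np.sqrt(2.0 * (g**2 + 1.0))
    return ConnectivitySpec(k=k, m_vectors=m[None, :], n_vectors=n[None, :])


def assemble_connectivity_matrix(spec: ConnectivitySpec) -> np.ndarray:
    """Dense W = k * sum_r m^r (n^r)^T."""
    return spec.k * (spec.m_vectors.T @ spec.n_vectors)


# ---------------------------------------------------------------------------
# serialization

def spec_to_json(spec: ConnectivitySpec) -> str:
    """JSON round-trip representation (vectors included verbatim)."""
    payload = {
        "N": spec.N,
        "R": spec.R,
        "k": spec.k,
        "seed": spec.seed,
        "rho_mn": spec.rho_mn.tolist(),
        "m_vectors": spec.m_vectors.tolist(),
        "n_vectors": spec.n_vectors.tolist(),
    }
    return json.dumps(payload)


def spec_from_json(text: str) -> ConnectivitySpec:
    payload = json.loads(text)
    return ConnectivitySpec(
        k=payload["k"],
        m_vectors=np.asarray(payload["m_vectors"], dtype=float),
        n_vectors=np.asarray(payload["n_vectors"], dtype=float),
        seed=payload.get("seed"),
    )


def vectors_to_csv(spec: ConnectivitySpec, path) -> None:
    """Full-vector export, one column per connectivity vector."""
    import pandas as pd

    cols = {f"m{r + 1}": spec.m_vectors[r] for r in range(spec.R)}
    cols.update({f"n{r + 1}": spec.n_vectors[r] for r in range(spec.R)})
    pd.DataFrame(cols).to_csv(path, index=False)
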