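"""Stochastic simulation of the low-rank network dynamics.

Euler-Maruyama discretization of dx/dt = -x + W x + U chi(t):

    x(t + tau) = (1 - tau) x(t) + tau W x(t) + sqrt(tau) U chi(t + tau)

with chi i.i.d. standard normal per step (unit-spectral-density white
noise). Optionally the activity is split into a local component (leaky
integration of the noise alone) and per-rank recurrent components, driven by
the same noise draws so that x = x_loc + sum_r x_rec_r holds exactly at
every sample.

The tau = 1 special case is the discrete-time map widely used in machine
learning and statistical modelling: the local component is then memoryless
(x_loc(n) = xi(n)) and local and recurrent components are uncorrelated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivitySpec
from .inputs import InputEnsemble

__all__ = [
    "SimulationConfig",
    "TrajectoryEnsemble",
    "simulate",
    "discrete_map_simulate",
    "empirical_covariance",
    "empirical_pcs",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    tau is the Euler step (leak time constant = 1), t_total the simulated
    duration per realization and burn_in the discarded initial transient
    (x(0) = 0, so exp(-burn_in) bounds the residual bias). record_every
    thins the stored samples; the integration itself always advances in
    steps of tau.
    """

    tau: float = 0.01
    t_total: float = 2000.0
    burn_in: float = 20.0
    seed: int | None = None
    n_realizations: int = 16
    track_components: bool = False
    record_every: int = 10
    strict_stability: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.burn_in < self.t_total:
            raise ValueError("need 0 <= burn_in < t_total")
        if self.n_realizations < 1 or self.record_every < 1:
            raise ValueError("n_realizations and record_every must be >= 1")


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Sampled activity, shape (n_realizations, n_samples, N)."""

    times: np.ndarray
    x: np.ndarray
    x_loc: np.ndarray | None = None
    x_rec: np.ndarray | None = None  # (n_real, n_samples, R, N) when tracked
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("x", data=self.x)
            if self.x_loc is not None:
                f.create_dataset("x_loc", data=self.x_loc)
            if self.x_rec is not None:
                f.create_dataset("x_rec", data=self.x_rec)
            f.attrs["metadata"] = json.dumps(self.metadata)


def _run(
    spec: ConnectivitySpec,
    ensemble: InputEnsemble,
    config: SimulationConfig,
    tau: float,
) -> TrajectoryEnsemble:
    import warnings

    if not spec.stable:
        if config.strict_stability:
            spec.require_stable()
        warnings.warn(
            f"simulating an unstable spec (max lambda = {spec.eigenvalues.max():.4g}); "
            "trajectories may diverge",
            stacklevel=3,
        )

    n_steps = int(round(config.t_total / tau))
    burn_steps = int(round(config.burn_in / tau))
    n_real, N, R = config.n_realizations, spec.N, spec.R
    rng = np.random.default_rng(config.seed)
    cols = ensemble.columns  # (N, C): only live columns receive noise
    C = cols.shape[1]
    sqrt_tau = np.sqrt(tau)
    w_mat = spec.matrix()
    a_full = (1.0 - tau) * np.eye(N) + tau * w_mat

    record_idx = np.arange(burn_steps + 1, n_steps + 1)
    record_idx = record_idx[(record_idx - burn_steps - 1) % config.record_every == 0]
    keep = np.zeros(n_steps + 2, dtype=bool)
    keep[record_idx] = True
    n_samples = int(keep.sum())

    x = np.zeros((n_real, N))
    out = np.empty((n_real, n_samples, N))
    track = config.track_components
    if track:
        x_loc = np.zeros((n_real, N))
        x_rec = np.zeros((n_real, R, N))
        out_loc = np.empty((n_real, n_samples, N))
        out_rec = np.empty((n_real, n_samples, R, N))
        k_m = tau * spec.k * spec.m_vectors  # (R, N)

    j = 0
    for step in range(1, n_steps + 1):
        xi = (rng.standard_normal((n_real, C)) @ cols.T) * sqrt_tau
        if track:
            # recurrent pieces read the full activity of the previous step
            drive = x @ spec.n_vectors.T  # (n_real, R)
            x_rec = (1.0 - tau) * x_rec + drive[:, :, None] * k_m[None, :, :]
            x_loc = (1.0 - tau) * x_loc + xi
            x = x_loc + x_rec.sum(axis=1)
        else:
            x = x @ a_full.T + xi
        if keep[step]:
            out[:, j] = x
            if track:
                out_loc[:, j] = x_loc
                out_rec[:, j] = x_rec
            j += 1

    times = record_idx * tau
    meta = {
        "tau": tau,
        "t_total": config.t_total,
        "burn_in": config.burn_in,
        "seed": config.seed,
        "n_realizations": n_real,
        "record_every": config.record_every,
        "spec": {"N": N, "R": R, "k": spec.k, "seed": spec.seed},
        "ensemble": {"mode": ensemble.mode, "C": ensemble.C, "seed": ensemble.seed},
    }
    return TrajectoryEnsemble(
        times=times,
        x=out,
        x_loc=out_loc if track else None,
        x_rec=out_rec if track else None,
        metadata=meta,
    )


def simulate(
    spec: ConnectivitySpec, ensemble: InputEnsemble, config: SimulationConfig
) -> TrajectoryEnsemble:
    """Euler-Maruyama trajectories from x(0) = 0, deterministic given seed."""
    if ensemble.N != spec.N:
        raise ValueError("spec and ensemble dimensions differ")
    return _run(spec, ensemble, config, config.tau)


def discrete_map_simulate(
    spec: ConnectivitySpec, ensemble: InputEnsemble, config: SimulationConfig
) -> TrajectoryEnsemble:
    """The tau = 1 discrete map x(t+1) = W x(t) + xi(t+1).

    Memory of past inputs is carried exclusively by the recurrent component.
    Requires spectral radius of W below one for stationarity.
    """
    if ensemble.N != spec.N:
        raise ValueError("spec and ensemble dimensions differ")
    if np.abs(spec.eigenvalues).max(initial=0.0) >= 1.0 and config.strict_stability:
        raise ValueError("discrete map needs |lambda^r| < 1 for all r")
    return _run(spec, ensemble, config, 1.0)


def empirical_covariance(traj: TrajectoryEnsemble) -> np.ndarray:
    """Covariance pooled over time and realizations, empirical mean removed."""
    samples = traj.x.reshape(-1, traj.x.shape[-1])
    if samples.shape[0] < 10:
        raise ValueError(f"need at least 10 retained samples, got {samples.shape[0]}")
    centered = samples - samples.mean(axis=0)
    return centered.T @ centered / samples.shape[0]


def empirical_pcs(cov_hat: np.ndarray, reference_vectors: dict[str, np.ndarray]):
    """Sorted eigenpairs of an empirical covariance with reference overlaps.

    Returns a DataFrame with one row per principal component (descending
    eigenvalue) and one column of absolute normalized overlaps per supplied
    reference vector; the sign of a PC is arbitrary, hence absolute values.
    """
    import pandas as pd

    cov_hat = np.asarray(cov_hat, dtype=float)
    if not np.allclose(cov_hat, cov_hat.T, atol=1e-8):
        raise ValueError("empirical covariance must be symmetric")
    evals, evecs = np.linalg.eigh(cov_hat)
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]
    data = {"pc": np.arange(1, evals.size + 1), "eigenvalue": evals}
    for name, ref in reference_vectors.items():
        ref = np.asarray(ref, dtype=float)
        ref = ref / np.linalg.norm(ref)
        data[f"overlap_{name}"] = np.abs(evecs.T @ ref)
    return pd.DataFrame(data)
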