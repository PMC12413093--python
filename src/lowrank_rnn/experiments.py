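"""Figure-level experiment drivers producing tidy tables.

Each driver evaluates the closed-form theory over a parameter grid and
returns a pandas DataFrame (one row per grid point) so that sweeps are
machine-readable and bit-reproducible from config + seed. Plotting is a
thin, optional layer on top and is never the source of any asserted number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import EICircuitParams, build_low_rank, build_rank_one, ei_to_rank_one
from .inputs import ei_input, make_input
from .spectrum import (
    closed_form_D_1d,
    eigenvalues_hd,
    gamma_hd,
    participation_ratio,
    spectrum_1d,
    spectrum_hd,
    spectrum_rank_r_hd,
)

__all__ = [
    "ExperimentConfig",
    "run_overlap_sweep",
    "run_rank_two_sweep",
    "run_ei_maps",
    "ei_stability_boundaries",
    "random_geometry_sweep",
]

SUM_DIRECTION = np.array([1.0, 1.0]) / np.sqrt(2.0)
DIFF_DIRECTION = np.array([1.0, -1.0]) / np.sqrt(2.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Config for a named experiment driver."""

    experiment: str  # fig2_one_d | fig3_overlap_sweep | fig4_examples | fig5_rank_two | fig6_ei_maps
    params: dict = field(default_factory=dict)
    seed: int | None = None
    out_dir: str | None = None


def run_overlap_sweep(k: float, rho_grid, N: int = 100) -> pd.DataFrame:
    """Covariance eigenvalues, PC geometry and dimensionality vs rho_mn.

    High-dimensional input, rank one. Rows with lambda = k rho_mn >= 1 are
    flagged unstable and carry NaN spectra. N enters only through the
    participation ratio's ceiling.
    """
    rows = []
    for rho in np.asarray(rho_grid, dtype=float):
        lam = k * rho
        row = {"rho_mn": rho, "lam": lam, "stable": lam < 1.0}
        if row["stable"]:
            mu_p, mu_m = (float(x) for x in eigenvalues_hd(k, rho))
            g_p, g_m = (float(x) for x in gamma_hd(k, rho))
            mu = np.concatenate([[mu_p, mu_m], np.full(N - 2, 0.5)])
            norm_p = np.sqrt(g_p**2 + 2.0 * rho * g_p + 1.0)
            norm_m = np.sqrt(g_m**2 + 2.0 * rho * g_m + 1.0)
            row.update(
                mu_plus=mu_p,
                mu_minus=mu_m,
                D=participation_ratio(mu),
                gamma_plus=g_p,
                gamma_minus=g_m,
                comp_vplus_m=abs(g_p) / norm_p,
                comp_vplus_n=1.0 / norm_p,
                comp_vminus_m=abs(g_m) / norm_m,
                comp_vminus_n=1.0 / norm_m,
                overlap_vplus_m=abs(g_p + rho) / norm_p,
                overlap_vplus_n=abs(g_p * rho + 1.0) / norm_p,
                overlap_vminus_m=abs(g_m + rho) / norm_m,
                overlap_vminus_n=abs(g_m * rho + 1.0) / norm_m,
            )
        else:
            row.update({c: np.nan for c in (
                "mu_plus", "mu_minus", "D", "gamma_plus", "gamma_minus",
                "comp_vplus_m", "comp_vplus_n", "comp_vminus_m", "comp_vminus_n",
                "overlap_vplus_m", "overlap_vplus_n", "overlap_vminus_m", "overlap_vminus_n",
            )})
        rows.append(row)
    return pd.DataFrame(rows)


def run_rank_two_sweep(
    parametrization: str,
    grid_1,
    grid_2,
    k: float = 2.0,
    N: int = 50,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Perturbed covariance eigenvalues and dimensionality for rank-two nets.

    parametrization='orthogonal': grid over (rho_m1n1, rho_m2n2) with all
    cross overlaps zero. parametrization='cross': grid over (rho_m1m2,
    rho_n1n2) with both internal overlaps zero (vanishing eigenvalues).
    The four perturbed eigenvalues are reported sorted ascending, together
    with counts above/below the reference value 1/2.
    """
    if parametrization not in ("orthogonal", "cross"):
        raise ValueError("parametrization must be 'orthogonal' or 'cross'")
    rows = []
    for r1 in np.asarray(grid_1, dtype=float):
        for r2 in np.asarray(grid_2, dtype=float):
            if parametrization == "orthogonal":
                spec = build_low_rank(N, k, rho_mn=[r1, r2], seed=seed)
                row = {"rho_m1n1": r1, "rho_m2n2": r2}
            else:
                spec = build_low_rank(N, k, rho_m1m2=r1, rho_n1n2=r2, seed=seed)
                row = {"rho_m1m2": r1, "rho_n1n2": r2}
            row["stable"] = spec.stable
            if spec.stable:
                summ = spectrum_rank_r_hd(spec)
                pert = np.sort(np.concatenate([np.atleast_1d(summ.mu_plus),
                                               np.atleast_1d(summ.mu_minus)]))
                for i, mu in enumerate(pert, start=1):
                    row[f"mu_{i}"] = mu
                row["n_above"] = int(np.sum(pert > 0.5))
                row["n_below"] = int(np.sum(pert < 0.5))
                row["D"] = summ.participation_ratio
            else:
                row.update({f"mu_{i}": np.nan for i in range(1, 5)})
                row.update(n_above=0, n_below=0, D=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def run_ei_maps(
    w_grid,
    g_grid,
    input_mode: str = "high_d",
    theta_grid=None,
) -> pd.DataFrame:
    """Amplification maps for the two-unit excitatory-inhibitory circuit.

    For each stable (w, g) — and each input angle theta under one-dimensional
    input — reports the variance explained by PC1/PC2 (mu_i / sum mu), the
    absolute overlaps of PC1 with the sum and difference directions, and the
    connectivity eigenvalue lambda = w (1 - g). Along fixed-theta slices the
    connectivity eigenvalues are constant while amplification varies: the
    signature of non-normal dynamics.
    """
    if input_mode == "one_d":
        thetas = np.asarray(
            theta_grid if theta_grid is not None else np.linspace(0.0, np.pi, 19)
        )
    elif input_mode == "high_d":
        thetas = np.array([np.nan])
    else:
        raise ValueError("input_mode must be 'one_d' or 'high_d'")

    rows = []
    for w in np.asarray(w_grid, dtype=float):
        for g in np.asarray(g_grid, dtype=float):
            lam = w * (1.0 - g)
            base = {"w": w, "g": g, "lam": lam, "stable": lam < 1.0 - 1e-6}
            for theta in thetas:
                row = dict(base)
                if input_mode == "one_d":
                    row["theta"] = theta
                if not base["stable"] or w == 0.0:
                    row.update(var_pc1=np.nan, var_pc2=np.nan,
                               overlap_pc1_sum=np.nan, overlap_pc1_diff=np.nan)
                    rows.append(row)
                    continue
                spec = ei_to_rank_one(EICircuitParams(w=w, g=g))
                if input_mode == "high_d":
                    summ = spectrum_hd(spec)
                else:
                    summ = spectrum_1d(spec, ei_input(theta))
                total = summ.eigenvalues.sum()
                pc1 = summ.v_plus
                row.update(
                    var_pc1=float(summ.eigenvalues[0] / total),
                    var_pc2=float(summ.eigenvalues[1] / total),
                    mu_plus=float(np.atleast_1d(summ.mu_plus)[0]),
                    mu_minus=float(np.atleast_1d(summ.mu_minus)[0]),
                    overlap_pc1_sum=float(abs(pc1 @ SUM_DIRECTION)),
                    overlap_pc1_diff=float(abs(pc1 @ DIFF_DIRECTION)),
                )
                rows.append(row)
    return pd.DataFrame(rows)


def random_geometry_sweep(
    n_samples: int, N: int = 100, k_max: float = 10.0, seed: int | None = 0
) -> pd.DataFrame:
    """Dimensionality of rank-one networks under one-dimensional input, over
    random vector geometries and stable couplings.

    Each sample draws m, n, u as independent random unit vectors in R^N and a
    coupling k ~ U(0, k_max]; wherever lambda = k rho_mn would reach 1, k is
    resampled uniformly below (1 - 1e-6)/rho_mn so every row is stable (for
    rho_mn <= 0 the stable range in k is unbounded and the raw draw stands).
    Returns the overlaps, the closed-form participation ratio D, its
    cross-check D_spectral = (mu_+ + mu_-)^2 / (mu_+^2 + mu_-^2) from the
    analytic eigenvalue pair, and the eigenvalues themselves.
    """
    rng = np.random.default_rng(seed)
    vecs = rng.standard_normal((n_samples, 3, N))
    vecs /= np.linalg.norm(vecs, axis=2, keepdims=True)
    m, n, u = vecs[:, 0], vecs[:, 1], vecs[:, 2]
    rho_mn = np.einsum("ij,ij->i", m, n)
    rho_nu = np.einsum("ij,ij->i", n, u)
    rho_mu = np.einsum("ij,ij->i", m, u)

    k = rng.uniform(0.0, k_max, n_samples)
    cap = np.where(rho_mn > 0, (1.0 - 1e-6) / np.maximum(rho_mn, 1e-12), np.inf)
    over = k * rho_mn >= 1.0 - 1e-6
    k = np.where(over, rng.uniform(0.0, 1.0, n_samples) * cap, k)

    from .spectrum import eigenvalues_1d, participation_ratio_1d

    d_closed = participation_ratio_1d(k, rho_mn, rho_nu, rho_mu)
    mu_p, mu_m = eigenvalues_1d(k, rho_mn, rho_nu, rho_mu)
    d_spectral = (mu_p + mu_m) ** 2 / (mu_p**2 + mu_m**2)
    return pd.DataFrame(
        {
            "k": k,
            "rho_mn": rho_mn,
            "rho_nu": rho_nu,
            "rho_mu": rho_mu,
            "lam": k * rho_mn,
            "mu_plus": mu_p,
            "mu_minus": mu_m,
            "D": d_closed,
            "D_spectral": d_spectral,
        }
    )


def ei_stability_boundaries(g_grid) -> pd.DataFrame:
    """Loci lambda = 1 (w = 1/(1 - g), g < 1) and lambda = 0 (g = 1) in the (w, g) plane."""
    g = np.asarray(g_grid, dtype=float)
    w_unstable = np.where(g < 1.0, 1.0 / np.maximum(1.0 - g, 1e-12), np.nan)
    return pd.DataFrame({"g": g, "w_lambda_1": w_unstable, "g_lambda_0": np.ones_like(g)})
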