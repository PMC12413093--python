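# lowrank-rnn

Closed-form stationary statistics — and validating stochastic simulation —
for linear recurrent neural networks with **low-rank connectivity** driven by
**white-noise inputs**:

```
dx/dt = -x + W x + U chi(t),        W = k * sum_r m^r (n^r)^T
```

Here `m^r`, `n^r` are unit-norm connectivity vectors, `k` is the coupling
strength, and `chi(t)` is unit-spectral-density Gaussian white noise fed in
through a weight matrix `U` whose `C` orthonormal non-vanishing columns set
the **input dimensionality** (`C = 1`: a single broadcast signal along a
vector `u`; `C = N`, `U = I`: independent noise per unit). The stationary
activity is a multivariate Ornstein–Uhlenbeck process, and everything about
its second-order statistics is computable in closed form.

The package is aimed at theorists and data analysts who work with low-rank
RNN models of neural circuits: it answers "given these connectivity vectors
and this input geometry, what covariance, principal components and
dimensionality should I expect?" without ever integrating the dynamics — and
then lets you integrate them anyway to check.

## What it computes

- **Propagator** `exp[(W - I)t]` in closed form for rank-R connectivity whose
  rank-one components act on mutually orthogonal subspaces
  (`n^r . m^s = 0` for `r != s`), including the zero-eigenvalue branch.
- **Stationary covariance** `Sigma` for any rank and input dimensionality,
  with local / cross / recurrent component terms kept separate, plus the
  time-lagged covariance `Sigma(t, s)` and a Lyapunov-equation residual
  check `(W - I) Sigma + Sigma (W - I)^T + U U^T = 0`.
- **Spectra by the reduced-matrix method**: with one-dimensional input the
  covariance is rank two — eigenvalues `mu_+-` and principal components
  `v_+- = gamma_+- m + u` in the `m`–`u` plane; with high-dimensional input
  `N - 2R` eigenvalues sit at the reference value `mu_ref = 1/2` and `2R`
  are perturbed (half amplified, half suppressed), with PCs in
  `span{m^r, n^r}`. Participation-ratio dimensionality
  `D = (sum mu)^2 / sum mu^2` (closed form and spectral).
- **Simulation**: Euler–Maruyama integration and the `tau = 1` discrete map,
  with exact splitting of activity into local and recurrent components, and
  empirical covariance / PC estimation.
- **Excitatory-inhibitory circuit**: the 2-unit circuit
  `W = w [[1, -g], [1, -g]]` mapped onto the rank-one form
  (`m` = sum direction, `n` ~ difference direction, `lambda = w(1 - g)`),
  with amplification maps over `(w, g)` and input direction — a compact
  laboratory for non-normal amplification.

## Worked example

```python
import numpy as np
import lowrank_rnn as lr

# rank-one network, N = 50 units, coupling k = 2, overlap rho_mn = -0.5
spec = lr.build_rank_one(N=50, k=2.0, rho_mn=-0.5, seed=11)
ens = lr.make_input(50, "high_d")          # independent noise to every unit

theory = lr.spectrum_hd(spec)
print(f"lambda       = {spec.eigenvalues[0]:+.3f}")
print(f"mu_+, mu_-   = {theory.mu_plus:.4f}, {theory.mu_minus:.4f}  (mu_ref = 0.5)")
print(f"gamma_+/-    = {theory.gamma_plus:+.4f}, {theory.gamma_minus:+.4f}")
print(f"dimension D  = {theory.participation_ratio:.2f}  (N = 50)")

traj = lr.simulate(spec, ens, lr.SimulationConfig(seed=123))
emp = lr.empirical_covariance(traj)
sigma = lr.stationary_covariance(spec, ens).sigma
rel = np.linalg.norm(emp - sigma) / np.linalg.norm(sigma)
print(f"simulated vs analytic covariance: {100 * rel:.1f}% Frobenius error")

pcs = lr.empirical_pcs(emp, {"v_plus": theory.v_plus, "v_minus": theory.v_minus})
print(f"PC1  overlap with v_+ : {pcs['overlap_v_plus'].iloc[0]:.3f}")
print(f"PC50 overlap with v_- : {pcs['overlap_v_minus'].iloc[-1]:.3f}")
```

Output:

```
lambda       = -1.000
mu_+, mu_-   = 0.7887, 0.2113  (mu_ref = 0.5)
gamma_+/-    = +1.3660, -0.3660
dimension D  = 49.34  (N = 50)
simulated vs analytic covariance: 4.1% Frobenius error
PC1  overlap with v_+ : 0.995
PC50 overlap with v_- : 0.999
```

Reading: this strongly anti-symmetric network (`lambda = k rho_mn = -1`)
perturbs exactly two of the fifty covariance eigenvalues away from the
reference value 1/2 — one amplified direction (`mu_+ = 0.79`, mostly along
`m`) and one suppressed direction (`mu_- = 0.21`, mostly along `n`) — so
activity stays nearly isotropic and high-dimensional (`D = 49.3` of 50).
A 2000-time-unit simulation reproduces the analytic covariance to ~4% and
recovers both theoretical principal components almost perfectly.

## Command line

Sweep drivers mirror the analysis figures as tidy CSV tables plus a JSON
run manifest:

```
lowrank-rnn overlap-sweep  --k 2 --points 99 --out results/
lowrank-rnn rank-two-sweep --parametrization orthogonal --out results/
lowrank-rnn ei-maps        --input-mode one_d --out results/
```

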