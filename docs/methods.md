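# Methods

## Model

The package analyzes the linear stochastic dynamics

    dx/dt = -x(t) + W x(t) + U chi(t)

for `N` units with the leak time constant set to 1. `chi(t)` is a zero-mean
Gaussian process, white in time and uncorrelated across channels, with unit
spectral density; the static input covariance is `Sigma_inp = U U^T`. The
connectivity is low rank, `W = k sum_{r=1..R} m^r (n^r)^T`, with unit-norm
vectors and an order-one coupling `k` (so vector entries scale as
`1/sqrt(N)` and the eigenvalues `lambda^r = k (m^r . n^r)` stay finite).

Assumptions baked into the closed forms:

- **Orthogonal rank-one components.** `n^r . m^s = 0` for `r != s`
  (enforced at construction, tolerance 1e-10). This makes the components
  commute, keeps all nonzero eigenvalues of `W` real
  (`lambda^r`, eigenvector `m^r`), and is what allows the propagator and
  covariance to be written in closed form. Low-rank matrices with complex
  eigenvalues are out of scope.
- **Stationarity.** All formulas require `max_r lambda^r < 1`; specs may be
  built unstable (for divergence demonstrations) but covariance and
  spectrum routines refuse them. The stability margin is 1e-6 below 1.
- **Input normalization.** The noise has unit spectral density by
  convention; there is no separate amplitude knob. Scaling the columns of
  `U` is the supported way to change input strength.

## Closed forms implemented

- Propagator: `exp[(W - I)t] = e^{-t}[I + sum_r k (e^{lambda^r t} - 1)/
  lambda^r m^r n^r^T]`, with the branch `k t m^r n^r^T` when
  `|lambda^r| < 1e-8`; the series `t + lambda t^2/2` is used there to avoid
  cancellation, and the switch is continuous to ~1e-16.
- Equal-time covariance (any rank, any input):
  `Sigma = 1/2 {Sigma_inp + sum_r a_r [d^r m^r^T + m^r d^r^T]
  + sum_{rr'} sigma_rr' b_rr' m^r m^r'^T}` with `a_r = k/(2 - lambda^r)`,
  `b_rr' = k^2 (4 - lambda^r - lambda^r') / [(2 - lambda^r - lambda^r')
  (2 - lambda^r)(2 - lambda^r')]`, `d^r = Sigma_inp n^r`,
  `sigma_rr' = n^r . Sigma_inp n^r'`. Specialized one-dimensional
  (`Sigma_inp = u u^T`) and high-dimensional (`Sigma_inp = I`) forms are
  kept as separately tagged code paths and tested to agree with the general
  form to 1e-12; every analytic covariance is verified to solve the
  Lyapunov equation to a residual below 1e-10.
- Lagged covariance: `Sigma(t, s) = c1 Sigma_inp + sum_r [c2_r d^r m^r^T +
  c3_r m^r d^r^T] + sum_{rr'} c4_rr' sigma_rr' m^r m^r'^T` with the
  stationary-limit coefficients; `c1 = e^{-|t-s|}/2`. Each of `c2..c4`
  carries a `1/lambda` prefactor whose pole cancels analytically; the
  implementation evaluates these as divided differences and, for
  `|lambda| < 1e-6`, as a complex-step midpoint derivative — exact to
  ~1e-14 and continuous through `lambda = 0` and through coincident
  eigenvalues (`c4` has no singularity at `lambda^r = lambda^r'`; the
  common-eigenvalue expression is its value there).
- Spectra via the reduced-matrix rule: the nonzero eigenvalues of
  `sum_p l_p r_p^T` are the eigenvalues of the matrix of inner products
  `l . r`. One-dimensional input gives the 2x2 problem with
  `mu_+- = 1/4 [T +- sqrt(T^2 - 4 rho_nu^2 (1 - rho_mu^2)(beta -
  alpha^2))]`, `T = 1 + 2 alpha rho_mu rho_nu + beta rho_nu^2`,
  `alpha = k/(2 - lambda)`, `beta = k^2/[(2 - lambda)(1 - lambda)]`, and
  eigenvectors `v_+- = gamma_+- m + u`. High-dimensional input gives
  `mu = (1 + mu^lr)/2` with the rank-R low-rank part reduced to a
  `2R x 2R` block matrix; for rank one,
  `gamma_+- = 1/2 [k/(1 - lambda) +- sqrt((2 rho_mn + k/(1 - lambda))^2 +
  4 (1 - rho_mn^2))]` and `mu^lr_+- = k (gamma_+- + rho_mn)/(2 - lambda)`.
  This `gamma`-first route is used in code because it stays finite at
  `k = 0` and `rho_mn = +-1`.
- Degenerate eigenvector cases (one-dimensional input): when
  `rho_nu = rho_mu = 0` the recurrence is disengaged, `mu = (1/2, 0)` and
  `gamma_+- = 0` (the only PC is `u`); when the usual denominator
  `rho_mu + alpha rho_nu` vanishes otherwise, the first equation of the
  ansatz eigen-system is used instead.
- Participation ratio `D = (sum mu)^2 / sum mu^2`, with the
  one-dimensional-input closed form
  `D = [1 - 2 rho_nu^2 (1 - rho_mu^2)(beta - alpha^2) / T^2]^{-1}`,
  bounded in [1, 2] (note `beta - alpha^2 = k^2/[(2 - lambda)^2
  (1 - lambda)] > 0` for stable specs).
- Limits (high-dimensional input, rank one). Symmetric
  (`rho_mn -> 1/k`): `mu_+ -> inf`, `mu_- -> 1/2`, `gamma_+ -> inf`,
  `gamma_- -> 0`. Anti-symmetric (`rho_mn = -1`): `mu_+ = 1/2`,
  `mu_- = 1/(2(1 + k))`, `gamma_+ = 1`, `gamma_- = -1/(1 + k)`.

A note on `mu_-` vs `k`: `mu_+` is strictly increasing in `k` at fixed
overlap, but `mu_-` is monotone decreasing only for `rho_mn <= 0`; for
positive overlap it turns around and returns to 1/2 as `lambda -> 1`
(consistent with the symmetric limit). The monotonicity test covers only
the regime where the property actually holds.

## Synthetic constructions (these are the study conditions)

All inputs are synthesized; there is no external data.

- **Orthonormal scaffold.** Seeded standard-normal matrix, QR
  factorization, column signs fixed so the first nonzero entry is positive.
  Identical seeds give bit-identical vectors.
- **Rank one.** `m = z1`, `n = rho_mn z1 + sqrt(1 - rho_mn^2) z2`.
- **Rank two, orthogonal-subspace parametrization.** `m^r = z_r`,
  `n^r = rho_r z_r + sqrt(1 - rho_r^2) z_{R+r}`; internal overlaps free,
  all cross overlaps zero.
- **Rank two, cross-overlap parametrization.** The m-span and n-span are
  built orthogonal to each other (all four `rho_{m^r n^s} = 0`, so both
  eigenvalues of `W` vanish) with `m^1 . m^2` and `n^1 . n^2` prescribed.
  The orthogonality of the two spans is an explicit modelling choice: it is
  the minimal structure under which the closed forms apply.
- **Inputs.** `one_d`: a supplied or seeded unit vector in the first
  column; `high_d`: `U = I`; `intermediate`: `C` seeded (or user-supplied)
  orthonormal columns. The E-I circuit input is `u = (cos theta,
  sin theta)`, `theta` in `[0, pi]`.
- **E-I circuit.** `m = (1,1)/sqrt(2)`, `n = (1,-g)/sqrt(g^2+1)`,
  `k = w sqrt(2(g^2+1))`, eigenvalue `w(1 - g)`.

What the generator does *not* emulate: sparse or sign-constrained synaptic
weights, heterogeneous leak time constants, temporally correlated or
non-Gaussian noise, and nonlinear rate dynamics. Passing tests therefore
certify the linear-Gaussian theory and its simulator, not the behaviour of
biological or trained nonlinear networks; the linear results apply to those
systems only through linearization around an operating point.

## Simulation

Euler–Maruyama: `x(t + tau) = (1 - tau) x + tau W x + sqrt(tau) U chi`,
`x(0) = 0`, noise drawn i.i.d. standard normal per step and channel.
Defaults: `tau = 0.01`, `t_total = 2000`, `burn_in = 20` (twenty leak time
constants; `e^{-20} ~ 2e-9` bounds the transient bias), 16 realizations,
samples recorded every 10 steps. Sixteen realizations were chosen from the
estimator-variance estimate (relative Frobenius error of the empirical
covariance ~ `N / (2 sqrt(T_total) ||Sigma||_F)`, about 4% for `N = 50` at
these settings) so that simulation-vs-theory comparisons at default
settings sit safely inside a 5% band; thinning to every 10th step (spacing
0.1 << leak time 1) does not reduce the information content of the
estimate. The empirical covariance subtracts the empirical mean even
though the true mean vanishes, keeping the estimator standard. Test
tolerances for stochastic quantities were calibrated on pilot runs and
frozen together with the seeds. The discrete map uses `tau = 1` and
requires spectral radius of `W` below one.

Unit tests use deliberately small problem sizes (N of order 10–50,
durations of order 30–2000 time units); the one full-default simulation
lives in the acceptance suite and runs in a few seconds.

## Randomized-geometry dimensionality sweep

The sweep behind the dimensionality bound samples `m, n, u` as independent
random unit vectors in `N = 100` and `k ~ U(0, 10]`; where `k rho_mn`
would reach 1 the coupling is resampled uniformly below
`(1 - 1e-6)/rho_mn` (for `rho_mn <= 0` the stable range in `k` is
unbounded and the raw draw stands). Every sample is evaluated with both
the closed-form `D` and the spectral definition on the analytic eigenvalue
pair, and the two must agree to 1e-10.

## Numerical conventions

- Eigenvalues sorted descending, ties broken by ascending original index.
- Principal components are sign-fixed to have non-negative overlap with
  `m` (high-dimensional input) or `u` (one-dimensional input); overlaps
  between estimated and theoretical PCs are reported as absolute values.
- "Perturbed away from the reference" means relative deviation from
  `mu_ref` above 1e-8.
- PSD tolerance for covariance validation: eigenvalues down to
  `-1e-10 * trace(Sigma)` count as numerical zeros.
- Spectra for intermediate input dimensionality (`1 < C < N`) are provided
  only numerically (dense eigendecomposition of the analytic covariance);
  no closed form is offered for that regime.

## Known limitations

- The connectivity class excludes non-commuting low-rank components and
  complex eigenvalues; `build_low_rank` rejects overlap requests that are
  not realizable as an orthonormal-scaffold construction.
- The lagged covariance is the stationary-limit expression; transients
  from arbitrary initial conditions are not modelled.
- The simulator is plain Euler–Maruyama (discretization bias O(tau),
  e.g. the unconnected stationary variance is `1/(2 - tau)` instead of
  1/2); exact OU transition-kernel sampling is intentionally out of scope.
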