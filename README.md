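# plrnnssm

State-space models with piecewise-linear recurrent neural network (PLRNN)
latent dynamics, for reconstructing nonlinear dynamical systems from short,
noisy multivariate time series.

The latent process is

```
z_t = A z_{t-1} + W phi(z_{t-1}) + h + C s_t + eps_t,   phi(z) = max(z, 0)
```

with diagonal `A`, zero-diagonal `W`, external inputs `s_t`, and diagonal
process noise. Observations are either Gaussian-linear (`x_t = B phi(z_t) +
eta_t`) or BOLD-like — the raw latent states convolved with a canonical
hemodynamic response kernel plus nuisance regressors (`x_t = B (hrf*z)_t +
J r_t + eta_t`). Swapping the ReLU for the identity gives the linear (LDS)
baseline.

What is here:

- **Inference** — EM with a global Laplace approximation. The E-step solves
  the piecewise-quadratic MAP problem with a banded bit-flip Newton scheme
  (optional sign-constrained QP polish for small problems), extracts the
  block-banded posterior covariance by a super-block tridiagonal recursion
  (linear in T), and computes the rectified-Gaussian moments E[phi],
  E[z phi^T], E[phi phi^T] in closed form (Owen's-T bivariate normal CDF).
  The M-step is closed-form: stacked least squares for the observation
  parameters, row-wise regularized regressions for the latent parameters.
- **Training protocols** — the stepwise annealing protocol (LDS
  initialization, then PLRNN EM while the process-noise scale is lowered
  stepwise and the loading matrix is frozen), a random-initialization
  baseline, and the LDS variant.
- **Benchmarks** — RK4 simulators for the Lorenz system and the van der Pol
  oscillator with per-step process noise, trajectory standardization, and
  reproducible sample sets.
- **Evaluation** — state-space occupancy KL divergence between true and
  freely generated trajectories (binned, Laplace-smoothed, normalized to
  [0, 1]), latent-space KL between the inferred posterior mixture and the
  free-running prior mixture (Monte-Carlo and deterministic variational
  estimators, plus a normalized version), n-step-ahead prediction MSE,
  power-spectrum correlation, analytic fixed-point enumeration over the
  2^M linear regions, attractor classification from random initial
  conditions, and Lyapunov-exponent estimation from log-distance slopes.

## CLI

```sh
plrnnssm simulate --system lorenz --T 1000 --noise 0.3 --seed 1 --out lorenz.tsv
plrnnssm fit --data lorenz.tsv --M 12 --protocol anneal --seed 1 --out fit.json
plrnnssm evaluate --fit fit.json --data lorenz.tsv --out report.json
plrnnssm analyze-dynamics --model fit.json --n-init 100 --T 5000 --out dynamics.json
plrnnssm benchmark --system lorenz --n-samples 10 --m-grid 8,10,12,14 --out summary.json
```

Every command writes a run manifest (config snapshot, input digests, master
seed, package version) next to its output. All randomness derives from the
`--seed` argument.

## Layout

```
src/plrnnssm/
  benchmarks.py   ground-truth systems and trajectory sampling
  model.py        latent PLRNN, generation, fixed points, attractors, Lyapunov
  observation.py  Gaussian and HRF-convolved observation models
  estep.py        MAP inference, posterior covariance, ReLU moments
  mstep.py        sufficient statistics and closed-form parameter updates
  training.py     annealed / random / LDS training protocols
  evaluation.py   KL_x, KL_z, n-step MSE, spectrum correlation
  io.py, cli.py   text/JSON round trips, manifests, command line
```
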