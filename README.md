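# peaklag

Dynamics of phenotype-structured populations whose fitness optima shift in
time.  The package simulates the non-local selection–mutation PDE

```
dn/dt - eps^2 n_xx = n * (a(x, t) - rho(t)),     rho(t) = integral of n
```

with fitness landscapes built from moving, compactly supported bumps
`(h - (x - x0)^p)^+ - d`, and cross-validates the simulations against the
asymptotic theory: principal-eigenvalue persistence criteria, lagged fitness
optima, concentration of the population strictly behind moving peaks, and
selection of the shallowest peak (minimal `|a''|`) in the rare-mutation limit.

## Modules

| module        | contents |
|---------------|----------|
| `landscapes`  | bump components, composite landscapes, assumption checks, global maxima/curvatures, lagged optima, figure presets (`fig4`–`fig8`) |
| `fd_solver`   | explicit finite-difference solver (forward Euler, centred Laplacian, Dirichlet boundaries), CFL helpers, co-moving drift option |
| `hj_solver`   | asymptotic-preserving Hamilton–Jacobi scheme for the phase `u = -eps log N`: the `eps > 0` scheme with non-local mass, and the `eps = 0` limit scheme with a per-step scalar multiplier enforcing `min v = 0` |
| `eigen`       | Dirichlet ball eigenproblems (symmetric tridiagonal), drift problems via exact diagonal similarity, monotonicity in the ball radius, the small-`eps` eigenvalue limit, decay envelopes, and two-speed persistence classification |
| `viscosity`   | eikonal representation-formula costs with a dynamic-programming oracle, limiting-phase construction, and concentration-point selection |
| `diagnostics` | co-moving reframing, windowed mass-fraction location, moving-track mass series, long-time mass vs. `-lambda_eps` |
| `workbench`   | experiment presets, parameter sweeps, plain-text outputs, CLI |

## CLI

```bash
peaklag simulate --preset fig4                  # finite-difference run + summary
peaklag hj --preset fig5 --scheme hj_limit      # constrained HJ limit scheme
peaklag eigen --preset fig4 --radius 20         # principal eigenvalue
peaklag lagged --preset fig4                    # lagged-optimum prediction table
peaklag sweep --preset fig6 --parameter c2 --values 1,1.5,2,2.5
peaklag report --preset fig4 --out out/         # tables + JSON summary
```

Presets reproduce the published experiments at reduced scale; every run is
fully deterministic.  Outputs are plain-text CSV tables (mass series,
snapshots) plus a JSON summary per run.

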