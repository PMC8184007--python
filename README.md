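# polkadots

Quantification and simulation of **Bcl10 filament dynamics** in activated
T cells.

When the T-cell receptor engages an antigen, the adaptor protein Bcl10
polymerizes into micron-scale helical filaments (the POLKADOTS signalosome)
that relay the signal to NF-κB; at the same time, autophagosomes attach to
the filaments and degrade them, switching the signal off. This package
implements the computational side of that story end to end:

- **Synthetic 3D cells** (`polkadots.synth`): iSIM-like binary volumes —
  tubular filaments from bounded-curvature random walks, spherical vesicles
  with controllable end-biased placement, an ellipsoidal cell mask — with
  exact ground truth, so every downstream measurement is testable.
- **Preprocessing** (`polkadots.preprocess`): isotropic cubic-spline
  resampling, thresholding, a 3×3×3 neighborhood filter (≥8/27 occupancy),
  small-object removal, 26-connected labeling.
- **Skeleton analysis** (`polkadots.skeleton`): medial-axis thinning,
  iterative pruning of sub-resolution spurs (<6 voxels = 150 nm), punctate
  classification, geodesic distance-from-end maps, and minimum-bending-energy
  untangling of filament crossings (branches paired at each junction to
  minimize Σ 1/R²).
- **Contacts** (`polkadots.contacts`): filament–autophagosome contacts as
  voxel overlaps, localized along the skeleton by distance from the nearest
  filament end.
- **Resampling null** (`polkadots.resample`): a bootstrap-like null that
  rigidly rotates each vesicle and re-places it uniformly inside the cell
  boundary (100 trials/cell) to test whether contact counts and end
  localization exceed chance.
- **Monte Carlo simulator** (`polkadots.simulate`): nucleation-limited
  filament growth (attachment probability switches from p_attach to p_grow
  once a filament crosses the n_barrier = 50 nucleation barrier) plus
  autophagosome-driven degradation (end removal and interior scission),
  with the analytic two-phase growth distribution

  ```
  P(len = x | n) = C(n,x) p_a^x (1-p_a)^(n-x)                      x < L0
                 = Σ_i NegBin(i; L0, p_a) · Binom(x-L0; n-i, p_g)  x ≥ L0
  ```

  and population summaries: the Pearson correlation ρ between per-cell
  puncta count and mean filament length, its over-time analog ρ(t), and the
  response-timing measures n_max / n_half.

## Worked example

```python
from polkadots.simulate import (InitDistributions, SimParams,
                                run_population, sample_population)

dists = InitDistributions()            # sites ~ Gamma(1.59, 15.92), etc.
cells = sample_population(dists, 100, seed=1)
params = SimParams(p_activate=0.5, p_attach=0.1, p_grow=0.4)
res = run_population(params, dists, n_cells=100, n_trials=10, seed=1,
                     growth_only=True, cells=cells, max_iter=400_000)
print(f"rho = {res.rho_end:+.3f}")
```

prints

```
rho = -0.584
```

the end-state correlation across 100 heterogeneous simulated cells between
the number of punctate Bcl10 structures (stranded below the nucleation
barrier) and the mean filament length: cells whose monomer pool is divided
among more filaments end up with shorter filaments *and* more puncta, so
the correlation is negative — the simulated analog of what is measured in
real cells.

The numbered drivers under `analysis/` run the full studies and write CSV
tables under `results/`:

```
python analysis/01_growth_simulation.py      # rho over a p_activate x p_attach grid
python analysis/02_degradation_simulation.py # rho(t) plateaus, n_max/n_half
python analysis/03_synthetic_image_analysis.py  # skeletons + contacts vs ground truth
python analysis/04_resampling_null.py        # null calibration and power
```

For example, `02_degradation_simulation.py` reports

```
p_degrade=0.05: plateau rho=-0.704 (<=-0.6 for 883 iterations), n_max=  1611, n_half=  5972
p_degrade=0.1:  plateau rho=-0.762 (<=-0.6 for 872 iterations), n_max=  1520, n_half=  7081
```

— with degradation switched on, the population sustains a strongly negative
ρ(t) (a transient equilibrium between polymerization and disassembly)
before the terminal rise as filaments and monomers run out.

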