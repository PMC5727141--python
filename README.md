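# polarphase

Phase reduction of contact-coupled reaction–diffusion cell models of tissue
polarity, together with simulators and analysis tools at both levels of
description.

Each cell is a reaction–diffusion system on its one-dimensional periodic
boundary; neighbouring cells interact through their shared contact surfaces.
When the pattern is stationary and the coupling is weak, every cell reduces
to a single polarity angle, and the pairwise interaction becomes a coupling
function `Γ_ij(φ_i, φ_j)` built from three ingredients: the harmonics of the
steady activator profile, the harmonics of the adjoint zero eigenfunction
(phase sensitivity function), and the geometry of the contact surface
(midpoint `η_ij`, width `d_ij`). The package derives this reduction
numerically for arbitrary two-species models, recovers it in closed form for
the real Ginzburg–Landau equation, and uses the reduced model to study
polarity alignment under cell elongation, coupling heterogeneity, external
signals and noise.

## Layout

| module | contents |
| --- | --- |
| `polarphase.models` | built-in kinetics (`gle`, `activator_inhibitor`), Jacobians, diffusivities, plug-in registry |
| `polarphase.ring_rd` | spectral (ETD-split) integrator for the coupled tissue PDEs, facing-point contact coupling, phase extraction |
| `polarphase.reduction` | steady pattern + Newton polish, adjoint zero mode, Fourier coefficients, `Γ` assembly and a direct quadrature oracle |
| `polarphase.tissue_geometry` | hexagonal cell shapes (regular/elongated), chains, periodic sheets, winding alignments, per-edge heterogeneity |
| `polarphase.phase_dynamics` | phase-model ODE/SDE integration, potentials and Boltzmann densities, two-cell stability, in-phase effective field, elongation coefficient `λ(δ)` |
| `polarphase.interface` / `polarphase.cli` | YAML/JSON config-driven runs (`reduce`, `simulate-rd`, `simulate-phase`, `analyze`) |

## CLI

Every run is driven by one config file:

```sh
polarphase reduce --config cfg.yaml          # steady state + adjoint mode + Γ terms -> JSON
polarphase simulate-rd --config cfg.yaml     # tissue PDE run -> per-cell phase CSV
polarphase simulate-phase --config cfg.yaml  # reduced model run -> phase + order-parameter CSV
polarphase analyze --config cfg.yaml         # λ(δ), two-cell stability, effective field -> JSON
```

Minimal reduction config:

```yaml
task: reduce
model: {name: activator_inhibitor}
numerics: {n_theta: 256, K: 8}
output: {dir: out}
```

The JSON written by `reduce` (Fourier coefficients plus `Γ` term lists per
contact width) is the coupling input for `simulate-phase`
(`coupling: {reduction_file: out/reduction.json}`). Stochastic tasks require
a seed; identical config + seed reproduces byte-identical outputs.

## Python API sketch

```python
import numpy as np
from polarphase import make_model, reduce_cell, fourier_coefficients, gamma_from_fourier
from polarphase import PhaseModelSpec, integrate_phase, PhaseState
from polarphase.tissue_geometry import chain

cell = reduce_cell(make_model("activator_inhibitor"), n_theta=256)
fd = fourier_coefficients(cell, K=8)
gamma = gamma_from_fourier(fd, d=np.pi / 3)          # Γ as sinusoidal terms
spec = PhaseModelSpec(chain(3), gamma, eps=0.001)
traj = integrate_phase(spec, PhaseState([1.0, 0.2, -0.7]), T=2000.0)
```
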