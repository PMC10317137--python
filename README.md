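# mcscale

Multi-component structure-factor modeling and per-resolution-shell scale
refinement for crystallographic data.

The total model structure factor in each resolution shell is

```
F_model(s) = k_overall * [ k_0 F_0(s) + sum_n k_n F_n(s) ]
```

where `F_0` is the principal (atomic) contribution and the `F_n` are
structure factors of additional scattering components (binary masks,
analytic spheres, Gaussian blobs, ...), each carrying an unknown
shell-constant scale `k_n`. Four search strategies for the scales are
provided:

1. **sequential** — components fitted one at a time by 1-D amplitude search;
2. **quartic least squares** — all scales refined simultaneously against
   intensities with analytic gradients (`2`) or gradients + second
   derivatives (`2h`);
3. **two-step analytic** — linear normal equations for the products
   `u_nm = k_n k_m`, then a log least squares to factor them (no
   initial values needed, but ill-conditioned for many components);
4. **phased linear solve** — phases borrowed from the current model turn
   the fit into an `(N+1)`-dimensional linear system, iterated to
   convergence (the recommended default).

A synthetic-crystal module reproduces the parameter-recovery
experiments used to validate the algorithms: a protein-mimicking atom
cluster occupying ~25% of a P1 cell plus non-overlapping spheres of
radius 3–10 Å packed into the solvent region, error-free simulated
amplitudes, controlled coordinate perturbation (exact target RMSD) and
Gaussian data errors calibrated to an exact target R factor.

## Library quick start

```python
import numpy as np
from mcscale import (UnitCell, generate_hkl, bin_shells, fit_driver,
                     ObservedData)
from mcscale.simulation import make_crystal, crystal_components, simulate_fobs

rng = np.random.default_rng(0)
crystal = make_crystal(rng, cell_edge=42.0, n_spheres=7)
miller = generate_hkl(crystal.cell, d_min=2.5)
comps = crystal_components(crystal, miller)   # [atoms, smeared spheres...]
obs = simulate_fobs(crystal, miller, comps)
shells = bin_shells(miller, n_shells=10)
scales = fit_driver(obs, comps, shells, algorithm="4")
print(scales.k_overall[:, None] * scales.k)   # per-shell coefficients
```

## Command line

```sh
# simulate an error-free synthetic crystal into a columnar reflection file
mcscale simulate --config scenario.yaml --seed 1 --out refl.txt

# fit per-shell scales (algorithms 1, 2, 2h, 3, 4)
mcscale fit refl.txt --algorithm 4 --shells 10 --out scales.tsv --log fit.json

# seeded parameter-recovery benchmark
mcscale benchmark --scenario coord-error --doses 0,0.2,0.4 --trials 50 \
    --algorithms 2h,4 --seed 1 --out summary.tsv
```

Scenario YAML keys (all optional): `kind` (`error-free` | `coord-error` |
`data-error`), `doses`, `cell_edge`, `d_min`, `n_atoms`,
`protein_fraction`, `n_spheres` (null = pack to saturation), `r_range`,
`k_range`, `smearing_b`, `n_shells`, `init_spread`.

### Reflection file format

Plain whitespace-separated text with headers:

```
# cell 42.0 42.0 42.0 90.0 90.0 90.0
# components atoms sphere0
# columns h k l F_obs I_obs re_atoms im_atoms re_sphere0 im_sphere0
1 0 0 123.4 15227.56 100.0 0.0 23.4 0.0
```

Floats are repr-exact; rows are lexicographic in (h, k, l); duplicated
indices are rejected. A minimal mmCIF reflection importer
(`mcscale.io.read_mmcif_reflections`) reads `_refln` loops
(amplitude column only).

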