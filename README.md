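# epimorph

Morphogenesis of an epithelial tissue — a fly notum or wing, a gastrulating
germband — is driven by a handful of cell-level processes: cells divide,
exchange neighbours (T1 rearrangements), change size and shape, delaminate,
occasionally fuse or integrate into the sheet, and flow across the edge of
the field of view.  Given a segmented and tracked time-lapse of a cell
monolayer, `epimorph` measures the local tissue deformation-rate tensor
**G** and decomposes it, *additively and completely*, into the contribution
of each process:

```
G = S + D + R + A + N + C + J
```

where **S** is cell size-and-shape change, **D** divisions, **R**
rearrangements, **A** delaminations/apoptoses, **N** new-cell integrations,
**C** fusions and **J** boundary flux.  All eight quantities are symmetric
2×2 tensors in h⁻¹ — an isotropic part (local growth or shrinkage) plus a
deviatoric part (convergence–extension, drawn as a bar along the elongation
axis).  The balance holds per cell patch and per time step, so the equation
can be checked on the data itself; the relative residual is reported with
every measurement.

The measurement is built on centroid-to-centroid *half-links* between
neighbouring cells.  Each half-link of each frame pair is classified into
exactly one category (conserved, or appearing/disappearing through one of
the six processes).  Conserved links yield **G** and the local rotation
rate Ω through a least-squares fit of the link displacement gradient; the
texture tensor M = (1/N) Σ ℓ⊗ℓ yields **S** through its own rate of
change; each process's appearing/disappearing links yield its tensor
through P = −¼(M⁻¹T_P + T_P M⁻¹).

The package also provides:

- **cohort statistics** — landmark-based spatial registration, rotation-peak
  time registration, weighted ensemble averages across animals, biological
  variability (weighted unbiased standard deviation), per-box significance
  masking, and wild-type vs mutant differencing ΔP with its component ΔP∥
  along the wild-type morphogenesis axis;
- **force inference** — Bayesian estimation of relative junction tensions γ
  and cell pressures p from junction-network geometry (vertex force balance,
  ABIC-selected prior strength), and patch-level junctional stress via the
  Batchelor formula σ = (1/𝒜)[−Σ p_c 𝒜_c 𝟙 + Σ γ_ck ℒ⊗ℒ/‖ℒ‖];
- **a synthetic test bed** (`morphosim`) — cellular Potts simulations of
  each single-process scenario (divisions, rearrangements, delaminations,
  fusions, integrations, boundary flux) and exact affine fixtures (pure
  dilation/convergence–extension, rotation), emitting tracked label stacks
  with ground-truth lineages and event logs.

## Worked example

Generate a division-dominated synthetic movie (80 cells, 61 frames at
5 min, cells stretched along x by an external force, every cell dividing
once along its long axis), then measure the decomposition over the whole
patch:

```python
import numpy as np
from epimorph.morphosim import ScenarioConfig, run_scenario
from epimorph.kinematics import measure_movie, window_average, rates_tensor
from epimorph.tensors import SymTensor2, bar_circle, tensor_norm

cfg = ScenarioConfig(scenario="divisions", frames=61, size=260, n_cells=80,
                     steps_per_frame=30, seed=2, force_x=6.0)
movie = run_scenario(cfg)
rates = measure_movie(movie.stack, movie.lineage, pixel_size=1.0,
                      dt_min=5.0, box_px=16384, overlap=0.0)
avg = window_average(rates).iloc[0]
for sym in ("G", "S", "D", "R"):
    bc = bar_circle(rates_tensor(avg, sym))
    print(f"{sym}: dilation {bc.dilation_rate:+.3f}/h, "
          f"CE {bc.ce_amplitude:.3f}/h at {np.degrees(bc.ce_angle):.0f} deg")
g, total = rates_tensor(avg, "G"), SymTensor2.zero()
for sym in ("S", "D", "R", "A", "N", "C", "J"):
    total = total + rates_tensor(avg, sym)
print(f"balance residual |G - sum P| = {tensor_norm(g - total):.4f}/h "
      f"({100 * tensor_norm(g - total) / tensor_norm(g):.1f}% of |G|)")
```

prints

```
G: dilation +0.070/h, CE 0.034/h at 176 deg
S: dilation +0.013/h, CE 0.008/h at 180 deg
D: dilation +0.055/h, CE 0.020/h at 175 deg
R: dilation +0.000/h, CE 0.006/h at 176 deg
balance residual |G - sum P| = 0.0017/h (2.2% of |G|)
```

Reading: the patch grows (G dilation +0.070 h⁻¹) and elongates nearly
along x (bar at ~176–180°).  Most of the growth is carried by divisions
(D, +0.055 h⁻¹ — the cell-number increase), the rest by transient cell
growth (S); the division bars are oriented with the stretch, with small
residual rearrangement and shape-change terms, and the balance closes to
2% — the decomposition accounts for the whole tissue deformation.

The same pipeline is available from the shell:

```sh
epimorph simulate --scenario divisions --frames 61 --size 260 \
    --n-cells 80 --seed 2 --out run/
epimorph measure --labels run/labels.tif --lineage run/lineage.csv --out maps/
epimorph average --manifest cohort.json --out archetype/
epimorph infer-stress --labels run/labels.tif --out forces/
```

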