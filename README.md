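# durasim

Voxel-based EEG forward simulation of the dura mater's effect on scalp
potentials.

The dura — a thin (~1 mm), poorly conducting membrane between the highly
conductive CSF and the resistive skull — is usually left out of EEG head
models.  `durasim` quantifies what that omission costs: it builds nested
multi-layer voxel head phantoms with distributed cortical dipole sources,
solves the quasi-static volume-conduction equation

    div( sigma grad phi ) = div J_p

with a cell-centered finite-volume scheme (harmonic-mean face
conductances, insulating air boundary, conjugate gradients under a
mean-zero gauge), and compares paired forward solutions — one with the
dura layer, one with the dura relabeled as CSF — through the standard
topography statistics

    RDM* = || v_RM/||v_RM|| − v_TM/||v_TM|| ||      (shape difference)
    MAG  = ||v_TM|| / ||v_RM||                      (magnitude ratio)

plus histogram/CDF summaries and the two-sample Kolmogorov–Smirnov test.
With the dura-bearing model as reference (RM), MAG > 1 means the dura
attenuates scalp potentials.  An exact analytic series for a dipole in N
concentric conductive shells serves as the independent oracle for the
numerical solver.

Intended users: researchers in EEG forward modeling and source analysis
who want a reproducible, fully synthetic test bed for layer-conductivity
effects — no subject data required, every stage seeded and scriptable.

## Worked example

```python
from durasim import ExperimentConfig, SourceConfig, Tissue
from durasim import run_single_source_comparison, run_surface_cascade
from durasim.experiments import prepare_head

config = ExperimentConfig(source=SourceConfig(seed=1))   # 2 mm head, 64^3
prepared = prepare_head(config)                          # phantom + dipoles

report = run_single_source_comparison(config, prepared)
print(f"MAG  = {report.comparison.mag:.3f}")
print(f"RDM* = {report.comparison.rdm_star:.3f}")
print(f"peak reduction = {report.peak_reduction_percent:.1f}%")

cascade = run_surface_cascade(config, prepared)
for name in ("cortex", "outer_dura", "outer_skull", "scalp"):
    print(f"{name:12s} std = {cascade.stds_v[name]:.2f} V")
```

prints

```
MAG  = 1.683
RDM* = 0.076
peak reduction = 46.5%
cortex       std = 48.83 V
outer_dura   std = 43.35 V
outer_skull  std = 2.39 V
scalp        std = 2.01 V
```

Reading: replacing the dura with CSF raises the root-sum-square scalp
potential by 68% (equivalently, including the dura cuts the scalp peak by
~47%) while barely changing the topography shape (RDM* 0.08 on a 0–2
scale) — magnitude changes dominate shape changes.  The per-surface
standard deviations drop monotonically from cortex to scalp: the skull
and dura progressively blur and attenuate the cortical potential pattern.
(The absolute voltages are large because the source model drives one
0–0.4 mA·m dipole in *every* cortical voxel; all comparison statistics
are scale-invariant.)

The same pipeline is scriptable from the shell:

```bash
durasim compare  -c config.yaml -o out/   # dura vs CSF comparison + figures
durasim cascade  -c config.yaml -o out/   # per-surface maps and stats
durasim trials   -c config.yaml -o out/   # repeated random dipole draws
durasim sensitivity -c config.yaml -o out/  # hard-skull conductivity sweep
durasim validate -o out/                  # solver vs analytic sphere
```

## Layout

| module | contents |
| --- | --- |
| `durasim.phantom` | shell phantoms, conductivity table, cortical normals, dipole sampling |
| `durasim.solver` | finite-volume operator, dipole discretization, CG solve, flux |
| `durasim.sphere_oracle` | analytic N-shell dipole series, attenuation ratios |
| `durasim.surfaces` | interface extraction, average reference, eye-level cap |
| `durasim.metrics` | RDM*, MAG, peak reduction, histograms/CDFs, K–S test |
| `durasim.experiments` | paired comparisons, trials, cascade, sensitivity, validation |
| `durasim.io` | NIfTI/CSV/JSON readers and writers, manifests, contour figures |
| `durasim.cli` | `durasim` command-line entry points |

See `docs/methods.md` for the model, the conductivity choices (including
why the replacement study uses a 0.001 S/m dura with 0.06 S/m CSF), the
sheet-resistance rule for the one-voxel dura shell, solver accuracy
against the analytic oracle, and known limitations of closed-shell
phantoms.
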