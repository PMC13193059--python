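# remicro

Stochastic microsphere deposition and ⁹⁰Y voxel microdosimetry for
radioembolization.

After ⁹⁰Y radioembolization the microspheres lodge in clusters, so the
absorbed dose at the sub-millimetre scale is far more heterogeneous than
macroscopic dosimetry suggests. `remicro` is for medical physicists and
modelers who want to study that microscopic structure: it builds voxelized
microsphere distributions from histology-derived cluster statistics,
convolves them with a high-resolution ⁹⁰Y dose kernel, and quantifies how
much statistical detail the deposition model needs.

## Model

Three cluster parameters are sampled from truncated continuous fits to
histology: the cluster diameter C_dia (biexponential, [21, 1489] μm), the
nearest-neighbour cluster distance C_dist (three-parameter generalized
extreme value, [89, 3105] μm), and the microspheres per cluster C_pop
(biexponential, [1, 98]). Cluster centers are laid down either on a 470 μm
lattice or by rejection sampling against the C_dist distribution; clusters
are populated until the target concentration is met exactly, rasterized to a
30 μm grid (735³ voxels, 2.2 cm cube by default), and convolved:

    D(x,y,z) = τ · A_MS · [ MS_dist ⊛ DVK ](x,y,z)

with τ = 1/λ the ⁹⁰Y mean lifetime, A_MS the per-microsphere activity and
DVK the dose-voxel kernel (energy-normalized to 1.485 × 10⁻¹³ J per decay;
built in-package from a synthetic condensed-history ⁹⁰Y dose-point kernel,
or from a user-supplied radial table). Dose-volume metrics (D_mean, COV,
D_x, V_t) are evaluated on the interior contracted by 80 voxels (2.4 mm,
the charged-particle-equilibrium margin). Model variants range from fully
uniform (`UNI`) through median-parameter (`MED`) to fully sampled (`REF`),
with single-parameter ablations (`DIA`, `DIST`, `POP`, `DIST_POP`).

## Worked example

```python
import remicro as rm

kernel = rm.build_two_scale_kernel(pitch_um=rm.ModelConfig().voxel_pitch_um,
                                   seed=8)          # ~1 min, synthetic 90Y DPK
cfg = rm.ModelConfig(variant="UNI", concentration_per_ml=5000.0, seed=1)
model = rm.build_model(cfg)                          # 53,240 microspheres
dose = rm.compute_dose(model.grid, kernel,
                       rm.DosimetryConfig(specific_activity_bq=300.0))
m = rm.metrics(rm.contract(dose, 80), thresholds=(100.0,))
print(f"D_mean {m.d_mean:.1f} Gy  SD {m.sd_dose:.1f} Gy  COV {m.cov:.2f}")
```

prints

```
D_mean 72.1 Gy  SD 23.1 Gy  COV 0.32
```

the interior mean dose of the uniform model at 5,000 microspheres/mL and
300 Bq per sphere — within 1% of the closed-form charged-particle-
equilibrium value τ·c·A_MS·E/ρ = 71.95 Gy, with the residual ~32% voxel-level
spread coming from the discrete 585 μm sphere spacing. The same pipeline with
`variant="REF"` yields D_mean ≈ 74 Gy and COV ≈ 1.1: clustering barely moves
the mean but triples the heterogeneity.

A CLI mirrors the library (`remicro deposit`, `remicro dose`,
`remicro metrics`, `remicro suite`, `remicro scenario`, `remicro fitpdf`,
`remicro kernel-build`); grids travel as raw+JSON sidecar containers and
tables as headered CSV.

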