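# Methods

## The problem

After ⁹⁰Y radioembolization, microspheres lodge in the tumor microvasculature
in clusters, producing absorbed-dose fields that are highly nonuniform at the
sub-millimetre scale. `remicro` simulates that microscopic dose structure: it
generates voxelized microsphere distributions from histology-derived cluster
statistics, convolves them with a ⁹⁰Y dose-voxel kernel, and compares
dose-volume metrics across deposition models of increasing statistical
complexity.

## Cluster statistics

Three quantities characterize the deposition pattern, each modelled by a
continuous family truncated to the observed range:

| quantity | family | parameters (default) | domain |
|---|---|---|---|
| cluster diameter C_dia [μm] | biexponential α e^{βx}+γ e^{δx} | 0.0253, −0.0015, 0.1132, −0.0199 | [21, 1489] |
| nearest-neighbour distance C_dist [μm] | generalized extreme value (μ, σ, k) | 445.5, 233.9, 0.2118 | [89, 3105] |
| cluster population C_pop [#] | biexponential a e^{bx}+c e^{dx} | 0.0389, −0.0300, 0.4760, −0.3706 | [1, 98] |

The GEV model is specified through its CDF, exp(−[1+k(x−μ)/σ]^{−1/k}); the
density used for fitting and rejection is its derivative (the printed
expression is monotone increasing and cannot itself be a density). CDFs are
tabulated on fine grids (0.5 μm diameter, 1 μm distance, 0.01 population),
renormalized over the truncated domain, and sampled by inverse transform with
linear interpolation; population samples are rounded to integers and clamped
to [1, 98]. Quantiles use linear interpolation throughout (type-7 style).

**Fitting.** `fit_distribution` fits exact bin-integral models (not midpoint
densities) to per-bin probability masses converted to densities, by
Levenberg–Marquardt least squares. The GEV model is normalized over the
histogram span, so noise-free discretized input is recovered to machine
precision; the biexponential is fit unnormalized because normalizing makes
the amplitude pair exactly scale-degenerate — amplitudes are therefore
reported on the probability-density scale (the generating amplitudes divided
by the domain normalization). Residuals are weighted by the expected bin mass
(two-stage: an unweighted pass supplies the expectation), which is what makes
the Jacobian/Student-t 95% intervals calibrated on counting-noise histograms;
unweighted least squares under-covers badly (≈70% observed at n = 500).

## Deposition models

The volume is a cube (default 2.2 cm side, 735³ voxels). These two published
figures are mutually inconsistent with a literal 30 μm pitch (22 mm/30 μm =
733.3), so the pitch is derived: 22 mm/735 = 29.932 μm, nominally 30 μm. The
side length is authoritative because every microsphere count follows from
concentration × volume (5,000/mL × 10.648 mL = 53,240).

**Stochastic placement** is a variable-radius Poisson-disk process: candidate
centers are uniform (the cluster sphere kept fully inside the volume), each
candidate draws a separation from the C_dist CDF, and is rejected when any
existing cluster lies closer than its drawn separation. The first cluster is
always accepted. This operationalization keeps the hard floor at 89 μm and
reproduces the reported upward bias of realized nearest-neighbour distances
through mutual exclusion. A density-proportional thinning scheme was tried
first and rejected: at the required cluster density it biases the realized
nearest-neighbour median *down* (≈294 μm), the opposite of the published
signature.

**Cluster budget.** Stochastic layouts are generated once at the reference
capacity concentration (60,000/mL) and re-populated per requested
concentration: the budget is 1.08 × (reference count)/E[C_pop] clusters
(the 8% margin keeps random population draws from falling short of the
reference capacity), capped at the median-spacing packing density
floor(L/470 μm)³. That cap is exactly what limits the fixed-population-5
variants — lattice and stochastic alike — to 45,000/mL at the default
geometry, the reported concentration ceiling.

**Population.** Clusters are chosen uniformly at random without replacement,
each assigned a population (sampled or the median 5), and the last cluster is
truncated so the total equals round(concentration × volume) exactly.
Microspheres are placed i.i.d. uniform inside each cluster sphere, with up to
100 redraws per sphere to avoid voxel-level collisions before multi-occupancy
is permitted. The uniform model instead uses ceil(N^{1/3}) equally spaced
sites per axis with half-pitch margins, surplus sites removed by a uniform
stride in raster order so exactly N remain.

Lattice variants clamp sampled diameters near the boundary so every cluster
sphere stays inside the volume (affects only edge sites drawing the largest
diameters).

## The ⁹⁰Y kernel

No kernel tabulation is bundled; the default radial dose-point kernel is
**synthetic**, generated by a condensed-history electron simulation: initial
energies sampled from the ⁹⁰Y beta spectrum (allowed statistical shape ×
Fermi Coulomb factor for Z = 40 × the first-forbidden-unique shape factor
q² + p²), energy loss by the Berger–Seltzer/Møller collision stopping power
of water scaled to 1.03 g/mL, angular deflection by the Highland formula,
scoring in spherical shells with deposits spread uniformly along each step
(this last point matters: scoring at step midpoints produces comb artifacts,
because all electrons share the same early radial step schedule). Radiative
losses, energy-loss straggling and delta-ray transport are neglected; the
shell estimate is projected onto the physically required monotone radial
decay by mass-weighted isotonic regression. Checks: the sampled mean beta
energy reproduces 1.485 × 10⁻¹³ J to a few percent, ≈90% of the energy falls
within ~5.5 mm, and the voxelized central value (1.58 × 10⁻⁵ Gy/decay) is
within 7% of the published Monte Carlo kernel. An ICRU-style radial table
can be supplied as CSV to replace the synthetic model.

**Voxelization** averages the radial kernel over uniform source–target point
pairs (the per-axis difference of two uniform points is triangular), with a
fixed-seed shared sample for far offsets, 8× more samples for near offsets,
and a pair-distance-histogram quadrature for touching voxels where the
distance can reach zero (there the r² volume factor cancels the 1/r² dose
singularity, keeping the integrand finite). Only the sorted octant
0 ≤ a ≤ b ≤ c is computed and mirrored, so point symmetry is exact. Radial
interpolation is log-linear in dose, flat below the first tabulated radius.

**Two-scale kernel.** ⁹⁰Y betas carry roughly half their energy beyond the
2.4 mm mean range, so a single kernel truncated at the 80-voxel contraction
margin would misplace it. The production kernel is therefore a pair: a 30 μm
near kernel (r ≤ 2.4 mm, 161³) plus a 150 μm far kernel (r > 2.4 mm, cyclic,
reaching the ~11 mm end-point range), jointly scaled so one decay deposits
exactly 1.485 × 10⁻¹³ J.

## Dose computation

D = τ·A_MS·(MS ⊛ DVK), with τ = 1/λ = 332,668 s (permanent implant) and A_MS
the per-microsphere activity in Bq. The production convention is **cyclic
(periodic) convolution** — the natural behaviour of an equal-size-matrix FFT
convolution, and the convention the published uniform-model mean dose
identifies: with a full-range kernel, zero-padding depresses the interior
mean ~4–5% below the charged-particle-equilibrium value τ·c·A_MS·E/ρ,
whereas the published value sits within 0.5% of it. Under the cyclic
convention a uniform source yields that value exactly, everywhere.

Engines: sparse superposition (exact linear convolution, reference engine
and default for grids < 256³) and a single-precision circular FFT at the
grid size, computed with chunked per-axis transforms to bound peak memory
(≈5 GB at 735³). Because the near-kernel support (80 voxels) does not exceed
the contraction margin, the circular near-field equals the linear one on the
analysed interior. The far field is convolved cyclically on the 5×-coarse
grid (kernel folded modulo the grid) and trilinearly interpolated back; the
far dose component is smooth at 150 μm. Dose grids are float32; all
reductions accumulate in float64.

Metrics on the 80-voxel-contracted interior (575³ voxels at full geometry):
D_mean, SD, COV; D_x as the (100−x)th linear-interpolation percentile; V_t
as percent of voxels ≥ t Gy; percent errors E_x relative to the matched-seed
reference model. E_x is invariant to A_MS by linearity.

## Problem sizes and reproduction

`scripts/acceptance.py` runs the full 735³ geometry: the uniform and
median-parameter models at 5,000/mL (the latter averaged over three seeds)
and the reference model at (5,000/mL, 500 Bq) and (50,000/mL, 50 Bq) with
one stochastic layout per seed, three seeds. The test suite runs the
concentration sweep (5,000–45,000/mL, step 10,000) and the scenario
comparison on a 400³ cube at the same pitch and margin — per-mL densities,
the capacity ceiling and error metrics are scale-free, which is what those
checks measure. All randomness flows from one master seed through named
`SeedSequence` streams (placement, population, deposition are independent
streams), so any run is bit-reproducible.

## Known limitations

* The three cluster parameters are sampled independently; the real data show
  correlations (larger populations in larger, closer clusters).
* The continuous families stand in for the digitized histology histograms.
  With the printed parameters the C_dia median is 287 μm (published discrete
  median 337 μm) and E[C_pop] ≈ 18; realized cluster statistics and the
  hot-spot/low-dose error medians inherit these offsets, and the
  population-model hot-spot error median changes sign relative to the
  published table.
* The published equal-mean scenario ("both fields have D_mean ≈ 100 Gy with
  V₁₀₀ = 38%/55%") is not reachable by any energy-conserving implementation
  of its stated operating points: τ·c·A_MS·E/ρ fixes D_mean ≈ 120 Gy for
  both pairs. We report V₁₀₀ at the literal operating points; the printed
  percentages correspond to fields ~17% colder than charged-particle
  equilibrium permits.
* The synthetic kernel neglects straggling, delta rays and bremsstrahlung;
  energy normalization pins the absolute scale, but the near/far energy
  split carries a few percent of model uncertainty (visible as a slightly
  low uniform-model COV, 0.32 vs the published 0.33).
* Cyclic convolution wraps the dose of sources near one face onto the
  opposite face; only the discarded 80-voxel shell is affected.
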