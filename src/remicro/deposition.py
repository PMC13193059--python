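"""Stochastic microsphere deposition: cluster placement, population, and
voxel occupancy grids.

A model is a cube of tissue (default 2.2 cm, 30 um voxels) seeded with
microsphere clusters.  Cluster centers are laid down either on a cubic
lattice at the published median spacing (470 um) or stochastically, by
rejection sampling: each uniformly proposed center draws a separation from
the cluster-distance distribution and is rejected if any existing cluster
lies closer (variable-radius Poisson disk, floor 89 um).  Clusters are
then populated with microspheres (uniformly inside each cluster sphere)
until a target concentration is met exactly, and the resulting positions are
rasterized into a per-voxel count grid.

Seven model-complexity variants are supported, from the fully uniform
``UNI`` layout to the fully sampled reference ``REF``:

========  =================  ==============  ===============
variant   cluster centers    diameter        population
========  =================  ==============  ===============
REF       stochastic         sampled         sampled
MED       lattice 470 um     337 um          5
DIA       lattice 470 um     sampled         5
DIST      stochastic         337 um          5
POP       lattice 470 um     337 um          sampled
DIST_POP  stochastic         337 um          sampled
UNI       (no clusters; microspheres equally spaced)
========  =================  ==============  ===============
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from . import distributions as dists
from .constants import (
    GRID_DIM,
    MEDIAN_C_DIA_UM,
    MEDIAN_C_DIST_UM,
    MEDIAN_C_POP,
    SIDE_LENGTH_MM,
    VOXEL_PITCH_UM,
)

__all__ = [
    "Cluster",
    "ModelConfig",
    "MicrosphereGrid",
    "DepositionResult",
    "CapacityError",
    "target_count",
    "place_clusters_stochastic",
    "place_clusters_lattice",
    "populate_clusters",
    "place_microspheres",
    "rasterize",
    "build_model",
    "uniform_positions",
]

Variant = Literal["REF", "MED", "UNI", "DIA", "DIST", "POP", "DIST_POP"]


class CapacityError(ValueError):
    """Requested concentration exceeds what the cluster layout can hold."""


@dataclass
class Cluster:
    center: np.ndarray          # (x, y, z) um
    diameter: float             # um
    population: int = 0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class ModelConfig:
    """Geometry, concentration and seeding for one simulated model.

    The cube side and voxel count are the primary inputs; the voxel pitch is
    derived as ``side / grid_dim`` (22 mm / 735 = 29.93 um at the default
    geometry, i.e. a nominally 30 um grid)."""

    variant: Variant = "REF"
    side_length_mm: float = SIDE_LENGTH_MM
    grid_dim: int = GRID_DIM
    concentration_per_ml: float = 5000.0
    seed: int = 0
    reference_capacity_per_ml: float = 60000.0

    def __post_init__(self):
        if self.concentration_per_ml <= 0:
            raise ValueError("concentration must be positive")
        if self.grid_dim < 1 or self.side_length_mm <= 0:
            raise ValueError("invalid geometry")

    @property
    def side_um(self) -> float:
        return self.side_length_mm * 1000.0

    @property
    def dims(self) -> int:
        return self.grid_dim

    @property
    def voxel_pitch_um(self) -> float:
        return self.side_um / self.grid_dim

    @property
    def volume_ml(self) -> float:
        return (self.side_length_mm * 0.1) ** 3


@dataclass
class MicrosphereGrid:
    """Integer microsphere counts per voxel (the occupancy map convolved with
    the dose kernel)."""

    counts: np.ndarray
    pitch_um: float

    def __post_init__(self):
        if self.counts.ndim != 3:
            raise ValueError("counts must be 3-D")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def dims(self):
        return self.counts.shape


@dataclass
class DepositionResult:
    grid: MicrosphereGrid
    clusters: list
    realized_nn_distances: np.ndarray
    seed_manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def target_count(config: ModelConfig) -> int:
    """Number of microspheres for the requested concentration (rounded)."""
    return int(round(config.concentration_per_ml * config.volume_ml))


def default_cluster_budget(config: ModelConfig, mean_pop: float = MEDIAN_C_POP,
                           margin: float = 1.08) -> int:
    """Cluster count for a stochastic layout.

    The layout is generated once at the reference capacity concentration
    (default 60,000 /mL) and sub-populated per requested concentration, so
    the budget is ``margin * reference_count / mean_pop`` clusters --
    ``margin`` keeps the achievable capacity safely above the reference when
    populations are random draws.  The budget is additionally capped at the
    median-spacing packing density floor(L/470um)^3 (the density at which
    the distance distribution can still be respected); that cap is what
    limits fixed-population-5 layouts to ~45,000 /mL at default geometry."""
    ref_count = config.reference_capacity_per_ml * config.volume_ml
    budget = int(np.ceil(margin * ref_count / mean_pop))
    packing_cap = int(config.side_um // MEDIAN_C_DIST_UM) ** 3
    return min(budget, packing_cap)


# ---------------------------------------------------------------------------
# Cluster placement
# ---------------------------------------------------------------------------

def place_clusters_stochastic(config: ModelConfig,
                              dist_pdf: dists.GEVDistribution | None = None,
                              dia_sampler=None,
                              n_clusters: int | None = None,
                              rng: np.random.Generator | None = None,
                              failure_cap: int = 100_000) -> list:
    """Rejection-sampled cluster layout (variable-radius Poisson disk).

    Candidate centers are proposed uniformly (each cluster sphere fully
    inside the volume) and every candidate draws a separation distance from
    the cluster-distance distribution; the candidate is rejected when any
    existing cluster lies closer than its drawn distance.  The first cluster
    is always accepted.  The scheme keeps the hard floor at the observed
    minimum distance (drawn separations never fall below it) and biases the
    realized nearest-neighbour median upward from the distribution median
    through mutual exclusion, matching the behaviour reported for the
    sampled layouts.  Placement stops after ``n_clusters`` acceptances or
    ``failure_cap`` consecutive rejections.  Returns unpopulated clusters.
    """
    dist_pdf = dist_pdf or dists.C_DIST
    rng = rng or np.random.default_rng(config.seed)
    if n_clusters is None:
        n_clusters = default_cluster_budget(config)
    if dia_sampler is None:
        def dia_sampler(n, rng):
            return np.full(n, MEDIAN_C_DIA_UM)

    dist_cdf = dists.build_cdf(dist_pdf, grid_step=1.0)
    side = config.side_um

    centers = np.empty((n_clusters, 3))
    diameters = np.empty(n_clusters)
    n_acc = 0
    consecutive_rej = 0
    tree = None
    tree_size = 0
    batch = 2048

    while n_acc < n_clusters and consecutive_rej < failure_cap:
        dias = np.asarray(dia_sampler(batch, rng), dtype=float)
        radii = dias / 2.0
        lo = radii[:, None]
        hi = side - radii[:, None]
        if np.any(hi <= lo):
            raise ValueError("cluster diameter exceeds volume side")
        cand = lo + rng.random((batch, 3)) * (hi - lo)
        sep = dists.sample(dist_cdf, batch, rng=rng)  # drawn C_dist per candidate

        if tree is not None:
            d_tree, _ = tree.query(cand, k=1)
        else:
            d_tree = np.full(batch, np.inf)
        recent = centers[tree_size:n_acc]
        if len(recent):
            d2 = ((cand[:, None, :] - recent[None, :, :]) ** 2).sum(axis=2)
            d_exist = np.minimum(d_tree, np.sqrt(d2.min(axis=1)))
        else:
            d_exist = d_tree

        passed = np.flatnonzero(d_exist >= sep)
        if n_acc == 0 and len(passed) == 0:
            passed = np.array([0])  # first cluster always accepted
        n_batch_start = n_acc
        for i in passed:
            if n_acc >= n_clusters:
                break
            newly = centers[n_batch_start:n_acc]
            if n_acc > 0 and len(newly):
                dmin2 = ((cand[i] - newly) ** 2).sum(axis=1).min()
                if dmin2 < sep[i] ** 2:
                    continue
            centers[n_acc] = cand[i]
            diameters[n_acc] = dias[i]
            n_acc += 1
        accepted = n_acc - n_batch_start
        if accepted:
            consecutive_rej = 0
        else:
            consecutive_rej += batch
        # grow the batch as the acceptance rate falls so tree queries stay
        # amortized near saturation
        if accepted < batch // 64:
            batch = min(batch * 2, 65536)
        if n_acc - tree_size >= max(1000, n_acc // 4):
            tree = cKDTree(centers[:n_acc])
            tree_size = n_acc

    if n_acc < n_clusters:
        warnings.warn(
            f"placement stopped after {failure_cap} consecutive rejections "
            f"with {n_acc}/{n_clusters} clusters")
    return [Cluster(center=centers[i].copy(), diameter=float(diameters[i]))
            for i in range(n_acc)]


def place_clusters_lattice(config: ModelConfig,
                           spacing_um: float = MEDIAN_C_DIST_UM,
                           diameter_um: float = MEDIAN_C_DIA_UM) -> list:
    """Cubic lattice of cluster centers with pitch ``spacing_um``, centered in
    the volume; floor(L/spacing) sites per axis."""
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    side = config.side_um
    if spacing_um > side:
        raise ValueError("spacing exceeds the volume side length")
    n = int(side // spacing_um)
    span = n * spacing_um
    offset = (side - span) / 2.0 + spacing_um / 2.0
    coords = offset + spacing_um * np.arange(n)
    cx, cy, cz = np.meshgrid(coords, coords, coords, indexing="ij")
    centers = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
    # clamp diameters so every sphere stays inside the volume
    margin = np.minimum(centers.min(axis=1), side - centers.max(axis=1))
    return [Cluster(center=c, diameter=float(min(diameter_um, 2.0 * m)))
            for c, m in zip(centers, margin)]


def nearest_neighbor_distances(clusters) -> np.ndarray:
    """Final center-to-center nearest-neighbour distance per cluster."""
    pts = np.array([c.center for c in clusters])
    if len(pts) < 2:
        return np.full(len(pts), np.nan)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


# ---------------------------------------------------------------------------
# Population and microsphere placement
# ---------------------------------------------------------------------------

def populate_clusters(clusters, pop_source, target: int,
                      rng: np.random.Generator | None = None,
                      variant: str = "") -> list:
    """Assign microsphere populations until ``target`` is reached exactly.

    Clusters are selected uniformly at random without replacement and each
    receives a population drawn from ``pop_source`` (a callable
    ``pop_source(n, rng) -> int array``, or a fixed integer); the final
    cluster's population is truncated so the total equals the target.
    Raises :class:`CapacityError` when every cluster is exhausted first.
    """
    rng = rng or np.random.default_rng(0)
    n = len(clusters)
    order = rng.permutation(n)
    if callable(pop_source):
        pops = np.asarray(pop_source(n, rng), dtype=int)
    else:
        pops = np.full(n, int(pop_source))
    pops = np.clip(pops, 1, None)
    csum = np.cumsum(pops)
    if csum[-1] < target:
        raise CapacityError(
            f"concentration unachievable for variant {variant or '?'}: "
            f"layout capacity {csum[-1]} microspheres < target {target}")
    k = int(np.searchsorted(csum, target))
    populated = []
    for c in clusters:
        c.population = 0
    for rank in range(k + 1):
        idx = order[rank]
        p = int(pops[rank])
        if rank == k:
            p = int(target - (csum[rank - 1] if rank else 0))
        clusters[idx].population = p
        populated.append(clusters[idx])
    return populated


def place_microspheres(cluster: Cluster, rng: np.random.Generator | None = None,
                       seed=None) -> np.ndarray:
    """Positions i.i.d. uniform inside the cluster sphere (rejection from the
    bounding cube)."""
    if cluster.population < 1:
        raise ValueError("population must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    return _uniform_in_spheres(
        np.repeat(cluster.center[None, :], cluster.population, axis=0),
        np.full(cluster.population, cluster.diameter / 2.0), rng)


def _uniform_in_spheres(centers, radii, rng):
    """Vectorized uniform sampling inside per-row spheres."""
    n = len(centers)
    out = np.empty((n, 3))
    todo = np.arange(n)
    while len(todo):
        v = rng.random((len(todo), 3)) * 2.0 - 1.0
        ok = (v * v).sum(axis=1) <= 1.0
        sel = todo[ok]
        out[sel] = centers[sel] + v[ok] * radii[sel, None]
        todo = todo[~ok]
    return out


def _deposit_positions(populated, rng, pitch_um, dims, max_redraws=100):
    """All microsphere positions for the populated clusters, with voxel-level
    collision avoidance: spheres landing in an occupied voxel are redrawn up
    to ``max_redraws`` times, after which multi-occupancy is permitted."""
    if not populated:
        return np.empty((0, 3))
    counts = np.array([c.population for c in populated])
    centers = np.repeat(np.array([c.center for c in populated]), counts, axis=0)
    radii = np.repeat(np.array([c.diameter / 2.0 for c in populated]), counts)
    pos = _uniform_in_spheres(centers, radii, rng)

    lin = _voxel_linear_index(pos, pitch_um, dims)
    for _ in range(max_redraws):
        # first occurrence of each voxel keeps its sphere; later ones redraw
        order = np.argsort(lin, kind="stable")
        sorted_lin = lin[order]
        dup_sorted = np.zeros(len(lin), dtype=bool)
        dup_sorted[1:] = sorted_lin[1:] == sorted_lin[:-1]
        dup = np.zeros(len(lin), dtype=bool)
        dup[order] = dup_sorted
        if not dup.any():
            break
        idx = np.flatnonzero(dup)
        pos[idx] = _uniform_in_spheres(centers[idx], radii[idx], rng)
        lin[idx] = _voxel_linear_index(pos[idx], pitch_um, dims)
    return pos


def _voxel_linear_index(pos, pitch_um, dims):
    ijk = np.minimum((pos / pitch_um).astype(np.int64), dims - 1)
    return (ijk[:, 0] * dims + ijk[:, 1]) * dims + ijk[:, 2]


def rasterize(positions, config: ModelConfig) -> MicrosphereGrid:
    """Accumulate positions into per-voxel counts; voxel index is
    floor(coordinate / pitch) with half-open intervals, and positions on the
    upper boundary clamp to the last voxel."""
    dims = config.dims
    positions = np.asarray(positions, dtype=float)
    if positions.size and (positions.min() < 0 or positions.max() > config.side_um):
        raise ValueError("positions outside the volume")
    counts = np.zeros((dims, dims, dims), dtype=np.uint16)
    if positions.size:
        lin = _voxel_linear_index(positions, config.voxel_pitch_um, dims)
        binc = np.bincount(lin, minlength=dims ** 3)
        counts = binc.reshape(dims, dims, dims).astype(np.uint16)
    return MicrosphereGrid(counts=counts, pitch_um=config.voxel_pitch_um)


def uniform_positions(config: ModelConfig) -> np.ndarray:
    """Near-uniform microsphere lattice for the UNI variant: ceil(N^(1/3))
    sites per axis with half-pitch margins; the surplus sites are removed by
    a uniform stride in raster order so exactly N remain."""
    n_total = target_count(config)
    if n_total > config.dims ** 3:
        raise CapacityError("more microspheres than voxels")
    n_ax = int(np.ceil(n_total ** (1.0 / 3.0)))
    while n_ax ** 3 < n_total:   # guard against cube-root rounding
        n_ax += 1
    pitch = config.side_um / n_ax
    coords = (np.arange(n_ax) + 0.5) * pitch
    gx, gy, gz = np.meshgrid(coords, coords, coords, indexing="ij")
    pos = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    surplus = n_ax ** 3 - n_total
    if surplus:
        drop = np.unique(np.round(np.linspace(0, n_ax ** 3 - 1, surplus)).astype(int))
        # rounding collisions would drop too few; extend deterministically
        extra = 0
        while len(drop) < surplus:
            cand = (drop[-1] + 1 + extra) % n_ax ** 3
            if cand not in drop:
                drop = np.append(drop, cand)
            extra += 1
        keep = np.ones(n_ax ** 3, dtype=bool)
        keep[drop[:surplus]] = False
        pos = pos[keep]
    return pos


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

def _integer_mean(cdf: dists.TabulatedCDF) -> float:
    """Mean of the integer-rounded inverse-CDF sampling distribution."""
    lo = int(np.ceil(cdf.grid_x[0]))
    hi = int(np.floor(cdf.grid_x[-1]))
    ks = np.arange(lo, hi + 1)
    upper = np.interp(np.minimum(ks + 0.5, cdf.grid_x[-1]), cdf.grid_x, cdf.cdf_values)
    lower = np.interp(np.maximum(ks - 0.5, cdf.grid_x[0]), cdf.grid_x, cdf.cdf_values)
    pmf = upper - lower
    pmf[0] += lower[0]
    pmf[-1] += 1.0 - upper[-1]
    return float((ks * pmf).sum())


def _samplers(params: dists.ClusterParamSet):
    dia_cdf = dists.build_cdf(params.dia, grid_step=0.5)
    pop_cdf = dists.build_cdf(params.pop, grid_step=0.01, integer_valued=True)

    def dia_sampler(n, rng):
        return dists.sample(dia_cdf, n, rng=rng)

    def pop_sampler(n, rng):
        return dists.sample(pop_cdf, n, rng=rng)

    return dia_sampler, pop_sampler, _integer_mean(pop_cdf)


def build_model(config: ModelConfig,
                params: dists.ClusterParamSet = dists.DEFAULT_PARAMS,
                layout: list | None = None) -> DepositionResult:
    """Generate the microsphere occupancy grid for one model variant.

    A precomputed unpopulated ``layout`` (from a previous call at the same
    geometry/seed) may be passed to re-populate at a different concentration,
    mirroring the concentration-scaling procedure: stochastic layouts are
    generated once at the reference cluster density and sub-populated.
    """
    ss = np.random.SeedSequence([config.seed, 0xD05E])
    rng_place, rng_pop, rng_dep = (np.random.default_rng(s) for s in ss.spawn(3))
    variant = config.variant
    n = target_count(config)
    dia_sampler, pop_sampler, pop_mean = _samplers(params)

    if variant == "UNI":
        pos = uniform_positions(config)
        grid = rasterize(pos, config)
        return DepositionResult(grid=grid, clusters=[],
                                realized_nn_distances=np.array([]),
                                seed_manifest={"seed": config.seed,
                                               "variant": variant})

    stochastic = variant in ("REF", "DIST", "DIST_POP")
    if layout is None:
        if stochastic:
            sampler = dia_sampler if variant == "REF" else None
            mean_pop = pop_mean if variant in ("REF", "DIST_POP") \
                else float(params.median_pop)
            budget = default_cluster_budget(config, mean_pop)
            clusters = place_clusters_stochastic(config, params.dist,
                                                 dia_sampler=sampler,
                                                 n_clusters=budget,
                                                 rng=rng_place)
        else:
            clusters = place_clusters_lattice(config)
            if variant == "DIA":
                dias = dia_sampler(len(clusters), rng_place)
                side = config.side_um
                for c, d in zip(clusters, dias):
                    m = min(c.center.min(), side - c.center.max())
                    c.diameter = float(min(d, 2.0 * m))
    else:
        clusters = layout

    pop_source = pop_sampler if variant in ("REF", "POP", "DIST_POP") \
        else MEDIAN_C_POP
    populated = populate_clusters(clusters, pop_source, n, rng=rng_pop,
                                  variant=variant)
    pos = _deposit_positions(populated, rng_dep, config.voxel_pitch_um,
                             config.dims)
    grid = rasterize(pos, config)
    return DepositionResult(
        grid=grid,
        clusters=clusters,
        realized_nn_distances=nearest_neighbor_distances(clusters),
        seed_manifest={"seed": config.seed, "variant": variant,
                       "n_clusters": len(clusters),
                       "n_populated": len(populated),
                       "n_microspheres": int(grid.total)},
    )
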