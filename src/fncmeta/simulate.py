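"""Synthetic fixtures with the statistical structure the analysis assumes.

The generators emulate the inputs of the two-stage analysis so that every
stage is testable without external downloads:

* multi-study peak tables arise from thresholding noisy per-study effect
  fields with planted effect regions (between-study heterogeneity tau on the
  region effect, spatially smooth noise), exactly the generative story the
  kernel-reconstruction + random-effects model assumes;
* spatially autocorrelated gene-expression columns, a known subset of which
  ("driver" genes) linearly track a target brain map, emulating an
  AHBA-style sample x gene matrix;
* category and cell-type fixtures with one known-enriched set.

All generators are pure functions of (config, seed); ground-truth artifacts
(region masks, driver identities, the enriched category id) are returned
beside the data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .enrichment import CategoryAnnotation
from .exceptions import DomainError
from .expression import ExpressionMatrix
from .grid import BrainGrid, make_ellipsoid_grid
from .study_io import PeakRecord, StudyDataset, StudyTable

__all__ = [
    "SimulationConfig",
    "EffectRegion",
    "simulate_studies",
    "simulate_expression",
    "make_annotation_fixtures",
    "smooth_noise_field",
]


@dataclass(frozen=True)
class EffectRegion:
    center_mm: tuple[float, float, float]
    radius_mm: float
    g_true: float


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale defaults: a 40 x 48 x 40 grid at 4 mm, 12 studies with
    30-80 subjects per arm, one planted region (g = 0.8, tau = 0.1), smooth
    noise with a 12 mm length scale, 200 expression samples x 600 genes with
    30 strongly driven genes (loading 1.5, a high-SNR power construction)."""

    seed: int = 0
    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 4.0
    n_studies: int = 12
    n_min: int = 30
    n_max: int = 80
    regions: tuple[EffectRegion, ...] = (EffectRegion((20.0, -40.0, 30.0), 16.0, 0.8),)
    tau: float = 0.1
    noise_sd: float = 0.25
    noise_length_scale_mm: float = 12.0
    reporting_p: float = 0.001
    publication_bias: bool = False
    n_samples: int = 200
    n_genes: int = 600
    n_drivers: int = 30
    driver_loading: float = 1.5
    expression_length_scale_mm: float = 15.0
    expression_noise_sd: float = 1.0
    n_categories: int = 20
    category_size: int = 20

    def __post_init__(self):
        if self.n_studies < 1 or self.n_samples < 1 or self.n_genes < 1:
            raise DomainError("all sizes must be >= 1")
        if min(self.tau, self.noise_sd, self.driver_loading) < 0:
            raise DomainError("tau, noise sd and driver loading must be >= 0")

    def make_grid(self) -> BrainGrid:
        return make_ellipsoid_grid(self.grid_shape, self.voxel_size_mm)


def smooth_noise_field(grid: BrainGrid, length_scale_mm: float, rng: np.random.Generator,
                       sd: float = 1.0) -> np.ndarray:
    """Spatially smooth Gaussian noise over in-mask voxels, unit-sd rescaled.

    Gaussian-kernel-filtered white noise; the length scale (mm) sets the
    filter sigma, matching the autocorrelation structure both the kernel
    reconstruction and variogram surrogates assume.
    """
    vol = _smooth_noise_volume(grid, length_scale_mm, rng)
    return sd * vol[grid.mask]


def _smooth_noise_volume(grid: BrainGrid, length_scale_mm: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-sd stationary smooth noise over the full array.

    Periodic (wrap) filtering keeps the field statistically identical at
    every voxel — with zero padding the variance would dip near the array
    edge and peak locations would not be exchangeable with a uniform
    relocation null.
    """
    white = rng.standard_normal(grid.shape)
    sigma_vox = length_scale_mm / grid.voxel_size.mean()
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    return smooth


def region_field(grid: BrainGrid, regions: Sequence[EffectRegion],
                 per_region_g: Optional[Sequence[float]] = None) -> np.ndarray:
    """Planted-effect template: Gaussian bumps, amplitude g at each centre."""
    coords = grid.coords_mm
    out = np.zeros(grid.n_voxels)
    for i, r in enumerate(regions):
        centre = np.asarray(r.center_mm, dtype=float)
        ijk = np.round(grid.mm_to_voxel(centre)[0]).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.array(grid.shape))) and grid.mask[tuple(ijk)]
        if not inside:
            raise DomainError(f"effect region centred at {r.center_mm} lies outside the mask")
        g = r.g_true if per_region_g is None else per_region_g[i]
        d2 = ((coords - centre) ** 2).sum(axis=1)
        out += g * np.exp(-d2 / (2.0 * (r.radius_mm / 2.0) ** 2))
    return out


def region_truth_mask(grid: BrainGrid, regions: Sequence[EffectRegion]) -> np.ndarray:
    """Boolean ground-truth mask: voxels within one radius of a centre."""
    coords = grid.coords_mm
    mask = np.zeros(grid.n_voxels, dtype=bool)
    for r in regions:
        d2 = ((coords - np.asarray(r.center_mm)) ** 2).sum(axis=1)
        mask |= d2 <= r.radius_mm**2
    return mask


def _local_maxima(vol: np.ndarray, mask: np.ndarray, threshold: float) -> np.ndarray:
    """In-mask voxel indices of local maxima of |vol| above threshold.

    The 3x3x3 comparison runs on the full volume so that voxels at the mask
    boundary compete with their true (out-of-mask) neighbours rather than
    with zeros.
    """
    mag = np.abs(vol)
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = (mag == ndimage.maximum_filter(mag, footprint=footprint)) & mask
    local_max &= mag > threshold
    return np.column_stack(np.nonzero(local_max))


def _region_volume(grid: BrainGrid, regions: Sequence[EffectRegion],
                   per_region_g: Sequence[float]) -> np.ndarray:
    """Planted-effect template over the full array (not just the mask)."""
    ii, jj, kk = np.meshgrid(*[np.arange(s, dtype=float) for s in grid.shape], indexing="ij")
    out = np.zeros(grid.shape)
    A = grid.affine
    xs = A[0, 0] * ii + A[0, 1] * jj + A[0, 2] * kk + A[0, 3]
    ys = A[1, 0] * ii + A[1, 1] * jj + A[1, 2] * kk + A[1, 3]
    zs = A[2, 0] * ii + A[2, 1] * jj + A[2, 2] * kk + A[2, 3]
    for g, r in zip(per_region_g, regions):
        cx, cy, cz = r.center_mm
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2
        out += g * np.exp(-d2 / (2.0 * (r.radius_mm / 2.0) ** 2))
    return out


def simulate_studies(cfg: SimulationConfig, grid: Optional[BrainGrid] = None):
    """Generate a multi-study peak table from thresholded noisy effect maps.

    Per study: region effects g_i ~ Normal(g_true, tau^2), plus smooth noise
    of sd ``noise_sd`` (in g units); group sizes uniform in [n_min, n_max];
    the study's t-map is thresholded at its one-tailed reporting p (both
    signs) and local maxima become PeakRecords carrying the local t-value.
    With ``publication_bias``, below-median-size studies whose largest peak
    is negative are replaced by a fresh draw (small unfavourable studies
    never reach the literature).

    Returns (StudyTable, truth) where truth holds the region mask and the
    per-study latent effects.
    """
    rng = np.random.default_rng(cfg.seed)
    if grid is None:
        grid = cfg.make_grid()
    for r in cfg.regions:
        ijk = np.round(grid.mm_to_voxel(np.asarray(r.center_mm))[0]).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.array(grid.shape))) and grid.mask[tuple(ijk)]
        if not inside:
            raise DomainError(f"effect region centred at {r.center_mm} lies outside the mask")
    truth_mask = region_truth_mask(grid, cfg.regions)
    datasets: list[StudyDataset] = []
    latent_g: list[np.ndarray] = []
    median_n = (cfg.n_min + cfg.n_max) / 2.0

    i = 0
    attempts = 0
    while i < cfg.n_studies:
        attempts += 1
        if attempts > 50 * cfg.n_studies:
            raise DomainError("publication-bias rejection loop failed to fill the roster")
        n1 = int(rng.integers(cfg.n_min, cfg.n_max + 1))
        n2 = int(rng.integers(cfg.n_min, cfg.n_max + 1))
        g_regions = [rng.normal(r.g_true, cfg.tau) for r in cfg.regions]
        field_vol = _region_volume(grid, cfg.regions, g_regions)
        field_vol += cfg.noise_sd * _smooth_noise_volume(grid, cfg.noise_length_scale_mm, rng)
        field_g = field_vol[grid.mask]
        se = np.sqrt(1.0 / n1 + 1.0 / n2)
        df = n1 + n2 - 2
        t_crit = stats.t.isf(cfg.reporting_p, df)
        vol = field_vol / se
        peaks_ijk = _local_maxima(vol, grid.mask, t_crit)
        peak_ts = [float(vol[tuple(ijk)]) for ijk in peaks_ijk]

        if cfg.publication_bias and (n1 + n2) / 2.0 < median_n:
            if not peak_ts or max(peak_ts) <= 0:
                continue  # suppressed: redraw the study

        peaks = []
        for ijk, t in zip(peaks_ijk, peak_ts):
            x, y, z = grid.voxel_to_mm(ijk)[0]
            peaks.append(PeakRecord(x=x, y=y, z=z, stat=t))
        datasets.append(StudyDataset(
            study_id=f"sim{i:02d}",
            n_patients=n1,
            n_controls=n2,
            male_patients=int(rng.integers(0, n1 + 1)),
            male_controls=int(rng.integers(0, n2 + 1)),
            mean_age_pat=float(rng.normal(27.0, 4.0)),
            mean_age_con=float(rng.normal(28.0, 4.0)),
            panss_total=float(rng.normal(80.0, 12.0)),
            fnc_type="binary" if rng.random() < 0.5 else "weighted",
            reporting_p=cfg.reporting_p,
            reporting_corrected=False,
            peaks=peaks,
        ))
        latent_g.append(field_g)
        i += 1

    truth = {
        "region_mask": truth_mask,
        "latent_effects": np.array(latent_g),
        "grid": grid,
    }
    return StudyTable(datasets=datasets), truth


def _sa_noise(coords: np.ndarray, length_scale: float, rng: np.random.Generator,
              n_draws: int, sd: float) -> np.ndarray:
    """(n_draws, S) spatially autocorrelated Gaussian draws over fixed points.

    Exact sampling from a squared-exponential Gaussian process via Cholesky;
    a small nugget keeps the covariance positive definite.
    """
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    C = np.exp(-d2 / (2.0 * length_scale**2)) + 1e-8 * np.eye(len(coords))
    L = np.linalg.cholesky(C)
    return sd * (rng.standard_normal((n_draws, len(coords))) @ L.T)


def simulate_expression(cfg: SimulationConfig, target_map: np.ndarray,
                        grid: Optional[BrainGrid] = None):
    """AHBA-style expression matrix whose driver genes track a target map.

    S sample coordinates are drawn from in-mask voxel centres. Driver gene
    columns are lambda * (standardised target at the sample) + SA noise;
    non-driver columns are SA noise only (squared-exponential Gaussian
    process with the configured length scale). Columns are returned raw;
    z-scoring happens downstream. Returns (ExpressionMatrix, driver gene
    names, target values per sample).
    """
    if cfg.n_samples < 10:
        raise DomainError("need at least 10 expression samples")
    rng = np.random.default_rng(cfg.seed + 1)
    if grid is None:
        grid = cfg.make_grid()
    target_map = np.asarray(target_map, dtype=float)
    if target_map.shape[0] != grid.n_voxels:
        raise DomainError("target_map must be defined on the grid (flat in-mask vector)")
    idx = rng.choice(grid.n_voxels, size=cfg.n_samples, replace=False)
    coords = grid.coords_mm[idx]
    t = target_map[idx]
    ts = (t - t.mean()) / t.std() if t.std() > 0 else t - t.mean()

    noise = _sa_noise(coords, cfg.expression_length_scale_mm, rng,
                      cfg.n_genes, cfg.expression_noise_sd)
    X = noise.T  # (S, G)
    drivers = [f"gene{j:04d}" for j in range(cfg.n_drivers)]
    X[:, : cfg.n_drivers] += cfg.driver_loading * ts[:, None]
    genes = [f"gene{j:04d}" for j in range(cfg.n_genes)]
    sample_ids = [f"s{j:04d}" for j in range(cfg.n_samples)]
    values = pd.DataFrame(X, index=pd.Index(sample_ids, name="sample_id"), columns=genes)
    cdf = pd.DataFrame(coords, index=values.index, columns=["x", "y", "z"])
    cdf["donor_id"] = "simdonor"
    cdf["structure"] = "cortex"
    em = ExpressionMatrix(values=values, coords=cdf,
                          provenance={"generator": "simulate_expression", "seed": cfg.seed})
    return em, drivers, pd.Series(t, index=values.index)


def make_annotation_fixtures(cfg: SimulationConfig, drivers: Sequence[str],
                             genes: Sequence[str]):
    """Category and cell-type fixtures with one known-enriched set.

    The enriched category is a random subset of the driver genes; the rest
    are size-matched random categories from the whole universe. Cell-type
    profiles put one cell type ("target_cells") overexpressing the drivers
    against baseline cell types.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    genes = list(genes)
    drivers = list(drivers)
    size = min(cfg.category_size, len(drivers))
    enriched = CategoryAnnotation(
        category_id="CAT_ENRICHED",
        name="driver-built category",
        members=sorted(rng.choice(drivers, size=size, replace=False).tolist()),
    )
    randoms = [
        CategoryAnnotation(
            category_id=f"CAT_RAND{j:03d}",
            name=f"random category {j}",
            members=sorted(rng.choice(genes, size=cfg.category_size, replace=False).tolist()),
        )
        for j in range(cfg.n_categories - 1)
    ]
    annotations = [enriched] + randoms

    cell_types = ["target_cells", "neuron_a", "neuron_b", "glia_a", "glia_b",
                  "glia_c", "immune_a", "immune_b", "vascular", "ependymal"]
    profiles = pd.DataFrame(
        rng.lognormal(0.0, 0.3, size=(len(cell_types), len(genes))),
        index=cell_types, columns=genes,
    )
    profiles.loc["target_cells", drivers] *= 6.0
    return annotations, profiles, enriched.category_id
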