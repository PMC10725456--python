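"""Voxel-wise random-effects pooling, permutation standardisation, clusters.

The pooled map is a DerSimonian–Laird random-effects combination of the
per-study reconstructed g maps at every in-mask voxel. The pooled mean is
standardised into an SDM-Z statistic against a permutation null obtained by
relocating each study's peaks to uniformly random in-mask voxels (keeping
peak counts and effect values) and re-running reconstruction and pooling.
Empirical voxel p-values are mid-p tail proportions of that null; clusters
are connected components (26-connectivity) of supra-threshold voxels, split
by sign of the pooled effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DomainError
from .grid import BrainGrid
from .reconstruction import (
    DEFAULT_FWHM_MM,
    reconstruct_from_points,
    reconstruct_study_maps,
    _peak_effects,
)
from .study_io import StudyDataset, StudyTable

__all__ = [
    "MetaResult",
    "Cluster",
    "random_effects_voxel",
    "sdm_z_map",
    "threshold_clusters",
]


@dataclass
class MetaResult:
    grid: BrainGrid
    study_ids: list[str]
    effects: np.ndarray          # (k, V) per-study reconstructed g
    variances: np.ndarray        # (k, V) per-study sampling variance
    pooled_effect: np.ndarray    # (V,) DL pooled mean
    se: np.ndarray               # (V,) pooled standard error
    tau2: np.ndarray             # (V,) between-study variance
    sdm_z: np.ndarray            # (V,) permutation-standardised statistic
    p_increase: np.ndarray       # (V,) upper-tail empirical p (mid-p)
    p_decrease: np.ndarray       # (V,) lower-tail empirical p (mid-p)
    n_perm: int = 0
    seed: Optional[int] = None

    @property
    def p(self) -> np.ndarray:
        """Per-voxel one-sided p in the direction of the pooled effect."""
        return np.where(self.pooled_effect >= 0, self.p_increase, self.p_decrease)


@dataclass
class Cluster:
    peak_xyz: tuple[float, float, float]
    size_voxels: int
    peak_sdm_z: float
    p: float
    member_voxels: np.ndarray = field(repr=False)  # flat in-mask indices
    sign: str = "increase"  # "increase" | "decrease"

    def as_row(self) -> dict:
        x, y, z = self.peak_xyz
        return {
            "sign": self.sign,
            "x": x, "y": y, "z": z,
            "size_voxels": self.size_voxels,
            "peak_sdm_z": self.peak_sdm_z,
            "p": self.p,
        }


def random_effects_voxel(effects: np.ndarray, variances: np.ndarray):
    """DerSimonian–Laird pooling; vectorised over trailing axes.

    effects/variances have shape (k,) or (k, V). Fixed weights w = 1/var give
    Q = sum w (g - g_fix)^2 and tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 /
    sum w)); re-weighting by w* = 1/(var + tau2) gives the pooled mean and
    se = 1/sqrt(sum w*). A single study returns (g, sqrt(var), 0).
    """
    g = np.atleast_2d(np.asarray(effects, dtype=float).T).T  # ensure (k, V)
    v = np.atleast_2d(np.asarray(variances, dtype=float).T).T
    if g.shape != v.shape or g.shape[0] < 1:
        raise DomainError("effects and variances must align with k >= 1 studies")
    if np.any(v <= 0):
        raise DomainError("variances must be strictly positive")
    k = g.shape[0]
    if k == 1:
        mu, se, tau2 = g[0], np.sqrt(v[0]), np.zeros_like(g[0])
    else:
        w = 1.0 / v
        sw = w.sum(axis=0)
        g_fix = (w * g).sum(axis=0) / sw
        Q = (w * (g - g_fix) ** 2).sum(axis=0)
        denom = sw - (w**2).sum(axis=0) / sw
        tau2 = np.maximum(0.0, (Q - (k - 1)) / denom)
        ws = 1.0 / (v + tau2)
        sws = ws.sum(axis=0)
        mu = (ws * g).sum(axis=0) / sws
        se = 1.0 / np.sqrt(sws)
    if np.asarray(effects).ndim == 1:
        return float(mu[0]), float(se[0]), float(tau2[0])
    return mu, se, tau2


def _pool(effects: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Pooled DL mean only (fast path used inside the permutation loop)."""
    k = effects.shape[0]
    w = 1.0 / variances
    sw = w.sum(axis=0)
    g_fix = (w * effects).sum(axis=0) / sw
    Q = (w * (effects - g_fix) ** 2).sum(axis=0)
    denom = sw - (w**2).sum(axis=0) / sw
    tau2 = np.maximum(0.0, (Q - (k - 1)) / denom)
    ws = 1.0 / (variances + tau2)
    return (ws * effects).sum(axis=0) / ws.sum(axis=0)


def sdm_z_map(
    studies: StudyTable | list[StudyDataset],
    grid: BrainGrid,
    fwhm_mm: float = DEFAULT_FWHM_MM,
    n_perm: int = 50,
    seed: Optional[int] = None,
) -> MetaResult:
    """Pool study maps and standardise against a peak-relocation null.

    For each of ``n_perm`` permutations every study's peaks are relocated to
    uniformly random in-mask voxels (peak count and g values preserved), maps
    are re-reconstructed and re-pooled; sdm_z = (mu - mean_null) / sd_null and
    the voxel p-values are mid-p tail proportions (ties counted half), so the
    degenerate all-zero problem yields z = 0 and p = 0.5.
    """
    datasets = list(studies)
    if len(datasets) < 2:
        raise DomainError("need at least two studies to meta-analyse")
    if n_perm < 20:
        raise DomainError(f"n_perm={n_perm} too small; the empirical null needs >= 20")
    rng = np.random.default_rng(seed)
    V = grid.n_voxels
    coords = grid.coords_mm
    k = len(datasets)

    effects = np.empty((k, V))
    variances = np.empty((k, V))
    peak_g: list[np.ndarray] = []
    sizes: list[tuple[int, int]] = []
    for i, d in enumerate(datasets):
        em, vm = reconstruct_study_maps(d, grid, fwhm_mm=fwhm_mm)
        effects[i] = em.values
        variances[i] = vm.values
        peak_g.append(_peak_effects(d))
        sizes.append((d.n_patients, d.n_controls))

    mu, se, tau2 = random_effects_voxel(effects, variances)

    null_mu = np.empty((n_perm, V))
    pe = np.empty((k, V))
    pv = np.empty((k, V))
    for b in range(n_perm):
        for i in range(k):
            gvals = peak_g[i]
            if len(gvals) == 0:
                pe[i] = 0.0
                pv[i] = variances[i]
                continue
            idx = rng.integers(0, V, size=len(gvals))
            e, v = reconstruct_from_points(coords[idx], gvals, grid, *sizes[i], fwhm_mm=fwhm_mm)
            pe[i], pv[i] = e, v
        null_mu[b] = _pool(pe, pv)

    null_mean = null_mu.mean(axis=0)
    null_sd = null_mu.std(axis=0)
    sdm_z = np.zeros(V)
    ok = null_sd > 0
    sdm_z[ok] = (mu[ok] - null_mean[ok]) / null_sd[ok]

    greater = (null_mu > mu[None, :]).sum(axis=0)
    ties = (null_mu == mu[None, :]).sum(axis=0)
    p_inc = (greater + 0.5 * ties) / n_perm
    less = (null_mu < mu[None, :]).sum(axis=0)
    p_dec = (less + 0.5 * ties) / n_perm

    return MetaResult(
        grid=grid,
        study_ids=[d.study_id for d in datasets],
        effects=effects,
        variances=variances,
        pooled_effect=mu,
        se=se,
        tau2=tau2,
        sdm_z=sdm_z,
        p_increase=p_inc,
        p_decrease=p_dec,
        n_perm=n_perm,
        seed=seed,
    )


_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


def threshold_clusters(
    result: MetaResult,
    p_thresh: float = 0.005,
    z_thresh: float = 1.0,
    min_extent: int = 10,
) -> list[Cluster]:
    """Extract supra-threshold clusters (voxel p < p_thresh, peak |Z| >
    z_thresh, extent strictly > min_extent voxels), split by effect sign.

    Connectivity is 26-neighbourhood; each cluster reports its peak voxel
    (maximum |sdm_z|) in MNI mm and the peak voxel's p-value.
    """
    grid = result.grid
    clusters: list[Cluster] = []
    flat_index = np.full(grid.shape, -1, dtype=int)
    flat_index[grid.mask] = np.arange(grid.n_voxels)

    for sign, pvals, zsign in (
        ("increase", result.p_increase, 1.0),
        ("decrease", result.p_decrease, -1.0),
    ):
        cand = (pvals < p_thresh) & (np.sign(result.pooled_effect) == zsign)
        vol = np.zeros(grid.shape, dtype=bool)
        vol[grid.mask] = cand
        labels, n = ndimage.label(vol, structure=_STRUCT_26)
        for lab in range(1, n + 1):
            members = flat_index[labels == lab]
            members = np.sort(members)
            if members.size <= min_extent:
                continue
            zvals = result.sdm_z[members]
            j = int(np.argmax(np.abs(zvals)))
            if abs(zvals[j]) <= z_thresh:
                continue
            peak_flat = members[j]
            xyz = tuple(float(c) for c in grid.coords_mm[peak_flat])
            clusters.append(
                Cluster(
                    peak_xyz=xyz,
                    size_voxels=int(members.size),
                    peak_sdm_z=float(zvals[j]),
                    p=float(pvals[peak_flat]),
                    member_voxels=members,
                    sign=sign,
                )
            )
    clusters.sort(key=lambda c: (c.sign, -abs(c.peak_sdm_z)))
    return clusters


def clusters_to_table(clusters: list[Cluster]) -> pd.DataFrame:
    """Cluster table in the layout of a published meta-analysis results table."""
    return pd.DataFrame([c.as_row() for c in clusters])
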