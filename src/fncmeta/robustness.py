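"""Validation analyses around the pooled meta-analysis.

Four families of checks: (1) per-cluster heterogeneity (Cochran's Q) and
publication bias (Egger regression + funnel data); (2) leave-one-out
jackknife stability; (3) subgroup meta-analyses gated on > 10 datasets;
(4) voxel-wise meta-regression of study effects on study-level covariates,
restricted to the main-analysis clusters at a stringent p < 0.0005.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import ndimage, stats

from .exceptions import DomainError, StageRefusal
from .grid import BrainGrid
from .meta import Cluster, MetaResult, sdm_z_map, threshold_clusters, _STRUCT_26
from .study_io import StudyDataset, StudyTable

log = logging.getLogger(__name__)

__all__ = [
    "ClusterDiagnostics",
    "JackknifeResult",
    "MetaRegressionResult",
    "cochran_q",
    "egger_test",
    "cluster_diagnostics",
    "jackknife",
    "subgroup_meta",
    "meta_regression",
    "COVARIATE_GETTERS",
]


@dataclass
class ClusterDiagnostics:
    cluster_id: int
    Q: float
    Q_df: int
    Q_p: float
    egger_intercept: float
    egger_p: float
    funnel_points: list[tuple[float, float]]  # (effect, se) per study


@dataclass
class JackknifeResult:
    probability_map: np.ndarray  # (V,) fraction of leave-one-out reruns significant
    stable_mask: np.ndarray      # (V,) bool, probability >= threshold
    threshold: float
    study_ids: list[str]
    per_iteration_masks: np.ndarray = field(repr=False)  # (k, V) bool


@dataclass
class MetaRegressionResult:
    covariate: str
    used_study_ids: list[str]
    slope_map: np.ndarray    # (V,) NaN outside main-analysis clusters
    p_map: np.ndarray        # (V,) permutation p (two-sided), NaN outside clusters
    significant_clusters: list[Cluster]
    p_thresh: float


def cochran_q(effects: Sequence[float], variances: Sequence[float]):
    """Cochran's Q heterogeneity statistic with its chi-square p-value.

    Q = sum (1/var) (g - g_fix)^2, chi-square with k-1 df under homogeneity.
    """
    g = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if g.ndim != 1 or g.shape != v.shape or len(g) < 2:
        raise DomainError("need >= 2 aligned effects/variances")
    if np.any(v <= 0):
        raise DomainError("variances must be positive")
    w = 1.0 / v
    g_fix = (w * g).sum() / w.sum()
    Q = float((w * (g - g_fix) ** 2).sum())
    df = len(g) - 1
    p = float(stats.chi2.sf(Q, df))
    return Q, df, p


def egger_test(effects: Sequence[float], ses: Sequence[float]):
    """Egger's regression asymmetry test for small-study / publication bias.

    Regresses the standardised effect (g / se) on precision (1 / se); the
    intercept's t-test (k - 2 df) indicates funnel-plot asymmetry. Returns
    (intercept, intercept_p, funnel_points) with funnel points as (g, se).
    """
    g = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    if len(g) < 3:
        raise DomainError("Egger's test needs at least 3 studies")
    if np.any(se <= 0):
        raise DomainError("standard errors must be positive")
    y = g / se
    x = 1.0 / se
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept = float(model.params[0])
    p = float(model.pvalues[0])
    return intercept, p, list(zip(g.tolist(), se.tolist()))


def cluster_effects(result: MetaResult, cluster: Cluster, aggregation: str = "mean"):
    """Per-study effect and variance for one cluster.

    ``mean``: average the reconstructed g (and variance) over member voxels;
    ``peak``: take the cluster's peak voxel.
    """
    if aggregation == "mean":
        g = result.effects[:, cluster.member_voxels].mean(axis=1)
        v = result.variances[:, cluster.member_voxels].mean(axis=1)
    elif aggregation == "peak":
        zvals = result.sdm_z[cluster.member_voxels]
        peak = cluster.member_voxels[int(np.argmax(np.abs(zvals)))]
        g = result.effects[:, peak]
        v = result.variances[:, peak]
    else:
        raise DomainError("aggregation must be 'mean' or 'peak'")
    return g, v


def cluster_diagnostics(
    result: MetaResult,
    clusters: list[Cluster],
    aggregation: str = "mean",
) -> list[ClusterDiagnostics]:
    """Q and Egger diagnostics for every main-analysis cluster."""
    out = []
    for i, c in enumerate(clusters):
        g, v = cluster_effects(result, c, aggregation)
        Q, df, Qp = cochran_q(g, v)
        se = np.sqrt(v)
        intercept, ep, funnel = egger_test(g, se)
        out.append(ClusterDiagnostics(i, Q, df, Qp, intercept, ep, funnel))
    return out


def stability_from_masks(masks: np.ndarray, threshold: float = 0.8):
    """Replication probability per voxel and the stable mask (prob >= threshold)."""
    masks = np.asarray(masks, dtype=bool)
    prob = masks.mean(axis=0)
    return prob, prob >= threshold


def jackknife(
    studies: StudyTable | list[StudyDataset],
    grid: BrainGrid,
    threshold: float = 0.8,
    n_perm: int = 50,
    seed: Optional[int] = None,
    **cluster_kwargs,
) -> JackknifeResult:
    """Leave-one-out sensitivity: rerun the full engine k times.

    Each rerun drops one dataset; a voxel's probability is the fraction of
    reruns in which it belonged to a significant cluster. Voxels at or above
    the stability threshold (80 % by default) form the stable mask.
    """
    datasets = list(studies)
    if len(datasets) < 3:
        raise DomainError("jackknife needs at least 3 datasets")
    k = len(datasets)
    V = grid.n_voxels
    masks = np.zeros((k, V), dtype=bool)
    for i in range(k):
        subset = datasets[:i] + datasets[i + 1:]
        res = sdm_z_map(subset, grid, n_perm=n_perm, seed=seed)
        for c in threshold_clusters(res, **cluster_kwargs):
            masks[i, c.member_voxels] = True
    prob, stable = stability_from_masks(masks, threshold)
    return JackknifeResult(
        probability_map=prob,
        stable_mask=stable,
        threshold=threshold,
        study_ids=[d.study_id for d in datasets],
        per_iteration_masks=masks,
    )


def subgroup_meta(
    studies: StudyTable | list[StudyDataset],
    predicate: Callable[[StudyDataset], bool],
    grid: BrainGrid,
    min_datasets: int = 10,
    label: str = "subgroup",
    **engine_kwargs,
) -> MetaResult:
    """Full engine rerun on the datasets selected by ``predicate``.

    Refuses (``StageRefusal``) unless strictly more than ``min_datasets``
    datasets are selected — subgroup results on tiny rosters are unstable.
    """
    datasets = [d for d in studies if predicate(d)]
    if len(datasets) <= min_datasets:
        raise StageRefusal(
            f"subgroup {label!r} selects only {len(datasets)} datasets "
            f"(> {min_datasets} required)"
        )
    result = sdm_z_map(datasets, grid, **engine_kwargs)
    log.info("subgroup %s: %d datasets analysed", label, len(datasets))
    return result


COVARIATE_GETTERS: dict[str, Callable[[StudyDataset], Optional[float]]] = {
    "mean_age_pat": lambda d: d.mean_age_pat,
    "pct_male_patients": lambda d: d.pct_male_patients,
    "panss_total": lambda d: d.panss_total,
    "panss_pos": lambda d: d.panss_pos,
    "panss_neg": lambda d: d.panss_neg,
    "illness_duration": lambda d: d.illness_duration,
    "smoothing_fwhm_mm": lambda d: d.smoothing_fwhm_mm,
    "corr_threshold": lambda d: d.corr_threshold,
}


def meta_regression(
    result: MetaResult,
    studies: StudyTable | list[StudyDataset],
    covariate: str | Sequence[float],
    main_clusters: list[Cluster],
    p_thresh: float = 0.0005,
    n_perm: int = 2000,
    min_studies: int = 9,
    method: str = "permutation",
    seed: Optional[int] = None,
    min_extent: int = 10,
) -> MetaRegressionResult:
    """Weighted meta-regression of study effects on a study-level covariate.

    Restricted to the union of main-analysis cluster voxels (regions outside
    the main findings are excluded). Per voxel, a random-effects-weighted
    least-squares slope of g on the centred covariate is computed; its p-value
    comes from permuting the covariate across studies (default) or from the
    parametric t-test (``method="parametric"``). Components of voxels with
    p < 0.0005 (26-connectivity, extent > ``min_extent``) are reported.
    """
    datasets = list(studies)
    if not main_clusters:
        raise DomainError("main_clusters must be non-empty")
    name = covariate if isinstance(covariate, str) else "custom"
    if isinstance(covariate, str):
        getter = COVARIATE_GETTERS.get(covariate)
        if getter is None:
            raise DomainError(f"unknown covariate {covariate!r}; choose from {sorted(COVARIATE_GETTERS)}")
        raw = [getter(d) for d in datasets]
    else:
        raw = list(covariate)
        if len(raw) != len(datasets):
            raise DomainError("covariate vector must align with datasets")
    keep = [i for i, v in enumerate(raw) if v is not None and np.isfinite(v)]
    dropped = [datasets[i].study_id for i in range(len(datasets)) if i not in keep]
    if dropped:
        log.info("meta-regression %s: dropping %d datasets without the covariate: %s",
                 name, len(dropped), dropped)
    if len(keep) < min_studies:
        raise StageRefusal(
            f"covariate {name!r} available for only {len(keep)} datasets (>= {min_studies} required)"
        )
    c = np.asarray([raw[i] for i in keep], dtype=float)
    if np.ptp(c) == 0:
        raise DomainError(f"covariate {name!r} is constant across studies")
    c = c - c.mean()

    order = np.asarray(keep)
    voxels = np.unique(np.concatenate([cl.member_voxels for cl in main_clusters]))
    G = result.effects[order][:, voxels]                      # (k, Vc)
    W = 1.0 / (result.variances[order][:, voxels] + result.tau2[voxels][None, :])

    def slopes(cov: np.ndarray) -> np.ndarray:
        # weighted least squares slope per voxel, centred covariate per-voxel weights
        sw = W.sum(axis=0)
        cbar = (W * cov[:, None]).sum(axis=0) / sw
        gbar = (W * G).sum(axis=0) / sw
        cc = cov[:, None] - cbar[None, :]
        num = (W * cc * (G - gbar[None, :])).sum(axis=0)
        den = (W * cc**2).sum(axis=0)
        return num / np.where(den == 0, np.nan, den)

    beta = slopes(c)
    rng = np.random.default_rng(seed)
    if method == "permutation":
        if n_perm < 100:
            raise DomainError("permutation meta-regression needs n_perm >= 100")
        exceed = np.zeros(voxels.shape[0])
        for _ in range(n_perm):
            b0 = slopes(rng.permutation(c))
            exceed += np.abs(b0) >= np.abs(beta)
        pvox = (exceed + 1.0) / (n_perm + 1.0)
    elif method == "parametric":
        k = len(c)
        sw = W.sum(axis=0)
        cbar = (W * c[:, None]).sum(axis=0) / sw
        cc = c[:, None] - cbar[None, :]
        se_beta = 1.0 / np.sqrt((W * cc**2).sum(axis=0))
        tstat = beta / se_beta
        pvox = 2.0 * stats.t.sf(np.abs(tstat), k - 2)
    else:
        raise DomainError("method must be 'permutation' or 'parametric'")

    V = result.grid.n_voxels
    slope_map = np.full(V, np.nan)
    p_map = np.full(V, np.nan)
    slope_map[voxels] = beta
    p_map[voxels] = pvox

    # significant components within the main-analysis clusters
    grid = result.grid
    flat_index = np.full(grid.shape, -1, dtype=int)
    flat_index[grid.mask] = np.arange(V)
    sig = np.zeros(grid.shape, dtype=bool)
    sel = voxels[pvox < p_thresh]
    vol_idx = np.nonzero(grid.mask)
    coords = tuple(a[sel] for a in vol_idx)
    sig[coords] = True
    labels, n = ndimage.label(sig, structure=_STRUCT_26)
    sig_clusters: list[Cluster] = []
    for lab in range(1, n + 1):
        members = np.sort(flat_index[labels == lab])
        if members.size <= min_extent:
            continue
        zvals = result.sdm_z[members]
        j = int(np.argmax(np.abs(zvals)))
        sig_clusters.append(
            Cluster(
                peak_xyz=tuple(float(x) for x in grid.coords_mm[members[j]]),
                size_voxels=int(members.size),
                peak_sdm_z=float(zvals[j]),
                p=float(p_map[members[j]]),
                member_voxels=members,
                sign="increase" if result.pooled_effect[members[j]] >= 0 else "decrease",
            )
        )
    return MetaRegressionResult(
        covariate=name,
        used_study_ids=[datasets[i].study_id for i in keep],
        slope_map=slope_map,
        p_map=p_map,
        significant_clusters=sig_clusters,
        p_thresh=p_thresh,
    )
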