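"""PLS regression of a brain map on gene expression, with spatial nulls.

The association between the case-control statistic map (sampled at
expression-sample locations) and the genes is modelled by univariate-response
partial least squares (PLS1), fit by deterministic NIPALS with deflation.
Component significance is assessed against surrogate response vectors that
preserve the empirical variogram — and hence the spatial autocorrelation —
of the real map (the BrainSMASH construction: permute, kernel-smooth over a
bandwidth grid, affinely rescale the variogram to match, keep the best fit).
Gene contributions are bootstrap-normalised weights (Z = weight / SE) with
Bonferroni selection into PLS+ / PLS- sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .exceptions import DomainError

log = logging.getLogger(__name__)

__all__ = [
    "PLSModel",
    "SurrogateEnsemble",
    "GeneWeightTable",
    "fit_pls",
    "variogram_surrogates",
    "component_significance",
    "bootstrap_gene_weights",
    "empirical_variogram",
]


@dataclass
class PLSModel:
    weights: np.ndarray            # (G, C) component-defining gene weights (unit norm)
    scores: np.ndarray             # (S, C) sample scores (deflated-X scores)
    loadings_x: np.ndarray         # (G, C) X loadings from deflation
    y_loadings: np.ndarray         # (C,) regression of y on each score
    explained_variance: np.ndarray  # (C,) fraction of var(y) per component
    score_y_correlation: np.ndarray  # (C,) Pearson r between score and y
    gene_names: Optional[list[str]] = None
    selected_component: Optional[int] = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


@dataclass
class SurrogateEnsemble:
    surrogates: np.ndarray  # (n, S)
    seed: Optional[int]
    bandwidths: np.ndarray  # chosen kernel bandwidth per surrogate (mm)
    variogram_sse: np.ndarray  # fit SSE per surrogate
    permutation_sse: np.ndarray  # SSE of the unsmoothed permutation (baseline)

    @property
    def n_surrogates(self) -> int:
        return self.surrogates.shape[0]


@dataclass
class GeneWeightTable:
    table: pd.DataFrame  # gene, weight, se, z, p, significant, gene_set
    component: int
    n_bootstrap: int
    alpha: float = 0.05

    @property
    def pls_plus(self) -> list[str]:
        t = self.table
        return list(t.loc[t.significant & (t.z > 0), "gene"])

    @property
    def pls_minus(self) -> list[str]:
        t = self.table
        return list(t.loc[t.significant & (t.z < 0), "gene"])


def _as_xy(X, y):
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != yv.shape[0]:
        raise DomainError(f"X has {Xv.shape[0]} rows but y has {yv.shape[0]}")
    genes = list(X.columns) if isinstance(X, pd.DataFrame) else None
    return Xv, yv, genes


def fit_pls(X, y, n_components: int = 5) -> PLSModel:
    """Univariate-response PLS (PLS1) by NIPALS with deflation.

    For a single response the NIPALS weight step is closed-form per
    component: w_c = X_c' y_c / ||X_c' y_c||, t_c = X_c w_c, followed by
    rank-one deflation of X and y. Deterministic: no random initialisation.
    The explained-variance fractions partition var(y) across components.
    """
    Xv, yv, genes = _as_xy(X, y)
    S, G = Xv.shape
    cmax = min(S - 1, G)
    if n_components > cmax:
        raise DomainError(f"n_components={n_components} exceeds min(samples-1, genes)={cmax}")
    Xc = Xv.copy()
    yc = yv.copy()
    ss_y = float(yv @ yv)
    if ss_y == 0:
        raise DomainError("response vector has zero variance")
    W = np.empty((G, n_components))
    T = np.empty((S, n_components))
    P = np.empty((G, n_components))
    q = np.empty(n_components)
    evar = np.empty(n_components)
    r_ty = np.empty(n_components)
    for c in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            # residual X orthogonal to residual y: nothing left to extract
            W[:, c:] = 0.0
            T[:, c:] = 0.0
            P[:, c:] = 0.0
            q[c:] = 0.0
            evar[c:] = 0.0
            r_ty[c:] = 0.0
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        p = Xc.T @ t / tt
        qc = float(yc @ t) / tt
        Xc -= np.outer(t, p)
        yc -= qc * t
        W[:, c] = w
        T[:, c] = t
        P[:, c] = p
        q[c] = qc
        evar[c] = qc**2 * tt / ss_y
        sd_t = t.std()
        r_ty[c] = float(np.corrcoef(t, yv)[0, 1]) if sd_t > 0 else 0.0
    return PLSModel(
        weights=W,
        scores=T,
        loadings_x=P,
        y_loadings=q,
        explained_variance=evar,
        score_y_correlation=r_ty,
        gene_names=genes,
    )


# ----------------------------------------------------------------------
# variogram-matched surrogates
# ----------------------------------------------------------------------

def empirical_variogram(y: np.ndarray, dist: np.ndarray, bins: np.ndarray):
    """Binned semivariogram: gamma(h) = mean of (y_i - y_j)^2 / 2 per lag bin.

    ``dist`` is the condensed pairwise-distance vector (pdist order); bins are
    right edges. Returns (bin centers, gamma) over non-empty bins.
    """
    dy2 = pdist(y[:, None], metric="sqeuclidean") / 2.0
    idx = np.digitize(dist, bins)
    nb = len(bins)
    gamma = np.full(nb, np.nan)
    for b in range(nb):
        sel = idx == b
        if sel.any():
            gamma[b] = dy2[sel].mean()
    centers = np.concatenate([[bins[0] / 2.0], (bins[:-1] + bins[1:]) / 2.0])
    ok = ~np.isnan(gamma)
    return centers[ok], gamma[ok], idx, dy2


def _binned_gamma(dy2: np.ndarray, idx: np.ndarray, nb: int) -> np.ndarray:
    gamma = np.full(nb, np.nan)
    for b in range(nb):
        sel = idx == b
        if sel.any():
            gamma[b] = dy2[sel].mean()
    return gamma


def variogram_surrogates(
    y: np.ndarray,
    sample_coords: np.ndarray,
    n: int = 1000,
    seed: Optional[int] = None,
    n_bins: int = 25,
    bandwidth_fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.7, 0.9),
    max_lag_fraction: float = 0.5,
) -> SurrogateEnsemble:
    """Spatial-autocorrelation-preserving surrogate response vectors.

    Each surrogate: (i) randomly permute y; (ii) Gaussian-kernel smooth the
    permutation over the sample graph at each candidate bandwidth (fractions
    of the maximum pairwise distance); (iii) solve the variogram regression
    gamma_emp(h) ~ alpha * gamma_smooth(h) + beta and form
    sqrt(|alpha|) * smooth + sqrt(max(beta, 0)) * white noise; keep the
    bandwidth with the smallest variogram SSE. Deterministic under ``seed``.
    """
    y = np.asarray(y, dtype=float).ravel()
    S = len(y)
    if S < 10:
        raise DomainError("variogram estimation needs at least 10 samples")
    xyz = np.asarray(sample_coords, dtype=float)
    if xyz.shape != (S, 3):
        raise DomainError("sample_coords must be (S, 3) mm")
    rng = np.random.default_rng(seed)

    dist = pdist(xyz)
    dmax = dist.max()
    bins = np.linspace(0, max_lag_fraction * dmax, n_bins + 1)[1:]
    idx = np.digitize(dist, bins)
    inrange = idx < n_bins
    dy2 = pdist(y[:, None], metric="sqeuclidean") / 2.0
    gamma_emp = _binned_gamma(dy2[inrange], idx[inrange], n_bins)
    ok = ~np.isnan(gamma_emp)
    gamma_emp = gamma_emp[ok]

    D = squareform(dist)
    kernels = []
    for f in bandwidth_fractions:
        bw = f * dmax
        K = np.exp(-(D**2) / (2.0 * bw**2))
        K /= K.sum(axis=1, keepdims=True)
        kernels.append((bw, K))

    surrogates = np.empty((n, S))
    chosen_bw = np.empty(n)
    sse = np.empty(n)
    perm_sse = np.empty(n)
    for i in range(n):
        xp = rng.permutation(y)
        gp = _binned_gamma(pdist(xp[:, None], metric="sqeuclidean")[inrange] / 2.0,
                           idx[inrange], n_bins)[ok]
        perm_sse[i] = float(((gp - gamma_emp) ** 2).sum())
        noise = rng.standard_normal(S)
        best = None
        for bw, K in kernels:
            xs = K @ xp
            gs = _binned_gamma(pdist(xs[:, None], metric="sqeuclidean")[inrange] / 2.0,
                               idx[inrange], n_bins)[ok]
            # regress gamma_emp on gamma_smooth: alpha scales, beta is a nugget
            A = np.column_stack([gs, np.ones_like(gs)])
            (alpha, beta), *_ = np.linalg.lstsq(A, gamma_emp, rcond=None)
            cand = np.sqrt(abs(alpha)) * xs + np.sqrt(max(beta, 0.0)) * noise
            gc = _binned_gamma(pdist(cand[:, None], metric="sqeuclidean")[inrange] / 2.0,
                               idx[inrange], n_bins)[ok]
            err = float(((gc - gamma_emp) ** 2).sum())
            if best is None or err < best[0]:
                best = (err, bw, cand)
        sse[i], chosen_bw[i], surrogates[i] = best
    return SurrogateEnsemble(
        surrogates=surrogates,
        seed=seed,
        bandwidths=chosen_bw,
        variogram_sse=sse,
        permutation_sse=perm_sse,
    )


def component_significance(
    model: PLSModel,
    ensemble: SurrogateEnsemble,
    X,
    alpha: float = 0.05,
    plus_one: bool = False,
) -> np.ndarray:
    """Per-component p-values from the surrogate null and component selection.

    For each surrogate response, PLS is refit and the explained variance of
    the same-index component recorded; p_c is the proportion of null values
    >= the real one (``plus_one`` switches to the (count+1)/(n+1) estimator).
    Marks the selected component on ``model``: lowest p among those with
    p < alpha, ties broken by larger explained variance; its score is
    sign-fixed to correlate positively with y.
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    C = model.n_components
    n = ensemble.n_surrogates
    null_ev = np.empty((n, C))
    for i, ys in enumerate(ensemble.surrogates):
        ys = ys - ys.mean()
        s = ys.std()
        if s > 0:
            ys = ys / s
        null_ev[i] = fit_pls(Xv, ys, n_components=C).explained_variance
    count = (null_ev >= model.explained_variance[None, :]).sum(axis=0)
    p = (count + 1.0) / (n + 1.0) if plus_one else count / n

    sig = np.nonzero(p < alpha)[0]
    if sig.size:
        best = sig[np.lexsort((-model.explained_variance[sig], p[sig]))][0]
        model.selected_component = int(best)
        if model.score_y_correlation[best] < 0:
            # fix sign convention: score correlates positively with y
            model.weights[:, best] *= -1.0
            model.scores[:, best] *= -1.0
            model.loadings_x[:, best] *= -1.0
            model.y_loadings[best] *= -1.0
            model.score_y_correlation[best] *= -1.0
    else:
        model.selected_component = None
    return p


def bootstrap_gene_weights(
    X,
    y,
    component_index: int,
    B: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> GeneWeightTable:
    """Bootstrap-normalised gene weights on one PLS component.

    Rows are resampled with replacement B times; each refit component is
    sign-aligned to the original (flip when its score correlates negatively
    with the original score over the resampled rows). SE = sd of aligned
    weights, Z = weight/SE, two-sided normal p, Bonferroni at alpha/G;
    significant genes split into PLS+ (Z > 0) and PLS- (Z < 0).
    """
    Xv, yv, genes = _as_xy(X, y)
    S, G = Xv.shape
    base = fit_pls(Xv, yv, n_components=component_index + 1)
    if not (0 <= component_index < base.n_components):
        raise DomainError(f"component index {component_index} out of range")
    if B < 100:
        log.warning("bootstrap_gene_weights: B=%d is small; SEs will be unstable", B)
    w0 = base.weights[:, component_index]
    t0 = base.scores[:, component_index]
    rng = np.random.default_rng(seed)
    boots = np.empty((B, G))
    for b in range(B):
        rows = rng.integers(0, S, size=S)
        mb = fit_pls(Xv[rows], yv[rows], n_components=component_index + 1)
        wb = mb.weights[:, component_index]
        tb = mb.scores[:, component_index]
        # align sign against the original component on the resampled rows
        ref = t0[rows]
        flip = np.sign(np.dot(tb - tb.mean(), ref - ref.mean()))
        if flip == 0:
            flip = np.sign(np.dot(wb, w0)) or 1.0
        boots[b] = flip * wb
    se = boots.std(axis=0, ddof=1)
    se = np.where(se == 0, np.nan, se)
    z = w0 / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    cutoff = alpha / G
    significant = p < cutoff
    gene_names = genes if genes is not None else [f"g{i}" for i in range(G)]
    gene_set = np.where(~significant, "none", np.where(z > 0, "PLS+", "PLS-"))
    table = pd.DataFrame(
        {
            "gene": gene_names,
            "weight": w0,
            "se": se,
            "z": z,
            "p": p,
            "significant": significant,
            "gene_set": gene_set,
        }
    ).sort_values("z", ascending=False, ignore_index=True)
    return GeneWeightTable(table=table, component=component_index, n_bootstrap=B, alpha=alpha)
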