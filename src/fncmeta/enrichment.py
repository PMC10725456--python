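"""Gene-category and cell-type enrichment of PLS gene results.

Two complementary analyses of the genes tracking the case-control map:

* GCEA — category scores are mean member-gene loadings (loading = Pearson
  correlation between the PLS score and the gene's expression profile),
  tested against an ensemble null built from spatial-autocorrelation-
  preserving permutations of the response map (PLS refit per permutation,
  null loadings and null category scores recomputed). This guards against
  the inflated significance that gene-label permutation gives on spatially
  smooth phenotypes.

* CSEA — Fisher's exact overlap of the PLS+ / PLS- gene sets with nested
  cell-type marker lists defined by a specificity-index probability (pSI)
  at tiers 0.05, 0.01, 1e-3 and 1e-4, BH-FDR corrected across all
  (cell type x tier) tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError
from .pls import PLSModel, SurrogateEnsemble, fit_pls, variogram_surrogates

log = logging.getLogger(__name__)

__all__ = [
    "CategoryAnnotation",
    "CategoryResult",
    "CellTypeResult",
    "gene_loadings",
    "gcea",
    "compute_psi",
    "psi_marker_lists",
    "csea_fisher",
    "read_gmt",
    "write_gmt",
]

PSI_TIERS = (0.05, 0.01, 1e-3, 1e-4)


@dataclass
class CategoryAnnotation:
    category_id: str
    name: str
    members: list[str]
    source: str = "gmt"


@dataclass
class CategoryResult:
    category_id: str
    name: str
    size: int
    score: float          # mean member loading
    null_mean: float
    null_sd: float
    p: float              # one-sided ensemble proportion


@dataclass
class CellTypeResult:
    cell_type: str
    psi_threshold: float
    overlap: int
    set_size: int
    list_size: int
    odds_ratio: float
    p: float
    q: float = float("nan")


# ----------------------------------------------------------------------
# GMT I/O
# ----------------------------------------------------------------------

def read_gmt(path) -> list[CategoryAnnotation]:
    """Read gene sets from a GMT file (id, description, members...)."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out.append(CategoryAnnotation(
                category_id=parts[0],
                name=parts[1] or parts[0],
                members=[g for g in parts[2:] if g],
            ))
    return out


def write_gmt(annotations: Sequence[CategoryAnnotation], path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write("\t".join([a.category_id, a.name, *a.members]) + "\n")


def load_go_annotations(obo_path, gaf_path, namespace: Optional[str] = None,
                        propagate: bool = True) -> list[CategoryAnnotation]:
    """GO-format inputs: OBO hierarchy + GAF gene associations.

    Annotations are propagated up the is_a graph (a gene annotated to a term
    is implicitly annotated to all its ancestors) unless ``propagate=False``.
    """
    import obonet  # optional input path; only needed for GO-format files
    import networkx as nx

    graph = obonet.read_obo(obo_path)
    gaf = pd.read_csv(
        gaf_path, sep="\t", comment="!", header=None, dtype=str, usecols=[2, 4],
        names=["gene", "go_id"],
    ).dropna()
    term2genes: dict[str, set[str]] = {}
    for gene, go_id in gaf.itertuples(index=False):
        term2genes.setdefault(go_id, set()).add(gene)
    if propagate:
        # obonet edges point child -> parent, so descendants() walks upward
        for go_id in list(term2genes):
            if go_id in graph:
                for anc in nx.descendants(graph, go_id):
                    term2genes.setdefault(anc, set()).update(term2genes[go_id])
    out = []
    for go_id, genes in term2genes.items():
        data = graph.nodes.get(go_id, {})
        if namespace and data.get("namespace") != namespace:
            continue
        out.append(CategoryAnnotation(
            category_id=go_id,
            name=data.get("name", go_id),
            members=sorted(genes),
            source="go",
        ))
    return out


# ----------------------------------------------------------------------
# loadings and GCEA
# ----------------------------------------------------------------------

def gene_loadings(X, pls_scores: np.ndarray) -> pd.Series:
    """Per-gene loading: Pearson correlation of expression with the score.

    Zero-variance genes have undefined loadings and are excluded (logged).
    """
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    genes = list(X.columns) if isinstance(X, pd.DataFrame) else [f"g{i}" for i in range(Xv.shape[1])]
    s = np.asarray(pls_scores, dtype=float).ravel()
    if Xv.shape[0] != s.shape[0]:
        raise DomainError("scores must align with expression rows")
    sc = s - s.mean()
    ssd = np.sqrt((sc**2).sum())
    if ssd == 0:
        raise DomainError("score vector is constant")
    Xc = Xv - Xv.mean(axis=0)
    xsd = np.sqrt((Xc**2).sum(axis=0))
    ok = xsd > 0
    if not ok.all():
        log.warning("gene_loadings: excluding %d zero-variance gene(s)", int((~ok).sum()))
    r = np.full(Xv.shape[1], np.nan)
    r[ok] = (Xc[:, ok] * sc[:, None]).sum(axis=0) / (xsd[ok] * ssd)
    return pd.Series(r, index=pd.Index(genes, name="gene")).dropna()


def _category_scores(loadings: pd.Series, annotations: Sequence[CategoryAnnotation]) -> np.ndarray:
    idx = {g: i for i, g in enumerate(loadings.index)}
    vals = loadings.to_numpy()
    out = np.empty(len(annotations))
    for j, a in enumerate(annotations):
        rows = [idx[g] for g in a.members]
        out[j] = vals[rows].mean()
    return out


def gcea(
    y: np.ndarray,
    X,
    annotations: Sequence[CategoryAnnotation],
    sample_coords: Optional[np.ndarray] = None,
    ensemble: Optional[SurrogateEnsemble] = None,
    component_index: int = 0,
    direction: str = "plus",
    n_perm: int = 1000,
    seed: Optional[int] = None,
    min_size: int = 10,
    max_size: int = 200,
) -> list[CategoryResult]:
    """Gene-category enrichment against a spatial-ensemble null.

    Real scores come from the real component's loadings; each of ``n_perm``
    SA-preserving surrogates of y is refit with PLS and yields null loadings
    and null category scores. p = proportion of null scores >= real, one-
    sided. ``direction="minus"`` negates loadings so enrichment means
    strongly negative loading (the PLS- context). Categories are intersected
    with the expression gene universe and size-filtered first.
    """
    if direction not in ("plus", "minus"):
        raise DomainError("direction must be 'plus' or 'minus'")
    genes = set(X.columns) if isinstance(X, pd.DataFrame) else {f"g{i}" for i in range(np.asarray(X).shape[1])}
    kept: list[CategoryAnnotation] = []
    for a in annotations:
        members = sorted(set(a.members) & genes)
        if not (min_size <= len(members) <= max_size):
            log.info("gcea: skipping category %s (size %d outside [%d, %d])",
                     a.category_id, len(members), min_size, max_size)
            continue
        kept.append(CategoryAnnotation(a.category_id, a.name, members, a.source))
    if not kept:
        return []

    y = np.asarray(y, dtype=float).ravel()
    if ensemble is None:
        if sample_coords is None:
            raise DomainError("provide sample_coords or a prebuilt surrogate ensemble")
        ensemble = variogram_surrogates(y, sample_coords, n=n_perm, seed=seed)
    nperm = ensemble.n_surrogates

    sgn = 1.0 if direction == "plus" else -1.0
    model = fit_pls(X, y, n_components=component_index + 1)
    if model.score_y_correlation[component_index] < 0:
        model.scores[:, component_index] *= -1.0
    real_load = sgn * gene_loadings(X, model.scores[:, component_index])
    real_scores = _category_scores(real_load, kept)

    null_scores = np.empty((nperm, len(kept)))
    for i, ys in enumerate(ensemble.surrogates):
        s = ys.std()
        ysz = (ys - ys.mean()) / s if s > 0 else ys - ys.mean()
        m = fit_pls(X, ysz, n_components=component_index + 1)
        score = m.scores[:, component_index]
        if m.score_y_correlation[component_index] < 0:
            score = -score
        null_load = sgn * gene_loadings(X, score)
        null_scores[i] = _category_scores(null_load, kept)

    count = (null_scores >= real_scores[None, :]).sum(axis=0)
    pvals = count / nperm
    return [
        CategoryResult(
            category_id=a.category_id,
            name=a.name,
            size=len(a.members),
            score=float(real_scores[j]),
            null_mean=float(null_scores[:, j].mean()),
            null_sd=float(null_scores[:, j].std()),
            p=float(pvals[j]),
        )
        for j, a in enumerate(kept)
    ]


# ----------------------------------------------------------------------
# cell-type specificity (pSI) and CSEA
# ----------------------------------------------------------------------

def _irwin_hall_cdf(x: np.ndarray, m: int) -> np.ndarray:
    """CDF of a sum of m iid Uniform(0, 1) variables (Irwin-Hall).

    P(S <= x) = (1/m!) * sum_{k=0}^{floor(x)} (-1)^k C(m, k) (x - k)^m.
    Stable for the small m (number of pairwise comparisons) used here.
    """
    x = np.clip(np.asarray(x, dtype=float), 0.0, float(m))
    out = np.zeros_like(x)
    from math import comb, factorial

    for k in range(m + 1):
        term = ((-1.0) ** k) * comb(m, k) * np.clip(x - k, 0.0, None) ** m
        out += term
    return np.clip(out / factorial(m), 0.0, 1.0)


def compute_psi(celltype_profiles: pd.DataFrame, tiers: Sequence[float] = PSI_TIERS) -> pd.DataFrame:
    """Specificity-index probabilities per gene and cell type.

    ``celltype_profiles``: cell types (rows) x genes (columns) mean
    expression. For each target cell type, genes are ranked by their
    expression advantage over every other cell type (rank 1 = most
    specific); the specificity index is the mean rank across the m pairwise
    comparisons. Its p-value is the lower tail of that mean rank under the
    null that ranks are exchangeable, evaluated with the exact Irwin-Hall
    distribution of a sum of m uniforms (a rank of r maps to the uniform
    midpoint (r - 0.5) / G). Thresholding the p-values at the tiers gives
    nested marker lists by construction. Returns a genes x cell types
    DataFrame of pSI p-values.
    """
    if celltype_profiles.shape[0] < 3:
        raise DomainError("need at least 3 cell types for specificity indexing")
    prof = celltype_profiles.astype(float)
    cells = list(prof.index)
    G = prof.shape[1]
    m = len(cells) - 1
    out = pd.DataFrame(index=prof.columns, columns=cells, dtype=float)
    for c in cells:
        ranks = np.zeros(G)
        for j in cells:
            if j == c:
                continue
            diff = prof.loc[c].to_numpy() - prof.loc[j].to_numpy()
            ranks += stats.rankdata(-diff, method="average")
        rank_sum_unit = (ranks - 0.5 * m) / G  # sum of m uniform midpoints
        out[c] = _irwin_hall_cdf(rank_sum_unit, m)
    return out


def psi_marker_lists(psi: pd.DataFrame, tiers: Sequence[float] = PSI_TIERS) -> dict[str, dict[float, list[str]]]:
    """Nested marker lists per cell type: tier -> genes with pSI p < tier."""
    lists: dict[str, dict[float, list[str]]] = {}
    for c in psi.columns:
        lists[c] = {t: list(psi.index[psi[c] < t]) for t in tiers}
    return lists


def psi_tiers_table(psi: pd.DataFrame, tiers: Sequence[float] = PSI_TIERS) -> pd.DataFrame:
    """Most stringent tier attained per gene/cell type (NaN = none)."""
    tier_arr = np.sort(np.asarray(tiers))  # ascending: most stringent first
    out = pd.DataFrame(np.nan, index=psi.index, columns=psi.columns)
    for t in tier_arr[::-1]:
        out = out.where(~(psi < t), t)
    return out


def csea_fisher(
    gene_set: Sequence[str],
    celltype_lists: dict[str, dict[float, list[str]]] | dict[str, list[str]],
    universe: Sequence[str],
    fdr_q: float = 0.05,
) -> list[CellTypeResult]:
    """Cell-type-specific expression analysis by one-sided Fisher tests.

    For every (cell type, pSI tier) marker list, a 2x2 table of membership in
    the gene set x membership in the list over the gene universe is tested
    for enrichment (one-sided greater); BH-FDR is applied across all tests.
    """
    uni = set(universe)
    if not uni:
        raise DomainError("empty gene universe")
    gset = set(gene_set) & uni
    if not gset:
        raise DomainError("gene set does not intersect the universe")
    # normalise to nested dict form
    nested: dict[str, dict[float, list[str]]] = {}
    for ct, v in celltype_lists.items():
        nested[ct] = v if isinstance(v, dict) else {PSI_TIERS[0]: list(v)}

    results: list[CellTypeResult] = []
    for ct, tiers in nested.items():
        for tier, members in tiers.items():
            lst = set(members) & uni
            a = len(gset & lst)
            b = len(gset - lst)
            c = len(lst - gset)
            d = len(uni) - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            results.append(CellTypeResult(
                cell_type=ct,
                psi_threshold=float(tier),
                overlap=a,
                set_size=len(gset),
                list_size=len(lst),
                odds_ratio=float(odds),
                p=float(p),
            ))
    if results:
        _, qvals, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q = float(q)
    return results


def celltype_results_table(results: list[CellTypeResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_type": r.cell_type,
        "psi_threshold": r.psi_threshold,
        "overlap": r.overlap,
        "set_size": r.set_size,
        "list_size": r.list_size,
        "odds_ratio": r.odds_ratio,
        "p": r.p,
        "q": r.q,
    } for r in results])
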