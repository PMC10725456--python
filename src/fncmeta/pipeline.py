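"""End-to-end orchestration: meta-analysis -> robustness -> PLS -> enrichment.

``run`` executes the toggled stages on either a user-supplied study table /
expression matrix or the synthetic generators, writes versioned outputs
(NIfTI volumes, TSV tables), and emits a machine-readable provenance block
(config hash, seeds, parameters, input hashes) sufficient to reproduce the
run. A refused optional stage (e.g. a subgroup with too few datasets) is
logged and recorded, not fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import celltype_results_table, compute_psi, csea_fisher, gcea, gene_loadings, psi_marker_lists
from .exceptions import DependencyError, DomainError, SchemaError, StageRefusal
from .expression import load_expression, sample_map_values, zscore_columns
from .grid import BrainGrid
from .meta import clusters_to_table, sdm_z_map, threshold_clusters
from .pls import bootstrap_gene_weights, component_significance, fit_pls, variogram_surrogates
from .robustness import (
    COVARIATE_GETTERS,
    cluster_diagnostics,
    jackknife,
    meta_regression,
    subgroup_meta,
)
from .simulate import SimulationConfig, simulate_expression, simulate_studies, make_annotation_fixtures
from .study_io import StudyTable, parse_study_table

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]

SUBGROUP_PREDICATES = {
    "binary_fnc": lambda d: d.fnc_type == "binary",
    "weighted_fnc": lambda d: d.fnc_type == "weighted",
    "drug_naive_or_free": lambda d: d.drug_naive_or_free is True,
    "medicated": lambda d: d.drug_naive_or_free is False,
    "scanner_ge": lambda d: d.scanner == "GE",
    "scanner_siemens": lambda d: d.scanner == "Siemens",
    "scanner_philips": lambda d: d.scanner == "Philips",
    "global_signal_removed": lambda d: d.global_signal_removed is True,
    "no_global_signal_removal": lambda d: d.global_signal_removed is False,
}


@dataclass
class RunConfig:
    """All tunables of the pipeline, with their analysis defaults.

    The thresholds mirror the analysis contract: kernel FWHM 20 mm; voxel
    p < 0.005 with peak |Z| > 1 and extent > 10 voxels; jackknife stability
    at 80 %; subgroups need > 10 datasets; meta-regression at p < 0.0005;
    4-mm sampling spheres; 1000 surrogates / bootstraps; Bonferroni 0.05 for
    gene selection; BH-FDR q < 0.05 for cell types.
    """

    # stage toggles
    stages: tuple[str, ...] = ("meta", "diagnostics", "jackknife", "subgroup",
                               "regression", "pls", "gcea", "csea")
    # inputs (None -> synthetic)
    study_table: Optional[str] = None
    peaks_file: Optional[str] = None
    mask_nifti: Optional[str] = None
    expression: Optional[str] = None
    expression_coords: Optional[str] = None
    annotations_gmt: Optional[str] = None
    celltype_profiles: Optional[str] = None
    # meta-analysis
    fwhm_mm: float = 20.0
    n_perm: int = 50
    voxel_p: float = 0.005
    z_thresh: float = 1.0
    min_extent: int = 10
    # robustness
    jackknife_threshold: float = 0.8
    subgroup_min_datasets: int = 10
    subgroups: tuple[str, ...] = ("binary_fnc", "weighted_fnc", "drug_naive_or_free",
                                  "medicated", "scanner_ge", "scanner_siemens",
                                  "scanner_philips")
    regression_p: float = 0.0005
    regression_covariates: tuple[str, ...] = ("panss_total",)
    regression_n_perm: int = 2000
    # transcriptomics
    sphere_radius_mm: float = 4.0
    n_pls_components: int = 5
    n_surrogates: int = 1000
    n_bootstrap: int = 1000
    bonferroni_alpha: float = 0.05
    fdr_q: float = 0.05
    gcea_n_perm: int = 1000
    gcea_min_size: int = 10
    gcea_max_size: int = 200
    # randomness and synthetic inputs
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("stages", "subgroups", "regression_covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if sim is not None:
            simknown = {f.name for f in dataclasses.fields(SimulationConfig)}
            bad = set(sim) - simknown
            if bad:
                raise SchemaError(f"unknown simulation key(s): {sorted(bad)}")
            if "regions" in sim:
                from .simulate import EffectRegion
                sim["regions"] = tuple(EffectRegion(tuple(r["center_mm"]), r["radius_mm"], r["g_true"])
                                       for r in sim["regions"])
            cfg = dataclasses.replace(cfg, simulation=dataclasses.replace(
                SimulationConfig(seed=cfg.seed), **sim))
        else:
            cfg = dataclasses.replace(cfg, simulation=dataclasses.replace(cfg.simulation, seed=cfg.seed))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["regions"] = [
            {"center_mm": list(r["center_mm"]), "radius_mm": r["radius_mm"], "g_true": r["g_true"]}
            for r in d["simulation"]["regions"]
        ]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run(config: RunConfig, outdir) -> Path:
    """Execute the toggled stages; returns the run directory.

    Stage order and dependencies: meta is required by everything downstream;
    pls requires meta; gcea/csea require pls. Requesting a dependent stage
    without its prerequisite raises ``DependencyError``. Optional-stage
    refusals (subgroup/regression gates) are logged into provenance and do
    not abort the run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    for stage, needs in (("diagnostics", "meta"), ("jackknife", "meta"),
                         ("subgroup", "meta"), ("regression", "meta"),
                         ("pls", "meta"), ("gcea", "pls"), ("csea", "pls")):
        if stage in stages and needs not in stages:
            raise DependencyError(f"stage {stage!r} requires stage {needs!r}")
    cfg_hash = config.config_hash()
    provenance: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "seed": config.seed,
        "input_hashes": {},
        "refusals": [],
        "notes": [],
    }

    # ---------------- inputs ----------------
    sim_truth = None
    if config.study_table is not None:
        table = parse_study_table(config.study_table, peaks_path=config.peaks_file)
        provenance["input_hashes"]["study_table"] = _file_hash(config.study_table)
        if config.mask_nifti is None:
            raise SchemaError("a mask NIfTI is required with a user study table")
        grid = BrainGrid.from_nifti_mask(config.mask_nifti)
        provenance["input_hashes"]["mask"] = _file_hash(config.mask_nifti)
    else:
        table, sim_truth = simulate_studies(config.simulation)
        grid = sim_truth["grid"]
        provenance["notes"].append("synthetic study table generated in-run")
    table.validate_for_analysis()
    (outdir / "study_table.json").write_text(table.to_json())

    drivers = enriched_id = None
    if config.expression is not None:
        expr = load_expression(config.expression, config.expression_coords)
        provenance["input_hashes"]["expression"] = _file_hash(config.expression)
    else:
        expr = None  # synthesised after the meta stage from the real sdm_z map

    result = None
    clusters = []
    if "meta" in stages:
        result = sdm_z_map(table, grid, fwhm_mm=config.fwhm_mm,
                           n_perm=config.n_perm, seed=config.seed)
        clusters = threshold_clusters(result, p_thresh=config.voxel_p,
                                      z_thresh=config.z_thresh,
                                      min_extent=config.min_extent)
        import nibabel as nib
        for name, arr in (("pooled_g", result.pooled_effect), ("sdm_z", result.sdm_z),
                          ("tau2", result.tau2), ("p", result.p)):
            nib.save(grid.to_nifti(arr), str(outdir / f"{name}.nii.gz"))
        _write_table(clusters_to_table(clusters), outdir / "clusters.tsv", cfg_hash)

    if "diagnostics" in stages and clusters:
        diag = cluster_diagnostics(result, clusters)
        rows = []
        for d, c in zip(diag, clusters):
            rows.append({"cluster_id": d.cluster_id, "sign": c.sign,
                         "x": c.peak_xyz[0], "y": c.peak_xyz[1], "z": c.peak_xyz[2],
                         "Q": d.Q, "Q_df": d.Q_df, "Q_p": d.Q_p,
                         "egger_intercept": d.egger_intercept, "egger_p": d.egger_p})
        _write_table(pd.DataFrame(rows), outdir / "cluster_diagnostics.tsv", cfg_hash)
        funnel = pd.concat([
            pd.DataFrame(d.funnel_points, columns=["effect", "se"]).assign(cluster_id=d.cluster_id)
            for d in diag
        ])
        _write_table(funnel, outdir / "funnel_points.tsv", cfg_hash)

    if "jackknife" in stages:
        jk = jackknife(table, grid, threshold=config.jackknife_threshold,
                       n_perm=config.n_perm, seed=config.seed,
                       p_thresh=config.voxel_p, z_thresh=config.z_thresh,
                       min_extent=config.min_extent)
        import nibabel as nib
        nib.save(grid.to_nifti(jk.probability_map), str(outdir / "jackknife_probability.nii.gz"))
        nib.save(grid.to_nifti(jk.stable_mask.astype(float)), str(outdir / "jackknife_stable.nii.gz"))

    if "subgroup" in stages:
        rows = []
        for name in config.subgroups:
            predicate = SUBGROUP_PREDICATES.get(name)
            if predicate is None:
                raise SchemaError(f"unknown subgroup {name!r}")
            try:
                sub = subgroup_meta(table, predicate, grid,
                                    min_datasets=config.subgroup_min_datasets,
                                    label=name, fwhm_mm=config.fwhm_mm,
                                    n_perm=config.n_perm, seed=config.seed)
            except StageRefusal as exc:
                log.warning("subgroup %s refused: %s", name, exc)
                provenance["refusals"].append({"stage": f"subgroup:{name}", "reason": str(exc)})
                continue
            subc = threshold_clusters(sub, p_thresh=config.voxel_p,
                                      z_thresh=config.z_thresh, min_extent=config.min_extent)
            for c in subc:
                row = c.as_row()
                row["subgroup"] = name
                rows.append(row)
        _write_table(pd.DataFrame(rows), outdir / "subgroup_clusters.tsv", cfg_hash)

    if "regression" in stages and clusters:
        rows = []
        for cov in config.regression_covariates:
            try:
                mr = meta_regression(result, table, cov, clusters,
                                     p_thresh=config.regression_p,
                                     n_perm=config.regression_n_perm,
                                     seed=config.seed)
            except (StageRefusal, DomainError) as exc:
                log.warning("meta-regression %s refused: %s", cov, exc)
                provenance["refusals"].append({"stage": f"regression:{cov}", "reason": str(exc)})
                continue
            for c in mr.significant_clusters:
                row = c.as_row()
                row["covariate"] = cov
                rows.append(row)
        _write_table(pd.DataFrame(rows), outdir / "meta_regression_clusters.tsv", cfg_hash)

    model = weights = None
    if "pls" in stages:
        if result is None:
            raise DependencyError("pls requires the meta stage")
        if expr is None:
            em, drivers, _ = simulate_expression(config.simulation, result.sdm_z, grid)
            expr = em
            provenance["notes"].append("synthetic expression matrix generated in-run")
        sampled = sample_map_values(result.sdm_z, grid, expr.coords,
                                    radius_mm=config.sphere_radius_mm)
        retained = expr.subset_samples(sampled.values.index)
        X = zscore_columns(retained.values)
        y = zscore_columns(sampled.values.to_numpy())
        ncomp = min(config.n_pls_components, X.shape[0] - 1, X.shape[1])
        model = fit_pls(X, y, n_components=ncomp)
        ensemble = variogram_surrogates(y, retained.sample_xyz,
                                        n=config.n_surrogates, seed=config.seed)
        pvals = component_significance(model, ensemble, X)
        ev = pd.DataFrame({
            "component": np.arange(1, ncomp + 1),
            "explained_variance": model.explained_variance,
            "score_y_correlation": model.score_y_correlation,
            "p_surrogate": pvals,
            "selected": [i == model.selected_component for i in range(ncomp)],
        })
        _write_table(ev, outdir / "pls_variance.tsv", cfg_hash)
        comp = model.selected_component
        provenance["notes"].append(f"selected PLS component: {comp}")
        if comp is not None:
            scores = pd.DataFrame({"sample_id": sampled.values.index,
                                   "score": model.scores[:, comp],
                                   "y": y})
            _write_table(scores, outdir / "pls_scores.tsv", cfg_hash)
            weights = bootstrap_gene_weights(X, y, comp, B=config.n_bootstrap,
                                             seed=config.seed, alpha=config.bonferroni_alpha)
            _write_table(weights.table, outdir / "gene_weights.tsv", cfg_hash)
        else:
            log.warning("no PLS component passed the surrogate test; gene analyses skipped")
            provenance["refusals"].append({"stage": "pls",
                                           "reason": "no component passed the surrogate test"})

    if "gcea" in stages and weights is not None:
        if config.annotations_gmt is not None:
            from .enrichment import read_gmt
            annotations = read_gmt(config.annotations_gmt)
            provenance["input_hashes"]["annotations"] = _file_hash(config.annotations_gmt)
        else:
            annotations, _, enriched_id = make_annotation_fixtures(
                config.simulation, drivers or [], list(X.columns))
            provenance["notes"].append("synthetic annotations generated in-run")
        rows = []
        for direction in ("plus", "minus"):
            res = gcea(y, X, annotations,
                       sample_coords=retained.sample_xyz,
                       component_index=model.selected_component,
                       direction=direction, n_perm=config.gcea_n_perm,
                       seed=config.seed, min_size=config.gcea_min_size,
                       max_size=config.gcea_max_size)
            for r in res:
                rows.append({"direction": direction, "category_id": r.category_id,
                             "name": r.name, "size": r.size, "score": r.score,
                             "p": r.p})
        _write_table(pd.DataFrame(rows), outdir / "gcea.tsv", cfg_hash)

    if "csea" in stages and weights is not None:
        if config.celltype_profiles is not None:
            profiles = pd.read_csv(config.celltype_profiles, sep="\t", index_col=0)
            provenance["input_hashes"]["celltype_profiles"] = _file_hash(config.celltype_profiles)
        else:
            _, profiles, _ = make_annotation_fixtures(config.simulation, drivers or [],
                                                      list(X.columns))
            provenance["notes"].append("synthetic cell-type profiles generated in-run")
        psi = compute_psi(profiles)
        lists = psi_marker_lists(psi)
        universe = list(X.columns)
        rows = []
        for set_name, genes in (("PLS+", weights.pls_plus), ("PLS-", weights.pls_minus)):
            if not genes:
                continue
            for r in csea_fisher(genes, lists, universe, fdr_q=config.fdr_q):
                rows.append({"gene_set": set_name, **{
                    "cell_type": r.cell_type, "psi_threshold": r.psi_threshold,
                    "overlap": r.overlap, "odds_ratio": r.odds_ratio,
                    "p": r.p, "q": r.q}})
        _write_table(pd.DataFrame(rows), outdir / "csea.tsv", cfg_hash)

    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    _write_report(outdir, cfg_hash)
    return outdir


def _write_report(outdir: Path, cfg_hash: str) -> None:
    """Plain-text summary pointing at the emitted tables."""
    lines = [f"fncmeta run summary (config_hash={cfg_hash})", ""]
    for name in ("clusters.tsv", "cluster_diagnostics.tsv", "subgroup_clusters.tsv",
                 "meta_regression_clusters.tsv", "pls_variance.tsv",
                 "gene_weights.tsv", "gcea.tsv", "csea.tsv"):
        path = outdir / name
        if path.exists():
            try:
                df = pd.read_csv(path, sep="\t", comment="#")
                lines.append(f"{name}: {len(df)} rows")
            except Exception:
                lines.append(f"{name}: present")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
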