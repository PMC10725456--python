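"""Transcriptome-neuroimaging association on a synthetic expression matrix.

Builds a target brain map with one active region, simulates an AHBA-style
samples x genes matrix in which 30 "driver" genes track the map, then runs
the full association stage: sphere sampling, PLS, variogram-matched
surrogate significance, bootstrap gene weights with Bonferroni selection,
spatial-null category enrichment (GCEA) and cell-type enrichment (CSEA).
"""

import numpy as np

import fncmeta as fm
from fncmeta.enrichment import CategoryAnnotation
from fncmeta.pls import component_significance, fit_pls, variogram_surrogates
from fncmeta.simulate import SimulationConfig, region_field, simulate_expression

cfg = SimulationConfig(seed=2)
grid = cfg.make_grid()
target = 3.0 * region_field(grid, cfg.regions)  # stands in for an SDM-Z map

expr, drivers, _ = simulate_expression(cfg, target, grid)
sampled = fm.sample_map_values(target, grid, expr.coords, radius_mm=4.0)
retained = expr.subset_samples(sampled.values.index)
X = fm.zscore_columns(retained.values)
y = fm.zscore_columns(sampled.values.to_numpy())
print(f"{X.shape[0]} samples x {X.shape[1]} genes; {len(sampled.dropped_samples)} empty spheres")

model = fit_pls(X, y, n_components=5)
ens = variogram_surrogates(y, retained.sample_xyz, n=200, seed=2)
pvals = component_significance(model, ens, X)
for i, (ev, p) in enumerate(zip(model.explained_variance, pvals), start=1):
    mark = " <- selected" if i - 1 == model.selected_component else ""
    print(f"  PLS{i}: {100 * ev:5.2f}% of var(y), surrogate p = {p:.3f}{mark}")

comp = model.selected_component
gw = fm.bootstrap_gene_weights(X, y, comp, B=500, seed=2)
rec = 100 * np.mean([d in gw.pls_plus for d in drivers])
print(f"\nBonferroni-significant genes: {gw.table.significant.sum()} "
      f"({len(gw.pls_plus)} PLS+, {len(gw.pls_minus)} PLS-)")
print(f"driver genes recovered in PLS+: {rec:.0f}% "
      f"(wrong sign: {len(set(drivers) & set(gw.pls_minus))})")

annotations, profiles, enriched_id = fm.make_annotation_fixtures(cfg, drivers, list(X.columns))
gres = fm.gcea(y, X, annotations, ensemble=ens, component_index=comp,
               direction="plus", min_size=5)
enr = {r.category_id: r.p for r in gres}
others = [p for cid, p in enr.items() if cid != enriched_id]
print(f"\nGCEA: driver-built category p = {enr[enriched_id]:.3f}, "
      f"median random-category p = {np.median(others):.2f}")

psi = fm.compute_psi(profiles)
res = fm.csea_fisher(gw.pls_plus, fm.psi_marker_lists(psi), list(X.columns))
top = min(res, key=lambda r: r.q)
print(f"CSEA: top cell type '{top.cell_type}' at pSI {top.psi_threshold}: "
      f"overlap {top.overlap}, q = {top.q:.2e}")

# The selected component is the one whose explained variance beats the
# spatial-autocorrelation-preserving null; the driver genes surface as the
# Bonferroni-significant PLS+ set, their category is GCEA-enriched against
# the spatial ensemble null, and the cell type overexpressing them wins CSEA.
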