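"""Coordinate-based meta-analysis on a synthetic multi-study peak table.

Simulates 12 studies reporting peaks from noisy effect maps with one planted
region (Hedges' g = 0.8, between-study tau = 0.1), reconstructs per-study
effect maps with the 20-mm Gaussian kernel, pools them voxel-wise
(DerSimonian-Laird) and standardises against the peak-relocation null.
Prints the recovered clusters and the Dice overlap with the planted region.
"""

import numpy as np

import fncmeta as fm
from fncmeta.simulate import SimulationConfig, simulate_studies

cfg = SimulationConfig(seed=1)
table, truth = simulate_studies(cfg)
grid = truth["grid"]
print(f"{len(table)} studies, {sum(len(d.peaks) for d in table)} reported peaks, "
      f"grid {grid.shape} at {grid.voxel_size[0]:.0f} mm ({grid.n_voxels} in-mask voxels)")

result = fm.sdm_z_map(table, grid, n_perm=50, seed=1)
clusters = fm.threshold_clusters(result)  # voxel p < 0.005, |Z| > 1, extent > 10

truth_mask = truth["region_mask"]
best = None
for c in clusters:
    member = np.zeros(grid.n_voxels, dtype=bool)
    member[c.member_voxels] = True
    dice = 2 * (member & truth_mask).sum() / (member.sum() + truth_mask.sum())
    if best is None or dice > best[0]:
        best = (dice, c)

print(f"\n{len(clusters)} clusters pass the threshold triple; the largest overlapping one:")
dice, c = best
print(f"  peak {tuple(round(v) for v in c.peak_xyz)} mm, {c.size_voxels} voxels, "
      f"SDM-Z {c.peak_sdm_z:.2f}, p {c.p:.3f}")
print(f"  Dice vs planted region: {dice:.2f}  (planted centre {cfg.regions[0].center_mm})")

# A Dice above 0.5 with the peak within a voxel of the planted centre means
# the kernel reconstruction + random-effects pooling localises the region at
# the method's 20-mm resolving scale; the remaining small clusters are the
# noise peaks an uncorrected p < 0.005 threshold admits.
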