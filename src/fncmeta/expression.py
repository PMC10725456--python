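"""Sample-level gene-expression matrix and map sampling for the PLS stage.

The transcriptome side of the analysis is a samples x genes expression matrix
with an MNI coordinate per sample (the layout an abagen-style AHBA export
produces; upstream probe aggregation and donor normalisation are provenance,
not re-implemented here). The imaging side is the per-sample mean SDM-Z
within a small sphere around each sample's coordinate. Both sides are
z-scored column-wise before PLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DomainError, SchemaError
from .grid import BrainGrid

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "MapSampleVector",
    "load_expression",
    "sample_map_values",
    "zscore_columns",
]


@dataclass
class ExpressionMatrix:
    """samples x genes expression with per-sample metadata.

    ``values``: DataFrame indexed by sample_id, columns = gene symbols.
    ``coords``: DataFrame indexed by sample_id with columns x, y, z and
    optionally donor_id and structure ({cortex, subcortex/brainstem,
    cerebellum}; provenance of upstream per-structure normalisation).
    """

    values: pd.DataFrame
    coords: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.coords.index):
            raise SchemaError("expression rows and coordinate rows do not align")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise SchemaError(f"duplicate gene column: {dup!r}")
        if self.values.isna().any().any():
            raise SchemaError("expression matrix contains missing values")
        xyz = self.coords[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise SchemaError("sample coordinates must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_xyz(self) -> np.ndarray:
        return self.coords[["x", "y", "z"]].to_numpy(dtype=float)

    def save(self, matrix_path, coords_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="sample_id")
        self.coords.to_csv(coords_path, sep="\t", index_label="sample_id")

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[sample_ids],
            coords=self.coords.loc[sample_ids],
            provenance=dict(self.provenance),
        )


@dataclass
class MapSampleVector:
    """Per-sample mean SDM-Z within a sphere; empty-sphere samples dropped."""

    values: pd.Series  # indexed by retained sample_id
    dropped_samples: list[str]
    radius_mm: float


def load_expression(path, coords_path=None) -> ExpressionMatrix:
    """Load an expression matrix from TSV (+ coordinates sidecar) or a
    directory in abagen export layout (``expression.csv`` + ``coords.csv``).
    """
    path = Path(path)
    if path.is_dir():
        matrix_path = next((path / n for n in ("expression.tsv", "expression.csv")
                            if (path / n).exists()), None)
        cpath = next((path / n for n in ("coords.tsv", "coords.csv", "coordinates.csv")
                      if (path / n).exists()), None)
        if matrix_path is None or cpath is None:
            raise SchemaError(f"directory {path} lacks expression/coords files")
    else:
        matrix_path, cpath = path, coords_path
        if cpath is None:
            raise SchemaError("a coordinates sidecar is required with a matrix file")
    sep = "\t" if str(matrix_path).endswith((".tsv", ".txt", ".tsv.gz")) else ","
    values = pd.read_csv(matrix_path, sep=sep, index_col=0)
    csep = "\t" if str(cpath).endswith((".tsv", ".txt", ".tsv.gz")) else ","
    coords = pd.read_csv(cpath, sep=csep, index_col=0)
    missing = [c for c in ("x", "y", "z") if c not in coords.columns]
    if missing:
        raise SchemaError(f"coordinates sidecar missing column(s): {missing}")
    if values.shape[0] != coords.shape[0]:
        raise SchemaError(
            f"dimension mismatch: {values.shape[0]} expression rows vs {coords.shape[0]} coordinate rows"
        )
    coords = coords.loc[values.index]
    return ExpressionMatrix(values=values, coords=coords,
                            provenance={"source": str(matrix_path)})


def sample_map_values(
    zmap: np.ndarray,
    grid: BrainGrid,
    sample_coords: pd.DataFrame | np.ndarray,
    radius_mm: float = 4.0,
) -> MapSampleVector:
    """Mean statistic value within a sphere around each sample coordinate.

    Sphere membership is by voxel-centre distance <= radius. Samples whose
    sphere contains no in-mask voxel are dropped and listed, not fatal.
    """
    if radius_mm <= 0:
        raise DomainError("radius must be positive")
    zmap = np.asarray(zmap, dtype=float)
    if zmap.shape[0] != grid.n_voxels:
        raise DomainError("zmap length must equal the grid's in-mask voxel count")
    if isinstance(sample_coords, pd.DataFrame):
        ids = list(sample_coords.index.astype(str))
        xyz = sample_coords[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        xyz = np.atleast_2d(np.asarray(sample_coords, dtype=float))
        ids = [str(i) for i in range(xyz.shape[0])]
    coords = grid.coords_mm
    values, kept, dropped = [], [], []
    for sid, p in zip(ids, xyz):
        d2 = ((coords - p) ** 2).sum(axis=1)
        inside = d2 <= radius_mm**2
        if not inside.any():
            dropped.append(sid)
            continue
        kept.append(sid)
        values.append(float(zmap[inside].mean()))
    if dropped:
        log.info("sample_map_values: dropped %d samples with empty spheres", len(dropped))
    return MapSampleVector(
        values=pd.Series(values, index=pd.Index(kept, name="sample_id")),
        dropped_samples=dropped,
        radius_mm=radius_mm,
    )


def zscore_columns(data):
    """Z-score columns to mean 0, sd 1 (population denominator).

    Accepts a DataFrame, Series or ndarray; constant columns are dropped
    (DataFrame) or rejected (vector) with a log message. The population-n
    denominator is immaterial to PLS directions.
    """
    if isinstance(data, pd.DataFrame):
        sd = data.std(axis=0, ddof=0)
        constant = sd[sd == 0].index
        if len(constant) == len(data.columns):
            raise DomainError("all columns are constant; nothing to z-score")
        if len(constant):
            log.warning("zscore_columns: dropping %d constant column(s): %s",
                        len(constant), list(constant[:5]))
            data = data.drop(columns=constant)
            sd = sd.drop(constant)
        return (data - data.mean(axis=0)) / sd
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        s = arr.std()
        if s == 0:
            raise DomainError("constant vector cannot be z-scored")
        return (arr - arr.mean()) / s
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)
    if np.all(sd == 0):
        raise DomainError("all columns are constant; nothing to z-score")
    if np.any(sd == 0):
        raise DomainError("constant columns present; use a DataFrame to drop them")
    return (arr - mean) / sd
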