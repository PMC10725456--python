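"""Study tables: parsing, validation, coordinate and statistic conversion.

A coordinate-based meta-analysis starts from per-study peak tables: each
included dataset contributes demographics, acquisition/analysis metadata and
a list of significant peak coordinates with a signed t-statistic (or, when no
statistic was printed, a sign marker: ``"p"`` for patients > controls, ``"n"``
for patients < controls). This module normalises everything to a common
representation — MNI millimetres and t-values — and computes the descriptive
aggregates of the included-study roster (pooled patients, unique controls,
sample-size-weighted mean ages).
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, ParseError, SchemaError

log = logging.getLogger(__name__)

__all__ = [
    "PeakRecord",
    "StudyDataset",
    "StudyTable",
    "parse_study_table",
    "convert_statistic",
    "tal_to_mni",
    "load_reference_roster",
    "roster_aggregates",
    "TAL2ICBM_SPM",
]

SIGN_MARKERS = ("p", "n")

# Lancaster et al. (2007) icbm_spm2tal affine ("SPM flavour"); the
# Talairach -> MNI direction is its inverse, as applied by GingerALE's
# tal2icbm_spm conversion.
ICBM_SPM2TAL = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
TAL2ICBM_SPM = np.linalg.inv(ICBM_SPM2TAL)


@dataclass
class PeakRecord:
    """One reported peak: MNI/Talairach mm plus a t-value or sign marker."""

    x: float
    y: float
    z: float
    stat: Union[float, str]  # signed t-value, or "p"/"n" marker
    space: str = "MNI"
    cluster_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.space not in ("MNI", "Talairach"):
            raise DomainError(f"unknown coordinate space {self.space!r}")
        for name in ("x", "y", "z"):
            v = float(getattr(self, name))
            setattr(self, name, v)
            if not math.isfinite(v) or abs(v) > 120.0:
                raise DomainError(f"peak {name}={v} outside +/-120 mm")
        if isinstance(self.stat, str):
            if self.stat not in SIGN_MARKERS:
                raise DomainError(f"stat marker must be one of {SIGN_MARKERS}, got {self.stat!r}")
        else:
            self.stat = float(self.stat)
            if not math.isfinite(self.stat):
                raise DomainError("stat must be finite")

    @property
    def has_tstat(self) -> bool:
        return not isinstance(self.stat, str)

    @property
    def sign(self) -> int:
        if isinstance(self.stat, str):
            return 1 if self.stat == "p" else -1
        return 1 if self.stat >= 0 else -1

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class StudyDataset:
    """One dataset of the meta-analysis: demographics, acquisition and peaks."""

    study_id: str
    n_patients: int
    n_controls: int
    male_patients: Optional[int] = None
    male_controls: Optional[int] = None
    mean_age_pat: Optional[float] = None
    mean_age_con: Optional[float] = None
    criteria: Optional[str] = None
    drug_naive_or_free: Optional[bool] = None
    illness_duration: Optional[float] = None  # months
    panss_total: Optional[float] = None
    panss_pos: Optional[float] = None
    panss_neg: Optional[float] = None
    scanner: Optional[str] = None
    tr_ms: Optional[float] = None
    te_ms: Optional[float] = None
    smoothing_fwhm_mm: Optional[float] = None
    global_signal_removed: Optional[bool] = None
    fnc_type: Optional[str] = None  # "binary" | "weighted"
    corr_threshold: Optional[float] = None
    reporting_p: float = 0.001  # voxel-level p of the study's own threshold
    reporting_corrected: bool = False
    peaks: list[PeakRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise DomainError(f"{self.study_id}: group sizes must be >= 1")
        for male, total, grp in (
            (self.male_patients, self.n_patients, "patients"),
            (self.male_controls, self.n_controls, "controls"),
        ):
            if male is not None and male > total:
                raise DomainError(f"{self.study_id}: male {grp} exceed group size")
        if self.fnc_type is not None and self.fnc_type not in ("binary", "weighted"):
            raise DomainError(f"{self.study_id}: fnc_type must be binary|weighted")

    @property
    def df(self) -> int:
        """Degrees of freedom of the two-sample contrast."""
        return self.n_patients + self.n_controls - 2

    @property
    def pct_male_patients(self) -> Optional[float]:
        if self.male_patients is None:
            return None
        return 100.0 * self.male_patients / self.n_patients


@dataclass
class StudyTable:
    datasets: list[StudyDataset]
    # group label -> list of dataset ids drawing on one shared control sample
    shared_control_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [d.study_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise SchemaError("dataset ids are not unique")
        known = set(ids)
        for label, members in self.shared_control_groups.items():
            unknown = set(members) - known
            if unknown:
                raise SchemaError(f"shared-control group {label!r} references unknown ids {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def get(self, study_id: str) -> StudyDataset:
        for d in self.datasets:
            if d.study_id == study_id:
                return d
        raise KeyError(study_id)

    def subset(self, predicate: Callable[[StudyDataset], bool]) -> "StudyTable":
        kept = [d for d in self.datasets if predicate(d)]
        kept_ids = {d.study_id for d in kept}
        groups = {
            label: [m for m in members if m in kept_ids]
            for label, members in self.shared_control_groups.items()
        }
        groups = {k: v for k, v in groups.items() if len(v) > 1}
        return StudyTable(datasets=kept, shared_control_groups=groups)

    def validate_for_analysis(self) -> None:
        """Analysis-time contract: every dataset must carry peaks."""
        empty = [d.study_id for d in self.datasets if not d.peaks]
        if empty:
            raise SchemaError(f"datasets without peaks cannot be analysed: {empty}")

    # --- lossless JSON round trip -------------------------------------
    def to_json(self) -> str:
        payload = {
            "datasets": [asdict(d) for d in self.datasets],
            "shared_control_groups": self.shared_control_groups,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StudyTable":
        payload = json.loads(text)
        datasets = []
        for d in payload["datasets"]:
            peaks = [PeakRecord(**p) for p in d.pop("peaks", [])]
            datasets.append(StudyDataset(peaks=peaks, **d))
        return cls(datasets=datasets, shared_control_groups=payload.get("shared_control_groups", {}))


# ----------------------------------------------------------------------
# statistic and coordinate conversion
# ----------------------------------------------------------------------

def convert_statistic(value: float, df: int, kind: str, two_tailed: bool = False) -> float:
    """Convert a reported Z-score or p-value to a t-statistic.

    Z-scores convert by matching the upper-tail probability of the standard
    normal to the t distribution with ``df`` degrees of freedom. P-values are
    taken one-tailed in the direction of the reported contrast (the sign is
    supplied separately by the caller); set ``two_tailed=True`` when a study
    reported two-tailed p-values.
    """
    if df <= 0:
        raise DomainError(f"df must be positive, got {df}")
    if kind == "z":
        return float(stats.t.isf(stats.norm.sf(float(value)), df))
    if kind == "p":
        p = float(value)
        if not (0.0 < p < 1.0):
            raise DomainError(f"p must lie in (0, 1), got {p}")
        if two_tailed:
            p = p / 2.0
        return float(stats.t.isf(p, df))
    raise DomainError(f"kind must be 'z' or 'p', got {kind!r}")


def tal_to_mni(coord: Iterable[float], space: str = "Talairach") -> np.ndarray:
    """Talairach -> MNI via the Lancaster tal2icbm (SPM flavour) affine.

    MNI-tagged input is returned unchanged with a warning (wrong-space guard).
    """
    xyz = np.asarray(list(coord), dtype=float)
    if xyz.shape != (3,):
        raise DomainError("coordinate must be a length-3 mm triple")
    if space == "MNI":
        warnings.warn("coordinate already in MNI space; returned unchanged", stacklevel=2)
        return xyz
    if space != "Talairach":
        raise DomainError(f"unknown space {space!r}")
    return (TAL2ICBM_SPM @ np.append(xyz, 1.0))[:3]


def mni_to_tal(coord: Iterable[float]) -> np.ndarray:
    """Inverse of :func:`tal_to_mni` (round-trip support)."""
    xyz = np.asarray(list(coord), dtype=float)
    return (ICBM_SPM2TAL @ np.append(xyz, 1.0))[:3]


def normalize_peaks(dataset: StudyDataset) -> StudyDataset:
    """Return a copy with every peak in MNI space (Lancaster transform)."""
    peaks = []
    for pk in dataset.peaks:
        if pk.space == "Talairach":
            x, y, z = tal_to_mni(pk.xyz)
            peaks.append(PeakRecord(x=x, y=y, z=z, stat=pk.stat, space="MNI",
                                    cluster_label=pk.cluster_label))
        else:
            peaks.append(pk)
    out = StudyDataset(**{**{k: v for k, v in asdict(dataset).items() if k != "peaks"}})
    out.peaks = peaks
    return out


# ----------------------------------------------------------------------
# parsing
# ----------------------------------------------------------------------

REQUIRED_COLUMNS = ("study_id", "n_patients", "n_controls")

_BOOL_MAP = {"yes": True, "no": False, "true": True, "false": False, "1": True, "0": False}

_OPTIONAL_NUMERIC = {
    "male_patients": "male_patients",
    "male_controls": "male_controls",
    "mean_age_pat": "mean_age_pat",
    "mean_age_con": "mean_age_con",
    "illness_duration_months": "illness_duration",
    "panss_total": "panss_total",
    "panss_pos": "panss_pos",
    "panss_neg": "panss_neg",
    "tr_ms": "tr_ms",
    "te_ms": "te_ms",
    "smoothing_fwhm_mm": "smoothing_fwhm_mm",
    "corr_threshold": "corr_threshold",
}

_SCANNER_ALIASES = {"phillips": "Philips", "philips": "Philips", "ge": "GE", "siemens": "Siemens"}


def _opt_float(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    if s == "" or s.upper() == "NA":
        return None
    try:
        return float(s)
    except ValueError:
        return None


def _opt_bool(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip().lower()
    if s in ("", "na"):
        return None
    return _BOOL_MAP.get(s)


def _parse_peak_row(row: pd.Series, study_id: str) -> PeakRecord:
    try:
        vals = {}
        for name in ("x", "y", "z"):
            vals[name] = float(row[name])
        raw = str(row["stat"]).strip()
        stat: Union[float, str]
        if raw in SIGN_MARKERS:
            stat = raw
        else:
            try:
                stat = float(raw)
            except ValueError:
                raise ParseError(
                    f"study {study_id!r}: peak statistic {raw!r} is neither numeric nor a p/n marker"
                )
        space = str(row.get("space", "MNI") or "MNI").strip() or "MNI"
        label = row.get("cluster_label")
        label = None if (label is None or (isinstance(label, float) and math.isnan(label))) else str(label)
        return PeakRecord(x=vals["x"], y=vals["y"], z=vals["z"], stat=stat, space=space, cluster_label=label)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"study {study_id!r}: malformed peak row ({exc})") from exc


def parse_study_table(path, peaks_path=None) -> StudyTable:
    """Parse a study roster TSV/CSV (optionally with a companion peaks file).

    The roster carries one row per dataset with the demographic / technical
    columns; peaks may come either from ``peaks_path`` (columns: study_id,
    x, y, z, stat[, space, cluster_label]) or from an embedded ``peaks_json``
    column. Missing optional fields are recorded as absent, never as zero.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"required column(s) missing: {missing}")

    peaks_by_study: dict[str, list[PeakRecord]] = {}
    if peaks_path is not None:
        psep = "\t" if str(peaks_path).endswith((".tsv", ".txt")) else ","
        pdf = pd.read_csv(peaks_path, sep=psep, dtype=str)
        pmissing = [c for c in ("study_id", "x", "y", "z", "stat") if c not in pdf.columns]
        if pmissing:
            raise SchemaError(f"peaks file: required column(s) missing: {pmissing}")
        for _, row in pdf.iterrows():
            sid = str(row["study_id"])
            peaks_by_study.setdefault(sid, []).append(_parse_peak_row(row, sid))

    datasets: list[StudyDataset] = []
    groups: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        sid = str(row["study_id"])
        try:
            kwargs = dict(
                study_id=sid,
                n_patients=int(row["n_patients"]),
                n_controls=int(row["n_controls"]),
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"study {sid!r}: non-numeric group size") from exc
        for col, fieldname in _OPTIONAL_NUMERIC.items():
            if col in df.columns:
                v = _opt_float(row[col])
                if fieldname in ("male_patients", "male_controls") and v is not None:
                    v = int(v)
                kwargs[fieldname] = v
        if "criteria" in df.columns:
            c = row["criteria"]
            kwargs["criteria"] = None if (isinstance(c, float) and math.isnan(c)) else str(c)
        if "medicated" in df.columns:
            med = _opt_bool(row["medicated"])
            kwargs["drug_naive_or_free"] = (not med) if med is not None else None
        elif "drug_naive_or_free" in df.columns:
            kwargs["drug_naive_or_free"] = _opt_bool(row["drug_naive_or_free"])
        if "global_signal_removed" in df.columns:
            kwargs["global_signal_removed"] = _opt_bool(row["global_signal_removed"])
        if "scanner" in df.columns and isinstance(row["scanner"], str):
            kwargs["scanner"] = _SCANNER_ALIASES.get(row["scanner"].strip().lower(), row["scanner"].strip())
        if "fnc_type" in df.columns and isinstance(row["fnc_type"], str):
            kwargs["fnc_type"] = row["fnc_type"].strip().lower()
        if "reporting_p" in df.columns:
            rp = _opt_float(row["reporting_p"])
            if rp is not None:
                kwargs["reporting_p"] = rp
        if "reporting_corrected" in df.columns:
            rc = _opt_bool(row["reporting_corrected"])
            if rc is not None:
                kwargs["reporting_corrected"] = rc

        peaks = peaks_by_study.get(sid, [])
        if "peaks_json" in df.columns and isinstance(row["peaks_json"], str) and row["peaks_json"].strip():
            for p in json.loads(row["peaks_json"]):
                peaks.append(PeakRecord(**p))
        datasets.append(StudyDataset(peaks=peaks, **kwargs))

        if "shared_control_group" in df.columns:
            g = row["shared_control_group"]
            if isinstance(g, str) and g.strip() and g.strip().upper() != "NA":
                groups.setdefault(g.strip(), []).append(sid)

    groups = {k: v for k, v in groups.items() if len(v) > 1}
    return StudyTable(datasets=datasets, shared_control_groups=groups)


def load_reference_roster() -> StudyTable:
    """The 25-dataset schizophrenia FNC roster shipped with the package.

    Transcribed from the included-study tables of the meta-analysis this
    package implements (demographics, acquisition and analysis metadata;
    the original studies' peak coordinates are not part of the table and
    are not included).
    """
    ref = importlib.resources.files("fncmeta").joinpath("data/schizophrenia_fnc_studies.tsv")
    with importlib.resources.as_file(ref) as path:
        return parse_study_table(path)


def roster_aggregates(table: StudyTable) -> dict:
    """Descriptive aggregates of an included-study roster.

    Controls shared between split datasets of one study are counted once.
    Mean ages are weighted by group size (controls: one entry per unique
    control sample).
    """
    pooled_patients = sum(d.n_patients for d in table.datasets)
    grouped = {sid for members in table.shared_control_groups.values() for sid in members}
    control_entries: list[StudyDataset] = [d for d in table.datasets if d.study_id not in grouped]
    for members in table.shared_control_groups.values():
        control_entries.append(table.get(members[0]))
    unique_controls = sum(d.n_controls for d in control_entries)

    pa = [(d.mean_age_pat, d.n_patients) for d in table.datasets if d.mean_age_pat is not None]
    ca = [(d.mean_age_con, d.n_controls) for d in control_entries if d.mean_age_con is not None]
    wmean = lambda pairs: float(np.average([a for a, _ in pairs], weights=[w for _, w in pairs]))
    return {
        "n_datasets": len(table.datasets),
        "n_studies": len(table.datasets) - sum(len(m) - 1 for m in table.shared_control_groups.values()),
        "pooled_patients": pooled_patients,
        "unique_controls": unique_controls,
        "weighted_mean_patient_age": wmean(pa) if pa else float("nan"),
        "weighted_mean_control_age": wmean(ca) if ca else float("nan"),
    }
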