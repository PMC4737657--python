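"""Tabular domain records: spines, pairs, vesicle clouds, replicate measurements.

Units follow the conventions of 3DEM spine morphometry: volumes in µm³,
areas in µm², lengths in µm, vesicle coordinates in nm (the docked-vesicle
distance rule is stated in nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DataError, DomainError, InsufficientDataError

__all__ = [
    "SpineRecord",
    "SpinePair",
    "VesicleCloud",
    "MeasurementReplicates",
    "SPINE_TABLE_COLUMNS",
    "PAIRABLE_METRICS",
    "records_to_frame",
    "frame_to_records",
]

#: Fixed header of the spine-table CSV, in writing order.
SPINE_TABLE_COLUMNS = [
    "spine_id",
    "dendrite_id",
    "axon_id",
    "head_volume",
    "head_area",
    "psd_area",
    "neck_length",
    "neck_diameter",
    "neck_volume",
    "whole_spine_volume",
    "docked_vesicles",
]

#: Metrics for which a per-pair CV is meaningful (strictly positive scales).
PAIRABLE_METRICS = [
    "head_volume",
    "head_area",
    "psd_area",
    "neck_length",
    "neck_diameter",
    "neck_volume",
    "whole_spine_volume",
]


@dataclass
class SpineRecord:
    """One spine's morphometric measurements plus connectivity labels.

    ``neck_volume`` must equal ``whole_spine_volume - head_volume`` up to a
    small tolerance; :meth:`validate` enforces this and the positivity of
    every size metric.
    """

    spine_id: str
    dendrite_id: str
    axon_id: str
    head_volume: float      # µm³
    head_area: float        # µm²
    psd_area: float         # µm²
    neck_length: float      # µm
    neck_diameter: float    # µm
    neck_volume: float      # µm³
    whole_spine_volume: float  # µm³
    docked_vesicles: int

    def validate(self, rtol: float = 1e-6) -> None:
        for name in ("head_volume", "head_area", "psd_area", "neck_length",
                     "neck_diameter", "neck_volume", "whole_spine_volume"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be finite and > 0, got {v!r}")
        if self.docked_vesicles < 0 or int(self.docked_vesicles) != self.docked_vesicles:
            raise DomainError(f"docked_vesicles must be a non-negative integer, "
                              f"got {self.docked_vesicles!r}")
        if self.whole_spine_volume < self.head_volume * (1 - rtol):
            raise ConsistencyError(
                f"whole_spine_volume {self.whole_spine_volume} < head_volume "
                f"{self.head_volume} for spine {self.spine_id}")
        expected = self.whole_spine_volume - self.head_volume
        if abs(self.neck_volume - expected) > rtol * max(self.whole_spine_volume, 1e-12):
            raise ConsistencyError(
                f"neck_volume {self.neck_volume} != whole - head = {expected} "
                f"for spine {self.spine_id}")


def _pair_cv_tolerant(a: float, b: float) -> float:
    # sample sd over n=2 (ddof=1) divided by the mean; 0/0 -> 0
    mean = 0.5 * (a + b)
    if mean == 0.0:
        return 0.0
    return (abs(a - b) / np.sqrt(2.0)) / mean


@dataclass
class SpinePair:
    """Two spine records sharing an axon, with pair-level statistics.

    ``pair_cv_head_volume`` is sd/mean of the two head volumes (sd with
    denominator n-1=1); ``metric_cvs`` holds the same statistic per metric.
    """

    spine_a: SpineRecord
    spine_b: SpineRecord
    same_dendrite: bool
    multi_contact: bool = False
    pair_cv_head_volume: float = field(init=False)
    metric_cvs: dict = field(init=False)

    def __post_init__(self) -> None:
        self.pair_cv_head_volume = _pair_cv_tolerant(
            self.spine_a.head_volume, self.spine_b.head_volume)
        self.metric_cvs = {
            m: _pair_cv_tolerant(getattr(self.spine_a, m), getattr(self.spine_b, m))
            for m in PAIRABLE_METRICS
        }
        self.metric_cvs["docked_vesicles"] = _pair_cv_tolerant(
            float(self.spine_a.docked_vesicles), float(self.spine_b.docked_vesicles))

    def mean(self, metric: str = "head_volume") -> float:
        return 0.5 * (getattr(self.spine_a, metric) + getattr(self.spine_b, metric))


@dataclass
class VesicleCloud:
    """Presynaptic vesicle centers in nm, with optional ground-truth docked labels."""

    centers_nm: np.ndarray  # (n, 3) float, nm
    terminal_id: str = "terminal_0"
    associated_spine_id: str = "spine_0"
    docked_truth: np.ndarray | None = None  # (n,) bool, set by the generator

    def __post_init__(self) -> None:
        self.centers_nm = np.asarray(self.centers_nm, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.centers_nm)):
            raise DomainError("vesicle coordinates must be finite")
        if self.docked_truth is not None:
            self.docked_truth = np.asarray(self.docked_truth, dtype=bool).reshape(-1)
            if self.docked_truth.shape[0] != self.centers_nm.shape[0]:
                raise DataError("docked_truth length must match number of centers")

    def __len__(self) -> int:
        return self.centers_nm.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.centers_nm, columns=["x_nm", "y_nm", "z_nm"])
        df["terminal_id"] = self.terminal_id
        return df


@dataclass
class MeasurementReplicates:
    """Repeated head-volume measurements of one spine (tracer replicates)."""

    spine_id: str
    head_volume_measurements: Sequence[float]

    def validate(self) -> None:
        vals = np.asarray(self.head_volume_measurements, dtype=float)
        if vals.size < 2:
            raise InsufficientDataError(
                f"spine {self.spine_id}: need >=2 replicate measurements, got {vals.size}")
        if not np.all(vals > 0):
            raise DomainError(f"spine {self.spine_id}: replicate measurements must be > 0")


def records_to_frame(records: Sequence[SpineRecord]) -> pd.DataFrame:
    """Spine records -> DataFrame with the fixed CSV header order."""
    rows = [{f.name: getattr(r, f.name) for f in fields(SpineRecord)} for r in records]
    return pd.DataFrame(rows, columns=SPINE_TABLE_COLUMNS)


def frame_to_records(df: pd.DataFrame, validate: bool = True) -> list[SpineRecord]:
    """DataFrame (or CSV read thereof) -> spine records; checks id uniqueness."""
    missing = [c for c in SPINE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"spine table is missing columns: {missing}")
    if df["spine_id"].duplicated().any():
        dup = df.loc[df["spine_id"].duplicated(), "spine_id"].iloc[0]
        raise DataError(f"duplicate spine_id {dup!r}")
    out = []
    for row in df.itertuples(index=False):
        rec = SpineRecord(
            spine_id=str(row.spine_id), dendrite_id=str(row.dendrite_id),
            axon_id=str(row.axon_id), head_volume=float(row.head_volume),
            head_area=float(row.head_area), psd_area=float(row.psd_area),
            neck_length=float(row.neck_length), neck_diameter=float(row.neck_diameter),
            neck_volume=float(row.neck_volume),
            whole_spine_volume=float(row.whole_spine_volume),
            docked_vesicles=int(row.docked_vesicles))
        if validate:
            rec.validate()
        out.append(rec)
    return out


def copy_record(record: SpineRecord, **changes) -> SpineRecord:
    """Shallow copy with field overrides (dataclasses.replace wrapper)."""
    return replace(record, **changes)
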