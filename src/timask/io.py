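"""Tabular input/output for time-intensity (TI) studies.

All interchange is plain CSV (comma separator, ``.`` decimal, UTF-8,
header required):

* ``curves.csv``    — ``material_id,panelist_id,replicate,time_s,intensity``
* ``materials.csv`` — ``material_id,name,mtype,category``
* ``vas.csv``       — ``material_id,panelist_id,beany_intensity``
* ``params.csv``    — ``material_id`` + the 14 TI-parameter columns

Readers validate every domain invariant and raise a located error; they
never silently coerce. Writers emit a canonical column order so that
``write ∘ read`` is the identity on canonical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Allowed material types. 100-mm VAS values are stored on the 0-10 scale
#: (mm / 10) at ingestion, matching the 10-point masking-score formula.
MTYPES = ("essence", "oil", "flavor")

#: Canonical order of the 14 TI-parameter columns in ``params.csv``.
PARAMETER_NAMES = (
    "Tstart", "Tend", "Imax", "TsPl", "TePl", "DurPl", "DurInc",
    "DurDec", "SIMInc", "SIMDec", "AreaTse", "AreaInc", "AreaDec", "AreaPl",
)

CURVE_COLUMNS = ("material_id", "panelist_id", "replicate", "time_s", "intensity")
MATERIAL_COLUMNS = ("material_id", "name", "mtype", "category")
VAS_COLUMNS = ("material_id", "panelist_id", "beany_intensity")


@dataclass
class MaterialInfo:
    """One flavoring material: id, display name, type and flavor category."""

    material_id: str
    name: str
    mtype: str
    category: str = ""

    def __post_init__(self) -> None:
        self.mtype = str(self.mtype).strip().lower()
        if self.mtype not in MTYPES:
            raise ValidationError(
                f"material {self.material_id!r}: unknown mtype {self.mtype!r}; "
                f"allowed values are {', '.join(MTYPES)}"
            )


@dataclass
class TICurve:
    """One replicate's sampled intensity trajectory for one material/panelist.

    ``times`` start at 0 s with a uniform (1 Hz by default) spacing;
    intensities are arbitrary units in [0, 100].
    """

    material_id: str
    panelist_id: str
    replicate: int
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.replicate = int(self.replicate)
        key = f"({self.material_id}, {self.panelist_id}, rep {self.replicate})"
        if self.replicate < 1:
            raise ValidationError(f"{key}: replicate index must be >= 1")
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValidationError(f"{key}: times and intensities must be equal-length 1-D arrays")
        if self.times.size < 3:
            raise ValidationError(f"{key}: a curve needs at least 3 samples, got {self.times.size}")
        if not np.isfinite(self.times).all() or not np.isfinite(self.intensities).all():
            raise ValidationError(f"{key}: non-finite values")
        if abs(self.times[0]) > 1e-9:
            raise ValidationError(f"{key}: time axis must start at 0 s, got {self.times[0]}")
        steps = np.diff(self.times)
        if steps.min() <= 0 or not np.allclose(steps, steps[0], atol=1e-9):
            raise ValidationError(f"{key}: non-uniform time spacing")
        lo, hi = self.intensities.min(), self.intensities.max()
        if lo < 0 or hi > 100:
            raise ValidationError(f"{key}: intensity outside [0, 100] (range {lo}..{hi})")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class VASRecord:
    """One panelist's beany-flavor rating for one material, 0-10 scale."""

    material_id: str
    panelist_id: str
    beany_intensity: float

    def __post_init__(self) -> None:
        self.beany_intensity = float(self.beany_intensity)
        if not 0.0 <= self.beany_intensity <= 10.0:
            raise ValidationError(
                f"VAS rating for ({self.material_id}, {self.panelist_id}) "
                f"out of range [0, 10]: {self.beany_intensity}"
            )


def _EXACT_FLOAT(v) -> str:
    # shortest representation that round-trips the exact binary value
    return repr(float(v))


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_curves(path) -> list[TICurve]:
    """Read ``curves.csv`` into validated :class:`TICurve` objects.

    Rows are grouped by (material, panelist, replicate) and sorted by time
    within each group before validation.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, CURVE_COLUMNS, path)
    curves = []
    for (mat, pan, rep), grp in df.groupby(
        ["material_id", "panelist_id", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_s")
        curves.append(
            TICurve(str(mat), str(pan), int(rep),
                    grp["time_s"].to_numpy(), grp["intensity"].to_numpy())
        )
    return curves


def write_curves(curves: Iterable[TICurve], path) -> None:
    """Write curves in canonical order: columns as in ``CURVE_COLUMNS``,
    groups sorted by (material, panelist, replicate), rows by time."""
    curves = sorted(curves, key=lambda c: (c.material_id, c.panelist_id, c.replicate))
    frames = [
        pd.DataFrame(
            {
                "material_id": c.material_id,
                "panelist_id": c.panelist_id,
                "replicate": c.replicate,
                "time_s": c.times,
                "intensity": c.intensities,
            }
        )
        for c in curves
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(CURVE_COLUMNS))
    )
    out.to_csv(path, index=False, float_format=_EXACT_FLOAT)


def read_materials(path) -> list[MaterialInfo]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, MATERIAL_COLUMNS, path)
    mats = [
        MaterialInfo(str(r.material_id), str(r.name), str(r.mtype),
                     "" if pd.isna(r.category) else str(r.category))
        for r in df.itertuples()
    ]
    ids = [m.material_id for m in mats]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate material_id values: {sorted(dupes)}")
    return mats


def write_materials(materials: Iterable[MaterialInfo], path) -> None:
    pd.DataFrame(
        [(m.material_id, m.name, m.mtype, m.category) for m in materials],
        columns=list(MATERIAL_COLUMNS),
    ).to_csv(path, index=False)


def read_vas(path) -> list[VASRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, VAS_COLUMNS, path)
    return [
        VASRecord(str(r.material_id), str(r.panelist_id), float(r.beany_intensity))
        for r in df.itertuples()
    ]


def write_vas(records: Iterable[VASRecord], path) -> None:
    pd.DataFrame(
        [(r.material_id, r.panelist_id, r.beany_intensity) for r in records],
        columns=list(VAS_COLUMNS),
    ).to_csv(path, index=False)


def write_parameter_matrix(matrix, path) -> None:
    """Write a ParameterMatrix as ``material_id`` + parameter columns."""
    matrix.data.to_csv(path, index=True, index_label="material_id",
                       float_format=_EXACT_FLOAT)


def read_parameter_matrix(path, standardized: bool = False):
    """Read ``params.csv`` back into a :class:`timask.stats.ParameterMatrix`."""
    from .stats import ParameterMatrix  # deferred: stats does not import io

    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("material_id",), path)
    df = df.set_index("material_id")
    df.index = df.index.astype(str)
    unknown = [c for c in df.columns if c not in PARAMETER_NAMES]
    if unknown:
        raise FormatError(f"{path}: unknown parameter columns {unknown}")
    return ParameterMatrix(df, standardized=standardized)
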