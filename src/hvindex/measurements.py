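"""Geometry-derived quantities for venous-graft angiography tables.

A graft cohort is a tidy table with one row per animal x timepoint carrying
the raw catheterization measurements: the smallest internal graft diameter
seen on angiography (mm), the IVC-HV junction angle (degrees), and peak
right-atrial / distal-IVC pressures (mmHg).  Everything downstream runs on
three derived quantities:

* least estimated area  — circular cross-section from the smallest internal
  diameter, ``pi * (d_min / 2)**2`` (mm^2);
* HV index              — junction angle divided by that area (deg/mm^2), a
  single score combining morphometry (narrowing widens the denominator's
  deficit) and congestion (venous distension opens the angle);
* pressure gradient     — peak distal-IVC minus peak right-atrial pressure
  (mmHg), the invasive reference the HV index is meant to track.

The ``native`` timepoint denotes the separate untreated control cohort; it is
never month 0 of an implanted animal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TIMEPOINTS",
    "MeasurementRecord",
    "CohortTable",
    "CohortValidationError",
    "least_estimated_area",
    "hv_index",
    "pressure_gradient",
    "read_measurements",
    "write_measurements",
]

#: Valid timepoint labels, in study order.  Post-implant labels are months.
TIMEPOINTS = ("native", "0.5", "1", "3", "6", "12")

REQUIRED_COLUMNS = (
    "animal_id",
    "timepoint",
    "d_min_mm",
    "angle_deg",
    "p_ra_mmhg",
    "p_distal_mmhg",
)
OPTIONAL_COLUMNS = ("p_mid_mmhg",)
DERIVED_COLUMNS = ("area_mm2", "hv_index", "gradient_mmhg")


class CohortValidationError(ValueError):
    """Raised when a measurement table violates the cohort schema.

    ``problems`` lists one human-readable message per offending row or rule.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid measurement table:\n  " + "\n  ".join(self.problems)
        )


def least_estimated_area(d_min):
    """Circular cross-sectional area from the smallest internal diameter.

    Parameters
    ----------
    d_min : float or array-like
        Smallest internal graft diameter on angiography, mm.  Must be > 0.

    Returns
    -------
    float or ndarray
        ``pi * (d_min / 2)**2`` in mm^2.
    """
    d = np.asarray(d_min, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        bad = np.flatnonzero(~(np.isfinite(d) & (d > 0)))
        raise ValueError(
            f"diameter must be finite and > 0 mm; offending entries at {bad.tolist()}"
        )
    area = math.pi * (d / 2.0) ** 2
    return float(area) if np.isscalar(d_min) else area


def hv_index(angle, d_min):
    """HV index: IVC-HV junction angle over the least estimated area.

    Parameters
    ----------
    angle : float or array-like
        Junction angle in degrees, strictly inside (0, 180).
    d_min : float or array-like
        Smallest internal diameter, mm, > 0.

    Returns
    -------
    float or ndarray
        ``angle / (pi * (d_min / 2)**2)`` in degrees/mm^2.
    """
    a = np.asarray(angle, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a <= 0) or np.any(a >= 180):
        bad = np.flatnonzero(~(np.isfinite(a) & (a > 0) & (a < 180)))
        raise ValueError(
            f"angle must lie strictly in (0, 180) degrees; offending entries at {bad.tolist()}"
        )
    out = a / least_estimated_area(d_min)
    return float(out) if (np.isscalar(angle) and np.isscalar(d_min)) else out


def pressure_gradient(p_distal, p_ra):
    """Trans-graft pressure gradient: peak distal-IVC minus peak right-atrial.

    Missing pressures propagate as NaN (the record is kept but excluded from
    gradient-based analyses).  Negative gradients are legitimate near-zero
    measurements and are returned as-is.
    """
    pd_ = np.asarray(p_distal, dtype=float)
    pr_ = np.asarray(p_ra, dtype=float)
    out = pd_ - pr_
    return float(out) if (np.isscalar(p_distal) and np.isscalar(p_ra)) else out


def _normalize_timepoint(value) -> str:
    """Map a raw timepoint cell to a canonical label, or raise ValueError."""
    if isinstance(value, str):
        s = value.strip().lower()
        if s == "native":
            return "native"
        try:
            value = float(s)
        except ValueError:
            raise ValueError(f"unknown timepoint label {value!r}")
    v = float(value)
    for label in TIMEPOINTS[1:]:
        if math.isclose(v, float(label)):
            return label
    raise ValueError(f"unknown timepoint {value!r}; expected one of {TIMEPOINTS}")


@dataclass(frozen=True)
class MeasurementRecord:
    """One animal x timepoint observation with its derived quantities."""

    animal_id: str
    timepoint: str
    d_min: float
    angle: float
    p_ra: float | None = None
    p_distal: float | None = None
    p_mid: float | None = None

    @property
    def area(self) -> float:
        return least_estimated_area(self.d_min)

    @property
    def hv_index(self) -> float:
        return hv_index(self.angle, self.d_min)

    @property
    def gradient(self) -> float:
        if self.p_distal is None or self.p_ra is None:
            return float("nan")
        return pressure_gradient(self.p_distal, self.p_ra)

    def as_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "timepoint": self.timepoint,
            "d_min_mm": self.d_min,
            "angle_deg": self.angle,
            "p_ra_mmhg": np.nan if self.p_ra is None else self.p_ra,
            "p_distal_mmhg": np.nan if self.p_distal is None else self.p_distal,
            "p_mid_mmhg": np.nan if self.p_mid is None else self.p_mid,
        }


class CohortTable:
    """Validated cohort of measurement records with derived columns.

    Wraps a :class:`pandas.DataFrame` with one row per animal x timepoint.
    On construction the table is validated (schema, positive diameters,
    angles in (0, 180), unique keys, native animals only at "native") and the
    derived columns ``area_mm2``, ``hv_index`` and ``gradient_mmhg`` are
    (re)computed from the raw measurements.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "observed",
                 seed: int | None = None):
        if provenance not in ("observed", "synthetic"):
            raise ValueError("provenance must be 'observed' or 'synthetic'")
        self.provenance = provenance
        self.seed = seed
        self._df = self._validate_and_derive(df)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[MeasurementRecord],
                     provenance: str = "observed",
                     seed: int | None = None) -> "CohortTable":
        df = pd.DataFrame([r.as_dict() for r in records])
        return cls(df, provenance=provenance, seed=seed)

    @staticmethod
    def _validate_and_derive(df: pd.DataFrame) -> pd.DataFrame:
        problems: list[str] = []
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError([f"missing required columns {missing}"])

        df = df.copy().reset_index(drop=True)
        if "p_mid_mmhg" not in df.columns:
            df["p_mid_mmhg"] = np.nan

        tp: list[str] = []
        for i, raw in enumerate(df["timepoint"]):
            try:
                tp.append(_normalize_timepoint(raw))
            except ValueError as exc:
                problems.append(f"row {i}: {exc}")
                tp.append("native")  # placeholder; table is rejected anyway
        df["timepoint"] = pd.Categorical(tp, categories=TIMEPOINTS, ordered=True)
        df["animal_id"] = df["animal_id"].astype(str)

        for col in ("d_min_mm", "angle_deg", "p_ra_mmhg", "p_distal_mmhg",
                    "p_mid_mmhg"):
            df[col] = pd.to_numeric(df[col], errors="coerce")

        bad_d = df.index[~(np.isfinite(df["d_min_mm"]) & (df["d_min_mm"] > 0))]
        for i in bad_d:
            problems.append(
                f"row {i} (animal {df.at[i, 'animal_id']}): nonpositive or "
                f"missing diameter {df.at[i, 'd_min_mm']!r}"
            )
        bad_a = df.index[~(np.isfinite(df["angle_deg"])
                           & (df["angle_deg"] > 0) & (df["angle_deg"] < 180))]
        for i in bad_a:
            problems.append(
                f"row {i} (animal {df.at[i, 'animal_id']}): angle "
                f"{df.at[i, 'angle_deg']!r} outside (0, 180) degrees"
            )

        dup = df.duplicated(subset=["animal_id", "timepoint"], keep=False)
        if dup.any():
            for i in df.index[dup]:
                problems.append(
                    f"row {i}: duplicate (animal_id, timepoint) = "
                    f"({df.at[i, 'animal_id']}, {df.at[i, 'timepoint']})"
                )

        native_ids = set(df.loc[df["timepoint"] == "native", "animal_id"])
        post = df["timepoint"] != "native"
        crossover = native_ids & set(df.loc[post, "animal_id"])
        if crossover:
            problems.append(
                f"native control animals also appear post-implant: {sorted(crossover)}"
            )

        if problems:
            raise CohortValidationError(problems)

        df["area_mm2"] = least_estimated_area(df["d_min_mm"].to_numpy())
        df["hv_index"] = hv_index(df["angle_deg"].to_numpy(),
                                  df["d_min_mm"].to_numpy())
        df["gradient_mmhg"] = pressure_gradient(
            df["p_distal_mmhg"].to_numpy(), df["p_ra_mmhg"].to_numpy())

        n_missing = int(np.isnan(df["gradient_mmhg"]).sum())
        if n_missing:
            logger.warning(
                "%d record(s) lack a pressure pair; excluded from "
                "gradient-based analyses", n_missing)
        n_neg = int((df["gradient_mmhg"] < 0).sum())
        if n_neg:
            logger.info("%d record(s) carry a negative gradient (retained)",
                        n_neg)
        return df

    # -- access -----------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """The validated table including derived columns (a copy)."""
        return self._df.copy()

    @property
    def n_records(self) -> int:
        return len(self._df)

    def __len__(self) -> int:
        return len(self._df)

    def timepoints(self) -> list[str]:
        """Timepoint labels present, in study order."""
        present = set(self._df["timepoint"].astype(str))
        return [t for t in TIMEPOINTS if t in present]

    def values(self, quantity: str, timepoint: str | None = None) -> np.ndarray:
        """Values of one column, optionally restricted to one timepoint."""
        df = self._df
        if timepoint is not None:
            df = df[df["timepoint"] == timepoint]
        return df[quantity].to_numpy(dtype=float)


def read_measurements(path: str | Path, provenance: str = "observed") -> CohortTable:
    """Read a cohort CSV (snake_case headers, '.' decimal) and validate it."""
    df = pd.read_csv(path)
    try:
        table = CohortTable(df, provenance=provenance)
    except CohortValidationError as exc:
        raise CohortValidationError(
            [f"{path}: {p}" for p in exc.problems]) from None
    logger.info("read %d records from %s", table.n_records, path)
    return table


def write_measurements(table: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV with the derived columns appended."""
    cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS) + list(DERIVED_COLUMNS)
    table.df[cols].to_csv(path, index=False)
    logger.info("wrote %d records to %s", table.n_records, path)
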