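"""Virtual-simulation grid: posterior slope over SPOI x correction angle.

Runs the deterministic sweep — four sagittal osteotomy inclinations
(20°, 10°, 0°, −10°) by correction angles 0°–30° in 5° steps on the
10°-slope column — and reproduces the published virtual-simulation
table cell for cell.  Two interchangeable backends are exposed: the
analytic closed form and the explicit Rodrigues rotation pipeline.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .geometry import OsteotomyPlan, closed_form_pts, opened_slope_direction, sagittal_slope_angle

__all__ = [
    "DEFAULT_ALPHA0",
    "DEFAULT_SPOIS",
    "DEFAULT_CORRECTIONS",
    "SlopeTable",
    "run_grid",
    "compare_to_reference",
    "reference_table",
    "write_grid_csv",
    "write_grid_json",
]

DEFAULT_ALPHA0 = 10.0
DEFAULT_SPOIS = (20.0, 10.0, 0.0, -10.0)
DEFAULT_CORRECTIONS = tuple(float(t) for t in range(0, 35, 5))


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for table cells)."""
    f = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * f + 0.5) / f)


@dataclass(frozen=True)
class SlopeTable:
    """Grid of posterior-slope values: rows = correction angle, cols = SPOI."""

    corrections: tuple[float, ...]
    spois: tuple[float, ...]
    values: np.ndarray  # shape (len(corrections), len(spois)), degrees
    rounded: bool = True
    alpha0: float = DEFAULT_ALPHA0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.corrections), len(self.spois)):
            raise ValueError("values shape does not match the grid")
        object.__setattr__(self, "values", v)

    def cell(self, correction: float, spoi: float) -> float:
        i = self.corrections.index(correction)
        j = self.spois.index(spoi)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        cols = [_spoi_col(s) for s in self.spois]
        return pd.DataFrame(self.values, index=pd.Index(self.corrections, name="correction_deg"), columns=cols)


def _spoi_col(spoi: float) -> str:
    return f"spoi_{spoi:g}"


def run_grid(
    alpha0: float = DEFAULT_ALPHA0,
    spois=DEFAULT_SPOIS,
    corrections=DEFAULT_CORRECTIONS,
    decimals: int | None = 1,
    backend: Literal["closed_form", "rodrigues"] = "closed_form",
) -> SlopeTable:
    """Compute the slope grid.

    ``decimals=None`` keeps unrounded values; otherwise cells are rounded
    half-away-from-zero to that many decimals (the published table uses 1).
    """
    spois = tuple(float(s) for s in spois)
    corrections = tuple(float(t) for t in corrections)
    if not spois or not corrections:
        raise ValueError("SPOI and correction lists must be non-empty")
    vals = np.empty((len(corrections), len(spois)))
    for i, th in enumerate(corrections):
        for j, phi in enumerate(spois):
            if backend == "closed_form":
                a = closed_form_pts(alpha0, phi, th)
            elif backend == "rodrigues":
                plan = OsteotomyPlan(spoi=phi, correction=th)
                a = sagittal_slope_angle(opened_slope_direction(alpha0, plan))
            else:
                raise ValueError(f"unknown backend {backend!r}")
            vals[i, j] = round_half_away(a, decimals) if decimals is not None else a
    return SlopeTable(corrections=corrections, spois=spois, values=vals,
                      rounded=decimals is not None, alpha0=alpha0)


def compare_to_reference(table: SlopeTable, reference: SlopeTable, atol: float = 0.05):
    """Cell-by-cell diff of two grids.

    Returns a list of ``(correction, spoi, computed, reference, delta)``
    for cells differing by more than ``atol`` (default: below the 0.1°
    print resolution).  An empty list means exact reproduction.
    """
    if table.corrections != reference.corrections or table.spois != reference.spois:
        raise ValueError("grid mismatch: tables cover different cells")
    diff = []
    for i, th in enumerate(table.corrections):
        for j, phi in enumerate(table.spois):
            a, b = float(table.values[i, j]), float(reference.values[i, j])
            if abs(a - b) > atol:
                diff.append((th, phi, a, b, a - b))
    return diff


def reference_table() -> SlopeTable:
    """The packaged published virtual-simulation table (0.1° cells)."""
    with importlib.resources.files("owhto.data").joinpath("table1_reference.csv").open() as fh:
        df = pd.read_csv(fh)
    corrections = tuple(float(t) for t in df["correction_deg"])
    spois = tuple(float(c.split("_", 1)[1]) for c in df.columns[1:])
    return SlopeTable(corrections=corrections, spois=spois,
                      values=df.iloc[:, 1:].to_numpy(float), rounded=True)


def write_grid_csv(table: SlopeTable, path) -> None:
    """Fixed-point CSV, rows = correction angle, columns = SPOI."""
    df = table.to_frame()
    df.to_csv(path, float_format="%.1f" if table.rounded else "%.12g")


def write_grid_json(table: SlopeTable, path) -> None:
    """JSON with unrounded cell values and grid metadata."""
    payload = {
        "alpha0_deg": table.alpha0,
        "corrections_deg": list(table.corrections),
        "spois_deg": list(table.spois),
        "rounded": table.rounded,
        "slope_deg": table.values.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
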