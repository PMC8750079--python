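"""Readers and writers: CSV tables, MetaImage dose grids, JSON plans."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .dose import DoseGrid
from .sobp import SOBPPlan

FIELD_TABLE_COLUMNS = ["configuration", "slit_offset_mm", "energy_MeV", "field_T"]


def write_field_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=FIELD_TABLE_COLUMNS,
                 float_format="%.6g")


def read_field_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FIELD_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"field table misses columns {sorted(missing)}")
    return df


def write_metrics(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_profile(x: np.ndarray, dose: np.ndarray, path) -> None:
    pd.DataFrame({"x_mm": x, "dose": dose}).to_csv(path, index=False)


def write_dose_grid(grid: DoseGrid, path) -> None:
    """Write a dose grid as MetaImage (.mhd + .raw sidecar).

    The array is stored with SimpleITK's (z, y, x) memory order; voxel
    spacing and the physical origin (voxel-center convention) go in the
    header, so a round trip restores values bit-exactly and geometry
    exactly.
    """
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetSpacing(tuple(float(v) for v in grid.voxel))
    img.SetOrigin((float(grid.voxel[0] / 2 - grid.phantom[0] / 2),
                   float(grid.voxel[1] / 2 - grid.phantom[1] / 2),
                   float(grid.voxel[2] / 2)))
    sitk.WriteImage(img, str(path))


def read_dose_grid(path) -> DoseGrid:
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T
    voxel = tuple(img.GetSpacing())
    origin = img.GetOrigin()
    phantom = (2.0 * (voxel[0] / 2 - origin[0]),
               2.0 * (voxel[1] / 2 - origin[1]),
               values.shape[2] * voxel[2])
    return DoseGrid(values=values, voxel=voxel, phantom=phantom)


def write_plan(plan: SOBPPlan, path, extra: dict | None = None) -> None:
    payload = {"energies_MeV": list(plan.energies),
               "weights_normalized": [float(w) for w in plan.weights],
               "window_mm": list(plan.window)}
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_plan(path) -> SOBPPlan:
    d = json.loads(Path(path).read_text())
    return SOBPPlan(energies=tuple(d["energies_MeV"]),
                    weights=np.array(d["weights_normalized"]),
                    window=tuple(d["window_mm"]))
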