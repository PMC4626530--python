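"""File formats at the package boundary.

Internally everything is SI (m, S/m, A, V); on disk the tabular formats
use the field's bench units — micrometres, nanoamperes, microvolts —
with unit-suffixed column names so conversions happen exactly once,
here.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .electrodes import ElectrodeContact
from .exceptions import GeometryError
from .geometry import LineSource, PointSource, SliceGeometry
from .neural_sources import CompartmentRecording

__all__ = [
    "load_geometry",
    "save_geometry",
    "read_sources",
    "write_sources",
    "read_electrodes",
    "write_electrodes",
    "read_recording",
    "write_recording",
    "write_potentials",
    "read_potentials",
]

UM = 1e-6
NA = 1e-9
UV = 1e-6


def load_geometry(path) -> SliceGeometry:
    """Read slice geometry from YAML or JSON (h_um, sigma_T, sigma_S, ...)."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return geometry_from_dict(data)


def geometry_from_dict(data: dict) -> SliceGeometry:
    known = {"h_um", "sigma_T", "sigma_S", "sigma_G", "n_terms"}
    unknown = set(data) - known
    if unknown:
        raise GeometryError(f"unknown geometry keys: {sorted(unknown)}")
    if "h_um" not in data:
        raise GeometryError("geometry requires h_um")
    return SliceGeometry(
        h=float(data["h_um"]) * UM,
        sigma_T=data.get("sigma_T", 0.3),
        sigma_S=data.get("sigma_S", 1.5),
        sigma_G=float(data.get("sigma_G", 0.0)),
        n_terms=int(data.get("n_terms", 20)),
    )


def geometry_to_dict(geo: SliceGeometry) -> dict:
    return {
        "h_um": geo.h / UM,
        "sigma_T": list(geo.sigma_T),
        "sigma_S": list(geo.sigma_S),
        "sigma_G": geo.sigma_G,
        "n_terms": geo.n_terms,
    }


def save_geometry(path, geo: SliceGeometry) -> None:
    Path(path).write_text(yaml.safe_dump(geometry_to_dict(geo)))


def read_sources(path) -> list[PointSource | LineSource]:
    """Sources table: x0_um,y0_um,z0_um,x1_um,y1_um,z1_um,I_nA.

    A row with identical start and end coordinates is a point source.
    """
    df = pd.read_csv(path)
    required = ["x0_um", "y0_um", "z0_um", "x1_um", "y1_um", "z1_um", "I_nA"]
    missing = set(required) - set(df.columns)
    if missing:
        raise GeometryError(f"sources table missing columns: {sorted(missing)}")
    out: list[PointSource | LineSource] = []
    for row in df.itertuples(index=False):
        start = (row.x0_um * UM, row.y0_um * UM, row.z0_um * UM)
        end = (row.x1_um * UM, row.y1_um * UM, row.z1_um * UM)
        current = row.I_nA * NA
        if start == end:
            out.append(PointSource(start, current))
        else:
            out.append(LineSource(start, end, current))
    return out


def write_sources(path, sources) -> None:
    rows = []
    for s in sources:
        if isinstance(s, PointSource):
            start = end = s.position
        else:
            start, end = s.start, s.end
        rows.append(
            {
                "x0_um": start[0] / UM, "y0_um": start[1] / UM, "z0_um": start[2] / UM,
                "x1_um": end[0] / UM, "y1_um": end[1] / UM, "z1_um": end[2] / UM,
                "I_nA": s.current / NA,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_electrodes(path, m: int = 100, seed: int = 0) -> list[ElectrodeContact]:
    """Electrode layout CSV: name,x_um,y_um,radius_um."""
    df = pd.read_csv(path)
    missing = {"name", "x_um", "y_um", "radius_um"} - set(df.columns)
    if missing:
        raise GeometryError(f"electrode table missing columns: {sorted(missing)}")
    return [
        ElectrodeContact(
            x=row.x_um * UM, y=row.y_um * UM, radius=row.radius_um * UM,
            m=m, seed=seed + i, name=str(row.name_col),
        )
        for i, row in enumerate(
            df.rename(columns={"name": "name_col"}).itertuples(index=False)
        )
    ]


def write_electrodes(path, electrodes) -> None:
    pd.DataFrame(
        {
            "name": [e.name for e in electrodes],
            "x_um": [e.x / UM for e in electrodes],
            "y_um": [e.y / UM for e in electrodes],
            "radius_um": [e.radius / UM for e in electrodes],
        }
    ).to_csv(path, index=False)


def write_recording(path, rec: CompartmentRecording) -> None:
    """Compartment recording to HDF5 (.h5/.hdf5) or wide CSV.

    HDF5 layout: coords_start, coords_end (n x 3, um), imem (n x n_t, nA),
    t (s), cell_id (n).  The CSV fallback stores one compartment per row
    with imem columns named ``i_nA@<t>``.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("coords_start", data=rec.coords_start / UM)
            f.create_dataset("coords_end", data=rec.coords_end / UM)
            f.create_dataset("imem", data=rec.imem / NA)
            f.create_dataset("t", data=rec.t)
            f.create_dataset("cell_id", data=rec.cell_id)
        return
    cols = {
        "x0_um": rec.coords_start[:, 0] / UM,
        "y0_um": rec.coords_start[:, 1] / UM,
        "z0_um": rec.coords_start[:, 2] / UM,
        "x1_um": rec.coords_end[:, 0] / UM,
        "y1_um": rec.coords_end[:, 1] / UM,
        "z1_um": rec.coords_end[:, 2] / UM,
        "cell_id": rec.cell_id,
    }
    for k, tk in enumerate(rec.t):
        cols[f"i_nA@{tk:.9g}"] = rec.imem[:, k] / NA
    pd.DataFrame(cols).to_csv(path, index=False)


def read_recording(path) -> CompartmentRecording:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            return CompartmentRecording(
                coords_start=f["coords_start"][...] * UM,
                coords_end=f["coords_end"][...] * UM,
                imem=f["imem"][...] * NA,
                t=f["t"][...],
                cell_id=f["cell_id"][...] if "cell_id" in f else None,
            )
    df = pd.read_csv(path)
    tcols = [c for c in df.columns if c.startswith("i_nA@")]
    if not tcols:
        raise GeometryError("recording CSV has no i_nA@<t> current columns")
    t = np.array([float(c.split("@", 1)[1]) for c in tcols])
    order = np.argsort(t)
    return CompartmentRecording(
        coords_start=df[["x0_um", "y0_um", "z0_um"]].to_numpy() * UM,
        coords_end=df[["x1_um", "y1_um", "z1_um"]].to_numpy() * UM,
        imem=df[tcols].to_numpy()[:, order] * NA,
        t=t[order],
        cell_id=df["cell_id"].to_numpy() if "cell_id" in df else None,
    )


def write_potentials(path, phi: np.ndarray, electrodes, t=None) -> None:
    """Potentials (V internally) to HDF5 or CSV in uV.

    HDF5: datasets ``phi`` (n_elec x n_t, uV), ``t`` (s) and an electrode
    table; CSV: one electrode per row, columns ``phi_uV@<t>`` (or a single
    ``phi_uV`` for snapshots).
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("phi", data=phi / UV)
            if t is not None:
                f.create_dataset("t", data=np.asarray(t))
            f.create_dataset("x_um", data=[e.x / UM for e in electrodes])
            f.create_dataset("y_um", data=[e.y / UM for e in electrodes])
        return
    cols = {
        "name": [e.name for e in electrodes],
        "x_um": [e.x / UM for e in electrodes],
        "y_um": [e.y / UM for e in electrodes],
    }
    if phi.shape[1] == 1 and t is None:
        cols["phi_uV"] = phi[:, 0] / UV
    else:
        tvec = np.arange(phi.shape[1]) if t is None else np.asarray(t)
        for k, tk in enumerate(tvec):
            cols[f"phi_uV@{tk:.9g}"] = phi[:, k] / UV
    pd.DataFrame(cols).to_csv(path, index=False)


def read_potentials(path):
    """Read a potentials file back; returns (phi_volts, x_m, y_m, t_or_None)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            phi = f["phi"][...] * UV
            t = f["t"][...] if "t" in f else None
            return phi, f["x_um"][...] * UM, f["y_um"][...] * UM, t
    df = pd.read_csv(path)
    if "phi_uV" in df.columns:
        phi = df[["phi_uV"]].to_numpy() * UV
        t = None
    else:
        tcols = [c for c in df.columns if c.startswith("phi_uV@")]
        if not tcols:
            raise GeometryError("potentials CSV has no phi_uV columns")
        t = np.array([float(c.split("@", 1)[1]) for c in tcols])
        order = np.argsort(t)
        phi = df[tcols].to_numpy()[:, order] * UV
        t = t[order]
    return phi, df["x_um"].to_numpy() * UM, df["y_um"].to_numpy() * UM, t
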