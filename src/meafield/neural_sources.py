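"""From multicompartment transmembrane currents to MEA potential series.

The forward problem is linear and the geometry is fixed over a recording,
so the mapping factorises into a time-independent matrix M (electrodes x
compartments, V/A) with potential time series phi(t) = M @ I(t).
Compartments can enter either as point sources at the axis midpoints or
as uniform line sources along the axes, recorded by ideal point
electrodes or surface-averaged disc contacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .electrodes import ElectrodeContact, disc_average
from .exceptions import GeometryError
from .forward import moi_line_mea_plane, moi_point_mea_plane
from .geometry import LineSource, PointSource, SliceGeometry

__all__ = [
    "CompartmentRecording",
    "squeeze_transform",
    "forward_matrix",
    "compute_mea_timeseries",
]

logger = logging.getLogger(__name__)


@dataclass
class CompartmentRecording:
    """Compartment geometry plus transmembrane-current time series.

    coords_start, coords_end : (n_comp, 3) segment endpoints, metres
    imem : (n_comp, n_t) transmembrane currents, amperes
    t : (n_t,) time vector, seconds
    cell_id : (n_comp,) integer cell identifier per compartment
    """

    coords_start: np.ndarray
    coords_end: np.ndarray
    imem: np.ndarray
    t: np.ndarray
    cell_id: np.ndarray = None

    def __post_init__(self):
        self.coords_start = np.asarray(self.coords_start, dtype=float)
        self.coords_end = np.asarray(self.coords_end, dtype=float)
        self.imem = np.atleast_2d(np.asarray(self.imem, dtype=float))
        self.t = np.asarray(self.t, dtype=float)
        n = self.coords_start.shape[0]
        if self.coords_start.shape != (n, 3) or self.coords_end.shape != (n, 3):
            raise GeometryError("coords_start/coords_end must have shape (n, 3)")
        if self.imem.shape != (n, self.t.size):
            raise GeometryError(
                f"imem shape {self.imem.shape} does not match "
                f"{n} compartments x {self.t.size} time steps"
            )
        if self.cell_id is None:
            self.cell_id = np.zeros(n, dtype=int)
        else:
            self.cell_id = np.asarray(self.cell_id, dtype=int)
            if self.cell_id.shape != (n,):
                raise GeometryError("cell_id must have shape (n,)")

    @property
    def n_compartments(self) -> int:
        return self.coords_start.shape[0]

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.coords_start + self.coords_end)

    def check_current_conservation(self, rtol: float = 1e-3) -> bool:
        """Kirchhoff sanity check: per cell and time step, currents sum ~0.

        Sums are taken with exact compensated summation (math.fsum).
        Violations are logged, not fatal — simulator exports carry numeric
        noise.  Returns True if every cell passes at every time step.
        """
        ok = True
        for cid in np.unique(self.cell_id):
            rows = self.imem[self.cell_id == cid]
            scale = np.max(np.sum(np.abs(rows), axis=0))
            if scale == 0:
                continue
            residual = max(
                abs(math.fsum(rows[:, k])) for k in range(rows.shape[1])
            )
            if residual > rtol * scale:
                logger.warning(
                    "cell %d violates current conservation: residual %.3e "
                    "(%.2e of total current)", cid, residual, residual / scale,
                )
                ok = False
        return ok


def squeeze_transform(
    rec: CompartmentRecording,
    factor: float,
    axis: str = "z",
    pivot: float | None = None,
    geometry: SliceGeometry | None = None,
) -> CompartmentRecording:
    """Compress compartment coordinates along one axis about a pivot.

    Mimics fitting a tall morphology into a thin slice after the neural
    simulation: coordinates along ``axis`` are replaced by
    pivot + (c - pivot)/factor, currents are untouched.  ``pivot``
    defaults to the first compartment's coordinate of each cell (the soma
    by convention).  If ``geometry`` is given, compartments falling
    outside the slice interior afterwards raise an error listing the
    offenders.
    """
    if not factor > 0:
        raise GeometryError("squeeze factor must be positive")
    ax = {"x": 0, "y": 1, "z": 2}.get(axis)
    if ax is None:
        raise GeometryError(f"axis must be one of x, y, z, got {axis!r}")

    start = rec.coords_start.copy()
    end = rec.coords_end.copy()
    for cid in np.unique(rec.cell_id):
        mask = rec.cell_id == cid
        p = pivot if pivot is not None else start[mask][0, ax]
        start[mask, ax] = p + (start[mask, ax] - p) / factor
        end[mask, ax] = p + (end[mask, ax] - p) / factor

    out = CompartmentRecording(start, end, rec.imem.copy(), rec.t.copy(),
                               rec.cell_id.copy())
    if geometry is not None:
        z = np.concatenate([start[:, 2], end[:, 2]])
        bad = np.where((z <= 0) | (z >= geometry.h))[0] % rec.n_compartments
        if bad.size:
            raise GeometryError(
                "compartments outside slice after squeeze: "
                f"{sorted(set(bad.tolist()))}"
            )
    return out


def forward_matrix(
    rec: CompartmentRecording,
    electrodes: list[ElectrodeContact],
    geo: SliceGeometry,
    source_mode: str = "line",
    electrode_mode: str = "point",
) -> np.ndarray:
    """(n_electrodes, n_compartments) map from currents (A) to potentials (V).

    source_mode 'point' places a unit point source at each compartment's
    axis midpoint; 'line' spreads it uniformly along the axis (degenerate
    zero-length compartments fall back to points).  electrode_mode 'disc'
    surface-averages over each contact's sample points, 'point' reads at
    the contact centre.
    """
    if source_mode not in ("point", "line"):
        raise ValueError(f"source_mode must be 'point' or 'line', got {source_mode!r}")
    if electrode_mode not in ("point", "disc"):
        raise ValueError(
            f"electrode_mode must be 'point' or 'disc', got {electrode_mode!r}"
        )
    n_comp = rec.n_compartments
    mids = rec.midpoints
    for k in range(n_comp):
        geo.require_inside(rec.coords_start[k, 2], f"compartment {k} start")
        geo.require_inside(rec.coords_end[k, 2], f"compartment {k} end")

    matrix = np.empty((len(electrodes), n_comp))
    centres = np.array([[e.x, e.y] for e in electrodes])
    for k in range(n_comp):
        length = np.linalg.norm(rec.coords_end[k] - rec.coords_start[k])
        if source_mode == "point" or length == 0.0:
            src = PointSource(tuple(mids[k]), 1.0)
            direct = moi_point_mea_plane
        else:
            src = LineSource(tuple(rec.coords_start[k]), tuple(rec.coords_end[k]), 1.0)
            direct = moi_line_mea_plane
        if electrode_mode == "point":
            matrix[:, k] = direct(src, centres, geo)
        else:
            matrix[:, k] = [disc_average(e, src, geo) for e in electrodes]
    return matrix


def compute_mea_timeseries(rec: CompartmentRecording, matrix: np.ndarray) -> np.ndarray:
    """Potential time series (n_electrodes, n_t) in volts: matrix @ imem."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != rec.n_compartments:
        raise GeometryError(
            f"matrix shape {matrix.shape} incompatible with "
            f"{rec.n_compartments} compartments"
        )
    return matrix @ rec.imem
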