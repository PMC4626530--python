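"""Finite-extent disc electrodes and MEA lead-field maps.

A real MEA contact reads approximately the average potential over its
exposed metal surface.  The disc-electrode model therefore averages the
point-electrode image-series potential over sample points drawn with
uniform planar density on the contact disc; sample points are fixed per
contact (seeded) so readings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError
from .forward import moi_line_mea_plane, moi_point_mea_plane
from .geometry import LineSource, PointSource, SliceGeometry

__all__ = ["ElectrodeContact", "LeadField", "disc_average", "lead_field_map", "mea_grid"]


@dataclass(frozen=True)
class ElectrodeContact:
    """A planar disc contact in the MEA plane.

    centre (x, y) and radius in metres; ``radius = 0`` denotes an ideal
    point electrode.  ``m`` surface sample points are drawn once from
    ``seed`` with uniform planar density (radius * sqrt(u) polar sampling).
    """

    x: float
    y: float
    radius: float = 0.0
    m: int = 100
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if self.radius < 0:
            raise GeometryError("electrode radius must be >= 0")
        if self.m < 1:
            raise GeometryError("number of surface samples m must be >= 1")

    @property
    def centre(self) -> tuple[float, float]:
        return (self.x, self.y)

    def sample_points(self) -> np.ndarray:
        """(m, 2) fixed sample points on the disc; the centre if radius = 0."""
        if self.radius == 0.0:
            return np.array([[self.x, self.y]])
        rng = np.random.default_rng(self.seed)
        u = rng.random(self.m)
        theta = rng.random(self.m) * 2.0 * np.pi
        r = self.radius * np.sqrt(u)
        return np.column_stack([self.x + r * np.cos(theta), self.y + r * np.sin(theta)])


@dataclass
class LeadField:
    """Potential per unit source current as a function of source position."""

    electrode: ElectrodeContact
    positions: np.ndarray  # (n, 3) source positions, metres
    values: np.ndarray  # (n,) V per A


def _eval_source(src, obs_xy, geo: SliceGeometry):
    if isinstance(src, PointSource):
        return moi_point_mea_plane(src, obs_xy, geo)
    if isinstance(src, LineSource):
        return moi_line_mea_plane(src, obs_xy, geo)
    raise TypeError(f"unsupported source type {type(src).__name__}")


def disc_average(contact: ElectrodeContact, src, geo: SliceGeometry) -> float:
    """Surface-averaged potential recorded by a disc contact.

    Mean of the point-electrode MoI potential over the contact's fixed
    sample points; reduces to the point-electrode value for radius = 0.
    """
    pts = contact.sample_points()
    return float(np.mean(_eval_source(src, pts, geo)))


def lead_field_map(
    contact: ElectrodeContact,
    source_positions,
    geo: SliceGeometry,
    normalize_height: float | None = None,
) -> LeadField:
    """Lead field of one contact over a grid of point-source positions.

    Each value is the recorded potential for a unit (1 A) point source at
    that position.  If ``normalize_height`` is given, values are divided
    by the lead field of an on-centre source at that height (the
    conventional reference is 1 um).
    """
    pos = np.asarray(source_positions, dtype=float)
    if pos.size == 0:
        raise GeometryError("empty source-position grid")
    pos = pos.reshape(-1, 3)
    values = np.array(
        [disc_average(contact, PointSource(tuple(p), 1.0), geo) for p in pos]
    )
    if normalize_height is not None:
        ref = disc_average(
            contact, PointSource((contact.x, contact.y, normalize_height), 1.0), geo
        )
        values = values / ref
    return LeadField(electrode=contact, positions=pos, values=values)


def mea_grid(
    nx: int = 30,
    ny: int = 10,
    pitch_x: float = 103e-6,
    pitch_y: float = 111e-6,
    radius: float = 0.0,
    m: int = 100,
    seed: int = 0,
) -> list[ElectrodeContact]:
    """Rectangular MEA layout centred on the origin.

    Defaults mirror a 30 x 10 array at 103/111 um pitch spanning roughly
    3000 x 1000 um^2.
    """
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pitch_x
    ys = (np.arange(ny) - (ny - 1) / 2.0) * pitch_y
    contacts = []
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            contacts.append(
                ElectrodeContact(
                    x=float(x), y=float(y), radius=radius, m=m,
                    seed=seed + i + nx * j, name=f"e{i}_{j}",
                )
            )
    return contacts
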