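"""Domain types for the layered MEA slice geometry.

Coordinate convention: z = 0 is the MEA chip plane, z increases into the
slice; the tissue occupies 0 < z < h with an (infinitely thick) bath above
and the chip substrate below.  x is the anisotropy principal axis (the
apical-dendrite direction in cortical slices).  All quantities are SI
internally: metres, siemens per metre, amperes, volts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError

__all__ = [
    "SliceGeometry",
    "PointSource",
    "LineSource",
    "ObservationPoint",
    "reflection_coefficient",
]


def reflection_coefficient(sigma_1: float, sigma_2: float) -> float:
    """Image-source scaling factor across a planar conductivity jump.

    W = (sigma_1 - sigma_2) / (sigma_1 + sigma_2), where ``sigma_1`` is the
    conductivity of the medium containing the real source and ``sigma_2``
    the conductivity on the far side of the interface.  Always in [-1, 1].
    """
    if sigma_1 < 0 or sigma_2 < 0:
        raise GeometryError("conductivities must be non-negative")
    total = sigma_1 + sigma_2
    if total == 0:
        raise GeometryError(
            "reflection coefficient undefined for two non-conducting media"
        )
    return (sigma_1 - sigma_2) / total


def _as_triple(sigma, name: str) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(sigma, dtype=float))
    if arr.size == 1:
        s = float(arr[0])
        return (s, s, s)
    if arr.size == 3:
        return (float(arr[0]), float(arr[1]), float(arr[2]))
    raise GeometryError(f"{name} must be a scalar or a 3-vector, got {sigma!r}")


@dataclass(frozen=True)
class SliceGeometry:
    """Layered volume-conductor parameters of the in vitro MEA set-up.

    Parameters
    ----------
    h : float
        Slice thickness in metres (e.g. 300e-6 for a 300 um slice).
    sigma_T : float or (3,) sequence
        Tissue conductivity in S/m; a scalar means isotropic, a triple is
        (sigma_Tx, sigma_Ty, sigma_Tz).
    sigma_S : float or (3,) sequence
        Bath (saline) conductivity in S/m.
    sigma_G : float
        Substrate (chip) conductivity in S/m; the default 0 models a fully
        insulating MEA chip.
    n_terms : int
        Truncation order of the image-source series.  The series converges
        geometrically with ratio |W_TS| so 20 terms are ample for saline
        over tissue (|W_TS| = 2/3).
    """

    h: float
    sigma_T: tuple[float, float, float] = (0.3, 0.3, 0.3)
    sigma_S: tuple[float, float, float] = (1.5, 1.5, 1.5)
    sigma_G: float = 0.0
    n_terms: int = 20

    def __post_init__(self):
        object.__setattr__(self, "sigma_T", _as_triple(self.sigma_T, "sigma_T"))
        object.__setattr__(self, "sigma_S", _as_triple(self.sigma_S, "sigma_S"))
        if not self.h > 0:
            raise GeometryError(f"slice thickness must be positive, got h={self.h}")
        if any(s < 0 for s in self.sigma_T + self.sigma_S) or self.sigma_G < 0:
            raise GeometryError("conductivities must be non-negative")
        if self.n_terms < 0:
            raise GeometryError("n_terms must be >= 0")

    # -- derived scalars -------------------------------------------------
    @property
    def is_isotropic(self) -> bool:
        return (
            self.sigma_T[0] == self.sigma_T[1] == self.sigma_T[2]
            and self.sigma_S[0] == self.sigma_S[1] == self.sigma_S[2]
        )

    @property
    def sigma_T_scalar(self) -> float:
        if not (self.sigma_T[0] == self.sigma_T[1] == self.sigma_T[2]):
            raise GeometryError("tissue conductivity is anisotropic")
        return self.sigma_T[0]

    @property
    def sigma_S_scalar(self) -> float:
        if not (self.sigma_S[0] == self.sigma_S[1] == self.sigma_S[2]):
            raise GeometryError("saline conductivity is anisotropic")
        return self.sigma_S[0]

    @property
    def alpha_a(self) -> float:
        """Planar tissue anisotropy ratio sigma_Tx / sigma_Ty."""
        if self.sigma_T[1] == 0:
            raise GeometryError("sigma_Ty must be positive to define alpha_a")
        return self.sigma_T[0] / self.sigma_T[1]

    @property
    def W_TG(self) -> float:
        """Reflection coefficient at the tissue-chip interface."""
        return reflection_coefficient(self.sigma_T_scalar, self.sigma_G)

    @property
    def W_TS(self) -> float:
        """Reflection coefficient at the tissue-saline interface."""
        return reflection_coefficient(self.sigma_T_scalar, self.sigma_S_scalar)

    @property
    def W_TS_a(self) -> float:
        """Anisotropic tissue-saline reflection coefficient.

        With matched planar anisotropy in tissue and bath this reduces to
        (sigma_Ty - sigma_Sy) / (sigma_Ty + sigma_Sy).
        """
        self._require_planar_anisotropy()
        return reflection_coefficient(self.sigma_T[1], self.sigma_S[1])

    def _require_planar_anisotropy(self) -> None:
        if self.sigma_T[1] != self.sigma_T[2] or self.sigma_S[1] != self.sigma_S[2]:
            raise GeometryError(
                "the anisotropic formula requires sigma_Ty == sigma_Tz and "
                "sigma_Sy == sigma_Sz"
            )

    def require_inside(self, z: float, what: str = "source") -> None:
        """Require 0 < z < h (strict interior of the slice)."""
        if not (0.0 < z < self.h):
            raise GeometryError(
                f"{what} at z={z} m is outside the slice interior (0, {self.h})"
            )


@dataclass(frozen=True)
class PointSource:
    """A point transmembrane current source inside the slice.

    position = (x', y', z') in metres with 0 < z' < h; current in amperes.
    """

    position: tuple[float, float, float]
    current: float = 1.0

    def __post_init__(self):
        pos = tuple(float(c) for c in self.position)
        if len(pos) != 3:
            raise GeometryError("position must have three coordinates")
        object.__setattr__(self, "position", pos)

    @property
    def z(self) -> float:
        return self.position[2]


@dataclass(frozen=True)
class LineSource:
    """A finite line source: current spread uniformly along a segment axis.

    Represents a cylindrical neural compartment by the segment from
    ``start`` to ``end`` (metres) carrying total current ``current`` (A).
    """

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    current: float = 1.0

    def __post_init__(self):
        start = tuple(float(c) for c in self.start)
        end = tuple(float(c) for c in self.end)
        if len(start) != 3 or len(end) != 3:
            raise GeometryError("endpoints must have three coordinates")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if self.length == 0:
            raise GeometryError("line source has zero length; use PointSource")

    @property
    def length(self) -> float:
        return float(
            np.linalg.norm(np.asarray(self.end) - np.asarray(self.start))
        )

    @property
    def midpoint(self) -> tuple[float, float, float]:
        return tuple(
            0.5 * (a + b) for a, b in zip(self.start, self.end)
        )


@dataclass(frozen=True)
class ObservationPoint:
    """A field observation point (x, y, z) in metres, 0 <= z <= h."""

    position: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self):
        pos = tuple(float(c) for c in self.position)
        if len(pos) != 3:
            raise GeometryError("position must have three coordinates")
        object.__setattr__(self, "position", pos)
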