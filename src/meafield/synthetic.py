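"""Synthetic inputs for exercising the forward and inverse machinery.

Everything the toolkit consumes can be generated here: an oscillatory
stimulus waveform, toy ball-and-stick compartment recordings with exactly
balanced transmembrane currents, and planar Gaussian CSD scenes with
matched forward-modelled MEA potentials.  Default slice and array
parameters mirror the reference set-up used throughout the package:
h = 300 um, sigma_T = 0.3 S/m, sigma_S = 1.5 S/m, and a 30 x 10
electrode grid at 103/111 um pitch.  All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .electrodes import ElectrodeContact
from .exceptions import GeometryError
from .geometry import SliceGeometry
from .kcsd import _RadialBasisPotential
from .neural_sources import CompartmentRecording

__all__ = [
    "StimulusWaveform",
    "stimulus_current",
    "GaussianCSDPatch",
    "CSDScene",
    "make_toy_neuron",
    "make_csd_scene",
    "smooth_csd",
    "default_geometry",
]


def default_geometry(n_terms: int = 20) -> SliceGeometry:
    """Reference slice: 300 um tissue (0.3 S/m) under saline (1.5 S/m)."""
    return SliceGeometry(h=300e-6, sigma_T=0.3, sigma_S=1.5, n_terms=n_terms)


@dataclass(frozen=True)
class StimulusWaveform:
    """Switched-on sinusoidal current injection.

    I(t) = I_inj * sin(2 pi f (t - t0)) * Heaviside(t - t0).
    Defaults: 2 nA at 50 Hz.
    """

    amplitude: float = 2e-9  # A
    frequency: float = 50.0  # Hz
    onset: float = 0.0  # s


def stimulus_current(t, waveform: StimulusWaveform):
    """Evaluate the stimulus waveform at time(s) t (seconds)."""
    t = np.asarray(t, dtype=float)
    out = np.where(
        t >= waveform.onset,
        waveform.amplitude
        * np.sin(2.0 * np.pi * waveform.frequency * (t - waveform.onset)),
        0.0,
    )
    return out if out.ndim else float(out)


def make_toy_neuron(
    seed: int,
    n_compartments: int = 10,
    geometry: SliceGeometry | None = None,
    soma_height: float | None = None,
    compartment_length: float = 20e-6,
    waveform: StimulusWaveform | None = None,
    t_stop: float = 40e-3,
    dt: float = 0.5e-3,
) -> CompartmentRecording:
    """Ball-and-stick cell lying parallel to the MEA plane.

    The soma (compartment 0) carries the stimulus current; return
    currents are distributed over the dendritic compartments with
    exponential distance weighting.  All currents are quantised to a
    common dyadic grid (relative resolution 2^-40, far below any physical
    scale of interest) so that per-time-step sums cancel exactly in
    floating point, whatever the summation order.
    """
    if n_compartments < 2:
        raise GeometryError("a ball-and-stick cell needs >= 2 compartments")
    geometry = geometry or default_geometry()
    rng = np.random.default_rng(seed)
    z0 = soma_height if soma_height is not None else geometry.h / 2.0
    length = n_compartments * compartment_length
    if not (0.0 < z0 < geometry.h):
        raise GeometryError("soma height outside the slice interior")
    if length > 20e-3:
        raise GeometryError("cell too large for the slice set-up")

    x_edges = np.arange(n_compartments + 1) * compartment_length
    x_edges = x_edges - length / 2.0  # centre the cell over the origin
    jitter = rng.normal(0.0, 1e-6, size=(n_compartments, 2))  # slight y wobble
    start = np.column_stack([x_edges[:-1], jitter[:, 0], np.full(n_compartments, z0)])
    end = np.column_stack([x_edges[1:], jitter[:, 1], np.full(n_compartments, z0)])

    waveform = waveform or StimulusWaveform(onset=5e-3)
    t = np.arange(0.0, t_stop, dt)
    inj = stimulus_current(t, waveform)

    d = np.arange(1, n_compartments)  # dendritic distance in compartments
    # gentle exponential decay (length constant ~ cell length): the soma
    # carries the concentrated stimulus, returns leak out all along the
    # dendrite, so the near field is strongest under the soma
    w = np.exp(-d / float(n_compartments))
    w = w / w.sum()
    imem = np.empty((n_compartments, t.size))
    returns = -w[:, None] * inj[None, :]
    scale = np.max(np.abs(returns))
    if scale > 0.0:
        # snap to a dyadic grid: sums of <= 2^12 terms of <= 2^40 quanta
        # stay exact integers in the 53-bit mantissa
        q = 2.0 ** (np.floor(np.log2(scale)) - 40.0)
        returns = np.round(returns / q) * q
    imem[1:, :] = returns
    imem[0, :] = -np.sum(returns, axis=0)
    return CompartmentRecording(start, end, imem, t,
                                cell_id=np.zeros(n_compartments, dtype=int))


@dataclass(frozen=True)
class GaussianCSDPatch:
    """Isotropic planar Gaussian CSD patch, uniform across slice thickness.

    amplitude is the peak volume CSD (A/m^3); width is the Gaussian sigma
    in the plane (metres).
    """

    x: float
    y: float
    width: float
    amplitude: float

    def density(self, xy) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        d2 = (xy[..., 0] - self.x) ** 2 + (xy[..., 1] - self.y) ** 2
        return self.amplitude * np.exp(-d2 / (2.0 * self.width**2))


@dataclass
class CSDScene:
    """Ground-truth CSD raster plus matched forward-modelled potentials."""

    patches: list[GaussianCSDPatch]
    grid_x: np.ndarray  # (nx,)
    grid_y: np.ndarray  # (ny,)
    csd_true: np.ndarray  # (ny, nx), A/m^3
    elec_xy: np.ndarray  # (n_elec, 2)
    potentials: np.ndarray  # (n_elec,), V
    voxel: float
    seed: int
    n_terms: int


def make_csd_scene(
    seed: int,
    n_patches: int,
    electrodes,
    geometry: SliceGeometry | None = None,
    n_terms: int = 20,
    voxel: float = 67e-6,
    patch_width_range: tuple[float, float] = (90e-6, 150e-6),
    amplitude: float = 100.0,
    margin: float = 150e-6,
) -> CSDScene:
    """Random Gaussian CSD patches and the potentials they generate.

    Patch centres are drawn uniformly inside the electrode hull shrunk by
    ``margin``; amplitudes are +-[0.5, 1] * ``amplitude`` (A/m^3).  MEA
    potentials follow the depth-integrated image-series kernel at the
    stated ``n_terms``; ground truth is rasterised on a grid with
    ``voxel`` spacing covering the electrode hull.
    """
    geometry = geometry or default_geometry()
    rng = np.random.default_rng(seed)
    if len(electrodes) and isinstance(electrodes[0], ElectrodeContact):
        elec_xy = np.array([[e.x, e.y] for e in electrodes])
    else:
        elec_xy = np.asarray(electrodes, dtype=float).reshape(-1, 2)
    x0, y0 = elec_xy.min(axis=0)
    x1, y1 = elec_xy.max(axis=0)

    patches = []
    for _ in range(n_patches):
        cx = rng.uniform(x0 + margin, x1 - margin)
        cy = rng.uniform(y0 + margin, y1 - margin)
        width = rng.uniform(*patch_width_range)
        amp = rng.uniform(0.5, 1.0) * amplitude * rng.choice([-1.0, 1.0])
        patches.append(GaussianCSDPatch(cx, cy, width, amp))

    gx = np.arange(x0, x1 + voxel / 2, voxel)
    gy = np.arange(y0, y1 + voxel / 2, voxel)
    mesh = np.stack(np.meshgrid(gx, gy), axis=-1)  # (ny, nx, 2)
    csd_true = np.zeros(mesh.shape[:-1])
    potentials = np.zeros(elec_xy.shape[0])
    span = float(np.hypot(x1 - x0, y1 - y0))
    for p in patches:
        csd_true += p.density(mesh)
        profile = _RadialBasisPotential(
            p.width, geometry.h, geometry.sigma_T_scalar, geometry.W_TS,
            n_terms, r_max=span + 6.0 * p.width,
        )
        d = np.hypot(elec_xy[:, 0] - p.x, elec_xy[:, 1] - p.y)
        potentials += p.amplitude * profile(d)

    return CSDScene(
        patches=patches, grid_x=gx, grid_y=gy, csd_true=csd_true,
        elec_xy=elec_xy, potentials=potentials, voxel=voxel,
        seed=seed, n_terms=n_terms,
    )


def smooth_csd(csd_grid: np.ndarray, sigma_voxels: float = 1.1) -> np.ndarray:
    """Gaussian-smooth a CSD raster (sigma in voxels, default 1.1)."""
    return gaussian_filter(np.asarray(csd_grid, dtype=float), sigma=sigma_voxels)
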