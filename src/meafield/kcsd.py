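"""Kernel current-source-density estimation with image-series correction.

Kernel CSD (kCSD) estimates a planar CSD distribution from MEA potentials
by kernel regression over a family of basis source distributions.  Here
the basis forward model is the image-series point-source formula for the
slice/bath sandwich, integrated analytically across the slice thickness
under the assumption that sources are distributed homogeneously in z.
For a planar basis density b~_i(x', y') (A/m^3 within 0 < z < h) the
potential it generates on the MEA plane is

    b_i(x, y) = 1/(2 pi sigma_T) *
        integral dx' dy' [ arsinh(h/L)
            + sum_{n>=1} W_TS^n (arsinh(h(1-2n)/L) + arsinh(h(1+2n)/L)) ]
        * b~_i(x', y'),   L = |(x, y) - (x', y')|.

Truncating the series at 0 terms gives the no-bath variant (kCSD0,
semi-infinite slice); 20 terms give the bath-corrected variant (kCSD20).

Sign convention: positive CSD = current source (current leaving cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import i0e

from .electrodes import ElectrodeContact
from .exceptions import GeometryError, NumericalError
from .geometry import SliceGeometry

__all__ = [
    "KCSDModel",
    "kcsd_fit",
    "kcsd_predict",
    "kcsd_basis_potential",
    "image_source_ratios",
    "laplacian_csd",
]


def arsinh_image_kernel(L, h: float, w_ts: float, n_terms: int):
    """Depth-integrated image kernel: arsinh(h/L) plus n_terms image pairs.

    Finite for L -> 0+ contributions under the integral; L must be > 0
    pointwise (arsinh(h/L) diverges logarithmically, which is integrable).
    """
    L = np.asarray(L, dtype=float)
    K = np.arcsinh(h / L)
    for n in range(1, n_terms + 1):
        K = K + w_ts**n * (
            np.arcsinh(h * (1 - 2 * n) / L) + np.arcsinh(h * (1 + 2 * n) / L)
        )
    return K


class _RadialBasisPotential:
    """Radial profile b(r) of the potential of one Gaussian basis source.

    For an isotropic planar Gaussian b~(rho) = exp(-rho^2 / (2 R^2)) the
    2D convolution with the radial image kernel reduces to a 1D integral
    (the angular integral of the shifted Gaussian is a Bessel term):

        b(r) = (1/sigma_T) * int_0^inf ds s K(s)
               exp(-(r-s)^2/(2R^2)) i0e(r s / R^2),

    evaluated by Gauss-Legendre quadrature on the Gaussian's support
    (|s - r| <= 6R) and tabulated on a dense grid for spline lookup.
    """

    _NODES = 240

    def __init__(self, R, h, sigma_T, w_ts, n_terms, r_max):
        self.R, self.h, self.sigma_T = R, h, sigma_T
        self.w_ts, self.n_terms = w_ts, n_terms
        self.r_max = r_max
        n_grid = min(4000, max(800, int(np.ceil(r_max / (R / 10.0)))))
        r = np.linspace(0.0, r_max, n_grid)
        self._spline = CubicSpline(r, self._quadrature(r))

    def _quadrature(self, r):
        R = self.R
        t, wq = np.polynomial.legendre.leggauss(self._NODES)
        s_lo = np.maximum(0.0, r - 6.0 * R)
        s_hi = r + 6.0 * R
        half = 0.5 * (s_hi - s_lo)
        s = s_lo[:, None] + half[:, None] * (t[None, :] + 1.0)
        kern = arsinh_image_kernel(s, self.h, self.w_ts, self.n_terms)
        gauss = np.exp(-((r[:, None] - s) ** 2) / (2.0 * R * R))
        bessel = i0e(r[:, None] * s / (R * R))
        integ = s * kern * gauss * bessel
        return (integ @ wq) * half / self.sigma_T

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        if np.any(r > self.r_max):
            raise GeometryError(
                f"basis-potential profile tabulated only up to r={self.r_max}"
            )
        return self._spline(np.abs(r))


@dataclass
class KCSDModel:
    """Planar kCSD model for MEA potentials in the slice/bath geometry.

    basis_xy : (M, 2) Gaussian basis centres (metres), covering the
        electrode hull with a margin
    R : basis width (Gaussian sigma), default the mean electrode pitch
    n_terms : image-series depth (0 = kCSD0, 20 = kCSD20)
    lam : ridge regulariser; default 1e-5 * trace(K)/n at fit time
    """

    basis_xy: np.ndarray
    R: float
    h: float
    sigma_T: float
    w_ts: float
    n_terms: int = 20
    lam: float | None = None
    # fitted state
    elec_xy: np.ndarray | None = None
    beta_: np.ndarray | None = None
    K_: np.ndarray | None = None
    B_: np.ndarray | None = None  # (M, n_elec) basis potentials at electrodes
    _profile: _RadialBasisPotential | None = field(default=None, repr=False)

    def _profile_for(self, r_needed: float) -> _RadialBasisPotential:
        if self._profile is None or self._profile.r_max < r_needed:
            self._profile = _RadialBasisPotential(
                self.R, self.h, self.sigma_T, self.w_ts, self.n_terms,
                r_max=1.25 * r_needed + 6.0 * self.R,
            )
        return self._profile

    def basis_potential(self, i: int, xy) -> np.ndarray:
        """MEA-plane potential b_i at point(s) xy per unit basis amplitude."""
        xy = np.asarray(xy, dtype=float)
        d = np.sqrt(np.sum((xy - self.basis_xy[i]) ** 2, axis=-1))
        prof = self._profile_for(float(np.max(d)) if d.size else 0.0)
        return prof(d)

    def _basis_matrix(self, points: np.ndarray) -> np.ndarray:
        """(M, P) matrix of b_i evaluated at the given plane points."""
        d = np.sqrt(
            np.sum((self.basis_xy[:, None, :] - points[None, :, :]) ** 2, axis=-1)
        )
        prof = self._profile_for(float(d.max()))
        return prof(d)

    def fit(self, elec_xy: np.ndarray, potentials: np.ndarray) -> "KCSDModel":
        elec_xy = np.asarray(elec_xy, dtype=float).reshape(-1, 2)
        v = np.asarray(potentials, dtype=float).ravel()
        if elec_xy.shape[0] < 4:
            raise GeometryError("kCSD needs at least 4 electrodes")
        if not np.all(np.isfinite(v)):
            raise GeometryError("potentials must be finite")
        if v.size != elec_xy.shape[0]:
            raise GeometryError("one potential value per electrode required")
        B = self._basis_matrix(elec_xy)
        K = B.T @ B
        lam = self.lam
        if lam is None:
            lam = 1e-5 * np.trace(K) / K.shape[0]
        if lam == 0.0 and np.linalg.cond(K) > 1e12:
            raise NumericalError(
                "electrode kernel matrix is numerically singular; "
                "set a ridge parameter lam > 0"
            )
        self.elec_xy, self.B_, self.K_ = elec_xy, B, K
        self.beta_ = np.linalg.solve(K + lam * np.eye(K.shape[0]), v)
        return self

    def predict(self, grid_xy) -> np.ndarray:
        """Estimated CSD (A/m^3) at the requested plane points."""
        if self.beta_ is None:
            raise NumericalError("model is not fitted; call fit() first")
        grid = np.asarray(grid_xy, dtype=float)
        pts = grid.reshape(-1, 2)
        d2 = np.sum((self.basis_xy[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        Bt = np.exp(-d2 / (2.0 * self.R * self.R))  # (M, P) basis densities
        csd = (Bt.T @ self.B_) @ self.beta_
        return csd.reshape(grid.shape[:-1])


def _electrode_xy(electrodes) -> np.ndarray:
    if len(electrodes) and isinstance(electrodes[0], ElectrodeContact):
        return np.array([[e.x, e.y] for e in electrodes])
    return np.asarray(electrodes, dtype=float).reshape(-1, 2)


def _default_basis_grid(elec_xy: np.ndarray, spacing: float, margin: float):
    x0, y0 = elec_xy.min(axis=0) - margin
    x1, y1 = elec_xy.max(axis=0) + margin
    nx = max(2, int(np.round((x1 - x0) / spacing)) + 1)
    ny = max(2, int(np.round((y1 - y0) / spacing)) + 1)
    gx, gy = np.meshgrid(np.linspace(x0, x1, nx), np.linspace(y0, y1, ny))
    return np.column_stack([gx.ravel(), gy.ravel()])


def _mean_pitch(elec_xy: np.ndarray) -> float:
    pitches = []
    for col in (0, 1):
        u = np.unique(np.round(elec_xy[:, col], 12))
        if u.size > 1:
            pitches.append(np.min(np.diff(u)))
    if not pitches:
        raise GeometryError("cannot infer electrode pitch from a single position")
    return float(np.mean(pitches))


def kcsd_fit(
    potentials,
    electrodes,
    geometry: SliceGeometry,
    R: float | None = None,
    n_terms: int = 20,
    lam: float | None = None,
    basis_xy: np.ndarray | None = None,
    margin: float | None = None,
) -> KCSDModel:
    """Fit a kCSD model to one potential snapshot on an electrode layout.

    ``n_terms = 0`` is the no-bath kCSD0 variant, ``n_terms = 20`` (the
    default) the bath-corrected kCSD20 variant.  ``R`` defaults to the
    mean inter-electrode pitch; the basis grid covers the electrode hull
    with margin (default 2R) at spacing R.
    """
    elec_xy = _electrode_xy(electrodes)
    if R is None:
        R = _mean_pitch(elec_xy)
    if margin is None:
        margin = 2.0 * R
    if basis_xy is None:
        basis_xy = _default_basis_grid(elec_xy, spacing=R, margin=margin)
    model = KCSDModel(
        basis_xy=np.asarray(basis_xy, dtype=float),
        R=float(R),
        h=geometry.h,
        sigma_T=geometry.sigma_T_scalar,
        w_ts=geometry.W_TS,
        n_terms=n_terms,
        lam=lam,
    )
    return model.fit(elec_xy, potentials)


def kcsd_predict(model: KCSDModel, grid_xy) -> np.ndarray:
    """Evaluate a fitted kCSD model on a planar grid."""
    return model.predict(grid_xy)


def kcsd_basis_potential(i: int, xy, model: KCSDModel):
    """Potential b_i(x, y) of basis source i per unit CSD amplitude."""
    return model.basis_potential(i, xy)


def image_source_ratios(z: float, h: float, w_ts: float) -> tuple[float, float]:
    """First-image-to-principal ratios on the MEA plane below a source.

    For a point source at (0, 0, z) the nearest bath image sits at
    (0, 0, 2h - z).  Directly below the source the image contributes a
    fraction |W_TS z / (2h - z)| of the potential but only
    |W_TS z^3 / (2h - z)^3| of the 2D-Laplacian CSD estimate — the CSD is
    the curvature of the potential and curvature decays faster with
    source distance.  Returns (potential_ratio, laplacian_ratio).
    """
    if not (0.0 < z < h):
        raise GeometryError(f"source height z={z} must lie strictly inside (0, {h})")
    q = z / (2.0 * h - z)
    return abs(w_ts * q), abs(w_ts * q**3)


def laplacian_csd(phi, spacing, sigma_T: float = 0.3, x=None, y=None) -> np.ndarray:
    """Traditional CSD estimate: negative five-point 2D Laplacian times sigma_T.

    ``phi`` is a 2D potential grid (V) on a regular mesh with ``spacing``
    (scalar or (dx, dy), metres).  Returns -sigma_T * laplacian(phi) with
    the one-cell boundary frame set to NaN (the stencil is undefined
    there).  Positive output = current source.  Passing coordinate
    vectors ``x``/``y`` enables a regularity check: non-uniform spacing
    raises an error.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or min(phi.shape) < 3:
        raise GeometryError("potential grid must be 2D with >= 3 points per axis")
    dx, dy = (spacing, spacing) if np.isscalar(spacing) else spacing
    for coords, d, name in ((x, dx, "x"), (y, dy, "y")):
        if coords is not None:
            diffs = np.diff(np.asarray(coords, dtype=float))
            if not np.allclose(diffs, d, rtol=1e-9, atol=0.0):
                raise GeometryError(f"{name} grid is irregular; CSD stencil "
                                    "requires uniform spacing")
    lap = np.full_like(phi, np.nan)
    lap[1:-1, 1:-1] = (
        (phi[2:, 1:-1] - 2.0 * phi[1:-1, 1:-1] + phi[:-2, 1:-1]) / dx**2
        + (phi[1:-1, 2:] - 2.0 * phi[1:-1, 1:-1] + phi[1:-1, :-2]) / dy**2
    )
    return -sigma_T * lap
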