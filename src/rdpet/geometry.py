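"""Desk-scale matched forward/adjoint projection model for a ring PET scanner.

The forward model is ``A = att ∘ P ∘ G`` where ``G`` is an isotropic Gaussian
resolution blur applied in image space, ``P`` a sparse parallel-beam geometric
projector built once per geometry, and ``att`` a per-bin multiplicative
attenuation factor derived from a supplied attenuation (mu) image.  Because
``P`` is an explicit sparse matrix and ``G`` is a symmetric convolution with
zero boundary, the adjoint is the exact transpose of the forward map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

__all__ = [
    "ImageGrid",
    "SinogramGeometry",
    "SystemModel",
    "build_system_model",
    "build_geometric_projector",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ImageGrid:
    """Voxel grid: ``shape`` voxel counts per axis, ``spacing`` in mm per axis."""

    shape: tuple[int, ...]
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.shape) != len(self.spacing):
            raise ValueError("shape and spacing must have the same length")
        if any(s < 1 for s in self.shape):
            raise ValueError("all shape entries must be >= 1")
        if any(sp_ <= 0 for sp_ in self.spacing):
            raise ValueError("all spacings must be > 0")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def center_coords(self) -> tuple[np.ndarray, ...]:
        """Physical coordinates (mm) of voxel centers, origin at grid center."""
        axes = []
        for n, d in zip(self.shape, self.spacing):
            axes.append((np.arange(n) - (n - 1) / 2.0) * d)
        return tuple(np.meshgrid(*axes, indexing="ij"))


@dataclass(frozen=True)
class SinogramGeometry:
    """Parallel-beam sinogram layout: views over 180 deg x radial bins [x planes]."""

    n_views: int
    n_radial: int
    n_planes: int = 1
    radial_spacing: float = 2.5

    def __post_init__(self) -> None:
        if self.n_views < 2:
            raise ValueError("n_views must be >= 2")
        if self.n_radial < 1 or self.n_planes < 1:
            raise ValueError("n_radial and n_planes must be >= 1")
        if self.radial_spacing <= 0:
            raise ValueError("radial_spacing must be > 0")

    @property
    def shape(self) -> tuple[int, ...]:
        if self.n_planes == 1:
            return (self.n_views, self.n_radial)
        return (self.n_views, self.n_radial, self.n_planes)

    @property
    def n_bins(self) -> int:
        return self.n_views * self.n_radial * self.n_planes

    def view_angles(self) -> np.ndarray:
        return np.arange(self.n_views) * np.pi / self.n_views

    def radial_coords(self) -> np.ndarray:
        n = self.n_radial
        return (np.arange(n) - (n - 1) / 2.0) * self.radial_spacing


def build_geometric_projector(grid: ImageGrid, geom: SinogramGeometry) -> sp.csr_matrix:
    """Sparse geometric projector P mapping an image to a sinogram.

    Pixel-driven discretization of the (plane-by-plane) Radon transform: the
    projection of each voxel center onto the radial axis of each view is
    splatted onto the two nearest radial bins with linear interpolation,
    weighted by in-plane voxel area / radial bin width.  Rows are ordered
    view-major: bin index = view * n_radial + radial (+ plane offset for 3D),
    which makes view-subset restriction a contiguous row slice per view.
    """
    if grid.ndim not in (2, 3):
        raise ValueError("only 2D or 3D grids are supported")
    if grid.ndim == 2 and geom.n_planes != 1:
        raise ValueError("2D grid requires n_planes == 1")
    if grid.ndim == 3 and grid.shape[2] != geom.n_planes:
        raise ValueError("third grid axis must match n_planes")

    ny, nx = grid.shape[0], grid.shape[1]
    coords = grid.center_coords()
    cy = coords[0][..., 0] if grid.ndim == 3 else coords[0]
    cx = coords[1][..., 0] if grid.ndim == 3 else coords[1]
    cy = cy.ravel()
    cx = cx.ravel()
    n_pix = ny * nx

    area = grid.spacing[0] * grid.spacing[1]
    scale = area / geom.radial_spacing

    angles = geom.view_angles()
    r0 = geom.radial_coords()[0]
    dr = geom.radial_spacing
    n_rad = geom.n_radial

    rows, cols, vals = [], [], []
    pix_idx = np.arange(n_pix)
    for v, th in enumerate(angles):
        t = cy * np.cos(th) + cx * np.sin(th)
        f = (t - r0) / dr
        i0 = np.floor(f).astype(np.int64)
        w1 = f - i0
        w0 = 1.0 - w1
        for off, w in ((0, w0), (1, w1)):
            b = i0 + off
            ok = (b >= 0) & (b < n_rad) & (w > 0)
            rows.append(v * n_rad + b[ok])
            cols.append(pix_idx[ok])
            vals.append(w[ok] * scale)

    P2 = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geom.n_views * n_rad, n_pix),
    )
    if grid.ndim == 2:
        return P2
    # 3D: identical transaxial projection per plane (plane = fastest axis)
    return sp.kron(P2, sp.eye(geom.n_planes, format="csr"), format="csr")


@dataclass
class SystemModel:
    """Matched linear PET forward model with resolution blur and attenuation."""

    grid: ImageGrid
    geom: SinogramGeometry
    geometric_projector: sp.csr_matrix
    attenuation_factors: np.ndarray
    resolution_fwhm: float = 0.0
    #: counts per unit activity line-integral; the scanner's absolute
    #: sensitivity calibration linking image activity units to counts
    detection_efficiency: float = 1.0
    sensitivity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.attenuation_factors = np.asarray(self.attenuation_factors, dtype=float)
        if self.attenuation_factors.shape != self.geom.shape:
            raise ValueError("attenuation_factors shape must match sinogram geometry")
        if np.any(self.attenuation_factors <= 0) or np.any(self.attenuation_factors > 1):
            raise ValueError("attenuation_factors must lie in (0, 1]")
        if self.detection_efficiency <= 0:
            raise ValueError("detection_efficiency must be > 0")
        self.sensitivity = self.adjoint(np.ones(self.geom.shape))

    # -- resolution blur (self-adjoint: symmetric kernel, zero boundary) --
    @property
    def _sigma_vox(self) -> tuple[float, ...]:
        if self.resolution_fwhm <= 0:
            return tuple(0.0 for _ in self.grid.spacing)
        return tuple(self.resolution_fwhm / _FWHM_TO_SIGMA / d for d in self.grid.spacing)

    def _blur(self, x: np.ndarray) -> np.ndarray:
        if self.resolution_fwhm <= 0:
            return x
        return gaussian_filter(x, self._sigma_vox, mode="constant", cval=0.0, truncate=4.0)

    def _check_image(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != self.grid.shape:
            raise ValueError(f"image shape {x.shape} does not match grid {self.grid.shape}")
        return x

    def _check_sino(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if s.shape != self.geom.shape:
            raise ValueError(f"sinogram shape {s.shape} does not match geometry {self.geom.shape}")
        return s

    def forward(self, x: np.ndarray) -> np.ndarray:
        """A x = eff * att * P(G x)."""
        x = self._check_image(x)
        s = self.geometric_projector @ self._blur(x).ravel()
        return self.detection_efficiency * self.attenuation_factors * s.reshape(self.geom.shape)

    def adjoint(self, s: np.ndarray) -> np.ndarray:
        """A^T s = eff * G^T P^T (att * s)."""
        s = self._check_sino(s)
        x = self.geometric_projector.T @ (self.attenuation_factors * s).ravel()
        return self.detection_efficiency * self._blur(x.reshape(self.grid.shape))

    def subset_model(self, views: list[int] | np.ndarray) -> "SubsetModel":
        views = np.asarray(views, dtype=int)
        if views.size == 0:
            raise ValueError("views must be nonempty")
        if np.unique(views).size != views.size:
            raise ValueError("duplicate view indices")
        if views.min() < 0 or views.max() >= self.geom.n_views:
            raise ValueError("view index out of range")
        return SubsetModel(self, views)


class SubsetModel:
    """Restriction A_i of a SystemModel to a list of views.

    Operates on subset-shaped sinograms (len(views), n_radial[, n_planes]).
    Sums of subset adjoints over a disjoint view partition reproduce the full
    adjoint, and subset sensitivities add up to the full sensitivity.
    """

    def __init__(self, parent: SystemModel, views: np.ndarray):
        self.parent = parent
        self.views = views
        geom = parent.geom
        nr, npl = geom.n_radial, geom.n_planes
        rows = (views[:, None] * nr + np.arange(nr)[None, :]).ravel()
        if npl > 1:
            rows = (rows[:, None] * npl + np.arange(npl)[None, :]).ravel()
        self._rows = rows
        self._P = parent.geometric_projector[rows]
        self._att = parent.attenuation_factors.reshape(-1)[rows].reshape(self.shape)
        self.sensitivity = self.adjoint(np.ones(self.shape))

    @property
    def shape(self) -> tuple[int, ...]:
        geom = self.parent.geom
        if geom.n_planes == 1:
            return (len(self.views), geom.n_radial)
        return (len(self.views), geom.n_radial, geom.n_planes)

    def extract(self, s: np.ndarray) -> np.ndarray:
        """Restrict a full sinogram to this subset's views."""
        s = self.parent._check_sino(s)
        return s.reshape(-1)[self._rows].reshape(self.shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self.parent._check_image(x)
        s = self._P @ self.parent._blur(x).ravel()
        return self.parent.detection_efficiency * self._att * s.reshape(self.shape)

    def adjoint(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if s.shape != self.shape:
            raise ValueError("sinogram shape does not match subset geometry")
        x = self._P.T @ (self._att * s).ravel()
        return self.parent.detection_efficiency * self.parent._blur(
            x.reshape(self.parent.grid.shape)
        )


def build_system_model(
    grid: ImageGrid,
    geom: SinogramGeometry,
    mu_image: np.ndarray | None = None,
    resolution_fwhm: float = 0.0,
    detection_efficiency: float = 1.0,
) -> SystemModel:
    """Assemble the matched system model A = att ∘ P ∘ G.

    Parameters
    ----------
    grid, geom
        Image and sinogram layouts.
    mu_image
        Linear attenuation coefficients in 1/mm on ``grid`` (e.g. 0.0096 for
        water at 511 keV), or None for no attenuation.  Attenuation factors
        are exp(-P mu), the survival probability along each line of response.
    resolution_fwhm
        FWHM in mm of the isotropic Gaussian resolution model applied in
        image space (0 disables the blur).
    detection_efficiency
        Scalar counts-per-unit-line-integral calibration of the scanner;
        the attenuation line integral itself is not affected by it.
    """
    P = build_geometric_projector(grid, geom)
    if mu_image is None:
        att = np.ones(geom.shape)
    else:
        mu_image = np.asarray(mu_image, dtype=float)
        if mu_image.shape != grid.shape:
            raise ValueError(
                f"mu_image shape {mu_image.shape} does not match grid {grid.shape}"
            )
        att = np.exp(-(P @ mu_image.ravel()).reshape(geom.shape))
    return SystemModel(grid, geom, P, att, resolution_fwhm, detection_efficiency)
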