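"""Mask-driven deformable registration between EE and EI lung shapes.

The fixed image is the end-inspiration (EI) aerated mask and the moving
image the end-expiration (EE) one; the estimated displacement field lives
on the EI grid and points backward, ``x_EE = x_EI + u(x_EI)``, so that
meshes built at EI can be pushed to their reference (expiratory)
configuration.

Binary masks carry no interior intensity gradients, so the built-in
backend registers *clamped signed-distance transforms* of the masks: the
SDT is clipped to a narrow band (a few voxels) around the surface, which
turns the similarity term into a boundary-alignment force, and the
interior motion is supplied by the smoothness of the deformation model.
The model is a free-form deformation on a coarse control lattice with
trilinear (first-order B-spline) basis, fitted by L-BFGS-B on

    E(u) = mean_band ( SDT_EI(x) - SDT_EE(x + u(x)) )^2  +  lambda * B(u)

where ``B`` is the discrete bending energy (squared second differences of
the control lattice).  A moment-matching diagonal affine initialisation
supplies the capture range.  Linear fields have zero bending energy and
are represented exactly by the lattice, so uniform inflations are
recovered without bias; smoother large-scale variation (e.g. a
dorsoventral stretch gradient) is captured by the lattice refinement.

The backend is pluggable: externally computed dense fields in the same
layout can be imported with :func:`load_displacement_field`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .core import BinaryMask, load_nifti, save_nifti


class FoldedFieldError(RuntimeError):
    """The estimated map has non-positive Jacobian somewhere on the mask."""


@dataclass(frozen=True)
class FFDParams:
    """Tuning knobs of the built-in FFD backend.

    control_spacing: control-lattice spacing in working-grid voxels.
    bending_weight: weight of the bending-energy penalty (lambda).
    max_iters: L-BFGS-B iteration cap.
    working_size: registration runs at a resolution downsampled so that
        the largest axis is at most this many voxels; the smooth field is
        then evaluated back on the full grid.  Caps cost on large volumes.
    band_clamp_vox: SDT clamp half-width in working voxels.
    band_dilate: dilation (voxels) of the sampling band around the clamp.
    """

    control_spacing: int = 6
    bending_weight: float = 1e-3
    max_iters: int = 300
    working_size: int = 64
    band_clamp_vox: float = 2.0
    band_dilate: int = 2


@dataclass
class DisplacementField:
    """Dense backward displacement (mm) on the EI voxel grid.

    ``values[i, j, k]`` is the 3-vector u such that the EI point at voxel
    (i, j, k) maps to ``x + u`` in the EE configuration.
    """

    values: np.ndarray  # (nx, ny, nz, 3), mm
    spacing: float
    info: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 4 or self.values.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        if not np.isfinite(self.values).all():
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    def jacobian(self) -> np.ndarray:
        """Dense Jacobian determinant of the induced map x -> x + u(x)."""
        h = self.spacing
        grad = np.empty(self.shape + (3, 3))
        for c in range(3):
            for ax in range(3):
                grad[..., c, ax] = np.gradient(self.values[..., c], h, axis=ax)
        return np.linalg.det(grad + np.eye(3))


def sample_displacement(field: DisplacementField, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the dense field at arbitrary points (mm).

    Exact on voxel centres and for affine fields (trilinear interpolation
    reproduces linear functions).  Points outside the grid raise: the
    field is not extrapolated.
    """
    pts = np.atleast_2d(np.asarray(points_mm, float))
    vox = pts / field.spacing
    upper = np.asarray(field.shape) - 1
    if (vox < -1e-9).any() or (vox > upper + 1e-9).any():
        bad = np.flatnonzero(((vox < -1e-9) | (vox > upper + 1e-9)).any(axis=1))
        raise ValueError(f"{len(bad)} point(s) outside the field grid, e.g. {pts[bad[0]]}")
    vox = np.clip(vox, 0.0, upper)
    out = np.empty_like(pts)
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(field.values[..., c], vox.T, order=1, mode="nearest")
    return out


def mask_to_sdt(mask: BinaryMask, clamp_mm: float | None = None) -> np.ndarray:
    """Signed distance transform (mm): negative inside, positive outside.

    Optionally clamped to ``+/- clamp_mm`` to form the narrow-band
    similarity surrogate used by the registration.
    """
    m = mask.data
    if not m.any():
        raise ValueError("empty mask has no signed distance transform")
    h = mask.spacing
    inside = ndimage.distance_transform_edt(m, sampling=h)
    outside = ndimage.distance_transform_edt(~m, sampling=h)
    sdt = outside - inside
    if clamp_mm is not None:
        sdt = np.clip(sdt, -clamp_mm, clamp_mm)
    return sdt


# -------------------------------------------------------- FFD machinery


class _Lattice:
    """Trilinear control lattice over a voxel grid (working coordinates)."""

    def __init__(self, shape: tuple[int, int, int], spacing_vox: int):
        self.shape = shape
        self.cps = spacing_vox
        self.nc = tuple(int(np.ceil((n - 1) / spacing_vox)) + 3 for n in shape)
        self.origin = -spacing_vox  # lattice node 0 sits one cell outside

    def _weights(self, pts: np.ndarray):
        t = (pts - self.origin) / self.cps
        i0 = np.floor(t).astype(np.int64)
        f = t - i0
        return i0, f

    def control_coords(self) -> np.ndarray:
        axes = [np.arange(n) * self.cps + self.origin for n in self.nc]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).astype(float)

    def evaluate(self, params: np.ndarray, pts: np.ndarray) -> np.ndarray:
        i0, f = self._weights(pts)
        u = np.zeros((len(pts), 3))
        for corner in range(8):
            dx, dy, dz = corner >> 2 & 1, corner >> 1 & 1, corner & 1
            w = (
                (f[:, 0] if dx else 1 - f[:, 0])
                * (f[:, 1] if dy else 1 - f[:, 1])
                * (f[:, 2] if dz else 1 - f[:, 2])
            )
            u += w[:, None] * params[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        return u

    def scatter(self, pts: np.ndarray, vals: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`evaluate` (accumulate point values to lattice)."""
        i0, f = self._weights(pts)
        n_lattice = int(np.prod(self.nc))
        acc = np.zeros((n_lattice, 3))
        strides = np.array([self.nc[1] * self.nc[2], self.nc[2], 1], dtype=np.int64)
        base = i0 @ strides
        for corner in range(8):
            dx, dy, dz = corner >> 2 & 1, corner >> 1 & 1, corner & 1
            w = (
                (f[:, 0] if dx else 1 - f[:, 0])
                * (f[:, 1] if dy else 1 - f[:, 1])
                * (f[:, 2] if dz else 1 - f[:, 2])
            )
            lin = base + dx * strides[0] + dy * strides[1] + dz
            for c in range(3):
                acc[:, c] += np.bincount(lin, weights=w * vals[:, c], minlength=n_lattice)
        return acc.reshape(self.nc + (3,))


def _bending(params: np.ndarray) -> tuple[float, np.ndarray]:
    """Squared second differences of the lattice, with gradient."""
    energy = 0.0
    grad = np.zeros_like(params)
    for ax in range(3):
        d2 = np.diff(params, n=2, axis=ax)
        energy += float(np.sum(d2**2))
        g = np.zeros_like(params)
        n = d2.shape[ax]
        sl = [slice(None)] * params.ndim
        sl[ax] = slice(0, n)
        g[tuple(sl)] += d2
        sl[ax] = slice(2, n + 2)
        g[tuple(sl)] += d2
        sl[ax] = slice(1, n + 1)
        g[tuple(sl)] -= 2 * d2
        grad += g
    return energy, 2.0 * grad


def _downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return mask
    from skimage.measure import block_reduce

    return block_reduce(mask.astype(np.float32), (factor,) * 3, np.mean) > 0.5


def _moment_affine(fixed: np.ndarray, moving: np.ndarray):
    """Diagonal affine matching per-axis centroid and spread (voxel units)."""
    pf = np.argwhere(fixed).astype(float)
    pm = np.argwhere(moving).astype(float)
    cf, cm = pf.mean(0), pm.mean(0)
    sf = np.maximum(pf.std(0), 1e-6)
    sm = np.maximum(pm.std(0), 1e-6)
    return cf, cm, sm / sf


def register_ffd(
    fixed: BinaryMask,
    moving: BinaryMask,
    params: FFDParams | None = None,
    *,
    check_jacobian: bool = True,
) -> DisplacementField:
    """Estimate the EI -> EE backward displacement from the two masks.

    ``fixed`` is the EI aerated mask, ``moving`` the EE one.  Returns the
    dense field on the (full-resolution) EI grid; ``field.info`` carries
    the energy history, convergence flag, working resolution and minimum
    Jacobian.  Raises :class:`FoldedFieldError` when the induced map folds
    on the fixed mask.
    """
    if params is None:
        params = FFDParams()
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving masks must share a grid")
    if not fixed.data.any() or not moving.data.any():
        raise ValueError("masks must be non-empty")
    h = fixed.spacing
    factor = max(1, int(np.ceil(max(fixed.shape) / params.working_size)))
    fw = _downsample_mask(fixed.data, factor)
    mw = _downsample_mask(moving.data, factor)
    hw = h * factor
    tau = params.band_clamp_vox * hw

    f_sdt = mask_to_sdt(BinaryMask(fw, hw), clamp_mm=tau)
    m_sdt = mask_to_sdt(BinaryMask(mw, hw), clamp_mm=tau)
    band = ndimage.binary_dilation(np.abs(f_sdt) < tau * 0.999, iterations=params.band_dilate)
    pts = np.argwhere(band).astype(float)
    fvals = f_sdt[band]
    grad_m = np.stack(np.gradient(m_sdt, hw), axis=-1)
    npts = len(pts)

    lattice = _Lattice(fw.shape, params.control_spacing)
    lam = params.bending_weight

    def cost(x: np.ndarray):
        p = x.reshape(lattice.nc + (3,))
        u = lattice.evaluate(p, pts)
        q = (pts + u).T
        warped = ndimage.map_coordinates(m_sdt, q, order=1, mode="nearest")
        r = warped - fvals
        gm = np.stack(
            [ndimage.map_coordinates(grad_m[..., c], q, order=1, mode="nearest") for c in range(3)],
            axis=-1,
        )
        g_data = lattice.scatter(pts, (2.0 / npts) * r[:, None] * gm * hw)
        e_bend, g_bend = _bending(p)
        return float(np.sum(r**2) / npts + lam * e_bend), (g_data + lam * g_bend).ravel()

    cf, cm, scale = _moment_affine(fw, mw)
    cgrid = lattice.control_coords()
    x0 = (cm + scale * (cgrid - cf) - cgrid).ravel()

    history: list[float] = [cost(x0)[0]]
    res = minimize(
        cost,
        x0,
        jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=params.max_iters, ftol=1e-14, gtol=1e-12, maxcor=30),
        callback=lambda xk: history.append(cost(xk)[0]),
    )
    converged = res.nit < params.max_iters
    if not converged:
        warnings.warn(
            f"FFD registration hit the iteration cap ({params.max_iters}); "
            "returning best iterate",
            stacklevel=2,
        )
    lattice_params = res.x.reshape(lattice.nc + (3,))

    # Evaluate the working-resolution field on the full grid.  Full voxel i
    # (centre at i*h) sits at working coordinate (i - (factor-1)/2) / factor.
    shape = fixed.shape
    full = np.indices(shape).reshape(3, -1).T.astype(float)
    work_pts = (full - (factor - 1) / 2.0) / factor
    u_full = np.empty((len(full), 3))
    chunk = 1_000_000
    for s in range(0, len(full), chunk):
        u_full[s : s + chunk] = lattice.evaluate(lattice_params, work_pts[s : s + chunk])
    u_full = u_full.reshape(shape + (3,)) * hw  # working voxels -> mm

    fld = DisplacementField(
        u_full,
        h,
        info=dict(
            backend="ffd",
            converged=converged,
            n_iter=int(res.nit),
            energy_history=history,
            final_cost=float(res.fun),
            working_factor=factor,
            params=params,
            convention="x_EE = x_EI + u(x_EI); fixed=EI, moving=EE",
        ),
    )
    if check_jacobian:
        jac = fld.jacobian()
        min_j = float(jac[fixed.data].min())
        fld.info["min_jacobian"] = min_j
        if min_j <= 0:
            raise FoldedFieldError(
                f"registered map folds on the fixed mask (min J = {min_j:.4f})"
            )
    return fld


# ------------------------------------------------------------------- I/O


def save_displacement_field(fld: DisplacementField, path: str | Path) -> None:
    """Store as a 4D NIfTI (last axis = displacement components, mm)."""
    save_nifti(fld.values, fld.spacing, path)


def load_displacement_field(path: str | Path) -> DisplacementField:
    """Import a dense field (e.g. computed by an external package)."""
    data, spacing = load_nifti(path)
    return DisplacementField(np.asarray(data, float), spacing, info=dict(backend="imported"))
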