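"""Image alignment and deformation analysis.

Two registration problems arise in the pipeline:

* **SPECT to CT**: the tracer volume is aligned to the expiration CT with
  an affine transform maximising mutual information (multi-resolution,
  full sampling, so the result is deterministic).
* **Expiration to inspiration CT**: a mass-preserving deformable
  registration. The similarity metric is the sum of squared tissue-volume
  differences (SSTVD): each voxel's tissue volume is its volume times the
  tissue fraction inferred from HU, and the warped expiration tissue
  volume is weighted by the local Jacobian so that tissue mass, not
  intensity, is matched. The displacement is parameterised by a
  multi-resolution free-form deformation on a coarse control grid
  (trilinear basis), optimised by L-BFGS-B with an analytic
  frozen-Jacobian gradient.

Displacement fields live on the fixed grid and map fixed-domain points
into the moving domain (pull-back); derived metrics are the Jacobian
determinant J = det(I + grad u) (local volume-change ratio) and the
anisotropic deformation index (ADI) from the principal stretches
l1 >= l2 >= l3 of the right stretch tensor:

    ADI = sqrt(((l1 - l2) / l2)^2 + ((l2 - l3) / l3)^2)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage, optimize

from .images import AffineTransform, DisplacementField, ImageVolume, LabelMap

__all__ = [
    "DeformationMetrics",
    "affine_register_mi",
    "resample_affine",
    "apply_displacement",
    "deformation_metrics",
    "deformable_register_sstvd",
]


# --------------------------------------------------------------------------
# Affine mutual-information registration (SimpleITK backend)
# --------------------------------------------------------------------------

def _dilated_mask_image(mask: LabelMap, dilate_voxels: int = 2) -> sitk.Image:
    m = ndimage.binary_dilation(mask.lung_mask, iterations=dilate_voxels)
    img = sitk.GetImageFromArray(np.ascontiguousarray(m.T).astype(np.uint8))
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    return img


def affine_register_mi(
    moving: ImageVolume,
    fixed: ImageVolume,
    mask: LabelMap | None = None,
    *,
    bins: int = 32,
    shrink_factors: tuple[int, ...] = (4, 2),
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0),
    iterations: int = 150,
    seed: int = 0,
) -> AffineTransform:
    """Affine registration maximising Mattes mutual information.

    Two deterministic stages, both multi-resolution with the
    full-sampling joint histogram (``bins`` bins, evaluated over the lung
    mask dilated by 2 voxels when a mask is given): a translation-only
    stage absorbs the bulk misalignment, then a full affine refines it.
    ``seed`` is accepted for interface stability; full sampling consumes
    no randomness. Returns the affine mapping fixed physical points into
    the moving domain, ready for resampling.
    """
    del seed  # deterministic with full sampling
    for name, img in (("moving", moving), ("fixed", fixed)):
        if float(np.ptp(img.data)) == 0.0:
            raise ValueError(f"degenerate histogram: {name} image is constant")
    if mask is not None and not np.any(mask.lung_mask):
        raise ValueError("empty mask")

    f_img, m_img = fixed.to_sitk(), moving.to_sitk()
    mask_img = _dilated_mask_image(mask) if mask is not None else None

    def _make_reg() -> sitk.ImageRegistrationMethod:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
        reg.SetMetricSamplingStrategy(reg.NONE)  # use every voxel
        reg.SetInterpolator(sitk.sitkLinear)
        if mask_img is not None:
            reg.SetMetricFixedMask(mask_img)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=2.0, minStep=1e-5, numberOfIterations=iterations,
            gradientMagnitudeTolerance=1e-8,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel(list(shrink_factors))
        reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        return reg

    reg1 = _make_reg()
    reg1.SetInitialTransform(sitk.TranslationTransform(3), inPlace=False)
    stage1 = reg1.Execute(f_img, m_img)
    offset = sitk.CompositeTransform(stage1).GetNthTransform(0).GetOffset()

    reg2 = _make_reg()
    a0 = sitk.AffineTransform(3)
    a0.SetTranslation(offset)
    reg2.SetInitialTransform(a0, inPlace=False)
    final = reg2.Execute(f_img, m_img)
    stop = reg2.GetOptimizerStopConditionDescription()
    if "Maximum number of iterations" in stop:
        warnings.warn(
            "affine MI registration stopped at the iteration cap "
            f"(final metric {reg2.GetMetricValue():.5f}); result may not be converged",
            RuntimeWarning,
            stacklevel=2,
        )

    affine = sitk.AffineTransform(sitk.CompositeTransform(final).GetNthTransform(0))
    A = np.asarray(affine.GetMatrix()).reshape(3, 3)
    c = np.asarray(affine.GetCenter())
    t = np.asarray(affine.GetTranslation())
    # y = A (x - c) + t + c  ->  matrix A, translation t + c - A c
    return AffineTransform(A, t + c - A @ c)


def resample_affine(
    moving: ImageVolume,
    fixed_grid: ImageVolume | LabelMap,
    transform: AffineTransform,
    *,
    interpolation: str = "linear",
    fill_value: float = 0.0,
) -> ImageVolume:
    """Resample ``moving`` onto the fixed grid through an affine transform."""
    order = {"linear": 1, "nearest": 0}[interpolation]
    xs, ys, zs = fixed_grid.world_coordinates()
    pts = np.stack([xs, ys, zs], axis=-1)
    idx = moving.world_to_index(transform.apply(pts))
    out = ndimage.map_coordinates(
        np.asarray(moving.data, float), np.moveaxis(idx, -1, 0),
        order=order, mode="constant", cval=fill_value,
    )
    return ImageVolume(out, fixed_grid.spacing, fixed_grid.origin)


# --------------------------------------------------------------------------
# Displacement-field application and metrics
# --------------------------------------------------------------------------

def apply_displacement(
    img: ImageVolume,
    field: DisplacementField,
    interpolation: str = "linear",
    fill_value: float = 0.0,
) -> ImageVolume:
    """Pull ``img`` back onto the field's fixed grid: out(x) = img(x + u(x))."""
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    grid = field.grid_like()
    xs, ys, zs = grid.world_coordinates()
    pts = np.stack([xs, ys, zs], axis=-1) + field.vectors
    idx = img.world_to_index(pts)
    out = ndimage.map_coordinates(
        np.asarray(img.data, float), np.moveaxis(idx, -1, 0),
        order=order, mode="constant", cval=fill_value,
    )
    return ImageVolume(out, field.spacing, field.origin)


@dataclass
class DeformationMetrics:
    jacobian: np.ndarray  # per-voxel J = det(I + grad u)
    adi: np.ndarray  # per-voxel anisotropic deformation index, >= 0


def _deformation_gradient(field: DisplacementField) -> np.ndarray:
    """F = I + grad u, shape (nx, ny, nz, 3, 3), derivatives in world mm."""
    grads = [np.gradient(field.vectors[..., i], *field.spacing) for i in range(3)]
    F = np.empty(field.shape + (3, 3))
    for i in range(3):
        for j in range(3):
            F[..., i, j] = grads[i][j]
        F[..., i, i] += 1.0
    return F


def deformation_metrics(field: DisplacementField) -> DeformationMetrics:
    """Jacobian determinant and ADI of a displacement field.

    Central differences in the interior, one-sided at the boundary. The
    principal stretches are the singular values of F; local isotropic
    deformation (l1 = l2 = l3) gives ADI = 0 exactly.
    """
    F = _deformation_gradient(field)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite deformation gradient")
    J = np.linalg.det(F)
    s = np.linalg.svd(F, compute_uv=False)  # sorted descending: l1 >= l2 >= l3
    with np.errstate(divide="ignore", invalid="ignore"):
        adi = np.sqrt(
            ((s[..., 0] - s[..., 1]) / s[..., 1]) ** 2
            + ((s[..., 1] - s[..., 2]) / s[..., 2]) ** 2
        )
    return DeformationMetrics(jacobian=J, adi=adi)


# --------------------------------------------------------------------------
# Mass-preserving deformable registration (SSTVD free-form deformation)
# --------------------------------------------------------------------------

def _tissue_volume_image(ct: ImageVolume) -> np.ndarray:
    """Per-voxel tissue fraction (voxel volume factored out of the metric)."""
    return np.clip((np.asarray(ct.data, float) + 1000.0) / 1000.0, 0.0, 1.0)


def _downsample(arr: np.ndarray, factor: int, *, binary: bool = False) -> np.ndarray:
    if factor == 1:
        return arr.astype(float)
    if binary:
        sm = ndimage.zoom(arr.astype(float), 1.0 / factor, order=1)
        return (sm > 0.25).astype(float)
    sm = ndimage.gaussian_filter(arr.astype(float), sigma=0.5 * factor)
    return ndimage.zoom(sm, 1.0 / factor, order=1)


def _trilinear_weights(ic: np.ndarray, cshape: tuple[int, int, int]):
    """Corner indices and weights for trilinear interpolation at points ``ic``.

    ``ic``: (N, 3) fractional control-grid indices (clamped to the grid).
    Returns flat corner indices (8, N) into the control grid and weights (8, N).
    """
    ic = np.clip(ic, 0.0, np.asarray(cshape) - 1.0 - 1e-9)
    i0 = np.floor(ic).astype(int)
    f = ic - i0
    idx8, w8 = [], []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                corner = i0 + np.array([dx, dy, dz])
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                idx8.append(np.ravel_multi_index(corner.T, cshape))
                w8.append(w)
    return np.stack(idx8), np.stack(w8)


class _FFDLevel:
    """One resolution level of the SSTVD free-form deformation problem."""

    def __init__(self, t_fixed, t_moving, mask, spacing, origin_f, spacing_m, origin_m,
                 control_spacing_mm, smooth_weight):
        self.tf = t_fixed
        self.tm = t_moving
        self.mask = mask
        self.spacing = np.asarray(spacing, float)
        self.origin_m = np.asarray(origin_m, float)
        self.spacing_m = np.asarray(spacing_m, float)
        self.smooth_weight = smooth_weight
        shape = np.asarray(t_fixed.shape)
        extent = (shape - 1) * self.spacing
        # control nodes padded one spacing beyond the domain on each side
        self.c_origin = np.asarray(origin_f, float) - control_spacing_mm
        self.c_spacing = float(control_spacing_mm)
        self.cshape = tuple(int(np.ceil(e / control_spacing_mm)) + 3 for e in extent)
        xs = [np.asarray(origin_f)[i] + self.spacing[i] * np.arange(shape[i]) for i in range(3)]
        grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
        self.world = grid.reshape(-1, 3)
        ic = (self.world - self.c_origin) / self.c_spacing
        self.idx8, self.w8 = _trilinear_weights(ic, self.cshape)
        # precompute moving-image gradient (world units, mm^-1)
        self.gm = np.stack(np.gradient(self.tm, *self.spacing_m), axis=-1)

    # -- parameterisation ---------------------------------------------------
    def dense_field(self, c: np.ndarray) -> np.ndarray:
        """(nx, ny, nz, 3) displacement from control coefficients (3, *cshape)."""
        flat = c.reshape(3, -1)
        u = np.einsum("kn,ckn->nc", self.w8, flat[:, self.idx8])
        return u.reshape(self.tf.shape + (3,))

    def _restrict(self, g_dense: np.ndarray) -> np.ndarray:
        """Adjoint of dense_field: scatter (nx,ny,nz,3) gradients to controls."""
        g = g_dense.reshape(-1, 3)
        out = np.zeros((3, int(np.prod(self.cshape))))
        for a in range(3):
            for k in range(8):
                np.add.at(out[a], self.idx8[k], self.w8[k] * g[:, a])
        return out.reshape((3,) + self.cshape)

    # -- objective ----------------------------------------------------------
    def cost_grad(self, cflat: np.ndarray) -> tuple[float, np.ndarray]:
        c = cflat.reshape((3,) + self.cshape)
        u = self.dense_field(c)
        pts = self.world.reshape(u.shape) + u
        idx_m = (pts - self.origin_m) / self.spacing_m
        idx_m = np.moveaxis(idx_m, -1, 0)
        tm_w = ndimage.map_coordinates(self.tm, idx_m, order=1, mode="nearest")
        gm_w = np.stack(
            [ndimage.map_coordinates(self.gm[..., a], idx_m, order=1, mode="nearest")
             for a in range(3)],
            axis=-1,
        )
        grads = [np.gradient(u[..., i], *self.spacing) for i in range(3)]
        F = np.empty(u.shape[:3] + (3, 3))
        for i in range(3):
            for j in range(3):
                F[..., i, j] = grads[i][j]
            F[..., i, i] += 1.0
        J = np.linalg.det(F)
        r = (self.tf - J * tm_w) * self.mask
        n_mask = max(float(self.mask.sum()), 1.0)
        cost = float(np.sum(r**2)) / n_mask
        # frozen-Jacobian gradient: dr/du ~= -J * grad(tm)(x+u)
        g_dense = (-2.0 / n_mask * r * J)[..., None] * gm_w
        grad = self._restrict(g_dense)
        # first-difference smoothness penalty on the control grid,
        # normalised per difference so the weight is resolution-independent
        lam = self.smooth_weight
        n_diff = max(3 * (int(np.prod(self.cshape)) - 1), 1)
        for a in range(3):
            for axis in range(3):
                d = np.diff(c[a], axis=axis)
                cost += lam * float(np.sum(d**2)) / n_diff
                grad_a = np.zeros_like(c[a])
                sl_hi = [slice(None)] * 3
                sl_lo = [slice(None)] * 3
                sl_hi[axis] = slice(1, None)
                sl_lo[axis] = slice(None, -1)
                grad_a[tuple(sl_hi)] += 2 * lam / n_diff * d
                grad_a[tuple(sl_lo)] -= 2 * lam / n_diff * d
                grad[a] += grad_a
        return cost, grad.ravel()


def deformable_register_sstvd(
    exp: ImageVolume,
    insp: ImageVolume,
    mask: LabelMap,
    *,
    levels: tuple[int, ...] = (4, 2),
    control_spacing_mm: tuple[float, ...] = (16.0, 8.0),
    max_iter: tuple[int, ...] = (80, 60),
    smooth_weight: float = 0.03,
) -> DisplacementField:
    """Mass-preserving deformable registration of expiration to inspiration CT.

    Minimises, over a coarse-to-fine free-form deformation, the sum of
    squared tissue-volume differences between the inspiration image and
    the Jacobian-weighted warped expiration image, plus a first-difference
    smoothness penalty on the control grid. The returned field lives on
    the inspiration (fixed) grid and maps TLC points to their expiration
    positions.

    ``levels``/``control_spacing_mm``/``max_iter`` set the image
    downsampling factor, control-node spacing and optimiser budget of each
    resolution level.
    """
    if not np.any(mask.lung_mask):
        raise ValueError("empty lung mask")
    lo_f = np.asarray(insp.origin)
    hi_f = lo_f + (np.asarray(insp.shape) - 1) * np.asarray(insp.spacing)
    lo_m = np.asarray(exp.origin)
    hi_m = lo_m + (np.asarray(exp.shape) - 1) * np.asarray(exp.spacing)
    if np.any(hi_f < lo_m) or np.any(hi_m < lo_f):
        raise ValueError("fixed and moving volumes do not overlap in physical space")

    tf_full = _tissue_volume_image(insp)
    tm_full = _tissue_volume_image(exp)
    mask_full = ndimage.binary_dilation(mask.lung_mask, iterations=2).astype(float)

    c = None
    prev_level = None
    for factor, cs_mm, iters in zip(levels, control_spacing_mm, max_iter):
        level = _FFDLevel(
            _downsample(tf_full, factor),
            _downsample(tm_full, factor),
            _downsample(mask_full, factor, binary=True),
            np.asarray(insp.spacing) * factor,
            insp.origin,
            np.asarray(exp.spacing) * factor,
            exp.origin,
            cs_mm,
            smooth_weight,
        )
        if c is None:
            c = np.zeros((3,) + level.cshape)
        else:
            # resample previous control grid onto the new one
            nodes = np.stack(
                np.meshgrid(*[np.arange(s) for s in level.cshape], indexing="ij"),
                axis=-1,
            ).reshape(-1, 3)
            world = level.c_origin + nodes * level.c_spacing
            ic_prev = (world - prev_level.c_origin) / prev_level.c_spacing
            ic_prev = np.clip(ic_prev, 0, np.asarray(prev_level.cshape) - 1.0)
            c = np.stack(
                [
                    ndimage.map_coordinates(c[a], ic_prev.T, order=1, mode="nearest")
                    for a in range(3)
                ]
            ).reshape((3,) + level.cshape)
        res = optimize.minimize(
            level.cost_grad, c.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": iters, "ftol": 1e-10, "gtol": 1e-8},
        )
        c = res.x.reshape((3,) + level.cshape)
        prev_level = level

    # evaluate the final control grid on the full-resolution fixed grid
    final = _FFDLevel(
        tf_full, tm_full, mask_full,
        insp.spacing, insp.origin, exp.spacing, exp.origin,
        control_spacing_mm[-1], smooth_weight,
    )
    u = _resample_controls(c, prev_level, final)
    return DisplacementField(u, insp.spacing, insp.origin)


def _resample_controls(c: np.ndarray, src: _FFDLevel, dst: _FFDLevel) -> np.ndarray:
    """Evaluate control coefficients of ``src`` on the dense grid of ``dst``."""
    ic = (dst.world - src.c_origin) / src.c_spacing
    idx8, w8 = _trilinear_weights(ic, src.cshape)
    flat = c.reshape(3, -1)
    u = np.einsum("kn,ckn->nc", w8, flat[:, idx8])
    return u.reshape(dst.tf.shape + (3,))
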