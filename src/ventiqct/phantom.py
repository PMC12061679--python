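"""Synthetic lung phantoms with known ground truth.

The generator emulates the statistical structure the analysis assumes,
on a scaled-down lung:

* paired inspiration (TLC) / expiration (FRC-like) CT volumes in HU,
  linked by a known smooth contraction whose Jacobian J < 1 encodes
  regional ventilation, with tissue mass preserved voxel-wise
  (tissue fraction scales by 1/J on deflation);
* a five-lobe ellipsoidal lung with per-voxel disease classes (normal /
  gas-trapped fSAD / emphysema) seeded as smooth blobs at exact target
  fractions, with HU drawn so the parametric-response-map thresholds
  reproduce the seeded classes on the registered pair;
* a SPECT-like tracer volume proportional to regional air-volume change,
  with elevated deposition in gas-trapped regions plus focal hot spots,
  blurred to SPECT resolution, resampled onto a coarse misaligned grid,
  and optionally Poisson-degraded;
* a two-wave bivariate panel generator with a controllable cross-lagged
  effect for calibrating the causal-direction analysis.

All randomness flows from ``PhantomSpec.seed``; identical specs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import DisplacementField, ImageVolume, LabelMap, LOBE_LABELS
from .registration import deformation_metrics

__all__ = [
    "CLASS_NAMES",
    "CLASS_NOT_LUNG",
    "CLASS_NORMAL",
    "CLASS_FSAD",
    "CLASS_EMPH",
    "PhantomSpec",
    "PhantomTruth",
    "make_ct_pair",
    "make_spect",
    "make_panel_dataset",
]

CLASS_NOT_LUNG, CLASS_NORMAL, CLASS_FSAD, CLASS_EMPH = 0, 1, 2, 3
CLASS_NAMES = {0: "NotLung", 1: "Normal", 2: "fSAD", 3: "Emph"}

# PRM boundaries in tissue-fraction units: insp -950 HU <-> beta 0.05,
# exp -856 HU <-> beta 0.144.
_BETA_INSP_THR = 0.05
_BETA_EXP_THR = 0.144


@dataclass
class PhantomSpec:
    """Generator configuration; defaults are the reference study conditions."""

    grid_shape: tuple[int, int, int] = (96, 96, 88)
    ct_spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    spect_spacing_mm: tuple[float, float, float] = (3.895, 3.895, 3.895)
    fsad_fraction: float = 0.15
    emph_fraction: float = 0.10
    n_hotspots: int = 2
    hotspot_amplitude: float = 6.0
    fsad_tracer_boost: float = 2.0
    deformation_magnitude: float = 6.0
    noise_model: str = "none"  # {"none", "poisson"}
    mean_counts: float = 150.0
    ventilation_mode: str = "jacobian"  # {"jacobian", "uniform"}
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValueError(f"degenerate grid {self.grid_shape}: need >= 16 voxels per axis")
        if any(s <= 0 for s in self.ct_spacing_mm) or any(s <= 0 for s in self.spect_spacing_mm):
            raise ValueError("spacings must be positive")
        if not (0 <= self.fsad_fraction <= 1 and 0 <= self.emph_fraction <= 1):
            raise ValueError("class fractions must lie in [0, 1]")
        if self.fsad_fraction + self.emph_fraction > 1:
            raise ValueError("fsad_fraction + emph_fraction must not exceed 1")
        if self.n_hotspots < 0:
            raise ValueError("n_hotspots must be >= 0")
        if self.n_hotspots > 0 and self.hotspot_amplitude <= 1:
            raise ValueError("hotspot_amplitude must exceed 1")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.ventilation_mode not in ("jacobian", "uniform"):
            raise ValueError(f"unknown ventilation mode {self.ventilation_mode!r}")
        if self.deformation_magnitude < 0:
            raise ValueError("deformation_magnitude must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth accompanying one generated phantom."""

    class_map: np.ndarray  # CLASS_* labels on the inspiration grid
    true_displacement: DisplacementField  # TLC -> expiration, on the TLC grid
    true_lobar_ventilation: pd.Series  # per-lobe air-volume-change fractions, sum 1
    jacobian: np.ndarray  # per-voxel J of the true field
    exp_lobes: LabelMap  # lobe labels in the expiration configuration
    exp_warped_true: ImageVolume  # expiration HU pulled back with the true field
    true_hotspot_centers: list[np.ndarray] = dc_field(default_factory=list)  # world mm
    spect_offset_mm: np.ndarray | None = None  # rigid misalignment of the SPECT grid
    tracer_clean: ImageVolume | None = None  # noise-free tracer on the TLC grid
    # lung tissue volumes (mL) at both configurations, evaluated with
    # partial-volume boundary weights; equal up to quadrature error when
    # mass is conserved
    tissue_volume_insp_ml: float = np.nan
    tissue_volume_exp_ml: float = np.nan

    def class_fraction(self, cls: int) -> float:
        lung = self.class_map > 0
        return float(np.mean(self.class_map[lung] == cls))


# --------------------------------------------------------------------------
# geometry and fields
# --------------------------------------------------------------------------

def _world_axes(spec: PhantomSpec):
    return [spec.ct_spacing_mm[i] * np.arange(spec.grid_shape[i]) for i in range(3)]


def _lobe_map(spec: PhantomSpec) -> tuple[LabelMap, np.ndarray]:
    """Two ellipsoidal lungs split into five lobes by axial planes."""
    xs, ys, zs = np.meshgrid(*_world_axes(spec), indexing="ij")
    E = np.array(spec.grid_shape) * np.array(spec.ct_spacing_mm)
    centers = {
        "L": np.array([0.32 * E[0], 0.52 * E[1], 0.52 * E[2]]),
        "R": np.array([0.68 * E[0], 0.50 * E[1], 0.52 * E[2]]),
    }
    semi = {
        "L": np.array([0.15 * E[0], 0.26 * E[1], 0.34 * E[2]]),
        "R": np.array([0.16 * E[0], 0.27 * E[1], 0.35 * E[2]]),
    }
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    for side in ("L", "R"):
        c, a = centers[side], semi[side]
        rho = ((xs - c[0]) / a[0]) ** 2 + ((ys - c[1]) / a[1]) ** 2 + ((zs - c[2]) / a[2]) ** 2
        inside = rho < 1.0
        z_rel = (zs - (c[2] - a[2])) / (2 * a[2])  # 0 at lobe base, 1 at apex
        if side == "L":
            labels[inside & (z_rel >= 0.55)] = LOBE_LABELS["LUL"]
            labels[inside & (z_rel < 0.55)] = LOBE_LABELS["LLL"]
        else:
            labels[inside & (z_rel >= 0.66)] = LOBE_LABELS["RUL"]
            labels[inside & (z_rel < 0.66) & (z_rel >= 0.40)] = LOBE_LABELS["RML"]
            labels[inside & (z_rel < 0.40)] = LOBE_LABELS["RLL"]
    body_c = 0.5 * E
    body_a = np.array([0.46 * E[0], 0.42 * E[1], 0.47 * E[2]])
    body = (
        ((xs - body_c[0]) / body_a[0]) ** 2
        + ((ys - body_c[1]) / body_a[1]) ** 2
        + ((zs - body_c[2]) / body_a[2]) ** 2
    ) < 1.0
    return LabelMap(labels, spec.ct_spacing_mm), body


def _true_displacement(spec: PhantomSpec, lung: np.ndarray) -> np.ndarray:
    """Smooth anisotropic contraction toward the thorax centre, scaled so the
    peak displacement inside the lung equals ``deformation_magnitude``."""
    if spec.deformation_magnitude == 0:
        return np.zeros(spec.grid_shape + (3,))
    xs, ys, zs = np.meshgrid(*_world_axes(spec), indexing="ij")
    E = np.array(spec.grid_shape) * np.array(spec.ct_spacing_mm)
    c = 0.5 * E
    # diaphragm-dominant contraction with a gentle harmonic modulation so
    # the Jacobian varies regionally (regional ventilation differences)
    u = np.empty(spec.grid_shape + (3,))
    u[..., 0] = -0.06 * (xs - c[0]) * (1 + 0.25 * np.sin(2 * np.pi * (ys - c[1]) / E[1]))
    u[..., 1] = -0.08 * (ys - c[1]) * (1 + 0.25 * np.sin(2 * np.pi * (zs - c[2]) / E[2]))
    u[..., 2] = -0.13 * (zs - c[2]) * (1 + 0.25 * np.cos(2 * np.pi * (xs - c[0]) / E[0]))
    peak = float(np.linalg.norm(u[lung], axis=-1).max())
    return u * (spec.deformation_magnitude / peak)


def _smooth_field(shape, rng, sigma_voxels: float) -> np.ndarray:
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_voxels)
    return (g - g.mean()) / (g.std() + 1e-12)


def _inverse_map(u: np.ndarray, spec: PhantomSpec, n_iter: int = 20) -> np.ndarray:
    """Fixed-point inversion of y = x + u(x); returns x(y) on the same grid."""
    xs, ys, zs = np.meshgrid(*_world_axes(spec), indexing="ij")
    y = np.stack([xs, ys, zs], axis=-1)
    spacing = np.asarray(spec.ct_spacing_mm)
    x = y.copy()
    for _ in range(n_iter):
        idx = np.moveaxis(x / spacing, -1, 0)
        ux = np.stack(
            [ndimage.map_coordinates(u[..., a], idx, order=1, mode="nearest") for a in range(3)],
            axis=-1,
        )
        x = y - ux
    return x


def _sample(volume: np.ndarray, points_world: np.ndarray, spacing, order: int = 1) -> np.ndarray:
    idx = np.moveaxis(points_world / np.asarray(spacing), -1, 0)
    return ndimage.map_coordinates(volume.astype(float), idx, order=order, mode="nearest")


# --------------------------------------------------------------------------
# CT pair
# --------------------------------------------------------------------------

def make_ct_pair(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume, LabelMap, PhantomTruth]:
    """Generate a registered inspiration/expiration CT pair with ground truth.

    The expiration volume is the inspiration volume pushed through the true
    contraction with HU adjusted for local volume change: tissue fraction
    scales by 1/J, so tissue mass is conserved voxel-wise. HU values are
    drawn per seeded class so that the PRM thresholds (-950 insp / -856 exp)
    reproduce the seeded class map on the registered pair.
    """
    rng = np.random.default_rng(spec.seed)
    lobes, body = _lobe_map(spec)
    lung = lobes.lung_mask

    u = _true_displacement(spec, lung)
    field = DisplacementField(u, spec.ct_spacing_mm)
    J = deformation_metrics(field).jacobian
    if np.any(J[lung] <= 0.3):
        raise ValueError("requested deformation collapses lung voxels (J <= 0.3)")

    # -- seeded classes: smooth blobs at exact voxel-count fractions --------
    # a standoff term keeps disease blobs off the pleural surface, where
    # partial-volume mixing with the chest wall would corrupt recovery
    class_map = np.zeros(spec.grid_shape, dtype=np.int16)
    class_map[lung] = CLASS_NORMAL
    g = _smooth_field(spec.grid_shape, rng, sigma_voxels=8.0)
    edge_dist = ndimage.distance_transform_edt(lung)  # voxels to lung surface
    g = g + 3.0 * np.exp(-((edge_dist / 3.0) ** 2))
    gl = g[lung]
    if spec.emph_fraction > 0:
        q_e = np.quantile(gl, spec.emph_fraction)
        class_map[lung & (g < q_e)] = CLASS_EMPH
    if spec.fsad_fraction > 0:
        q_e = np.quantile(gl, spec.emph_fraction)
        q_f = np.quantile(gl, spec.emph_fraction + spec.fsad_fraction)
        class_map[lung & (g >= q_e) & (g < q_f)] = CLASS_FSAD

    # -- tissue fractions consistent with the PRM thresholds ---------------
    # Class levels sit symmetrically around each decision boundary so that
    # the partial-volume flips caused by resampling at class interfaces
    # cancel to first order and seeded fractions are preserved.
    t = np.tanh(_smooth_field(spec.grid_shape, rng, sigma_voxels=4.0))
    beta = np.full(spec.grid_shape, 1.0)  # body soft tissue
    beta[~body] = 0.0  # air outside the thorax
    normal = class_map == CLASS_NORMAL
    fsad = class_map == CLASS_FSAD
    emph = class_map == CLASS_EMPH
    thr_e = _BETA_EXP_THR * J  # expiration threshold in inspiration-beta units
    d_exp = 0.045  # half-gap across the fSAD | normal boundary
    d_insp = 0.018  # half-gap across the emphysema | fSAD boundary
    beta[normal] = (thr_e + d_exp + 0.010 * t)[normal]
    beta[fsad] = np.clip(thr_e - d_exp + 0.004 * t, _BETA_INSP_THR + 0.004, None)[fsad]
    beta[emph] = np.clip(_BETA_INSP_THR - d_insp + 0.004 * t, 0.008, None)[emph]

    insp_hu = -1000.0 * (1.0 - beta)
    insp = ImageVolume(insp_hu, spec.ct_spacing_mm)

    # -- expiration volume: push forward with mass conservation -------------
    beta_exp_on_insp = np.where(lung, beta / J, beta)
    exp_warped_true = ImageVolume(-1000.0 * (1.0 - beta_exp_on_insp), spec.ct_spacing_mm)
    voxel_ml = float(np.prod(spec.ct_spacing_mm)) / 1000.0
    tv_insp = float(beta[lung].sum()) * voxel_ml
    if spec.deformation_magnitude == 0:
        exp = ImageVolume(insp_hu.copy(), spec.ct_spacing_mm)
        exp_lobes = LabelMap(lobes.data.copy(), spec.ct_spacing_mm)
        tv_exp = tv_insp
    else:
        x_of_y = _inverse_map(u, spec)
        # warp lung and body separately: the lung tissue field is extended
        # outside the lung by nearest-neighbour fill before interpolation,
        # so lung-edge voxels never mix with chest-wall values
        fill_idx = ndimage.distance_transform_edt(
            ~lung, return_distances=False, return_indices=True
        )
        beta_lung_filled = np.where(lung, beta_exp_on_insp, beta_exp_on_insp[tuple(fill_idx)])
        exp_lobes = LabelMap(
            _sample(lobes.data, x_of_y, spec.ct_spacing_mm, order=0).astype(np.int16),
            spec.ct_spacing_mm,
        )
        exp_lung = exp_lobes.lung_mask
        beta_body = np.where(lung, 1.0, beta)  # body with the lung cavity filled in
        beta_lung_exp = np.clip(
            _sample(beta_lung_filled, x_of_y, spec.ct_spacing_mm, order=3), 0.0, 1.0
        )
        beta_exp = np.where(exp_lung, beta_lung_exp, _sample(beta_body, x_of_y, spec.ct_spacing_mm))
        exp = ImageVolume(-1000.0 * (1.0 - beta_exp), spec.ct_spacing_mm)
        lung_weight = _sample(lung.astype(float), x_of_y, spec.ct_spacing_mm)
        tv_exp = float((beta_lung_exp * lung_weight).sum()) * voxel_ml

    # -- true lobar ventilation from the air-volume change (1 - J) ----------
    dv = np.where(lung, 1.0 - J, 0.0)
    per_lobe = pd.Series(
        {name: float(dv[lobes.lobe_mask(name)].sum()) for name in lobes.lobe_names()}
    )
    total = per_lobe.sum()
    lobar = per_lobe / total if abs(total) > 1e-12 else per_lobe * np.nan

    truth = PhantomTruth(
        class_map=class_map,
        true_displacement=field,
        true_lobar_ventilation=lobar,
        jacobian=J,
        exp_lobes=exp_lobes,
        exp_warped_true=exp_warped_true,
        tissue_volume_insp_ml=tv_insp,
        tissue_volume_exp_ml=tv_exp,
    )
    return insp, exp, lobes, truth


# --------------------------------------------------------------------------
# SPECT
# --------------------------------------------------------------------------

def make_spect(spec: PhantomSpec, truth: PhantomTruth, lobes: LabelMap) -> ImageVolume:
    """Generate a misaligned, coarse SPECT-like tracer volume.

    The tracer field is proportional to per-voxel fractional air-volume
    change (1 - J), boosted multiplicatively in gas-trapped regions
    (``fsad_tracer_boost``) and at ``n_hotspots`` focal Gaussian hot spots
    seeded inside fSAD tissue (sigma = 2 SPECT voxels), emulating aerosol
    deposition at narrowed airways. The field is pushed to the expiration
    configuration, blurred to SPECT resolution, resampled onto the coarse
    SPECT grid displaced by a recorded random rigid offset, and degraded
    with Poisson counting noise when requested.

    Records ``true_hotspot_centers`` (world mm, TLC frame),
    ``spect_offset_mm`` and the noise-free TLC-domain tracer in ``truth``.
    """
    if truth.true_displacement is None:
        raise ValueError("truth must carry the true displacement field")
    if truth.class_map.shape != tuple(lobes.shape):
        raise ValueError("truth and lobes must share the CT grid")
    rng = np.random.default_rng((spec.seed, 1))
    lung = lobes.lung_mask
    J = truth.jacobian

    if spec.ventilation_mode == "uniform" or spec.deformation_magnitude == 0:
        vent = lung.astype(float)
    else:
        vent = np.where(lung, np.clip(1.0 - J, 0.0, None), 0.0)

    # deposition enhancement in gas-trapped tissue (causal path fSAD -> CV)
    fsad_ind = ndimage.gaussian_filter((truth.class_map == CLASS_FSAD).astype(float), 2.0)
    boost = 1.0 + (spec.fsad_tracer_boost - 1.0) * np.clip(fsad_ind, 0.0, 1.0)

    # focal hot spots, preferentially inside fSAD blobs
    centers = []
    cand = np.argwhere(truth.class_map == CLASS_FSAD)
    if len(cand) == 0:
        cand = np.argwhere(lung)
    sigma_mm = 2.0 * float(np.mean(spec.spect_spacing_mm))
    if spec.n_hotspots > 0 and len(cand) > 0:
        xs, ys, zs = np.meshgrid(
            *[spec.ct_spacing_mm[i] * np.arange(spec.grid_shape[i]) for i in range(3)],
            indexing="ij",
        )
        picks = cand[rng.choice(len(cand), size=spec.n_hotspots, replace=False)]
        for p in picks:
            cw = p * np.asarray(spec.ct_spacing_mm)
            centers.append(cw)
            d2 = (xs - cw[0]) ** 2 + (ys - cw[1]) ** 2 + (zs - cw[2]) ** 2
            boost = boost * (1.0 + (spec.hotspot_amplitude - 1.0) * np.exp(-d2 / (2 * sigma_mm**2)))
    tracer_tlc = vent * boost
    truth.true_hotspot_centers = centers
    truth.tracer_clean = ImageVolume(tracer_tlc, spec.ct_spacing_mm)

    # push to the expiration configuration (SPECT is acquired near FRC)
    if spec.deformation_magnitude == 0:
        tracer_exp = tracer_tlc
        exp_lung = lung.astype(float)
    else:
        x_of_y = _inverse_map(truth.true_displacement.vectors, spec)
        tracer_exp = _sample(tracer_tlc, x_of_y, spec.ct_spacing_mm)
        exp_lung = (truth.exp_lobes.data > 0).astype(float)

    # blur to SPECT resolution, mask-normalised so the edge falloff does not
    # leak signal out of the lung
    sigma_blur = 0.5 * np.asarray(spec.spect_spacing_mm) / np.asarray(spec.ct_spacing_mm)
    num = ndimage.gaussian_filter(tracer_exp * exp_lung, sigma_blur)
    den = ndimage.gaussian_filter(exp_lung, sigma_blur)
    with np.errstate(invalid="ignore", divide="ignore"):
        blurred = np.where(den > 1e-3, num / den, 0.0) * (den > 1e-3)

    # resample onto the coarse SPECT grid with a random rigid offset
    offset = rng.uniform(-1.0, 1.0, size=3)
    offset = offset / np.linalg.norm(offset) * rng.uniform(4.0, 8.0)
    truth.spect_offset_mm = offset
    E = np.array(spec.grid_shape) * np.array(spec.ct_spacing_mm)
    n_spect = np.ceil(E / np.asarray(spec.spect_spacing_mm)).astype(int)
    axes = [np.asarray(spec.spect_spacing_mm)[i] * np.arange(n_spect[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1) - offset  # content shifted by +offset
    counts = _sample(blurred, pts, spec.ct_spacing_mm)

    if spec.mean_counts > 0 and counts.max() > 0:
        counts = counts * (spec.mean_counts / counts[counts > 0].mean())
    if spec.noise_model == "poisson":
        counts = rng.poisson(np.clip(counts, 0.0, None)).astype(float)
    return ImageVolume(counts, spec.spect_spacing_mm)


# --------------------------------------------------------------------------
# two-wave panel generator
# --------------------------------------------------------------------------

def make_panel_dataset(
    n_subjects: int,
    cross_lag_effect: float,
    seed: int,
    *,
    stability: tuple[float, float] = (0.5, 0.5),
    synchronous: float = 0.4,
) -> pd.DataFrame:
    """Two-wave bivariate Gaussian panel with a one-directional cross-lag.

    Structural model on standardised variables (x plays the fSAD role,
    y the ventilation-heterogeneity role):

        x1 ~ N(0, 1)
        y1 = synchronous * x1 + e
        x2 = stability_x * x1 + e          (no y1 -> x2 path)
        y2 = stability_y * y1 + cross_lag_effect * x1 + e

    Residual variances are set so every variable has unit variance; a
    parameter combination implying a non-positive residual variance (or
    any |correlation| >= 1) is rejected.
    """
    if n_subjects < 8:
        raise ValueError("need at least 8 subjects")
    sx, sy = stability
    for name, v in (("stability_x", sx), ("stability_y", sy), ("synchronous", synchronous)):
        if abs(v) >= 1:
            raise ValueError(f"|{name}| must be < 1, got {v}")
    var_y1 = 1.0 - synchronous**2
    var_x2 = 1.0 - sx**2
    var_y2 = 1.0 - (sy**2 + cross_lag_effect**2 + 2 * sy * cross_lag_effect * synchronous)
    if min(var_y1, var_x2, var_y2) <= 0:
        raise ValueError(
            "implied covariance is not positive definite: residual variances "
            f"({var_y1:.3f}, {var_x2:.3f}, {var_y2:.3f}) must all be positive"
        )
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n_subjects)
    y1 = synchronous * x1 + np.sqrt(var_y1) * rng.standard_normal(n_subjects)
    x2 = sx * x1 + np.sqrt(var_x2) * rng.standard_normal(n_subjects)
    y2 = sy * y1 + cross_lag_effect * x1 + np.sqrt(var_y2) * rng.standard_normal(n_subjects)
    return pd.DataFrame(
        {"subject": np.arange(1, n_subjects + 1), "x1": x1, "x2": x2, "y1": y1, "y2": y2}
    )
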