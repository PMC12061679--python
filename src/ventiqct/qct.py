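"""Quantitative-CT biomarkers from registered inspiration/expiration pairs.

Implements the parametric response map (PRM) classification into normal,
gas-trapped (fSAD) and emphysematous voxels, tissue-fraction and lobar
air-volume-change accounting, airway-measurement normalisation against
healthy-predicted values, and per-visit table summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .images import ImageVolume, LabelMap, DisplacementField, UPPER_LOBES, MID_LOWER_LOBES
from .registration import deformation_metrics

__all__ = [
    "PRM_THR_INSP",
    "PRM_THR_EXP",
    "PRMResult",
    "LobarVentilation",
    "AirwayRecord",
    "tissue_fraction",
    "prm_classify",
    "lobar_ventilation",
    "normalize_airway",
    "summarize_table",
]

# PRM thresholds (HU): emphysema below both, gas trapping below the
# expiration threshold only. Standard values from the PRM literature;
# overridable per call.
PRM_THR_INSP = -950.0
PRM_THR_EXP = -856.0


def tissue_fraction(ct: ImageVolume, mask: LabelMap | None = None) -> np.ndarray:
    """Per-voxel tissue fraction from the air/tissue HU mixture model.

    beta = clamp((HU + 1000) / 1000, 0, 1); -1000 HU is pure air, 0 HU pure
    soft tissue. Outside the mask (if given) the value is set to NaN.
    """
    beta = np.clip((ct.data + 1000.0) / 1000.0, 0.0, 1.0)
    if mask is not None:
        beta = np.where(mask.lung_mask, beta, np.nan)
    return beta


@dataclass
class PRMResult:
    """Per-region PRM percentages and counts (regions = lobes + 'Total')."""

    table: pd.DataFrame  # index: region; columns: fsad_pct, emph_pct, normal_pct, n_*
    thr_insp: float
    thr_exp: float

    def pct(self, region: str, which: str) -> float:
        return float(self.table.loc[region, f"{which}_pct"])

    @property
    def fsad_total(self) -> float:
        return self.pct("Total", "fsad")

    @property
    def emph_total(self) -> float:
        return self.pct("Total", "emph")


def prm_classify(
    insp: ImageVolume,
    exp_warped: ImageVolume,
    lobes: LabelMap,
    thr_insp: float = PRM_THR_INSP,
    thr_exp: float = PRM_THR_EXP,
) -> PRMResult:
    """Parametric response map on a registered inspiration/expiration pair.

    Voxel rule (HU): emphysema if insp < thr_insp and exp < thr_exp;
    fSAD if insp >= thr_insp and exp < thr_exp; normal otherwise.
    Percentages are of lung voxels, reported per lobe and for the total lung.
    """
    if not insp.same_grid_as(exp_warped) or not insp.same_grid_as(lobes):
        raise ValueError("insp, exp_warped and lobes must share one grid")
    lung = lobes.lung_mask
    if not np.any(lung):
        raise ValueError("empty lung mask")

    below_exp = exp_warped.data < thr_exp
    emph = lung & (insp.data < thr_insp) & below_exp
    fsad = lung & (insp.data >= thr_insp) & below_exp
    normal = lung & ~emph & ~fsad

    rows = {}
    regions = lobes.lobe_names() + ["Total"]
    for region in regions:
        m = lung if region == "Total" else lobes.lobe_mask(region)
        n = int(m.sum())
        n_e, n_f, n_n = int(emph[m].sum()), int(fsad[m].sum()), int(normal[m].sum())
        rows[region] = dict(
            n_voxels=n,
            n_emph=n_e,
            n_fsad=n_f,
            n_normal=n_n,
            emph_pct=100.0 * n_e / n if n else np.nan,
            fsad_pct=100.0 * n_f / n if n else np.nan,
            normal_pct=100.0 * n_n / n if n else np.nan,
        )
    return PRMResult(pd.DataFrame(rows).T, thr_insp=thr_insp, thr_exp=thr_exp)


@dataclass
class LobarVentilation:
    """Lobar air-volume change (mL), its whole-lung fractions, and the
    upper-to-middle/lower distribution ratio."""

    dvair_ml: pd.Series  # per lobe
    dvairf: pd.Series  # per lobe, sums to 1
    dvair_uml_f: float


def lobar_ventilation(
    field: DisplacementField,
    lobes: LabelMap,
    insp: ImageVolume | None = None,
    exp_warped: ImageVolume | None = None,
    upper_lobes: frozenset[str] = UPPER_LOBES,
    mid_lower_lobes: frozenset[str] = MID_LOWER_LOBES,
) -> LobarVentilation:
    """Lobar air-volume change from the expiration→inspiration registration.

    The field lives on the inspiration (TLC) grid and maps each TLC point to
    its expiration position; J = det(I + grad u) < 1 under lung deflation.
    Per-voxel air-volume change is the air content at TLC minus the air
    content of the corresponding (contracted) expiration region:

        dVair = v * [(1 - beta_insp) - J * (1 - beta_exp_warped)]

    When the CT images are not supplied, mass conservation
    (beta_exp = beta_insp / J) reduces this to dVair = v * (1 - J).
    """
    lung = lobes.lung_mask
    if not np.any(lung):
        raise ValueError("empty lung mask")
    J = deformation_metrics(field).jacobian
    v = lobes.voxel_volume_ml
    if insp is not None and exp_warped is not None:
        beta_i = tissue_fraction(insp)
        beta_e = tissue_fraction(exp_warped)
        dvair = v * ((1.0 - beta_i) - J * (1.0 - beta_e))
    else:
        dvair = v * (1.0 - J)

    per_lobe = pd.Series(
        {name: float(dvair[lobes.lobe_mask(name)].sum()) for name in lobes.lobe_names()}
    )
    total = per_lobe.sum()
    if abs(total) < 1e-12:
        raise ValueError("zero whole-lung air-volume change; fractions undefined")
    dvairf = per_lobe / total
    upper = per_lobe[[n for n in per_lobe.index if n in upper_lobes]].sum()
    lower = per_lobe[[n for n in per_lobe.index if n in mid_lower_lobes]].sum()
    if abs(lower) < 1e-12:
        raise ValueError("zero middle+lower air-volume change; UML ratio undefined")
    return LobarVentilation(dvair_ml=per_lobe, dvairf=dvairf, dvair_uml_f=float(upper / lower))


@dataclass
class AirwayRecord:
    """One airway-site measurement with healthy-predicted reference values.

    The normalised quantities are relative deviations from the predicted
    value: Dh* = |Dh - Dh_pred| / Dh_pred, and likewise WT*.
    """

    site: str
    dh_mm: float = np.nan
    wt_mm: float = np.nan
    dh_pred_mm: float = np.nan
    wt_pred_mm: float = np.nan
    dh_norm: float = np.nan
    wt_norm: float = np.nan
    flagged: bool = False


def _rel_dev(measured: float, predicted: float) -> float:
    if predicted <= 0:
        raise ValueError(f"predicted value must be positive, got {predicted}")
    return abs(measured - predicted) / predicted


def normalize_airway(record: AirwayRecord) -> AirwayRecord:
    """Normalise hydraulic diameter and wall thickness against predictions.

    Records missing a predicted value are flagged (excluded downstream)
    rather than failing; a non-positive predicted value is an error.
    """
    dh_norm = wt_norm = np.nan
    flagged = False
    if np.isfinite(record.dh_mm) and np.isfinite(record.dh_pred_mm):
        dh_norm = _rel_dev(record.dh_mm, record.dh_pred_mm)
    else:
        flagged = True
    if np.isfinite(record.wt_mm) and np.isfinite(record.wt_pred_mm):
        wt_norm = _rel_dev(record.wt_mm, record.wt_pred_mm)
    else:
        flagged = True
    return replace(record, dh_norm=dh_norm, wt_norm=wt_norm, flagged=flagged)


def summarize_table(
    table: pd.DataFrame, variable: str, visit: str, ddof: int = 0
) -> tuple[float, float]:
    """Mean and SD of one variable at one visit, mirroring "Mean ± SD" rows.

    ``table`` is tidy with ``subject``/``visit`` columns (or index levels);
    missing values are dropped. The cohort summary tables report the
    population SD, so ``ddof`` defaults to 0.
    """
    t = table.reset_index() if table.index.nlevels > 1 else table
    vals = t.loc[t["visit"] == visit, variable].astype(float).dropna()
    if len(vals) == 0:
        raise ValueError(f"all values missing for {variable} at {visit}")
    if len(vals) < 2:
        raise ValueError(f"need >= 2 values for an SD, got {len(vals)}")
    return float(vals.mean()), float(vals.std(ddof=ddof))
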