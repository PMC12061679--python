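"""Tracer-distribution statistics on SPECT volumes aligned to the TLC CT domain.

Three scale-invariant summaries of the tracer concentration (TC) field:
the lobar share of total tracer (TC%), the whole-lung coefficient of
variation (CV_Total, heterogeneity), and the standardised maximum
(TC_Max, hot-spot magnitude). All three are computed on the SPECT volume
after resampling onto the TLC CT grid, restricted to the lung mask, and
are invariant to global rescaling of the counts — so differences in the
amount of tracer inhaled do not affect them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .images import ImageVolume, LabelMap

__all__ = ["SpectSummary", "tc_percent", "cv_total", "tc_max", "summarize_spect"]


def _lung_values(spect: ImageVolume, mask: LabelMap) -> np.ndarray:
    if not spect.same_grid_as(mask):
        raise ValueError("SPECT volume and mask must share one grid (TLC CT domain)")
    vals = spect.data[mask.lung_mask].astype(float)
    if vals.size < 2:
        raise ValueError("need >= 2 lung voxels")
    return vals


def tc_percent(spect_aligned: ImageVolume, lobes: LabelMap) -> pd.Series:
    """Lobar tracer share: lobe voxel-sum / whole-lung voxel-sum x 100."""
    if not spect_aligned.same_grid_as(lobes):
        raise ValueError("SPECT volume and lobe map must share one grid")
    total = float(spect_aligned.data[lobes.lung_mask].sum())
    if total <= 0:
        raise ValueError("zero total tracer counts in lung")
    return pd.Series(
        {
            name: 100.0 * float(spect_aligned.data[lobes.lobe_mask(name)].sum()) / total
            for name in lobes.lobe_names()
        }
    )


def cv_total(spect_aligned: ImageVolume, mask: LabelMap) -> float:
    """Whole-lung heterogeneity: sample SD / mean of voxel tracer counts."""
    vals = _lung_values(spect_aligned, mask)
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("zero mean tracer concentration")
    return float(vals.std(ddof=1) / mean)


def tc_max(spect_aligned: ImageVolume, mask: LabelMap) -> float:
    """Hot-spot magnitude: maximum voxel count / mean voxel count.

    The max/mean standardisation keeps the statistic dimensionless and
    independent of the inhaled tracer amount; it equals 1 for a perfectly
    homogeneous field.
    """
    vals = _lung_values(spect_aligned, mask)
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("zero mean tracer concentration")
    return float(vals.max() / mean)


@dataclass
class SpectSummary:
    tc_sum: pd.Series  # per-lobe raw tracer sums
    tc_pct: pd.Series  # per-lobe share of whole-lung tracer (%)
    cv_total: float
    tc_max: float


def summarize_spect(spect_aligned: ImageVolume, lobes: LabelMap) -> SpectSummary:
    """All per-subject-visit SPECT statistics in one pass."""
    tc_pct = tc_percent(spect_aligned, lobes)
    sums = pd.Series(
        {
            name: float(spect_aligned.data[lobes.lobe_mask(name)].sum())
            for name in lobes.lobe_names()
        }
    )
    return SpectSummary(
        tc_sum=sums,
        tc_pct=tc_pct,
        cv_total=cv_total(spect_aligned, lobes),
        tc_max=tc_max(spect_aligned, lobes),
    )
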