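"""Small-cohort statistical layer: effect-size-first correlation analysis,
exploratory factor analysis, and cross-lagged panel analysis.

All correlation reporting is organised around Pearson's r with the
conventional strength bands used in ventilation-imaging studies
(|r| <= 0.3 negligible, 0.3-0.5 weak, 0.5-0.7 moderate, 0.7-0.9 strong,
> 0.9 very strong), because with eight subjects the effect size, not the
p-value, carries the evidential weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "EFAResult",
    "CrossLaggedResult",
    "pearson",
    "partial_correlation",
    "correlation_map",
    "parallel_analysis",
    "varimax",
    "efa_varimax",
    "cross_lagged_panel",
]

_STRENGTH_BANDS = (
    (0.3, "negligible"),
    (0.5, "weak"),
    (0.7, "moderate"),
    (0.9, "strong"),
    (np.inf, "very strong"),
)


def strength_category(r: float) -> str:
    """Map |r| to its strength band; bands are closed on the right."""
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise ValueError(f"|r| > 1: {r}")
    for upper, name in _STRENGTH_BANDS:
        if a <= upper:
            return name
    raise AssertionError("unreachable")


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    strength: str

    @property
    def large_effect(self) -> bool:
        """Effect-size highlight used in the correlation maps (|r| > 0.7)."""
        return abs(self.r) > 0.7


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x, y, *, missing: str = "pairwise") -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Parameters
    ----------
    x, y : array-like
        Paired observations; NaN encodes missingness.
    missing : {"pairwise", "raise"}
        ``pairwise`` drops incomplete pairs; ``raise`` rejects any NaN.
    """
    if missing not in ("pairwise", "raise"):
        raise ValueError(f"unknown missing policy {missing!r}")
    if missing == "raise" and (np.any(~np.isfinite(np.asarray(x, float)))
                               or np.any(~np.isfinite(np.asarray(y, float)))):
        raise ValueError("missing values present with missing='raise'")
    xc, yc = _complete_pairs(x, y)
    n = len(xc)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.std(xc) == 0 or np.std(yc) == 0:
        raise ValueError("zero variance in input vector")
    r, p = sps.pearsonr(xc, yc)
    return CorrelationResult(r=float(r), n=n, p=float(p), strength=strength_category(r))


def partial_correlation(a, b, c) -> tuple[float, int]:
    """First-order partial correlation r(a, b | c).

    Returns ``(r, n)``; the significance test uses n - 3 degrees of freedom.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    keep = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a, b, c = a[keep], b[keep], c[keep]
    n = len(a)
    if n < 4:
        raise ValueError(f"need >= 4 complete cases for a partial correlation, got {n}")
    rab = np.corrcoef(a, b)[0, 1]
    rac = np.corrcoef(a, c)[0, 1]
    rbc = np.corrcoef(b, c)[0, 1]
    denom = (1 - rac**2) * (1 - rbc**2)
    if denom <= 1e-14:
        raise ValueError("conditioning variable perfectly correlated with a or b")
    return float((rab - rac * rbc) / np.sqrt(denom)), n


_DELTA_MODES = {
    "delta(V1-V0)": ("V1", "V0"),
    "delta(V2-V1)": ("V2", "V1"),
    "delta(V2-V0)": ("V2", "V0"),
}


def correlation_map(
    table: pd.DataFrame,
    spect_vars: list[str],
    qct_vars: list[str],
    mode: str = "cross_sectional_pooled",
    deltas: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Correlation map between tracer-derived and CT-derived variables.

    ``table`` is a tidy per-subject-per-visit frame indexed (or keyed) by
    ``subject`` and ``visit``. In pooled mode, all subject-visit rows are
    treated as observations with pairwise deletion of missing values.
    Delta modes correlate per-subject between-visit changes; if a
    ``deltas`` frame (subject-indexed changes) is supplied it is used
    verbatim, otherwise changes are computed from the per-visit values.

    Returns a DataFrame of :class:`CorrelationResult` objects, rows =
    spect_vars, columns = qct_vars.
    """
    if mode == "cross_sectional_pooled":
        data = table.reset_index() if table.index.nlevels > 1 else table
    elif mode in _DELTA_MODES:
        if deltas is not None:
            data = deltas
        else:
            v_hi, v_lo = _DELTA_MODES[mode]
            wide = table.reset_index().pivot(index="subject", columns="visit")
            data = pd.DataFrame(
                {v: wide[(v, v_hi)] - wide[(v, v_lo)] for v in spect_vars + qct_vars}
            )
        n_ok = data[spect_vars + qct_vars].dropna().shape[0]
        if n_ok < 3:
            raise ValueError(f"mode {mode}: only {n_ok} subjects with both visits")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for v in spect_vars + qct_vars:
        if v not in data.columns:
            raise KeyError(f"variable {v!r} not in table")

    out = pd.DataFrame(index=spect_vars, columns=qct_vars, dtype=object)
    for sv in spect_vars:
        for qv in qct_vars:
            if sv == qv:
                x = np.asarray(data[sv], float)
                x = x[np.isfinite(x)]
                out.loc[sv, qv] = CorrelationResult(1.0, len(x), 0.0, "very strong")
            else:
                out.loc[sv, qv] = pearson(data[sv], data[qv])
    return out


def parallel_analysis(
    data: np.ndarray,
    n_reps: int = 200,
    quantile: float = 0.95,
    seed: int | None = None,
) -> int:
    """Horn's parallel analysis for the number of factors to retain.

    Eigenvalues of the observed correlation matrix are compared with the
    given quantile of eigenvalues from ``n_reps`` standard-normal datasets
    of identical shape; the retained count is the number of leading
    observed eigenvalues exceeding their random counterpart.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("constant columns in data")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    rand = np.empty((n_reps, p))
    for i in range(n_reps):
        R = np.corrcoef(rng.standard_normal((n, p)), rowvar=False)
        rand[i] = np.sort(np.linalg.eigvalsh(R))[::-1]
    thresh = np.quantile(rand, quantile, axis=0)
    above = obs > thresh
    # retain only the leading run: stop at the first eigenvalue below threshold
    k = 0
    for flag in above:
        if not flag:
            break
        k += 1
    return k


def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, int]:
    """Kaiser varimax rotation of a loading matrix.

    Returns ``(rotated, rotation, n_iter)`` with ``rotated = loadings @ rotation``
    and ``rotation`` orthogonal.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    R = np.eye(k)
    if k < 2:
        return L.copy(), R, 0
    d_old = 0.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p)
        )
        R = u @ vt
        d_new = np.sum(s)
        if d_old != 0 and (d_new - d_old) / d_old < tol:
            break
        d_old = d_new
    return L @ R, R, n_iter


@dataclass
class EFAResult:
    n_factors: int
    loadings: pd.DataFrame  # variables x factors
    variance_explained_pct: float
    key_variables: dict[str, list[str]] = field(default_factory=dict)
    rotation_iterations: int = 0


def efa_varimax(
    data: np.ndarray | pd.DataFrame,
    n_factors: int,
    loading_threshold: float = 0.6,
) -> EFAResult:
    """Principal-component factor extraction with varimax rotation.

    Loadings are eigenvector * sqrt(eigenvalue) of the correlation matrix
    (principal-component extraction on standardised variables), rotated by
    varimax. Key variables per factor are those with |loading| above the
    threshold (default 0.6).
    """
    if isinstance(data, pd.DataFrame):
        names = list(data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        names = [f"var{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if not (1 <= n_factors <= p):
        raise ValueError(f"n_factors must be in [1, {p}]")
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("constant columns in data")
    corr = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1][:n_factors]
    L = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0.0))
    Lrot, _, n_iter = varimax(L)
    # orient each factor so its largest-|loading| entry is positive
    for j in range(Lrot.shape[1]):
        if Lrot[np.argmax(np.abs(Lrot[:, j])), j] < 0:
            Lrot[:, j] = -Lrot[:, j]
    # order factors by explained variance after rotation
    ssl = np.sum(Lrot**2, axis=0)
    Lrot = Lrot[:, np.argsort(ssl)[::-1]]
    cols = [f"F{j + 1}" for j in range(n_factors)]
    loadings = pd.DataFrame(Lrot, index=names, columns=cols)
    key = {
        c: [v for v in names if abs(loadings.loc[v, c]) > loading_threshold]
        for c in cols
    }
    var_pct = float(np.sum(Lrot**2) / p * 100.0)
    return EFAResult(
        n_factors=n_factors,
        loadings=loadings,
        variance_explained_pct=var_pct,
        key_variables=key,
        rotation_iterations=n_iter,
    )


@dataclass
class CrossLaggedResult:
    """Six-correlation summary of a two-wave, two-variable panel.

    Cross-lagged entries are partial correlations with the prior wave of
    the outcome variable partialled out; verdicts are one-sided tests of
    r > 0 at ``alpha``.
    """

    r_sync1: float
    r_sync2: float
    r_stab_x: float
    r_stab_y: float
    r_cross_xy: float  # r(x1, y2 | y1)
    r_cross_yx: float  # r(y1, x2 | x1)
    p_values: dict[str, float]
    significant: dict[str, bool]
    n: int
    alpha: float
    assumption_flags: dict[str, bool]

    @property
    def causal_direction(self) -> str:
        sx = self.significant["r_cross_xy"]
        sy = self.significant["r_cross_yx"]
        if sx and not sy:
            return "x->y"
        if sy and not sx:
            return "y->x"
        if sx and sy:
            return "reciprocal"
        return "none"


def _one_sided_p(r: float, df: int) -> float:
    """P(r > 0) via the t transform of a (partial) correlation."""
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    t = r * np.sqrt(df / (1 - r**2))
    return float(sps.t.sf(t, df))


def cross_lagged_panel(x1, x2, y1, y2, alpha: float = 0.05) -> CrossLaggedResult:
    """Cross-lagged panel analysis on a two-wave bivariate panel.

    Computes the two synchronous correlations r(x1,y1), r(x2,y2), the two
    stability correlations r(x1,x2), r(y1,y2), and the two cross-lagged
    partial correlations r(x1,y2 | y1) and r(y1,x2 | x1). Each is tested
    one-sided against zero (greater-than), simple correlations with
    n - 2 df and partials with n - 3 df. Assumption flags record whether
    synchronicity (both synchronous r significant) and stationarity (both
    stability r significant) hold.
    """
    arrs = [np.asarray(v, float) for v in (x1, x2, y1, y2)]
    keep = np.logical_and.reduce([np.isfinite(a) for a in arrs])
    x1, x2, y1, y2 = (a[keep] for a in arrs)
    n = len(x1)
    if n < 4:
        raise ValueError(f"need >= 4 complete cases, got {n}")
    for name, a in (("x1", x1), ("x2", x2), ("y1", y1), ("y2", y2)):
        if np.std(a) == 0:
            raise ValueError(f"zero variance in {name}")

    r_sync1 = float(np.corrcoef(x1, y1)[0, 1])
    r_sync2 = float(np.corrcoef(x2, y2)[0, 1])
    r_stab_x = float(np.corrcoef(x1, x2)[0, 1])
    r_stab_y = float(np.corrcoef(y1, y2)[0, 1])
    try:
        r_cross_xy, _ = partial_correlation(x1, y2, y1)
        r_cross_yx, _ = partial_correlation(y1, x2, x1)
    except ValueError as e:
        raise ValueError(f"cross-lagged partials undefined: {e}") from e

    p = {
        "r_sync1": _one_sided_p(r_sync1, n - 2),
        "r_sync2": _one_sided_p(r_sync2, n - 2),
        "r_stab_x": _one_sided_p(r_stab_x, n - 2),
        "r_stab_y": _one_sided_p(r_stab_y, n - 2),
        "r_cross_xy": _one_sided_p(r_cross_xy, n - 3),
        "r_cross_yx": _one_sided_p(r_cross_yx, n - 3),
    }
    sig = {k: v < alpha for k, v in p.items()}
    flags = {
        "synchronicity": sig["r_sync1"] and sig["r_sync2"],
        "stationarity": sig["r_stab_x"] and sig["r_stab_y"],
    }
    return CrossLaggedResult(
        r_sync1=r_sync1,
        r_sync2=r_sync2,
        r_stab_x=r_stab_x,
        r_stab_y=r_stab_y,
        r_cross_xy=r_cross_xy,
        r_cross_yx=r_cross_yx,
        p_values=p,
        significant=sig,
        n=n,
        alpha=alpha,
        assumption_flags=flags,
    )
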