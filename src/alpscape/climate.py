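"""Climate grids, bioclimatic variables and delta downscaling.

Future climate surfaces are built by the classic anomaly ("delta") chain:
monthly differences between a coarse climate model's future and historical
periods are interpolated to the 100 m grid with bicubic splines and added
to the downscaled current climatology. Precipitation can additionally be
downscaled from coarse support points by ordinary kriging with elevation
as external drift. From the monthly fields four bioclimatic predictors are
derived: BIO6 (minimum temperature of the coldest month), BIO7 (annual
temperature range), BIO15 (precipitation seasonality) and BIO18
(precipitation of the warmest quarter).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
from scipy import interpolate, linalg, optimize

logger = logging.getLogger(__name__)

TEMP_VARS = ("tmin", "tmean", "tmax")
BIO_VARS = ("bio6", "bio7", "bio15", "bio18")

#: mid-century shift of the coldest-month minimum temperature per scenario (°C)
RCP_TMIN_DELTA = {"RCP2.6": 2.4, "RCP4.5": 3.0, "RCP8.5": 3.8}


@dataclass
class ClimateGrids:
    """Monthly 100 m climate fields (12, rows, cols) plus derived bioclim."""

    tmin: np.ndarray
    tmean: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray
    period: str = "current"

    def __post_init__(self) -> None:
        for name in ("tmin", "tmean", "tmax", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 3 or arr.shape[0] != 12:
                raise ValueError(f"{name} must have shape (12, rows, cols)")
            setattr(self, name, arr)
        if not (self.tmin <= self.tmean + 1e-9).all() or not (
            self.tmean <= self.tmax + 1e-9
        ).all():
            raise ValueError("monthly ordering tmin <= tmean <= tmax violated")
        if (self.prec < 0).any():
            raise ValueError("negative precipitation")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tmin.shape[1:]

    def bio(self) -> Dict[str, np.ndarray]:
        return bioclim(self.tmin, self.tmax, self.tmean, self.prec)


@dataclass
class DeltaGrids:
    """Monthly anomalies per variable at a (usually coarse) grid.

    Temperature deltas are additive (°C); precipitation deltas are additive
    (mm) by default or multiplicative when ``prec_ratio`` is set.
    """

    tmin: np.ndarray
    tmean: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray
    prec_ratio: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("tmin", "tmean", "tmax", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in {name} deltas")
            setattr(self, name, arr)


def bioclim(
    tmin: np.ndarray, tmax: np.ndarray, tmean: np.ndarray, prec: np.ndarray
) -> Dict[str, np.ndarray]:
    """Derive BIO6/BIO7/BIO15/BIO18 from monthly fields.

    Quarters are three consecutive calendar months, cyclic across the
    December-January boundary; the warmest quarter is chosen by mean
    temperature with ties resolved to the earliest starting month.
    """
    tmin, tmax, tmean, prec = (np.asarray(a, float) for a in (tmin, tmax, tmean, prec))
    for a in (tmin, tmax, tmean, prec):
        if a.shape[0] != 12:
            raise ValueError("12 monthly layers required")
    bio6 = tmin.min(axis=0)
    bio5 = tmax.max(axis=0)
    bio7 = bio5 - bio6
    mean_p = prec.mean(axis=0)
    # population SD over the 12 months, ANUCLIM "1 + mean" convention
    bio15 = 100.0 * prec.std(axis=0) / (1.0 + mean_p)
    # cyclic quarters: stack all 12 windows, pick by mean tmean (earliest tie)
    idx = (np.arange(12)[:, None] + np.arange(3)[None, :]) % 12
    q_t = tmean[idx].mean(axis=1)  # (12, rows, cols)
    q_p = prec[idx].sum(axis=1)
    warmest = q_t.argmax(axis=0)  # argmax returns first maximum -> earliest window
    bio18 = np.take_along_axis(q_p, warmest[None], axis=0)[0]
    return {"bio6": bio6, "bio7": bio7, "bio15": bio15, "bio18": bio18}


def compute_deltas(hindcast: ClimateGrids, forecast: ClimateGrids,
                   prec_ratio: bool = False, label: str = "") -> DeltaGrids:
    """Per variable-month-cell anomalies: forecast minus hindcast."""
    if hindcast.shape != forecast.shape:
        raise ValueError("hindcast/forecast geometry mismatch")
    if prec_ratio:
        prec = forecast.prec / np.maximum(hindcast.prec, 1e-9)
    else:
        prec = forecast.prec - hindcast.prec
    return DeltaGrids(
        tmin=forecast.tmin - hindcast.tmin,
        tmean=forecast.tmean - hindcast.tmean,
        tmax=forecast.tmax - hindcast.tmax,
        prec=prec,
        prec_ratio=prec_ratio,
        label=label,
    )


def _interp_field(coarse: np.ndarray, fine_shape: tuple[int, int]) -> np.ndarray:
    """Bicubic-spline surface through coarse cell centres, sampled at fine
    cell centres (bilinear fallback for grids too small for cubic)."""
    cr, cc = coarse.shape
    fr, fc = fine_shape
    # cell-centre coordinates on a shared unit extent
    ys = (np.arange(cr) + 0.5) / cr
    xs = (np.arange(cc) + 0.5) / cc
    yt = (np.arange(fr) + 0.5) / fr
    xt = (np.arange(fc) + 0.5) / fc
    k = 3
    if cr < 4 or cc < 4:
        warnings.warn("coarse grid too small for cubic splines; using bilinear")
        k = 1
        if cr < 2 or cc < 2:
            return np.full(fine_shape, float(coarse.ravel()[0]))
    spl = interpolate.RectBivariateSpline(ys, xs, coarse, kx=min(k, cr - 1), ky=min(k, cc - 1))
    return spl(yt, xt)


def interpolate_deltas(deltas: DeltaGrids, fine_shape: tuple[int, int]) -> DeltaGrids:
    """Interpolate monthly anomaly fields to the fine (100 m) grid."""
    out = {}
    for name in ("tmin", "tmean", "tmax", "prec"):
        coarse = getattr(deltas, name)
        out[name] = np.stack([_interp_field(coarse[m], fine_shape) for m in range(12)])
    return DeltaGrids(**out, prec_ratio=deltas.prec_ratio, label=deltas.label)


def apply_deltas(current: ClimateGrids, deltas: DeltaGrids, period: str = "future") -> ClimateGrids:
    """Add fine-grid anomalies to the current climatology.

    Precipitation is floored at zero and the tmin <= tmean <= tmax ordering
    re-asserted (variable-specific deltas can cross the monthly means).
    """
    if current.tmin.shape != np.asarray(deltas.tmin).shape:
        raise ValueError("delta/current geometry mismatch")
    tmin = current.tmin + deltas.tmin
    tmean = current.tmean + deltas.tmean
    tmax = current.tmax + deltas.tmax
    if deltas.prec_ratio:
        prec = current.prec * deltas.prec
    else:
        prec = current.prec + deltas.prec
    n_floor = int((prec < 0).sum())
    if n_floor:
        logger.info("floored %d negative precipitation cells to 0", n_floor)
    prec = np.maximum(prec, 0.0)
    tmin2 = np.minimum(tmin, tmean)
    tmax2 = np.maximum(tmax, tmean)
    return ClimateGrids(tmin=tmin2, tmean=tmean, tmax=tmax2, prec=prec, period=period)


# -- ordinary kriging with elevation as external drift ------------------------


def _exp_variogram(h, nugget, sill, rng):
    g = nugget + sill * (1.0 - np.exp(-h / rng))
    return np.where(h == 0.0, 0.0, g)


def fit_exponential_variogram(xy: np.ndarray, resid: np.ndarray, n_bins: int = 15):
    """Weighted least-squares fit of an exponential variogram with nugget."""
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(xy), k=1)
    dist = d[iu]
    gamma = 0.5 * (resid[iu[0]] - resid[iu[1]]) ** 2
    hmax = dist.max() * 0.6
    edges = np.linspace(0, hmax, n_bins + 1)
    which = np.digitize(dist, edges) - 1
    hs, gs, ws = [], [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() >= 2:
            hs.append(dist[m].mean())
            gs.append(gamma[m].mean())
            ws.append(m.sum())
    hs, gs, ws = np.array(hs), np.array(gs), np.array(ws)
    var0 = max(resid.var(), 1e-12)
    try:
        popt, _ = optimize.curve_fit(
            _exp_variogram,
            hs,
            gs,
            p0=[0.05 * var0, var0, hmax / 3],
            sigma=1.0 / np.sqrt(ws),
            bounds=([0, 1e-12, 1e-9], [var0 * 10, var0 * 10, hmax * 10]),
            maxfev=5000,
        )
    except RuntimeError:  # fall back to a heuristic model
        popt = np.array([0.05 * var0, var0, hmax / 3])
    return tuple(popt)


def kriging_external_drift(
    support_xy: np.ndarray,
    support_val: np.ndarray,
    support_drift: np.ndarray,
    target_xy: np.ndarray,
    target_drift: np.ndarray,
) -> np.ndarray:
    """Kriging with a linear external drift (here: elevation).

    Exact at support points; the variogram of the drift residuals is an
    exponential model with nugget fitted by weighted least squares.
    """
    n = len(support_xy)
    if n < 10:
        raise ValueError("need at least 10 support points for kriging")
    X = np.column_stack([np.ones(n), support_drift])
    beta, *_ = np.linalg.lstsq(X, support_val, rcond=None)
    resid = support_val - X @ beta
    if resid.var() < 1e-12:  # drift explains everything; kriging adds nothing
        pred = beta[0] + beta[1] * np.asarray(target_drift)
        return np.maximum(pred, 0.0)
    nugget, sill, rng = fit_exponential_variogram(support_xy, resid)

    d = np.sqrt(((support_xy[:, None, :] - support_xy[None, :, :]) ** 2).sum(-1))
    gamma = _exp_variogram(d, nugget, sill, rng)
    a = np.zeros((n + 2, n + 2))
    a[:n, :n] = gamma
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[:n, n + 1] = support_drift
    a[n + 1, :n] = support_drift
    try:
        lu = linalg.lu_factor(a)
    except linalg.LinAlgError:
        logger.warning("singular kriging system; regularizing with a small nugget")
        a[:n, :n] += np.eye(n) * max(sill, 1.0) * 1e-8
        lu = linalg.lu_factor(a)

    out = np.empty(len(target_xy))
    chunk = 4096
    for lo in range(0, len(target_xy), chunk):
        hi = min(lo + chunk, len(target_xy))
        dt = np.sqrt(
            ((support_xy[None, :, :] - target_xy[lo:hi, None, :]) ** 2).sum(-1)
        )
        rhs = np.empty((n + 2, hi - lo))
        rhs[:n] = _exp_variogram(dt, nugget, sill, rng).T
        rhs[n] = 1.0
        rhs[n + 1] = target_drift[lo:hi]
        lam = linalg.lu_solve(lu, rhs)
        out[lo:hi] = lam[:n].T @ support_val
    return np.maximum(out, 0.0)


def downscale_precipitation(
    coarse_prec: np.ndarray,
    coarse_elev: np.ndarray,
    fine_elev: np.ndarray,
    coarse_extent_cells: Optional[int] = None,
) -> np.ndarray:
    """Downscale a coarse precipitation field to the fine grid via kriging
    with elevation as external drift. ``coarse_prec``/``coarse_elev`` live on
    the same coarse grid covering the same extent as ``fine_elev``."""
    cr, cc = coarse_prec.shape
    fr, fc = fine_elev.shape
    sy = (np.arange(cr) + 0.5) / cr
    sx = (np.arange(cc) + 0.5) / cc
    support_xy = np.array([(y, x) for y in sy for x in sx])
    ty = (np.arange(fr) + 0.5) / fr
    tx = (np.arange(fc) + 0.5) / fc
    tgrid = np.array(np.meshgrid(ty, tx, indexing="ij")).reshape(2, -1).T
    est = kriging_external_drift(
        support_xy,
        coarse_prec.ravel(),
        coarse_elev.ravel(),
        tgrid,
        fine_elev.ravel(),
    )
    return est.reshape(fr, fc)
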