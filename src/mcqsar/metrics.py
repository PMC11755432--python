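"""Regression quality statistics for single-descriptor models.

Beyond the textbook panel (determination coefficient, Lin's concordance
correlation coefficient, RMSE, MAE, Fisher F-ratio, leave-one-out Q2),
two indices specific to the Monte Carlo correlation-weight literature
are provided:

* the **index of ideality of correlation** (IIC) — the Pearson
  correlation damped by the asymmetry between the mean absolute errors
  of over- and under-predictions,

      IIC = r * min(MAE-, MAE+) / max(MAE-, MAE+),

  where MAE- averages |obs - pred| over points with obs - pred < 0 and
  MAE+ over points with obs - pred >= 0 (ratio := 1 when a class is
  empty or the larger MAE is zero);

* the **correlation intensity index** (CII) — one minus the summed
  leave-one-out "protests",

      CII = 1 - sum_k max(0, R2_(-k) - R2),

  where R2_(-k) is the determination coefficient with point k removed.
  A point whose removal raises R2 was propping the correlation down;
  CII near 1 means no single point dominates.

Population (divide-by-n) variances are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError

__all__ = [
    "SetStatistics",
    "determination",
    "concordance",
    "ideality_index",
    "correlation_intensity",
    "cross_validated_q2",
    "error_stats",
    "fisher_ratio",
    "panel",
]


def _as_pair(obs, pred, min_n: int = 1):
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise UndefinedStatisticError("observed and predicted vectors must match in length")
    if o.size < min_n:
        raise UndefinedStatisticError(f"need at least {min_n} points, got {o.size}")
    return o, p


def _pearson(o: np.ndarray, p: np.ndarray) -> float:
    od = o - o.mean()
    pd = p - p.mean()
    denom = np.sqrt((od * od).sum() * (pd * pd).sum())
    if denom == 0.0:
        raise UndefinedStatisticError("correlation undefined for constant vector")
    return float((od * pd).sum() / denom)


def determination(obs, pred) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    o, p = _as_pair(obs, pred, min_n=3)
    r = _pearson(o, p)
    return r * r


def concordance(obs, pred) -> float:
    """Lin's concordance correlation coefficient (population variances)."""
    o, p = _as_pair(obs, pred, min_n=3)
    vo, vp = o.var(), p.var()
    if vo == 0.0 and vp == 0.0:
        raise UndefinedStatisticError("concordance undefined for two constant vectors")
    cov = ((o - o.mean()) * (p - p.mean())).mean()
    return float(2.0 * cov / (vo + vp + (o.mean() - p.mean()) ** 2))


def ideality_index(obs, pred) -> float:
    """Index of ideality of correlation."""
    o, p = _as_pair(obs, pred, min_n=3)
    r = _pearson(o, p)
    resid = o - p
    neg = np.abs(resid[resid < 0])
    pos = np.abs(resid[resid >= 0])
    if neg.size == 0 or pos.size == 0:
        ratio = 1.0
    else:
        lo, hi = sorted((neg.mean(), pos.mean()))
        ratio = 1.0 if hi == 0.0 else lo / hi
    return float(r * ratio)


def correlation_intensity(obs, pred) -> float:
    """Correlation intensity index: 1 minus the summed leave-one-out protests.

    A removal that leaves either vector constant contributes 0.
    """
    o, p = _as_pair(obs, pred, min_n=4)
    r2 = determination(o, p)
    n = o.size
    # leave-one-out Pearson r^2 from running sums, vectorized over k
    sx, sy = o.sum(), p.sum()
    sxx, syy, sxy = (o * o).sum(), (p * p).sum(), (o * p).sum()
    m = n - 1
    lx, ly = sx - o, sy - p
    lxx, lyy, lxy = sxx - o * o, syy - p * p, sxy - o * p
    num = m * lxy - lx * ly
    dx = m * lxx - lx * lx
    dy = m * lyy - ly * ly
    denom = dx * dy
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_loo = np.where(denom > 0, (num * num) / np.where(denom > 0, denom, 1.0), r2)
    protest = np.maximum(0.0, r2_loo - r2)
    return float(1.0 - protest.sum())


def cross_validated_q2(x, y) -> float:
    """Leave-one-out cross-validated R2 of the univariate regression y ~ x.

    Uses the closed-form PRESS residuals e_i / (1 - h_ii) of ordinary
    least squares, so it equals n explicit refits exactly.
    """
    xv, yv = _as_pair(x, y, min_n=4)
    n = xv.size
    xd = xv - xv.mean()
    sxx = (xd * xd).sum()
    if sxx == 0.0:
        raise UndefinedStatisticError("Q2 undefined for constant x")
    c1 = (xd * (yv - yv.mean())).sum() / sxx
    c0 = yv.mean() - c1 * xv.mean()
    resid = yv - (c0 + c1 * xv)
    h = 1.0 / n + xd * xd / sxx
    press = float(((resid / (1.0 - h)) ** 2).sum())
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise UndefinedStatisticError("Q2 undefined for constant y")
    return 1.0 - press / ss_tot


def error_stats(obs, pred) -> tuple[float, float]:
    """Root mean squared error and mean absolute error."""
    o, p = _as_pair(obs, pred, min_n=1)
    resid = o - p
    return float(np.sqrt((resid * resid).mean())), float(np.abs(resid).mean())


def fisher_ratio(r2: float, n: int) -> float:
    """Fisher F-ratio of a univariate regression: r2 (n - 2) / (1 - r2).

    Reports round this to an integer; the exact value is returned.
    """
    if not 0.0 <= r2 < 1.0:
        raise UndefinedStatisticError(f"F-ratio needs 0 <= r2 < 1, got {r2}")
    if n < 3:
        raise UndefinedStatisticError(f"F-ratio needs n >= 3, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


@dataclass(frozen=True)
class SetStatistics:
    """The eight-statistic quality panel of one data subset."""

    n: int
    r2: float
    ccc: float
    iic: float
    cii: float
    q2: float
    rmse: float
    mae: float
    f: float


def panel(obs, pred, dcw=None) -> SetStatistics:
    """Full quality panel for one set.

    ``dcw`` is the descriptor vector used for the leave-one-out Q2; it
    defaults to the predictions themselves (equivalent for a model that
    is affine in the descriptor).
    """
    o, p = _as_pair(obs, pred, min_n=4)
    x = p if dcw is None else np.asarray(dcw, dtype=float)
    r2 = determination(o, p)
    rmse, mae = error_stats(o, p)
    return SetStatistics(
        n=o.size,
        r2=r2,
        ccc=concordance(o, p),
        iic=ideality_index(o, p),
        cii=correlation_intensity(o, p),
        q2=cross_validated_q2(x, o),
        rmse=rmse,
        mae=mae,
        f=fisher_ratio(r2, o.size),
    )
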