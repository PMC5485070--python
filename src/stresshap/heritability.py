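"""Marker-based narrow-sense heritability.

Fits the genotypic-means model ``y = mu + g + e`` with ``g ~ N(0, va K)``
and ``e ~ N(0, ve I)`` by REML, using a single eigendecomposition of the
kinship matrix and a one-dimensional search over the log variance ratio
``delta = va / ve``.  Narrow-sense heritability is ``h2 = va / (va + ve)``.

With an (effectively) identity kinship the profiled restricted likelihood
is flat in the ratio, so no interior estimate exists; that degenerate case
is reported as ``h2 = 0`` with a warning flag rather than an arbitrary
interior value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .kinship import KinshipMatrix

__all__ = ["HeritabilityEstimate", "estimate_h2", "h2_table"]

_LOG_DELTA_RANGE = (-10.0, 10.0)


@dataclass
class HeritabilityEstimate:
    trait: str
    h2: float
    va: float
    ve: float
    h2_se: float | None
    n_accessions: int
    boundary: bool = False
    degenerate: bool = False
    reml_loglik: float | None = None


def _profiled_neg2_reml(log_delta: float, d: np.ndarray, yt: np.ndarray,
                        xt: np.ndarray) -> float:
    """-2 restricted loglik profiled over the intercept and ve."""
    delta = np.exp(log_delta)
    w = delta * d + 1.0                        # V = ve (delta K + I) eigenvalues
    xw = xt / w
    bhat = (xw @ yt) / (xw @ xt)
    r = yt - bhat * xt
    n = len(yt)
    s2 = float(np.sum(r * r / w) / (n - 1))
    return (n - 1) * np.log(s2) + float(np.sum(np.log(w))) + np.log(float(xw @ xt))


def estimate_h2(
    y: np.ndarray | pd.Series,
    K: KinshipMatrix,
    trait: str = "trait",
) -> HeritabilityEstimate:
    """REML estimate of h2, va, ve for one trait vector aligned with K."""
    if isinstance(y, pd.Series):
        K = K.align([str(a) for a in y.index])
        y = y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != K.n:
        raise ValueError("trait length does not match kinship")
    if np.var(y) == 0:
        raise ValueError("zero trait variance; heritability undefined")
    if n < 30:
        warnings.warn(f"only {n} accessions; h2 estimate will be imprecise",
                      stacklevel=2)
    d, U = np.linalg.eigh(K.K)
    if d[0] < -1e-8:
        raise ValueError("kinship is not PSD; ridge-repair it first")
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    lo, hi = _LOG_DELTA_RANGE
    grid = np.linspace(lo, hi, 21)
    vals = np.array([_profiled_neg2_reml(g, d, yt, xt) for g in grid])
    if vals.max() - vals.min() < 1e-6:
        warnings.warn(
            "restricted likelihood is flat in va/ve (identity-like kinship); "
            "reporting degenerate h2 = 0", stacklevel=2,
        )
        s2 = float(np.var(y, ddof=1))
        return HeritabilityEstimate(trait, 0.0, 0.0, s2, None, n,
                                    boundary=True, degenerate=True)
    res = optimize.minimize_scalar(
        _profiled_neg2_reml, bounds=(lo, hi), args=(d, yt, xt),
        method="bounded", options={"xatol": 1e-12},
    )
    log_delta = float(res.x)
    # Newton polish: the profile can be flat enough that Brent's last digits
    # wander; pin the stationary point so estimates are shift/scale-exact
    for _ in range(3):
        if not lo + 1e-6 < log_delta < hi - 1e-6:
            break
        eps = 1e-4
        fp = _profiled_neg2_reml(log_delta + eps, d, yt, xt)
        fm = _profiled_neg2_reml(log_delta - eps, d, yt, xt)
        f0 = _profiled_neg2_reml(log_delta, d, yt, xt)
        grad = (fp - fm) / (2 * eps)
        curv = (fp - 2 * f0 + fm) / eps**2
        if curv <= 0 or abs(grad / curv) > 0.5:
            break
        log_delta -= grad / curv
    # boundary solutions mean h2 -> 0 or 1 (flagged, ratio kept exact)
    boundary = log_delta <= lo + 1e-6 or log_delta >= hi - 1e-6
    if boundary:
        log_delta = lo if log_delta <= lo + 1e-6 else hi
    delta = np.exp(log_delta)
    w = delta * d + 1.0
    xw = xt / w
    bhat = (xw @ yt) / (xw @ xt)
    r = yt - bhat * xt
    ve = float(np.sum(r * r / w) / (n - 1))
    va = delta * ve
    h2 = va / (va + ve)
    # delta-method SE of h2 via numeric curvature in log delta
    h2_se = None
    if not boundary:
        eps = 1e-4
        f0 = _profiled_neg2_reml(log_delta, d, yt, xt)
        fp = _profiled_neg2_reml(log_delta + eps, d, yt, xt)
        fm = _profiled_neg2_reml(log_delta - eps, d, yt, xt)
        curv = (fp - 2 * f0 + fm) / eps**2   # of -2 loglik
        if curv > 0:
            var_logdelta = 2.0 / curv
            dh_dlog = delta / (1.0 + delta) ** 2
            h2_se = float(dh_dlog * np.sqrt(var_logdelta))
    return HeritabilityEstimate(
        trait, float(h2), float(va), float(ve), h2_se, n,
        boundary=boundary, reml_loglik=float(-0.5 * res.fun),
    )


def h2_table(responses: pd.DataFrame, K: KinshipMatrix) -> pd.DataFrame:
    """Trait-summary table: Min, Mean, Max, CV%, N, h2, va, ve per column.

    CV is computed on the scale of the stored responses (percentages,
    mm^2 or counts).  Traits whose estimation fails are flagged in the
    ``error`` column; the remaining rows are unaffected.
    """
    rows = []
    for trait in responses.columns:
        col = responses[trait].dropna()
        vals = col.to_numpy(dtype=float)
        row = {
            "trait": trait,
            "Min": float(vals.min()) if len(vals) else np.nan,
            "Mean": float(vals.mean()) if len(vals) else np.nan,
            "Max": float(vals.max()) if len(vals) else np.nan,
            "CV_pct": float(100.0 * vals.std(ddof=1) / vals.mean())
            if len(vals) > 1 and vals.mean() != 0 else np.nan,
            "N": int(len(vals)),
        }
        try:
            est = estimate_h2(col, K, trait=trait)
            row.update(h2=est.h2, va=est.va, ve=est.ve, h2_se=est.h2_se,
                       error="")
        except Exception as exc:
            row.update(h2=np.nan, va=np.nan, ve=np.nan, h2_se=np.nan,
                       error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")
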