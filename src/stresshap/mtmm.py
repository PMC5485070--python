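"""Two-trait multi-trait mixed model (MTMM) genome-wide association.

Two composite phenotypes are built as the first principal components of the
standardized stress responses in which summer annuals are the more
resistant (p1: P. rapae, P. xylostella, Drought&Pieris, Botrytis&Pieris)
and in which winter annuals are the more resistant (p2: F. occidentalis,
M. persicae, Drought).

The stacked two-trait model is ``Y = X beta + G + E`` with
``vec(G) ~ N(0, Vg (x) K)`` and ``vec(E) ~ N(0, Ve (x) I)`` (trait-block
outer Kronecker ordering).  The 2x2 matrices (Vg, Ve) are estimated once by
REML under the null (no SNP) model via a log-Cholesky parameterization,
then held fixed for every SNP — the standard plug-in (EMMAX-style)
approximation.  Each SNP x is tested by GLS F tests in the model

    y = s1 mu1 + s2 mu2 + x beta + (x o s1) alpha + upsilon

with three nested comparisons: *full* (beta = alpha = 0 against the full
model, 2 numerator df), *common* (beta = 0 against the alpha = 0 model,
1 df) and *specific* (alpha = 0 against the full model, 1 df).  P-values
use the exact F distribution with the residual df of the larger model in
each comparison.

Significant SNPs (-log10 p at or above a threshold, default 4) seed QTL
windows (default 20 kb total span) that are merged when they touch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix, minor_allele_frequency
from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TraitVectors",
    "MtmmFit",
    "SnpTestResult",
    "QTLRegion",
    "SUMMER_RESISTANT",
    "WINTER_RESISTANT",
    "build_trait_vectors",
    "fit_mtmm_varcomp",
    "gls_f_tests",
    "select_qtl_regions",
    "ld_r2",
]

SUMMER_RESISTANT = ["P_rapae", "P_xylostella", "Drought_Pieris", "Botrytis_Pieris"]
WINTER_RESISTANT = ["F_occidentalis", "M_persicae", "Drought"]


@dataclass
class TraitVectors:
    accession_ids: list[str]
    p1: np.ndarray
    p2: np.ndarray
    explained_fraction_p1: float
    explained_fraction_p2: float


@dataclass
class MtmmFit:
    Vg: np.ndarray
    Ve: np.ndarray
    reml_loglik: float
    converged: bool
    identifiable: bool = True

    @property
    def genetic_correlation(self) -> float:
        return float(self.Vg[0, 1] / np.sqrt(self.Vg[0, 0] * self.Vg[1, 1]))

    @property
    def residual_correlation(self) -> float:
        return float(self.Ve[0, 1] / np.sqrt(self.Ve[0, 0] * self.Ve[1, 1]))


@dataclass
class QTLRegion:
    chromosome: str
    start: int            # 1-based inclusive
    end: int
    member_snps: list[str]
    peak_neglog10p: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")


def _pc1(M: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC of column-standardized data; returns scores and explained
    fraction.  Sign: positively correlated with the row-mean of the
    standardized columns."""
    Z = (M - M.mean(0)) / M.std(0, ddof=1)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * s[0]
    explained = float(s[0] ** 2 / np.sum(s**2))
    rowmean = Z.mean(1)
    if np.corrcoef(scores, rowmean)[0, 1] < 0:
        scores = -scores
    return scores, explained


def build_trait_vectors(responses: pd.DataFrame) -> TraitVectors:
    """Composite phenotypes: PC1 of each resistance-direction trait group.

    Complete cases over all seven responses; each composite is
    standardized to unit variance, with its sign fixed so that it
    correlates positively with the group's mean standardized response.
    """
    needed = SUMMER_RESISTANT + WINTER_RESISTANT
    missing = [c for c in needed if c not in responses.columns]
    if missing:
        raise ValueError(f"responses lack columns {missing}")
    data = responses[needed].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete accessions")
    p1, ef1 = _pc1(data[SUMMER_RESISTANT].to_numpy(float))
    p2, ef2 = _pc1(data[WINTER_RESISTANT].to_numpy(float))
    p1 = p1 / p1.std(ddof=1)
    p2 = p2 / p2.std(ddof=1)
    return TraitVectors(
        accession_ids=[str(a) for a in data.index],
        p1=p1, p2=p2,
        explained_fraction_p1=ef1, explained_fraction_p2=ef2,
    )


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

def _chol_from_params(theta: np.ndarray) -> np.ndarray:
    return np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])


def _neg2_reml_bivariate(theta, d, Y, Xt):
    """-2 REML loglik over the 6 log-Cholesky parameters of (Vg, Ve).

    ``d``: kinship eigenvalues; ``Y``: n x 2 rotated traits; ``Xt``: n x k
    rotated fixed design shared by both traits (trait-specific intercepts
    built internally)."""
    Lg = _chol_from_params(theta[:3])
    Le = _chol_from_params(theta[3:])
    Vg = Lg @ Lg.T
    Ve = Le @ Le.T
    n = len(d)
    k = Xt.shape[1]
    # per-index 2x2 covariance and its inverse
    S = d[:, None, None] * Vg[None] + Ve[None]           # n x 2 x 2
    det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] ** 2
    if np.any(det <= 0) or np.any(S[:, 0, 0] <= 0):
        return 1e30, None
    inv = np.empty_like(S)
    inv[:, 0, 0] = S[:, 1, 1] / det
    inv[:, 1, 1] = S[:, 0, 0] / det
    inv[:, 0, 1] = inv[:, 1, 0] = -S[:, 0, 1] / det
    # fixed design: trait-specific copies of Xt -> 2k columns
    # X'(Omega^-1)X assembled blockwise over traits
    A11 = Xt.T @ (inv[:, 0, 0, None] * Xt)
    A12 = Xt.T @ (inv[:, 0, 1, None] * Xt)
    A22 = Xt.T @ (inv[:, 1, 1, None] * Xt)
    XOX = np.block([[A11, A12], [A12.T, A22]])
    b1 = Xt.T @ (inv[:, 0, 0] * Y[:, 0] + inv[:, 0, 1] * Y[:, 1])
    b2 = Xt.T @ (inv[:, 1, 0] * Y[:, 0] + inv[:, 1, 1] * Y[:, 1])
    XOy = np.concatenate([b1, b2])
    try:
        beta = np.linalg.solve(XOX, XOy)
    except np.linalg.LinAlgError:
        return 1e30, None
    mu = np.stack([Xt @ beta[:k], Xt @ beta[k:]], axis=1)
    R = Y - mu
    quad = float(np.einsum("ni,nij,nj->", R, inv, R))
    sign, logdet_xox = np.linalg.slogdet(XOX)
    if sign <= 0:
        return 1e30, None
    f = float(np.sum(np.log(det))) + logdet_xox + quad
    return f, (Vg, Ve, beta)


def fit_mtmm_varcomp(
    p1: np.ndarray,
    p2: np.ndarray,
    K: KinshipMatrix,
) -> MtmmFit:
    """REML estimate of the 2x2 genetic and residual trait covariances.

    Initialized from single-trait variance splits; PSD is enforced by the
    log-Cholesky parameterization.  With an identity-like kinship only
    Vg + Ve is identified; that case is flagged on the result.
    """
    from .heritability import estimate_h2

    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n = len(p1)
    if len(p2) != n or K.n != n:
        raise ValueError("p1, p2 and K must have matching dimensions")
    if n < 20:
        warnings.warn(f"only {n} accessions; MTMM components will be noisy",
                      stacklevel=2)
    d, U = np.linalg.eigh(K.K)
    d = np.clip(d, 0.0, None)
    Y = np.column_stack([U.T @ p1, U.T @ p2])
    Xt = (U.T @ np.ones(n))[:, None]

    identifiable = float(np.std(d)) > 1e-6

    # single-trait variance splits plus the phenotypic correlation seed the
    # log-Cholesky parameters
    inits = []
    for y in (p1, p2):
        try:
            est = estimate_h2(y, K)
            inits.append((max(est.va, 1e-3), max(est.ve, 1e-3)))
        except Exception:
            v = float(np.var(y, ddof=1))
            inits.append((v / 2, v / 2))
    r = float(np.clip(np.corrcoef(p1, p2)[0, 1], -0.95, 0.95))

    def chol_params(v1, v2, rho):
        L = np.linalg.cholesky(
            np.array([[v1, rho * np.sqrt(v1 * v2)],
                      [rho * np.sqrt(v1 * v2), v2]]))
        return [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])]

    theta0 = np.array(
        chol_params(inits[0][0], inits[1][0], r)
        + chol_params(inits[0][1], inits[1][1], r)
    )

    def obj(theta):
        f, _ = _neg2_reml_bivariate(theta, d, Y, Xt)
        return f

    res = optimize.minimize(obj, theta0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8,
                                     "fatol": 1e-10})
    # restart once from the solution: Nelder-Mead can stall on the
    # near-singular boundary (perfectly correlated traits)
    res = optimize.minimize(obj, res.x, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-9,
                                     "fatol": 1e-12})
    f, parts = _neg2_reml_bivariate(res.x, d, Y, Xt)
    if parts is None:
        raise RuntimeError(f"MTMM variance-component fit failed: {res.message}")
    Vg, Ve, _ = parts
    if not identifiable:
        warnings.warn(
            "kinship is identity-like: only Vg + Ve is identified",
            stacklevel=2,
        )
    return MtmmFit(Vg=Vg, Ve=Ve, reml_loglik=float(-0.5 * f),
                   converged=bool(res.success), identifiable=identifiable)


# ---------------------------------------------------------------------------
# Per-SNP GLS F tests
# ---------------------------------------------------------------------------

def _whiten_factors(d: np.ndarray, Vg: np.ndarray, Ve: np.ndarray) -> np.ndarray:
    """Inverse Cholesky factor of the per-eigenindex 2x2 covariance."""
    S = d[:, None, None] * Vg[None] + Ve[None]
    W = np.empty_like(S)
    a = np.sqrt(S[:, 0, 0])
    b = S[:, 0, 1] / a
    c = np.sqrt(S[:, 1, 1] - b**2)
    # inverse of [[a,0],[b,c]]
    W[:, 0, 0] = 1.0 / a
    W[:, 0, 1] = 0.0
    W[:, 1, 0] = -b / (a * c)
    W[:, 1, 1] = 1.0 / c
    return W


def gls_f_tests(
    geno: GenotypeMatrix,
    fit: MtmmFit,
    p1: np.ndarray,
    p2: np.ndarray,
    K: KinshipMatrix,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Full / common / specific GLS F tests for every SNP with MAF > maf_min.

    The plug-in covariance ``Vg (x) K + Ve (x) I`` from ``fit`` is held
    fixed across SNPs.  SNPs that are constant after filtering are skipped
    with a log entry.  Returns a DataFrame with marker metadata, the
    common-effect (beta) and trait-specific (alpha) estimates and the three
    p-values.
    """
    n = geno.n_accessions
    if K.n != n or len(p1) != n:
        raise ValueError("genotypes, traits and kinship must align")
    maf = minor_allele_frequency(geno)
    keep = maf > maf_min
    d, U = np.linalg.eigh(K.K)
    d = np.clip(d, 0.0, None)
    W = _whiten_factors(d, fit.Vg, fit.Ve)
    y = np.column_stack([U.T @ p1, U.T @ p2])            # n x 2
    ones = U.T @ np.ones(n)
    Xg = U.T @ geno.calls[:, keep].astype(float)          # n x m'

    def whiten(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
        """Apply per-index W to a (trait1, trait2) column pair -> n x 2."""
        out = np.empty((len(c1), 2))
        out[:, 0] = W[:, 0, 0] * c1
        out[:, 1] = W[:, 1, 0] * c1 + W[:, 1, 1] * c2
        return out

    yw = whiten(y[:, 0], y[:, 1]).ravel()
    s1w = whiten(ones, np.zeros(n)).ravel()
    s2w = whiten(np.zeros(n), ones).ravel()
    B = np.column_stack([s1w, s2w])
    Q, _ = np.linalg.qr(B)
    r0 = yw - Q @ (Q.T @ yw)
    rss0 = float(r0 @ r0)

    m_kept = Xg.shape[1]
    xw = np.empty((2 * n, m_kept))
    xs1w = np.empty((2 * n, m_kept))
    xw[0::2] = W[:, 0, 0, None] * Xg
    xw[1::2] = W[:, 1, 0, None] * Xg + W[:, 1, 1, None] * Xg
    xs1w[0::2] = W[:, 0, 0, None] * Xg
    xs1w[1::2] = W[:, 1, 0, None] * Xg

    A = xw - Q @ (Q.T @ xw)
    C = xs1w - Q @ (Q.T @ xs1w)
    aa = np.einsum("ij,ij->j", A, A)
    ab = np.einsum("ij,ij->j", A, C)
    bb = np.einsum("ij,ij->j", C, C)
    ar = A.T @ r0
    br = C.T @ r0

    df_full = 2 * n - 4
    df_common = 2 * n - 3
    results = []
    kept_idx = np.flatnonzero(keep)
    markers = geno.markers
    skipped = 0
    for j in range(m_kept):
        det = aa[j] * bb[j] - ab[j] ** 2
        if aa[j] < 1e-12:
            skipped += 1
            continue
        rss1 = rss0 - ar[j] ** 2 / aa[j]
        if det < 1e-12 * max(aa[j] * bb[j], 1.0):
            # x and x*s1 collinear after projection; specific test undefined
            rss2 = rss1
            beta_hat = ar[j] / aa[j]
            alpha_hat = np.nan
        else:
            sol0 = (bb[j] * ar[j] - ab[j] * br[j]) / det
            sol1 = (aa[j] * br[j] - ab[j] * ar[j]) / det
            rss2 = rss0 - (sol0 * ar[j] + sol1 * br[j])
            beta_hat, alpha_hat = sol0, sol1
        rss2 = max(rss2, 1e-300)
        f_full = ((rss0 - rss2) / 2.0) / (rss2 / df_full)
        f_common = (rss0 - rss1) / (rss1 / df_common)
        f_specific = (rss1 - rss2) / (rss2 / df_full)
        k = kept_idx[j]
        results.append({
            "marker_id": markers["marker_id"].iloc[k],
            "chromosome": markers["chromosome"].iloc[k],
            "position": int(markers["position"].iloc[k]),
            "maf": float(maf[k]),
            "beta": float(beta_hat),
            "alpha": float(alpha_hat) if np.isfinite(alpha_hat) else np.nan,
            "p_full": float(stats.f.sf(max(f_full, 0.0), 2, df_full)),
            "p_common": float(stats.f.sf(max(f_common, 0.0), 1, df_common)),
            "p_specific": float(stats.f.sf(max(f_specific, 0.0), 1, df_full)),
        })
    if skipped:
        logger.info("gls_f_tests: skipped %d degenerate SNPs", skipped)
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# QTL windows and LD
# ---------------------------------------------------------------------------

def select_qtl_regions(
    results: pd.DataFrame,
    test: str = "specific",
    neg_log10_threshold: float = 4.0,
    window_bp: int = 20_000,
) -> list[QTLRegion]:
    """Merge windows around significant SNPs into QTL regions.

    A SNP seeds a window of total span ``window_bp`` centred on its
    position (floored at 1); touching or overlapping windows on the same
    chromosome merge.  Regions are returned in genome order.
    """
    col = f"p_{test}"
    if col not in results.columns:
        raise ValueError(f"unknown test {test!r}")
    sig = results[-np.log10(results[col]) >= neg_log10_threshold]
    regions: list[QTLRegion] = []
    half = window_bp // 2
    for chrom, grp in sig.groupby("chromosome", sort=True):
        grp = grp.sort_values("position")
        cur: dict | None = None
        for _, row in grp.iterrows():
            start = max(int(row["position"]) - half, 1)
            end = int(row["position"]) + half
            nl = float(-np.log10(row[col]))
            if cur is not None and start <= cur["end"]:
                cur["end"] = max(cur["end"], end)
                cur["snps"].append(row["marker_id"])
                cur["peak"] = max(cur["peak"], nl)
            else:
                if cur is not None:
                    regions.append(QTLRegion(chrom, cur["start"], cur["end"],
                                             cur["snps"], cur["peak"]))
                cur = {"start": start, "end": end,
                       "snps": [row["marker_id"]], "peak": nl}
        if cur is not None:
            regions.append(QTLRegion(chrom, cur["start"], cur["end"],
                                     cur["snps"], cur["peak"]))
    return regions


def regions_to_bed(regions: list[QTLRegion]) -> pd.DataFrame:
    """0-based half-open BED (start = internal 1-based start - 1)."""
    return pd.DataFrame(
        {
            "chrom": [r.chromosome for r in regions],
            "start": [r.start - 1 for r in regions],
            "end": [r.end for r in regions],
            "name": [f"QTL{i + 1}" for i in range(len(regions))],
            "score": [r.peak_neglog10p for r in regions],
        }
    )


def ld_r2(geno: GenotypeMatrix, focal: str, window_bp: int = 20_000) -> pd.Series:
    """Squared Pearson correlation with the focal marker inside the window.

    Monomorphic companions have undefined r^2 and are reported as NaN.
    """
    mk = geno.markers
    hit = mk.index[mk["marker_id"] == focal]
    if len(hit) == 0:
        raise KeyError(f"marker {focal!r} not found")
    i = int(hit[0])
    chrom = mk["chromosome"].iloc[i]
    pos = int(mk["position"].iloc[i])
    inwin = (mk["chromosome"] == chrom) & (mk["position"].sub(pos).abs() <= window_bp)
    idx = np.flatnonzero(inwin.to_numpy())
    x = geno.calls[:, i].astype(float)
    out = {}
    for j in idx:
        yj = geno.calls[:, j].astype(float)
        if yj.std() == 0 or x.std() == 0:
            out[mk["marker_id"].iloc[j]] = np.nan
        else:
            out[mk["marker_id"].iloc[j]] = float(np.corrcoef(x, yj)[0, 1] ** 2)
    return pd.Series(out, name="r2")
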