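"""Per-plant bioassay mixed models and derived stress responses.

Four glasshouse experiments measure, per plant, rosette fresh weight
(experiments 1 and 2), thrips silver-damage area in mm^2 (experiment 3) or
aphid offspring count (experiment 4).  Each experiment is analysed with a
linear mixed model whose fixed part is genotype (GEN), treatment (TRT) and
their interaction where a treatment factor exists, and whose random part is
a set of independent positional/temporal variance components:

* experiment 1: B, R, S, BxRxS, BxRxSxT, BxRxSxTxX, BxRxSxTxY
* experiment 2: B, BxT, BxTxX, BxTxY
* experiments 3-4: B, B/SB

(B block, SB sub-block, R rack, S shelf, T tray, X/Y tray coordinates).

Genotypic predicted means (fixed-effect cell means, random terms at zero)
are extracted per GEN x TRT cell, and per-accession stress responses are
derived as percentage weight reduction relative to the relevant baseline
(the unstressed control, or the drought-only treatment for the combined
drought + herbivory stress).  Damage areas and aphid counts pass through
unchanged.

The REML solver profiles the residual variance and maximizes the restricted
likelihood over log variance ratios with an analytic gradient, operating
entirely on sufficient statistics (X'X, Z'Z, ...), so its cost is governed
by the number of random-effect levels rather than the number of plants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = [
    "EXPERIMENT_FIXED",
    "EXPERIMENT_RANDOM_TERMS",
    "EXPERIMENT_TREATMENTS",
    "LmmFit",
    "fit_experiment_lmm",
    "predicted_means",
    "derive_stress_responses",
    "classify_life_cycle",
    "RESPONSE_COLUMNS",
]

EXPERIMENT_RANDOM_TERMS: dict[int, list[tuple[str, ...]]] = {
    1: [
        ("block",),
        ("rack",),
        ("shelf",),
        ("block", "rack", "shelf"),
        ("block", "rack", "shelf", "tray"),
        ("block", "rack", "shelf", "tray", "x"),
        ("block", "rack", "shelf", "tray", "y"),
    ],
    2: [("block",), ("block", "tray"), ("block", "tray", "x"), ("block", "tray", "y")],
    3: [("block",), ("block", "sub_block")],
    4: [("block",), ("block", "sub_block")],
}

# whether the experiment has a treatment factor, and its vocabulary
EXPERIMENT_TREATMENTS: dict[int, list[str] | None] = {
    1: ["control", "drought", "p_rapae", "drought_pieris", "botrytis_pieris"],
    2: ["control", "p_xylostella"],
    3: None,
    4: None,
}

EXPERIMENT_FIXED = {1: "GEN*TRT", 2: "GEN*TRT", 3: "GEN", 4: "GEN"}

RESPONSE_COLUMNS = [
    "Drought",
    "P_rapae",
    "Drought_Pieris",
    "Botrytis_Pieris",
    "P_xylostella",
    "F_occidentalis",
    "M_persicae",
]


class LmmConvergenceError(RuntimeError):
    def __init__(self, message: str, last_iterate: dict | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class LmmFit:
    """Converged REML fit of one experiment's mixed model."""

    experiment: int
    beta: np.ndarray
    beta_se: np.ndarray
    beta_names: list[str]
    variance_components: dict[str, float]
    sigma2_e: float
    reml_loglik: float
    converged: bool
    n_obs: int
    gen_levels: list[str]
    trt_levels: list[str] | None
    n_iter: int = 0
    blup_gen: pd.Series | None = None    # shrunken genotype effects, optional


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _fixed_design(data: pd.DataFrame, with_trt: bool):
    gen_levels = sorted(data["accession_id"].astype(str).unique())
    gi = pd.Categorical(data["accession_id"].astype(str), categories=gen_levels).codes
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for g in range(1, len(gen_levels)):
        cols.append((gi == g).astype(float))
        names.append(f"GEN[{gen_levels[g]}]")
    trt_levels = None
    if with_trt:
        trt_levels = list(data["treatment"].astype(str).unique())
        # stable, vocabulary-ordered if known
        trt_levels = sorted(trt_levels)
        ti = pd.Categorical(data["treatment"].astype(str), categories=trt_levels).codes
        for t in range(1, len(trt_levels)):
            cols.append((ti == t).astype(float))
            names.append(f"TRT[{trt_levels[t]}]")
        for g in range(1, len(gen_levels)):
            for t in range(1, len(trt_levels)):
                cols.append(((gi == g) & (ti == t)).astype(float))
                names.append(f"GEN[{gen_levels[g]}]:TRT[{trt_levels[t]}]")
    X = np.column_stack(cols)
    return X, names, gen_levels, trt_levels


def _indicator(data: pd.DataFrame, cols: tuple[str, ...]) -> sparse.csr_matrix:
    key = data[list(cols)].astype(str).agg("\x1f".join, axis=1)
    codes, levels = pd.factorize(key, sort=True)
    n, q = len(codes), len(levels)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, q)
    )
    return Z


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

class _RemlProblem:
    """Profiled REML over variance ratios gamma_k = sigma2_k / sigma2_e."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Zs: list[sparse.csr_matrix]):
        self.n, self.p = X.shape
        self.q_sizes = [Z.shape[1] for Z in Zs]
        self.q = sum(self.q_sizes)
        self.slices = []
        start = 0
        for q in self.q_sizes:
            self.slices.append(slice(start, start + q))
            start += q
        Z = sparse.hstack(Zs, format="csr")
        self.G1 = (Z.T @ Z).toarray()
        self.G2 = Z.T @ X
        self.G3 = X.T @ X
        self.g4 = Z.T @ y
        self.g5 = X.T @ y
        self.yty = float(y @ y)
        self.Z = Z
        self.X = X
        self.y = y
        rank = np.linalg.matrix_rank(self.G3)
        if rank < self.p:
            raise ValueError(
                f"aliased fixed effects: design rank {rank} < {self.p} columns; "
                "some GEN/TRT level combinations are confounded or empty"
            )

    def _pieces(self, gammas: np.ndarray):
        inv_g = np.concatenate(
            [np.full(q, 1.0 / g) for q, g in zip(self.q_sizes, gammas)]
        )
        A = self.G1 + np.diag(inv_g)
        cA, low = cho_factor(A, lower=True)
        logdetA = 2.0 * np.sum(np.log(np.diag(cA)))
        AiG1 = cho_solve((cA, low), self.G1)
        AiG2 = cho_solve((cA, low), self.G2)
        Aig4 = cho_solve((cA, low), self.g4)
        B = self.G3 - self.G2.T @ AiG2            # X' H^-1 X
        XHy = self.g5 - self.G2.T @ Aig4
        ZHy = self.g4 - self.G1 @ Aig4
        ZHX = self.G2 - self.G1 @ AiG2
        yHy = self.yty - self.g4 @ Aig4
        cB, lowB = cho_factor(B, lower=True)
        logdetB = 2.0 * np.sum(np.log(np.diag(cB)))
        BiXHy = cho_solve((cB, lowB), XHy)
        yPy = yHy - XHy @ BiXHy
        ZPy = ZHy - ZHX @ BiXHy
        # diag(Z' P Z) = diag(Z'H^-1 Z) - rowwise quadform of ZHX with B^-1
        diag_ZHZ = np.diag(self.G1) - np.einsum("ij,ji->i", self.G1, AiG1)
        BiZHX = cho_solve((cB, lowB), ZHX.T)      # p x q
        diag_corr = np.einsum("ij,ji->i", ZHX, BiZHX)
        diag_ZPZ = diag_ZHZ - diag_corr
        return {
            "logdetA": logdetA,
            "logdetB": logdetB,
            "yPy": float(yPy),
            "ZPy": ZPy,
            "diag_ZPZ": diag_ZPZ,
            "B": B,
            "cB": (cB, lowB),
            "XHy": XHy,
            "BiXHy": BiXHy,
            "Aig4": Aig4,
            "AiG2": AiG2,
        }

    def neg2_reml(self, log_gammas: np.ndarray):
        gammas = np.exp(log_gammas)
        pc = self._pieces(gammas)
        n, p = self.n, self.p
        logdetH = sum(q * lg for q, lg in zip(self.q_sizes, log_gammas)) + pc["logdetA"]
        # floor guards the noiseless limit (exact fit -> yPy == 0)
        sigma2 = max(pc["yPy"] / (n - p), 1e-14 * (self.yty / n + 1.0))
        f = (n - p) * np.log(sigma2) + logdetH + pc["logdetB"] + (n - p)
        # gradient wrt gamma_k, then chain rule to log gamma
        grad = np.empty(len(gammas))
        for k, sl in enumerate(self.slices):
            tr_k = float(np.sum(pc["diag_ZPZ"][sl]))
            sq_k = float(np.sum(pc["ZPy"][sl] ** 2))
            grad[k] = (tr_k - sq_k / sigma2) * gammas[k]
        return f, grad, pc, sigma2

    def _polish(self, x: np.ndarray, n_steps: int = 3) -> np.ndarray:
        """Newton steps on the interior components (numeric Jacobian of the
        analytic gradient) to pin the optimum to high precision, so REML
        results are invariant to reparameterizations of the fixed part."""
        free = np.flatnonzero((x > -19.5) & (x < 11.5))
        if len(free) == 0:
            return x
        x = x.copy()
        f_best, g_best, *_ = self.neg2_reml(x)
        for _ in range(n_steps):
            f0, g0, *_ = self.neg2_reml(x)
            gf = g0[free]
            if np.max(np.abs(gf)) < 1e-10:
                break
            eps = 1e-6
            J = np.empty((len(free), len(free)))
            for a, k in enumerate(free):
                xp = x.copy()
                xp[k] += eps
                _, gp, *_ = self.neg2_reml(xp)
                J[:, a] = (gp[free] - gf) / eps
            try:
                step = np.linalg.solve(J + 1e-10 * np.eye(len(free)), gf)
            except np.linalg.LinAlgError:
                break
            step = np.clip(step, -1.0, 1.0)
            accepted = False
            for _ in range(6):       # damped Newton: halve until grad drops
                xn = x.copy()
                xn[free] -= step
                fn, gn, *_ = self.neg2_reml(xn)
                if np.max(np.abs(gn[free])) < np.max(np.abs(gf)):
                    x, f_best, accepted = xn, fn, True
                    break
                step *= 0.5
            if not accepted:
                break
        return x

    def solve(self, max_iter: int = 200, tol: float = 1e-8,
              init_gamma: float = 0.1):
        k = len(self.q_sizes)
        x0 = np.full(k, np.log(init_gamma))
        state: dict = {}

        def fun(lg):
            f, g, pc, s2 = self.neg2_reml(lg)
            state["pc"], state["sigma2"], state["lg"] = pc, s2, lg.copy()
            return f, g

        res = optimize.minimize(
            fun, x0, jac=True, method="L-BFGS-B",
            bounds=[(-20.0, 12.0)] * k,
            options={"maxiter": max_iter, "ftol": tol * 1e-4, "gtol": 1e-9},
        )
        if not (res.success or res.status == 0):
            if "maxiter" in str(res.message).lower() or res.nit >= max_iter:
                raise LmmConvergenceError(
                    f"REML did not converge in {max_iter} iterations: {res.message}",
                    last_iterate={"log_gammas": res.x, "neg2_reml": float(res.fun)},
                )
        x = self._polish(res.x)
        f, g, pc, sigma2 = self.neg2_reml(x)
        res.x = x
        gammas = np.exp(res.x)
        # floor numerically-zero components
        gammas = np.where(gammas < 2.5e-9, 0.0, gammas)
        B = pc["B"]
        beta = pc["BiXHy"]
        beta_cov = sigma2 * np.linalg.inv(B)
        u = np.concatenate(
            [g * pc["ZPy"][sl] for g, sl in zip(np.exp(res.x), self.slices)]
        )
        loglik = -0.5 * (f + (self.n - self.p) * np.log(2 * np.pi))
        return {
            "gammas": gammas,
            "sigma2_e": sigma2,
            "beta": beta,
            "beta_se": np.sqrt(np.clip(np.diag(beta_cov), 0.0, None)),
            "u": u,
            "reml_loglik": float(loglik),
            "n_iter": int(res.nit),
        }


def fit_experiment_lmm(
    data: pd.DataFrame,
    experiment: int,
    max_iter: int = 200,
    tol: float = 1e-8,
    shrink_genotype: bool = False,
) -> LmmFit:
    """REML fit of the experiment-specific mixed model.

    ``data`` is a per-plant table with columns ``accession_id``,
    ``treatment`` (experiments 1-2 only), the positional factors required
    by the experiment, and ``value``.  With ``shrink_genotype`` the
    genotype enters as a random term as well and its BLUPs are recorded
    (the shrunken alternative to fixed-effect genotypic means).
    """
    if experiment not in EXPERIMENT_RANDOM_TERMS:
        raise ValueError(f"experiment must be 1-4, got {experiment}")
    terms = EXPERIMENT_RANDOM_TERMS[experiment]
    needed = {"accession_id", "value"} | {c for t in terms for c in t}
    with_trt = EXPERIMENT_TREATMENTS[experiment] is not None
    if with_trt:
        needed.add("treatment")
    missing = needed - set(data.columns)
    if missing:
        raise ValueError(f"bioassay table missing columns {sorted(missing)}")
    if with_trt:
        vocab = set(EXPERIMENT_TREATMENTS[experiment])
        bad = set(data["treatment"].astype(str)) - vocab
        if bad:
            raise ValueError(
                f"unknown treatments {sorted(bad)} for experiment {experiment}; "
                f"expected {sorted(vocab)}"
            )
    y = data["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in bioassay table")

    if shrink_genotype:
        X, names, gen_levels, trt_levels = _fixed_design(
            data.assign(accession_id="pooled"), with_trt
        )
        gen_levels = sorted(data["accession_id"].astype(str).unique())
        Zs = [_indicator(data, ("accession_id",))]
        term_names = ["GEN"]
    else:
        X, names, gen_levels, trt_levels = _fixed_design(data, with_trt)
        Zs, term_names = [], []
    short = {"block": "B", "sub_block": "SB", "rack": "R", "shelf": "S",
             "tray": "T", "x": "X", "y": "Y"}
    for t in terms:
        Zs.append(_indicator(data, t))
        term_names.append(" x ".join(short.get(c, c.upper()) for c in t))

    problem = _RemlProblem(y, X, Zs)
    sol = problem.solve(max_iter=max_iter, tol=tol)
    comps = {
        name: float(g * sol["sigma2_e"])
        for name, g in zip(term_names, sol["gammas"])
    }
    blup_gen = None
    if shrink_genotype:
        q0 = Zs[0].shape[1]
        blup_gen = pd.Series(sol["u"][:q0], index=gen_levels, name="blup")
    fit = LmmFit(
        experiment=experiment,
        beta=sol["beta"],
        beta_se=sol["beta_se"],
        beta_names=names,
        variance_components=comps,
        sigma2_e=float(sol["sigma2_e"]),
        reml_loglik=sol["reml_loglik"],
        converged=True,
        n_obs=len(y),
        gen_levels=gen_levels,
        trt_levels=trt_levels,
        n_iter=sol["n_iter"],
    )
    fit.blup_gen = blup_gen
    return fit


# ---------------------------------------------------------------------------
# Predicted means and stress responses
# ---------------------------------------------------------------------------

def predicted_means(fit: LmmFit) -> pd.DataFrame:
    """Fixed-effect predicted cell means, random terms at zero.

    Returns a DataFrame indexed by accession with one column per treatment
    (a single ``mean`` column for the no-treatment experiments).  For a
    ``shrink_genotype`` fit the genotype BLUP replaces the fixed genotype
    effect.
    """
    if not fit.converged:
        raise ValueError("predicted means require a converged fit")
    lookup = {name: k for k, name in enumerate(fit.beta_names)}
    mu = fit.beta[lookup["(Intercept)"]]

    def gen_eff(g: str) -> float:
        if fit.blup_gen is not None:
            return float(fit.blup_gen[g])
        key = f"GEN[{g}]"
        return float(fit.beta[lookup[key]]) if key in lookup else 0.0

    if fit.trt_levels is None:
        rows = {g: mu + gen_eff(g) for g in fit.gen_levels}
        return pd.DataFrame({"mean": rows}).rename_axis("accession_id")

    out = pd.DataFrame(index=pd.Index(fit.gen_levels, name="accession_id"),
                       columns=fit.trt_levels, dtype=float)
    for g in fit.gen_levels:
        for t in fit.trt_levels:
            val = mu + gen_eff(g)
            tkey = f"TRT[{t}]"
            if tkey in lookup:
                val += fit.beta[lookup[tkey]]
            ikey = f"GEN[{g}]:TRT[{t}]"
            if ikey in lookup and fit.blup_gen is None:
                val += fit.beta[lookup[ikey]]
            out.loc[g, t] = val
    return out


def derive_stress_responses(
    means: dict[int, pd.DataFrame],
) -> pd.DataFrame:
    """Per-accession stress-response table from per-experiment means.

    ``means`` maps experiment number to the output of
    :func:`predicted_means`.  Percentage responses are
    ``100 * (baseline - stressed) / baseline`` with the no-stress control
    as baseline, except the combined drought + Pieris response, whose
    baseline is the drought-only treatment.  Thrips damage (mm^2) and aphid
    counts pass through unchanged.  Negative percentages are valid (a
    stressed plant may outgrow its control).
    """
    out: dict[str, pd.Series] = {}

    def pct(base: pd.Series, stressed: pd.Series, label: str) -> pd.Series:
        bad = base <= 0
        if bad.any():
            raise ValueError(
                f"{label}: baseline mean <= 0 for accessions "
                f"{list(base.index[bad])[:5]}; percentage response undefined"
            )
        return 100.0 * (base - stressed) / base

    if 1 in means:
        m1 = means[1]
        out["Drought"] = pct(m1["control"], m1["drought"], "Drought")
        out["P_rapae"] = pct(m1["control"], m1["p_rapae"], "P_rapae")
        out["Drought_Pieris"] = pct(m1["drought"], m1["drought_pieris"], "Drought_Pieris")
        out["Botrytis_Pieris"] = pct(m1["control"], m1["botrytis_pieris"], "Botrytis_Pieris")
    if 2 in means:
        m2 = means[2]
        out["P_xylostella"] = pct(m2["control"], m2["p_xylostella"], "P_xylostella")
    if 3 in means:
        out["F_occidentalis"] = means[3]["mean"]
    if 4 in means:
        out["M_persicae"] = means[4]["mean"]
    return pd.DataFrame(out).rename_axis("accession_id")


# ---------------------------------------------------------------------------
# Life-cycle classification
# ---------------------------------------------------------------------------

def classify_life_cycle(
    flowering: pd.DataFrame,
    threshold_days: float = 75.0,
) -> pd.DataFrame:
    """Classify accessions as winter or summer annuals by flowering time.

    An accession is a winter annual iff its flowering time without
    vernalization is at or above ``threshold_days`` (winter annuals require
    vernalization to flower); plants that never flowered (``censored``
    column true, flowering time may be missing) are winter annuals by
    definition.  Missing flowering times otherwise are an error.
    """
    df = flowering.copy()
    if "accession_id" in df.columns:
        df = df.set_index("accession_id")
    censored = df["censored"].astype(bool) if "censored" in df.columns else (
        pd.Series(False, index=df.index)
    )
    ft = df["flowering_time_days"]
    missing = ft.isna() & ~censored
    if missing.any():
        raise ValueError(
            f"missing flowering time for accessions {list(df.index[missing])[:10]}"
        )
    winter = censored | (ft >= threshold_days)
    df["strategy"] = np.where(winter, "winter", "summer")
    return df
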