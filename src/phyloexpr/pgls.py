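"""Per-gene phylogenetic regression of expression on longevity traits.

Three residual models are fitted per gene — independent errors (OLS),
Brownian motion (BM), and Ornstein–Uhlenbeck (OU) — and the best model is
selected by information criterion. Significance then goes through a
two-step outlier-robust procedure:

* step 1: refit after dropping the single species with the largest
  absolute residual -> ``P_robust``;
* step 2: from the step-1 species set, drop each remaining species in
  turn and refit; the largest (least significant) P across those
  leave-one-out refits is ``P_max``.

Family-wise adjustment uses Westfall–Young min-P resampling: the trait is
permuted across species, the full two-step statistic is recomputed per
gene per permutation, and step-down adjusted P values are read off the
permutation distribution of successive minima.

A gene is called trait-significant when ``P_robust.adj < 0.005`` and
``P_max.adj < 0.05`` (strict), and longevity-correlated when
trait-significant for two or more longevity traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

from .trees import Phylogeny, bm_covariance

__all__ = [
    "FitResult",
    "fit_ols",
    "fit_pgls_bm",
    "fit_pgls_ou",
    "select_model",
    "robust_pvalues",
    "adjust_pvalues",
    "westfall_young_adjust",
    "call_longevity_genes",
    "run_association",
]

MODELS = ("OLS", "BM", "OU")
_MODEL_RANK = {m: i for i, m in enumerate(MODELS)}  # tie-break: simpler first
_DEGENERATE_REL_TOL = 1e-12


class FitError(ValueError):
    pass


@dataclass
class FitResult:
    """One GLS fit: slope inference plus the ML log-likelihood."""

    model: str
    intercept: float
    slope: float
    slope_se: float
    tstat: float
    pvalue: float
    loglik: float
    n_params: int
    sigma2: float
    n: int
    alpha: float | None = None
    degenerate: bool = False

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


# ---------------------------------------------------------------------------
# covariances


def ou_covariance(C: np.ndarray, alpha: float) -> np.ndarray:
    """OU transform of a BM covariance, normalized to the BM limit.

    V(alpha) -> C as alpha -> 0 and V(alpha) -> (diagonal) as alpha grows,
    so BM and OLS are both limits of the OU family on an ultrametric tree.
    """
    if alpha < 0:
        raise FitError("alpha must be non-negative")
    if alpha == 0:
        return C.copy()
    T = np.diag(C)
    # exponents are <= 0 (2 C_ij <= T_i + T_j), so this never overflows;
    # expm1 keeps precision in the alpha -> 0 (BM) limit
    pair = alpha * (T[:, None] + T[None, :])
    return (np.expm1(2.0 * alpha * C - pair) - np.expm1(-pair)) / (2.0 * alpha)


def _default_alpha_bounds(C: np.ndarray) -> tuple[float, float]:
    depth = float(np.mean(np.diag(C)))
    if depth <= 0:
        raise FitError("tree depth must be positive")
    return 1e-4 / depth, 1e3 / depth


# ---------------------------------------------------------------------------
# quadratic-form GLS core


def _stats_from_qf(s11, s1x, s1y, sxx, sxy, syy, logdet, n):
    """Slope inference for y ~ 1 + x from GLS quadratic forms.

    All arguments broadcast, so this serves scalar fits and vectorized
    leave-one-out / permutation batches alike. Returns a dict of arrays.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        det = s11 * sxx - s1x * s1x
        b1 = (s11 * sxy - s1x * s1y) / det
        b0 = (sxx * s1y - s1x * sxy) / det
        rss = syy - b0 * s1y - b1 * sxy
        rss = np.maximum(rss, 0.0)
        degenerate = rss <= _DEGENERATE_REL_TOL * np.maximum(syy, 1.0)
        df = n - 2
        sigma2_ml = rss / n
        loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet + n)
        s2 = rss / df
        var_b1 = s2 * s11 / det
        tstat = b1 / np.sqrt(var_b1)
    pvalue = 2.0 * sps.t.sf(np.abs(tstat), df)
    # degenerate (zero-residual) fits report P = 1 with a flag, never P = 0
    pvalue = np.where(degenerate, 1.0, pvalue)
    bad = ~np.isfinite(det) | (det <= 0)
    pvalue = np.where(bad, np.nan, pvalue)
    return {
        "intercept": b0,
        "slope": b1,
        "slope_se": np.sqrt(var_b1),
        "tstat": tstat,
        "pvalue": pvalue,
        "loglik": np.where(degenerate, np.inf, loglik),
        "sigma2": sigma2_ml,
        "degenerate": degenerate,
        "invalid": bad,
    }


def _qf_full(V: np.ndarray | None, x: np.ndarray, y: np.ndarray):
    """Quadratic forms (1, x, y)' V^-1 (1, x, y) and log|V|."""
    n = len(y)
    Z = np.column_stack([np.ones(n), x, y])
    if V is None:
        AZ = Z
        logdet = 0.0
    else:
        try:
            L = linalg.cholesky(V, lower=True)
        except linalg.LinAlgError as exc:
            raise FitError(f"singular covariance: {exc}") from None
        AZ = linalg.cho_solve((L, True), Z)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    G = Z.T @ AZ
    return G, logdet


def _fit_one(V, x, y, model, n_params, alpha=None) -> FitResult:
    n = len(y)
    G, logdet = _qf_full(V, x, y)
    st = _stats_from_qf(G[0, 0], G[0, 1], G[0, 2], G[1, 1], G[1, 2], G[2, 2], logdet, n)
    if st["invalid"]:
        raise FitError("zero variance in predictor (singular design)")
    ll = float(st["loglik"])
    return FitResult(
        model=model,
        intercept=float(st["intercept"]),
        slope=float(st["slope"]),
        slope_se=float(st["slope_se"]),
        tstat=float(st["tstat"]),
        pvalue=float(st["pvalue"]),
        loglik=ll if math.isfinite(ll) else float("inf"),
        n_params=n_params,
        sigma2=float(st["sigma2"]),
        n=n,
        alpha=alpha,
        degenerate=bool(st["degenerate"]),
    )


# ---------------------------------------------------------------------------
# public fitters


def _check_xy(y, x, min_n=4):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise FitError("y and x must be 1-d and aligned")
    if len(y) < min_n:
        raise FitError(f"need at least {min_n} paired observations, got {len(y)}")
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise FitError("non-finite values in regression input")
    return y, x


def fit_ols(y, x) -> FitResult:
    """Ordinary least squares with Gaussian ML log-likelihood."""
    y, x = _check_xy(y, x)
    return _fit_one(None, x, y, "OLS", 3)


def _resolve_cov(tree, species, C):
    if C is not None:
        return np.asarray(C, dtype=float)
    if tree is None:
        raise FitError("either a tree or a covariance matrix is required")
    phy = tree if isinstance(tree, Phylogeny) else Phylogeny.from_newick(tree)
    return bm_covariance(phy, list(species))


def fit_pgls_bm(y, x, tree=None, species=None, C=None) -> FitResult:
    """GLS under Brownian-motion covariance from the (pruned) tree."""
    y, x = _check_xy(y, x)
    V = _resolve_cov(tree, species, C)
    if V.shape != (len(y), len(y)):
        raise FitError("covariance does not match observation count")
    return _fit_one(V, x, y, "BM", 3)


def fit_pgls_ou(
    y,
    x,
    tree=None,
    species=None,
    C=None,
    alpha_bounds: tuple[float, float] | None = None,
    n_grid: int = 12,
    refine: bool = True,
) -> FitResult:
    """GLS under stationary OU covariance with alpha profiled by ML.

    alpha is scanned on a log-spaced grid within ``alpha_bounds`` (defaults
    scale with tree depth) and optionally refined by bounded search around
    the best grid point.
    """
    y, x = _check_xy(y, x)
    Cmat = _resolve_cov(tree, species, C)
    lo, hi = alpha_bounds or _default_alpha_bounds(Cmat)
    if not 0 < lo < hi:
        raise FitError("alpha bounds must satisfy 0 < lo < hi")
    grid = np.geomspace(lo, hi, n_grid)

    def negll(log_alpha: float) -> float:
        a = math.exp(log_alpha)
        try:
            fit = _fit_one(ou_covariance(Cmat, a), x, y, "OU", 4, alpha=a)
        except FitError:
            return np.inf
        return -fit.loglik

    lls = np.array([negll(math.log(a)) for a in grid])
    if not np.isfinite(lls).any():
        raise FitError("OU optimization failed at every grid point")
    best = int(np.argmin(lls))
    alpha_hat = grid[best]
    if refine:
        lo_b = math.log(grid[max(best - 1, 0)])
        hi_b = math.log(grid[min(best + 1, n_grid - 1)])
        if hi_b > lo_b:
            res = optimize.minimize_scalar(
                negll, bounds=(lo_b, hi_b), method="bounded",
                options={"xatol": 1e-3},
            )
            if res.success and res.fun <= lls[best] + 1e-12:
                alpha_hat = math.exp(res.x)
    return _fit_one(ou_covariance(Cmat, alpha_hat), x, y, "OU", 4, alpha=alpha_hat)


def select_model(fits, criterion: str = "aic") -> FitResult:
    """Pick the best fit by AIC (default) or raw maximum likelihood.

    Exact ties resolve to the simpler model (OLS < BM < OU). AIC is the
    default because OU nests BM, so raw likelihood would always favor OU.
    """
    fits = [f for f in fits if f is not None]
    if not fits:
        raise FitError("all fits failed")
    if criterion == "aic":
        key = lambda f: (f.aic, _MODEL_RANK[f.model])
    elif criterion in ("ml", "loglik"):
        key = lambda f: (-f.loglik, _MODEL_RANK[f.model])
    else:
        raise FitError(f"unknown criterion {criterion!r}")
    return min(fits, key=key)


# ---------------------------------------------------------------------------
# robust two-step procedure


@dataclass
class RobustResult:
    p_robust: float
    p_max: float
    dropped_species: str
    fit_full: FitResult
    fit_robust: FitResult
    p_max_species: str | None = None


def _loo_stats(V: np.ndarray | None, x: np.ndarray, y: np.ndarray):
    """P-value and ML log-likelihood of every single-species deletion.

    Exact leave-one-out GLS via inverse downdating of the full-set solve;
    returns dict of (n,) arrays, entry j = fit with species j removed.
    """
    n = len(y)
    one = np.ones(n)
    if V is None:
        A1, Ay, Ax = one, y, x
        adiag = one
        logdet = 0.0
        logdet_j = np.zeros(n)
    else:
        L = linalg.cholesky(V, lower=True)
        A = linalg.cho_solve((L, True), np.eye(n))
        A1, Ay, Ax = A @ one, A @ y, A @ x
        adiag = np.diag(A).copy()
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        logdet_j = logdet + np.log(adiag)
    s11, s1x, s1y = float(one @ A1), float(x @ A1), float(y @ A1)
    sxx, sxy, syy = float(x @ Ax), float(y @ Ax), float(y @ Ay)
    a = adiag
    w1, wx, wy = A1 - a * one, Ax - a * x, Ay - a * y

    def drop(full, pa, pb, Apa, Apb, wa, wb):
        return full - pa * Apb - pb * Apa + pa * pb * a - wa * wb / a

    q11 = drop(s11, one, one, A1, A1, w1, w1)
    q1x = drop(s1x, one, x, A1, Ax, w1, wx)
    q1y = drop(s1y, one, y, A1, Ay, w1, wy)
    qxx = drop(sxx, x, x, Ax, Ax, wx, wx)
    qxy = drop(sxy, x, y, Ax, Ay, wx, wy)
    qyy = drop(syy, y, y, Ay, Ay, wy, wy)
    return _stats_from_qf(q11, q1x, q1y, qxx, qxy, qyy, logdet_j, n - 1)


def _loo_model_selected(
    C1: np.ndarray | None, x1: np.ndarray, y1: np.ndarray, models, criterion, ou_grid
):
    """Per-deletion model-selected P values on one species set.

    Runs :func:`_loo_stats` for each candidate model (OU profiled on its
    alpha grid), then applies the information-criterion choice per
    deletion. Returns the (n,) array of selected P values.
    """
    n = len(y1)
    pvals, crits, ranks = [], [], []
    for m in models:
        if m == "OLS":
            st = _loo_stats(None, x1, y1)
            ll, p, k = st["loglik"], st["pvalue"], 3
        elif m == "BM":
            if C1 is None:
                continue
            st = _loo_stats(C1, x1, y1)
            ll, p, k = st["loglik"], st["pvalue"], 3
        elif m == "OU":
            if C1 is None:
                continue
            lo, hi = _default_alpha_bounds(C1)
            ll = np.full(n, -np.inf)
            p = np.full(n, np.nan)
            for alpha in np.geomspace(lo, hi, ou_grid):
                st = _loo_stats(ou_covariance(C1, alpha), x1, y1)
                better = st["loglik"] > ll
                ll = np.where(better, st["loglik"], ll)
                p = np.where(better, st["pvalue"], p)
            k = 4
        else:
            raise FitError(f"unknown model {m!r}")
        pvals.append(p)
        crit = 2.0 * k - 2.0 * ll if criterion == "aic" else -ll
        crits.append(crit)
        ranks.append(_MODEL_RANK[m])
    if not pvals:
        raise FitError("no fittable models")
    crit_mat = np.vstack(crits)
    # degenerate fits have loglik = +inf -> crit = -inf; treat as worst
    crit_mat = np.where(np.isfinite(crit_mat), crit_mat, np.inf)
    order = np.argsort(ranks)  # stable tie-break toward simpler models
    crit_mat = crit_mat[order]
    best = np.argmin(crit_mat, axis=0)
    p_mat = np.vstack(pvals)[order]
    return p_mat[best, np.arange(n)]


def _fit_subset(y, x, C, models, criterion, ou_grid):
    """Fit the requested models on one species subset and select."""
    fits = []
    for m in models:
        try:
            if m == "OLS":
                fits.append(fit_ols(y, x))
            elif m == "BM":
                fits.append(fit_pgls_bm(y, x, C=C))
            elif m == "OU":
                fits.append(
                    fit_pgls_ou(y, x, C=C, n_grid=ou_grid, refine=False)
                )
            else:
                raise FitError(f"unknown model {m!r}")
        except FitError:
            fits.append(None)
    return select_model(fits, criterion)


def robust_pvalues(
    y,
    x,
    tree=None,
    species=None,
    C=None,
    models=MODELS,
    criterion: str = "aic",
    floor: int = 6,
    reselect: bool = True,
    ou_grid: int = 10,
) -> RobustResult:
    """Two-step robust P-values for one gene.

    Step 1 drops the largest-|residual| species and refits (``P_robust``);
    step 2 drops each remaining species in turn from the step-1 set and
    takes the largest refit P (``P_max``). The model is re-selected at
    every refit by default; ``reselect=False`` holds the step-1 model.
    Genes with fewer than ``floor`` species raise :class:`FitError` so the
    caller can record a skip.
    """
    y, x = _check_xy(y, x, min_n=floor)
    species = list(species) if species is not None else [str(i) for i in range(len(y))]
    need_tree = any(m in ("BM", "OU") for m in models)
    Cfull = _resolve_cov(tree, species, C) if need_tree else None

    def sub_cov(idx):
        return Cfull[np.ix_(idx, idx)] if Cfull is not None else None

    all_idx = np.arange(len(y))
    fit_full = _fit_subset(y, x, Cfull, models, criterion, ou_grid)
    resid = y - fit_full.intercept - fit_full.slope * x
    drop1 = int(np.argmax(np.abs(resid)))

    keep1 = np.delete(all_idx, drop1)
    fit_rob = _fit_subset(y[keep1], x[keep1], sub_cov(keep1), models, criterion, ou_grid)

    models2 = models if reselect else (fit_rob.model,)
    p_loo = _loo_model_selected(
        sub_cov(keep1), x[keep1], y[keep1], models2, criterion, ou_grid
    )
    if not np.isfinite(p_loo).any():
        raise FitError("every leave-one-out refit failed")
    jbest = int(np.nanargmax(p_loo))
    p_max = float(p_loo[jbest])
    p_max_sp = species[keep1[jbest]]
    return RobustResult(
        p_robust=fit_rob.pvalue,
        p_max=float(p_max),
        dropped_species=species[drop1],
        fit_full=fit_full,
        fit_robust=fit_rob,
        p_max_species=p_max_sp,
    )


# ---------------------------------------------------------------------------
# permutation engine (fixed per-gene model, vectorized across permutations)


def _perm_model_pieces(V: np.ndarray | None, y: np.ndarray, Xp: np.ndarray):
    """Per-model precomputation for the vectorized permutation two-step."""
    n, m = Xp.shape
    one = np.ones(n)
    if V is None:
        A = np.eye(n)
        A1, Ay, AX = one, y.copy(), Xp
        logdet = 0.0
    else:
        L = linalg.cholesky(V, lower=True)
        A = linalg.cho_solve((L, True), np.eye(n))
        A1, Ay, AX = A @ one, A @ y, A @ Xp
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return {
        "A": A, "A1": A1, "Ay": Ay, "AX": AX, "adiag": np.diag(A).copy(),
        "logdet": logdet,
        "s11": float(one @ A1), "s1y": float(one @ Ay), "syy": float(y @ Ay),
        "s1x": one @ AX, "sxy": y @ AX,
        "sxx": np.einsum("ij,ij->j", Xp, AX),
    }


def _perm_two_step(models: list, y: np.ndarray, Xp: np.ndarray):
    """Recompute the two-step P values for every permuted trait column.

    ``models`` is a list of (covariance-or-None, n_params) candidates in
    simpler-first order; the best model is re-selected by AIC at the full
    fit, the step-1 refit, and every step-2 deletion — mirroring the
    observed-data pipeline. All refits are exact, obtained from the
    full-set inverse by block downdating. ``Xp`` is (n, n_perm).
    Returns (p_robust, p_max), each (n_perm,).
    """
    n, m = Xp.shape
    one = np.ones(n)
    cols = np.arange(m)
    pieces = [_perm_model_pieces(V, y, Xp) for V, _ in models]
    kparams = np.array([k for _, k in models], dtype=float)

    def aic_select(pvals, logliks, kvec):
        # stack (n_models, ...); ties go to the earlier (simpler) model
        crit = np.stack(
            [2.0 * k - 2.0 * ll for k, ll in zip(kvec, logliks)]
        )
        crit = np.where(np.isfinite(crit), crit, np.inf)
        best = np.argmin(crit, axis=0)
        p = np.stack(pvals)
        return np.take_along_axis(p, best[None], axis=0)[0], best

    # --- full fit per permutation: select model, get residual argmax ----
    full_stats = []
    for pc in pieces:
        st = _stats_from_qf(
            pc["s11"], pc["s1x"], pc["s1y"], pc["sxx"], pc["sxy"], pc["syy"],
            pc["logdet"], n,
        )
        full_stats.append(st)
    _, best0 = aic_select(
        [st["pvalue"] for st in full_stats],
        [st["loglik"] for st in full_stats],
        kparams,
    )
    b0 = np.choose(best0, [st["intercept"] for st in full_stats])
    b1 = np.choose(best0, [st["slope"] for st in full_stats])
    resid = y[:, None] - b0[None, :] - Xp * b1[None, :]
    d = np.argmax(np.abs(resid), axis=0)  # (m,)

    # --- step 1: single drop d, per permutation -------------------------
    # qf_drop(p, q) = p'Aq - p_d (Aq)_d - q_d (Ap)_d + p_d q_d a
    #                 - ((Ap)_d - a p_d)((Aq)_d - a q_d) / a
    p1_list, ll1_list = [], []
    for pc in pieces:
        a = pc["adiag"][d]  # (m,)
        pv = (one[d], Xp[d, cols], y[d])
        Apv = (pc["A1"][d], pc["AX"][d, cols], pc["Ay"][d])
        w = tuple(Apv[i] - a * pv[i] for i in range(3))

        def drop1(full, i, k):
            return (
                full - pv[i] * Apv[k] - pv[k] * Apv[i] + pv[i] * pv[k] * a
                - w[i] * w[k] / a
            )

        logdet1 = pc["logdet"] + np.log(a)
        st = _stats_from_qf(
            drop1(pc["s11"], 0, 0), drop1(pc["s1x"], 0, 1),
            drop1(pc["s1y"], 0, 2), drop1(pc["sxx"], 1, 1),
            drop1(pc["sxy"], 1, 2), drop1(pc["syy"], 2, 2),
            logdet1, n - 1,
        )
        p1_list.append(st["pvalue"])
        ll1_list.append(st["loglik"])
    p_robust, _ = aic_select(p1_list, ll1_list, kparams)

    # --- step 2: drop pair {d, j} for every remaining j ------------------
    p2_list, ll2_list = [], []
    for pc in pieces:
        A, A1, Ay, AX = pc["A"], pc["A1"], pc["Ay"], pc["AX"]
        a11 = pc["adiag"][d][:, None]  # (m, 1)
        a12 = A[d, :]  # (m, n)
        a22 = pc["adiag"][None, :]  # (1, n)
        with np.errstate(invalid="ignore"):
            detS = a11 * a22 - a12**2  # (m, n)
        vd = (one[d][:, None], Xp[d, cols][:, None], y[d][:, None])
        vj = (np.ones((1, n)), Xp[:, cols].T, y[None, :])
        Avd = (A1[d][:, None], AX[d, cols][:, None], Ay[d][:, None])
        Avj = (A1[None, :], AX[:, cols].T, Ay[None, :])

        def drop2(full, i, k):
            full = np.asarray(full, dtype=float)
            if full.ndim == 1:  # per-permutation scalar -> broadcast over j
                full = full[:, None]
            t2 = vd[i] * Avd[k] + vj[i] * Avj[k]
            t3 = Avd[i] * vd[k] + Avj[i] * vj[k]
            t4 = (a11 * vd[i] * vd[k] + a12 * (vd[i] * vj[k] + vj[i] * vd[k])
                  + a22 * vj[i] * vj[k])
            ua_d = Avd[i] - (a11 * vd[i] + a12 * vj[i])
            ua_j = Avj[i] - (a12 * vd[i] + a22 * vj[i])
            ub_d = Avd[k] - (a11 * vd[k] + a12 * vj[k])
            ub_j = Avj[k] - (a12 * vd[k] + a22 * vj[k])
            t5 = (a22 * ua_d * ub_d - a12 * (ua_d * ub_j + ua_j * ub_d)
                  + a11 * ua_j * ub_j)
            with np.errstate(divide="ignore", invalid="ignore"):
                return full - t2 - t3 + t4 - t5 / detS

        with np.errstate(divide="ignore", invalid="ignore"):
            logdet2 = pc["logdet"] + np.log(detS)
        st = _stats_from_qf(
            drop2(pc["s11"], 0, 0), drop2(pc["s1x"], 0, 1),
            drop2(pc["s1y"], 0, 2), drop2(pc["sxx"], 1, 1),
            drop2(pc["sxy"], 1, 2), drop2(pc["syy"], 2, 2),
            logdet2, n - 2,
        )
        p2 = st["pvalue"]
        p2[cols, d] = np.nan  # j == d is not a valid second drop
        ll2 = st["loglik"]
        ll2[cols, d] = -np.inf
        p2_list.append(p2)
        ll2_list.append(ll2)
    p_sel, _ = aic_select(p2_list, ll2_list, kparams)
    with np.errstate(all="ignore"):
        p_max = np.nanmax(p_sel, axis=1)
    return np.asarray(p_robust, dtype=float), np.asarray(p_max, dtype=float)


def permutation_null(
    gene_data: dict,
    trait: pd.Series,
    tree: Phylogeny | None,
    n_perm: int,
    seed: int,
    floor: int = 6,
    perm_mode: str = "shuffle",
    models=("OLS", "BM"),
):
    """Null distributions of (P_robust, P_max) under trait resampling.

    ``gene_data`` maps gene -> dict with keys ``species`` (list), ``y``
    (array aligned to species), and ``alpha`` (the observed-data OU rate,
    used as the OU candidate in the null since per-permutation profiling
    is prohibitive). One trait draw per permutation is shared across
    genes, preserving cross-gene correlation for family-wise control, and
    the two-step statistic re-selects among ``models`` per permutation,
    mirroring the observed pipeline.

    ``perm_mode='shuffle'`` permutes observed trait values across species;
    ``'bm'`` draws parametric Brownian-motion trait replicates on the tree
    (plain shuffling destroys the trait's phylogenetic structure and can
    be anticonservative when that structure is strong).
    Returns (genes, p_robust_null, p_max_null) with arrays (G, n_perm).
    """
    rng = np.random.default_rng(seed)
    union = list(trait.dropna().index)
    tvals = trait.loc[union].to_numpy(dtype=float)
    pos = {s: i for i, s in enumerate(union)}
    if perm_mode == "shuffle":
        perms = np.empty((len(union), n_perm))
        for b in range(n_perm):
            perms[:, b] = tvals[rng.permutation(len(union))]
    elif perm_mode == "bm":
        if tree is None:
            raise FitError("perm_mode='bm' requires a tree")
        Cu = bm_covariance(tree, union)
        L = linalg.cholesky(Cu + 1e-10 * np.eye(len(union)), lower=True)
        A1 = linalg.cho_solve((L, True), np.ones(len(union)))
        mu = float(A1 @ tvals) / float(A1.sum())
        resid = tvals - mu
        sigma2 = float(resid @ linalg.cho_solve((L, True), resid)) / len(union)
        perms = mu + np.sqrt(sigma2) * (L @ rng.standard_normal((len(union), n_perm)))
    else:
        raise FitError(f"unknown perm_mode {perm_mode!r}")

    genes = list(gene_data)
    Cfull = bm_covariance(tree, union) if tree is not None else None
    pr = np.full((len(genes), n_perm), np.nan)
    pm = np.full((len(genes), n_perm), np.nan)
    for gi, g in enumerate(genes):
        info = gene_data[g]
        sp = [s for s in info["species"] if s in pos]
        if len(sp) < floor:
            continue
        sel = np.array([pos[s] for s in sp])
        y = np.asarray(info["y"], dtype=float)
        y = y[[list(info["species"]).index(s) for s in sp]]
        Csub = Cfull[np.ix_(sel, sel)] if Cfull is not None else None
        candidates = []
        for mname in models:  # simpler-first order assumed
            if mname == "OLS":
                candidates.append((None, 3))
            elif mname == "BM" and Csub is not None:
                candidates.append((Csub, 3))
            elif mname == "OU" and Csub is not None:
                alpha = info.get("alpha")
                if alpha:  # observed-data OU rate; absent -> skip candidate
                    candidates.append((ou_covariance(Csub, alpha), 4))
        if not candidates:
            continue
        Xp = perms[sel, :]
        pr[gi], pm[gi] = _perm_two_step(candidates, y, Xp)
    return genes, pr, pm


def westfall_young_adjust(p_obs: np.ndarray, p_null: np.ndarray) -> np.ndarray:
    """Step-down min-P adjustment from a (G, n_perm) null matrix.

    Adjusted values are clamped to be >= the raw P, and monotone in the
    observed significance ordering.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    G, m = p_null.shape
    order = np.argsort(p_obs)
    null_sorted = p_null[order]
    with np.errstate(all="ignore"):
        succ_min = np.fmin.accumulate(null_sorted[::-1], axis=0)[::-1]
    counts = np.nansum(succ_min <= p_obs[order][:, None], axis=1)
    adj_sorted = (counts + 1.0) / (m + 1.0)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(G)
    adj[order] = adj_sorted
    return np.maximum(adj, p_obs)


def adjust_pvalues(
    raw: pd.DataFrame,
    gene_data: dict,
    trait: pd.Series,
    tree: Phylogeny | None,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "westfall-young",
    perm_mode: str = "shuffle",
    models=("OLS", "BM"),
) -> pd.DataFrame:
    """Family-wise adjust the per-gene P_robust and P_max columns.

    ``raw`` is indexed by gene with columns ``p_robust`` and ``p_max``.
    Default is Westfall–Young resampling (see :func:`permutation_null` for
    ``perm_mode``); ``method='bh'`` applies Benjamini–Hochberg as a
    documented fallback.
    """
    out = raw.copy()
    if method == "bh":
        from statsmodels.stats.multitest import multipletests

        for col in ("p_robust", "p_max"):
            ok = raw[col].notna()
            adj = np.full(len(raw), np.nan)
            if ok.any():
                adj[ok.to_numpy()] = multipletests(
                    raw.loc[ok, col], method="fdr_bh"
                )[1]
            out[col + "_adj"] = np.maximum(adj, raw[col])
        return out
    if method != "westfall-young":
        raise FitError(f"unknown adjustment method {method!r}")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is very low for resampling adjustment")
    genes, pr_null, pm_null = permutation_null(
        {g: gene_data[g] for g in raw.index}, trait, tree, n_perm, seed,
        perm_mode=perm_mode, models=models,
    )
    pr_null = pd.DataFrame(pr_null, index=genes).loc[raw.index].to_numpy()
    pm_null = pd.DataFrame(pm_null, index=genes).loc[raw.index].to_numpy()
    out["p_robust_adj"] = westfall_young_adjust(raw["p_robust"].to_numpy(), pr_null)
    out["p_max_adj"] = westfall_young_adjust(raw["p_max"].to_numpy(), pm_null)
    return out


# ---------------------------------------------------------------------------
# gene calling


def call_longevity_genes(
    records: pd.DataFrame,
    p_robust_cut: float = 0.005,
    p_max_cut: float = 0.05,
    min_traits: int = 2,
) -> pd.DataFrame:
    """Flag trait-significant records and call longevity-correlated genes.

    A record is significant iff ``p_robust_adj < p_robust_cut`` and
    ``p_max_adj < p_max_cut`` (both strict). A gene is longevity-correlated
    iff significant for >= ``min_traits`` traits within a tissue; its
    direction is the majority slope sign over significant traits, with
    exact sign conflicts flagged.
    """
    req = {"gene", "trait", "slope", "p_robust_adj", "p_max_adj"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"association records missing columns {sorted(missing)}")
    rec = records.copy()
    if "tissue" not in rec.columns:
        rec["tissue"] = "all"
    rec["significant"] = (rec["p_robust_adj"] < p_robust_cut) & (
        rec["p_max_adj"] < p_max_cut
    )
    rows = []
    for (tissue, gene), grp in rec.groupby(["tissue", "gene"], sort=False):
        sig = grp[grp["significant"]]
        n_sig = len(sig["trait"].unique())
        signs = np.sign(sig["slope"]).astype(int)
        pos, neg = int((signs > 0).sum()), int((signs < 0).sum())
        if pos > neg:
            direction = "positive"
        elif neg > pos:
            direction = "negative"
        else:
            direction = "conflict" if n_sig else "none"
        rows.append(
            {
                "tissue": tissue,
                "gene": gene,
                "n_significant_traits": n_sig,
                "significant_traits": ",".join(sorted(sig["trait"].unique())),
                "direction": direction,
                "longevity_correlated": n_sig >= min_traits,
                "sign_conflict": direction == "conflict",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline driver


def run_association(
    species_means: pd.DataFrame,
    traits: pd.DataFrame,
    tree: Phylogeny,
    tissue: str = "all",
    models=MODELS,
    criterion: str = "aic",
    n_perm: int = 1000,
    seed: int = 0,
    floor: int = 6,
    p_robust_cut: float = 0.005,
    p_max_cut: float = 0.05,
    log2_traits: bool = True,
    adjust_method: str = "westfall-young",
    perm_mode: str = "shuffle",
):
    """Full per-gene association pipeline for one tissue.

    ``species_means`` is gene x species (NaN = absent ortholog); ``traits``
    is species x trait. Absolute traits (ML, FTM, AW) are log2-scaled
    before regression; residual traits (already log-derived, possibly
    negative) are used untransformed. Returns (records, calls, skips).
    """
    records = []
    skips = []
    gene_cache: dict[str, dict] = {}
    for trait_name in traits.columns:
        tvals = traits[trait_name].dropna()
        if log2_traits and not trait_name.endswith("res"):
            tvals = np.log2(tvals)
        gene_data = {}
        raw_rows = {}
        for gene in species_means.index:
            expr = species_means.loc[gene].dropna()
            common = [s for s in expr.index if s in tvals.index]
            if len(common) < floor:
                skips.append(
                    {"gene": gene, "trait": trait_name, "reason": f"n={len(common)}<{floor}"}
                )
                continue
            y = expr.loc[common].to_numpy(dtype=float)
            x = tvals.loc[common].to_numpy(dtype=float)
            try:
                rr = robust_pvalues(
                    y, x, tree=tree, species=common, models=models,
                    criterion=criterion, floor=floor,
                )
            except FitError as exc:
                skips.append({"gene": gene, "trait": trait_name, "reason": str(exc)})
                continue
            gene_data[gene] = {
                "species": common,
                "y": y,
                "model": rr.fit_full.model,
                "alpha": rr.fit_full.alpha,
            }
            raw_rows[gene] = {
                "p_robust": rr.p_robust,
                "p_max": rr.p_max,
                "model": rr.fit_full.model,
                "slope": rr.fit_robust.slope,
                "p_raw": rr.fit_full.pvalue,
                "dropped_species": rr.dropped_species,
                "n_species": len(common),
            }
        if not raw_rows:
            continue
        raw = pd.DataFrame.from_dict(raw_rows, orient="index")
        adj = adjust_pvalues(
            raw[["p_robust", "p_max"]], gene_data, tvals, tree,
            n_perm=n_perm, seed=seed, method=adjust_method,
            perm_mode=perm_mode, models=models,
        )
        raw["p_robust_adj"] = adj["p_robust_adj"]
        raw["p_max_adj"] = adj["p_max_adj"]
        raw["trait"] = trait_name
        raw["tissue"] = tissue
        raw.index.name = "gene"
        records.append(raw.reset_index())
    rec = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(
            columns=["gene", "p_robust", "p_max", "model", "slope", "p_raw",
                     "dropped_species", "n_species", "p_robust_adj",
                     "p_max_adj", "trait", "tissue"]
        )
    )
    calls = (
        call_longevity_genes(rec, p_robust_cut, p_max_cut)
        if len(rec)
        else pd.DataFrame()
    )
    return rec, calls, pd.DataFrame(skips)
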