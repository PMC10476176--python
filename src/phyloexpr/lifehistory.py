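"""Allometric residual traits, phylogenetic imputation, and its benchmark.

Traits are log-transformed before modeling and back-transformed after.
The imputer treats the trait matrix as jointly multivariate normal with
covariance (between-trait phylogenetic covariance) x (BM tree covariance)
plus trait-specific diagonal noise, fits the parameters by restricted
maximum likelihood (ML switch available), and fills missing cells with
their conditional expectation given all observed cells. Observed cells
are never touched.

The benchmarking harness sweeps missingness mechanisms and proportions,
scoring each method by range-normalized RMSE over the blanked cells and
by the absolute change in the lifespan-vs-weight allometric slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .io import LifeHistoryTable
from .trees import Phylogeny, bm_covariance

__all__ = [
    "allometric_residuals",
    "pcoa_eigenvectors",
    "bm_impute",
    "grand_mean_impute",
    "pmm_impute",
    "nrmse",
    "slope_bias",
    "evaluate_imputation",
]


class ImputationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# residual traits


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) of y ~ x by ordinary least squares."""
    vx = np.var(x)
    if vx == 0:
        raise ImputationError("degenerate regression: zero variance in predictor")
    b = float(np.cov(x, y, ddof=0)[0, 1] / vx)
    a = float(np.mean(y) - b * np.mean(x))
    return a, b


def allometric_residuals(
    table: LifeHistoryTable, log_base: float = 2.0
) -> LifeHistoryTable:
    """Add MLres / FTMres: residuals of log trait on log adult weight.

    The OLS line is fitted over species with both values observed; fitted
    coefficients are stored in ``table.frame.attrs['allometric_fits']``.
    """
    out = table.copy()
    logf = lambda v: np.log(v) / np.log(log_base)
    fits = {}
    for trait in ("ML", "FTM"):
        ok = out.frame[["AW", trait]].notna().all(axis=1)
        if ok.sum() < 3:
            raise ImputationError(f"fewer than 3 complete (AW, {trait}) cases")
        x = logf(out.frame.loc[ok, "AW"].to_numpy(dtype=float))
        y = logf(out.frame.loc[ok, trait].to_numpy(dtype=float))
        a, b = _ols_line(x, y)
        fits[trait] = {"intercept": a, "slope": b, "n": int(ok.sum())}
        res = pd.Series(np.nan, index=out.frame.index)
        res[ok] = y - (a + b * x)
        out.frame[f"{trait}res"] = res
    out.frame.attrs["allometric_fits"] = fits
    return out


# ---------------------------------------------------------------------------
# PCoA


def pcoa_eigenvectors(distance_matrix, n_vectors: int | None = None) -> pd.DataFrame:
    """Classical scaling (PCoA) of a distance matrix.

    Double-centers the squared distances, eigendecomposes, keeps axes with
    positive eigenvalues ordered decreasingly (at most N-1), and scales
    each axis by sqrt(eigenvalue) so embedded distances approximate the
    input. The dropped (negative-eigenvalue) variance fraction is stored
    in ``result.attrs``.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = distance_matrix.index
        D = distance_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        labels = pd.RangeIndex(len(D))
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ImputationError("distance matrix must be square and symmetric")
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-10
    kept = min(int(pos.sum()), n - 1)
    if n_vectors is not None:
        kept = min(kept, n_vectors)
    coords = evecs[:, :kept] * np.sqrt(evals[:kept])
    out = pd.DataFrame(
        coords, index=labels, columns=[f"PCo{i + 1}" for i in range(kept)]
    )
    total_abs = np.abs(evals).sum()
    out.attrs["retained_variance"] = float(evals[:kept].sum() / total_abs) if total_abs else 1.0
    return out


# ---------------------------------------------------------------------------
# BM-conditional imputation


def _pack_lower(p: int):
    idx = np.tril_indices(p)
    return idx


def _neg_loglik(params, Cn, Ymask, Yobs_vec, obs_idx, X, n, p, reml):
    """Negative (restricted) log-likelihood of the observed cells."""
    tri = np.tril_indices(p)
    L = np.zeros((p, p))
    L[tri] = params[: len(tri[0])]
    diag_i = np.arange(p)
    L[diag_i, diag_i] = np.exp(np.clip(np.diag(L), -12, 12))
    R = L @ L.T
    d = np.exp(np.clip(params[len(tri[0]):], -12, 12))
    # covariance of the observed sub-vector of vec(Y) (trait-major order)
    Sigma = np.kron(R, Cn) + np.kron(np.diag(d), np.eye(n))
    S = Sigma[np.ix_(obs_idx, obs_idx)]
    S[np.diag_indices_from(S)] += 1e-9
    try:
        cf = linalg.cho_factor(S, lower=True)
    except linalg.LinAlgError:
        return 1e12
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Xo = X[obs_idx]
    SiX = linalg.cho_solve(cf, Xo)
    XtSiX = Xo.T @ SiX
    try:
        mu = linalg.solve(XtSiX, SiX.T @ Yobs_vec, assume_a="pos")
    except linalg.LinAlgError:
        return 1e12
    r = Yobs_vec - Xo @ mu
    quad = float(r @ linalg.cho_solve(cf, r))
    nll = 0.5 * (logdet + quad + len(obs_idx) * math.log(2 * math.pi))
    if reml:
        sign, ld = np.linalg.slogdet(XtSiX)
        if sign <= 0:
            return 1e12
        nll += 0.5 * ld
    return nll if np.isfinite(nll) else 1e12


def bm_impute(
    tree: Phylogeny,
    table: LifeHistoryTable,
    traits=("AW", "ML", "FTM"),
    reml: bool = True,
    log_transform: bool = True,
    max_iter: int = 300,
) -> LifeHistoryTable:
    """Fill missing trait cells by BM conditional expectation.

    Joint model: vec(log Y) ~ MVN(X mu, R (x) C + D (x) I) with R the
    phylogenetic between-trait covariance, C the BM tree covariance
    (normalized to unit mean depth), and D diagonal trait noise, all
    estimated by REML (``reml=False`` for plain ML). Missing cells take
    E[missing | observed]; observed cells are returned untouched.
    """
    traits = [t for t in traits if t in table.frame.columns]
    species = table.species
    missing_tree = set(species) - set(tree.tip_labels)
    if missing_tree:
        raise ImputationError(f"species not in tree: {sorted(missing_tree)[:5]}")
    Y = table.frame[traits].to_numpy(dtype=float)
    n, p = Y.shape
    for j, t in enumerate(traits):
        if np.isnan(Y[:, j]).all():
            raise ImputationError(f"trait {t!r} has no observed values")
    if not np.isnan(Y).any():
        return table.copy()
    if log_transform:
        Y = np.log(Y)
    C = bm_covariance(tree, species)
    Cn = C / float(np.mean(np.diag(C)))  # unit mean depth for stable scales

    obs_mask = ~np.isnan(Y)
    yv = Y.T.reshape(-1)  # trait-major vec
    obs_idx = np.where(~np.isnan(yv))[0]
    mis_idx = np.where(np.isnan(yv))[0]
    X = np.kron(np.eye(p), np.ones((n, 1)))  # per-trait mean design
    yobs = yv[obs_idx]

    # initialize R from complete-case covariance, D from 10% of variances
    col_var = np.array([np.nanvar(Y[:, j]) + 1e-6 for j in range(p)])
    R0 = np.diag(col_var * 0.9)
    tri = np.tril_indices(p)
    L0 = np.linalg.cholesky(R0 + 1e-8 * np.eye(p))
    start = np.concatenate(
        [
            np.where(
                tri[0] == tri[1],
                np.log(np.maximum(np.diag(L0), 1e-6))[tri[0]],
                L0[tri],
            ),
            np.log(col_var * 0.1),
        ]
    )
    res = optimize.minimize(
        _neg_loglik,
        start,
        args=(Cn, obs_mask, yobs, obs_idx, X, n, p, reml),
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    params = res.x  # use the best point even on imperfect convergence

    # rebuild fitted covariance and condition
    L = np.zeros((p, p))
    L[tri] = params[: len(tri[0])]
    L[np.arange(p), np.arange(p)] = np.exp(np.clip(np.diag(L), -12, 12))
    R = L @ L.T
    d = np.exp(np.clip(params[len(tri[0]):], -12, 12))
    Sigma = np.kron(R, Cn) + np.kron(np.diag(d), np.eye(n))
    Soo = Sigma[np.ix_(obs_idx, obs_idx)]
    Soo[np.diag_indices_from(Soo)] += 1e-9
    cf = linalg.cho_factor(Soo, lower=True)
    Xo = X[obs_idx]
    SiX = linalg.cho_solve(cf, Xo)
    mu = linalg.solve(Xo.T @ SiX, SiX.T @ yobs, assume_a="pos")
    resid = yobs - Xo @ mu
    alpha = linalg.cho_solve(cf, resid)
    Smo = Sigma[np.ix_(mis_idx, obs_idx)]
    filled = X[mis_idx] @ mu + Smo @ alpha

    out = table.copy()
    yfull = Y.T.copy().reshape(-1)  # trait-major, matching obs/mis indexing
    yfull[mis_idx] = filled
    Yfull = yfull.reshape(p, n).T
    if log_transform:
        Yfull = np.exp(Yfull)
    for j, t in enumerate(traits):
        was_missing = ~obs_mask[:, j]
        col = out.frame[t].to_numpy(dtype=float)
        col[was_missing] = Yfull[was_missing, j]
        out.frame[t] = col
        out.status.loc[was_missing, t] = "imputed"
    out.frame.attrs["bm_impute"] = {
        "R": R.tolist(),
        "noise": d.tolist(),
        "mu": mu.tolist(),
        "reml": reml,
        "converged": bool(res.success),
    }
    return out


def grand_mean_impute(
    table: LifeHistoryTable, traits=("AW", "ML", "FTM"), log_transform: bool = True
) -> LifeHistoryTable:
    """Baseline: fill each trait with the mean of its observed (log) values."""
    out = table.copy()
    for t in traits:
        if t not in out.frame.columns:
            continue
        col = out.frame[t].astype(float)
        miss = col.isna()
        if not miss.any():
            continue
        if col.notna().sum() == 0:
            raise ImputationError(f"trait {t!r} has no observed values")
        fill = (
            float(np.exp(np.log(col.dropna()).mean()))
            if log_transform
            else float(col.dropna().mean())
        )
        out.frame.loc[miss, t] = fill
        out.status.loc[miss, t] = "imputed"
    return out


def pmm_impute(
    table: LifeHistoryTable,
    traits=("AW", "ML", "FTM"),
    covariates: pd.DataFrame | None = None,
    log_transform: bool = True,
    seed: int = 0,
) -> LifeHistoryTable:
    """Predictive-mean-matching baseline.

    Each incomplete trait is regressed (OLS) on the other log traits plus
    optional covariate columns over complete cases; every missing cell is
    then filled with the observed value whose prediction is nearest to its
    own. Rows lacking all predictors fall back to the trait mean.
    """
    out = table.copy()
    frame = out.frame[list(traits)].astype(float)
    logY = np.log(frame) if log_transform else frame.copy()
    for t in traits:
        miss = logY[t].isna()
        if not miss.any():
            continue
        others = [c for c in traits if c != t]
        Xcols = logY[others]
        if covariates is not None:
            Xcols = Xcols.join(covariates.reindex(logY.index))
        train = logY[t].notna() & Xcols.notna().all(axis=1)
        target = miss & Xcols.notna().all(axis=1)
        if train.sum() >= 3 and target.any():
            Xt = np.column_stack([np.ones(train.sum()), Xcols[train].to_numpy()])
            beta, *_ = np.linalg.lstsq(Xt, logY.loc[train, t].to_numpy(), rcond=None)
            pred_obs = Xt @ beta
            Xm = np.column_stack([np.ones(target.sum()), Xcols[target].to_numpy()])
            pred_mis = Xm @ beta
            donors = logY.loc[train, t].to_numpy()
            nearest = np.abs(pred_mis[:, None] - pred_obs[None, :]).argmin(axis=1)
            logY.loc[target, t] = donors[nearest]
        still = logY[t].isna()
        if still.any():
            logY.loc[still, t] = logY.loc[~miss, t].mean()
    filled = np.exp(logY) if log_transform else logY
    for t in traits:
        miss = out.frame[t].isna()
        out.frame.loc[miss, t] = filled.loc[miss, t]
        out.status.loc[miss, t] = "imputed"
    return out


# ---------------------------------------------------------------------------
# evaluation metrics


def nrmse(
    imputed: LifeHistoryTable,
    truth: LifeHistoryTable,
    trait: str,
    missing_mask: pd.Series | None = None,
    log_transform: bool = True,
) -> float:
    """RMSE over originally-missing cells / range of the true trait values."""
    t_true = truth.frame[trait].astype(float)
    t_imp = imputed.frame[trait].reindex(t_true.index).astype(float)
    if log_transform:
        t_true, t_imp = np.log(t_true), np.log(t_imp)
    if missing_mask is None:
        missing_mask = imputed.status[trait].reindex(t_true.index) == "imputed"
    if missing_mask.sum() == 0:
        return 0.0
    rng_true = t_true.max() - t_true.min()
    if rng_true == 0:
        raise ImputationError("zero range in true trait values")
    err = t_imp[missing_mask] - t_true[missing_mask]
    return float(np.sqrt(np.mean(err**2)) / rng_true)


def slope_bias(
    truth: LifeHistoryTable,
    imputed: LifeHistoryTable,
    y_trait: str = "ML",
    x_trait: str = "AW",
) -> float:
    """|allometric slope on complete data - slope on imputed data|."""
    def fit(tab: LifeHistoryTable) -> float:
        ok = tab.frame[[x_trait, y_trait]].notna().all(axis=1)
        if ok.sum() < 3:
            raise ImputationError("degenerate regression: fewer than 3 cases")
        x = np.log(tab.frame.loc[ok, x_trait].to_numpy(dtype=float))
        y = np.log(tab.frame.loc[ok, y_trait].to_numpy(dtype=float))
        return _ols_line(x, y)[1]

    return float(abs(fit(truth) - fit(imputed)))


# ---------------------------------------------------------------------------
# harness

PAPER_PROPORTIONS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40, 0.50)


def evaluate_imputation(
    train_table: LifeHistoryTable,
    tree: Phylogeny,
    proportions=PAPER_PROPORTIONS,
    mechanisms=("MCAR", "MAR_AW", "MAR_HD"),
    methods=("bm", "grand_mean", "pmm"),
    reps: int = 10,
    seed: int = 0,
    traits=("ML", "FTM"),
    pcoa_grid=(0,),
) -> pd.DataFrame:
    """Missingness-grid benchmark of the imputation methods.

    For each mechanism x proportion x method x replicate: blank cells,
    impute, and score NRMSE per trait plus the allometric slope bias.
    ``pcoa_grid`` controls how many leading PCoA eigenvectors the PMM
    baseline may use; the best count by NRMSE is kept and reported.
    """
    from .simulate import inject_missingness
    from .trees import patristic_distances

    if train_table.frame[list(traits) + ["AW"]].isna().any().any():
        raise ImputationError("training table must be complete")
    D = patristic_distances(tree, train_table.species)
    Dfr = pd.DataFrame(D, index=train_table.species, columns=train_table.species)
    pcoa_all = pcoa_eigenvectors(Dfr) if max(pcoa_grid, default=0) > 0 else None
    rows = []
    rep_seed = seed
    for mechanism in mechanisms:
        for prop in proportions:
            for rep in range(reps):
                rep_seed += 1
                holed = inject_missingness(
                    train_table, mechanism, prop, seed=rep_seed, traits=traits,
                    tree=tree,
                )
                blanked = {
                    t: (holed.frame[t].isna() & train_table.frame[t].notna())
                    for t in traits
                }
                for method in methods:
                    if method == "bm":
                        imp = bm_impute(tree, holed)
                        best_k = None
                    elif method == "grand_mean":
                        imp = grand_mean_impute(holed)
                        best_k = None
                    elif method == "pmm":
                        imp, best_k = None, 0
                        best_score = np.inf
                        for kvec in pcoa_grid:
                            cov = (
                                pcoa_all.iloc[:, :kvec] if kvec and pcoa_all is not None
                                else None
                            )
                            cand = pmm_impute(holed, covariates=cov, seed=rep_seed)
                            score = float(
                                np.mean(
                                    [
                                        nrmse(cand, train_table, t, blanked[t])
                                        for t in traits
                                    ]
                                )
                            )
                            if score < best_score:
                                best_score, imp, best_k = score, cand, kvec
                    else:
                        raise ImputationError(f"unknown method {method!r}")
                    sbias = slope_bias(train_table, imp)
                    for t in traits:
                        rows.append(
                            {
                                "mechanism": mechanism,
                                "proportion": prop,
                                "method": method,
                                "replicate": rep,
                                "trait": t,
                                "nrmse": nrmse(imp, train_table, t, blanked[t]),
                                "slope_bias": sbias,
                                "n_pcoa_vectors": best_k,
                            }
                        )
    return pd.DataFrame(rows)
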