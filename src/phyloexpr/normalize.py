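"""Count filtering, TMM-RPKM log normalization, Tau specificity, and PCA.

Filters run in the documented order: low-expression, dominant-gene,
minimum-species. Normalized values are ``log2(count * 1e9 /
(effective_library * length) + 1)`` with the effective library equal to
the raw library size times its trimmed-mean-of-M-values (TMM) factor.
Masked (absent-ortholog) cells are excluded from library sizes, filters,
and specificity denominators alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import COUNTS, LOG2_TMM_RPKM, ExpressionMatrix, SampleTable

__all__ = [
    "filter_low_expression",
    "filter_dominant_gene",
    "filter_min_species",
    "tmm_factors",
    "log2_tmm_rpkm",
    "species_mean",
    "tau_index",
    "tau_table",
    "TauResult",
    "pca_top_variance",
]


class NormalizationError(ValueError):
    pass


def _require_counts(matrix: ExpressionMatrix) -> None:
    if matrix.scale_tag != COUNTS:
        raise NormalizationError(
            f"expected a counts matrix, got scale {matrix.scale_tag!r}"
        )


# ---------------------------------------------------------------------------
# filters


def filter_low_expression(
    matrix: ExpressionMatrix, min_value: float = 10.0, min_samples: int = 4
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose count is below ``min_value`` in >= ``min_samples`` samples.

    Masked cells count as neither pass nor fail: a gene is judged only over
    the samples where it is observed. Returns (filtered matrix, removed genes).
    """
    _require_counts(matrix)
    if matrix.values.empty:
        raise NormalizationError("empty expression matrix")
    low = (matrix.values < min_value) & matrix.values.notna()
    removed = matrix.values.index[low.sum(axis=1) >= min_samples].tolist()
    keep = [g for g in matrix.gene_ids if g not in set(removed)]
    return matrix.subset_genes(keep), removed


def filter_dominant_gene(
    matrix: ExpressionMatrix, share: float = 0.05
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes holding >= ``share`` of the grand count total."""
    _require_counts(matrix)
    totals = matrix.values.sum(axis=1, skipna=True)
    grand = totals.sum()
    if grand <= 0:
        raise NormalizationError("grand count total is zero")
    removed = totals.index[totals >= share * grand].tolist()
    keep = [g for g in matrix.gene_ids if g not in set(removed)]
    return matrix.subset_genes(keep), removed


def filter_min_species(
    matrix: ExpressionMatrix, min_species: int = 68
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose ortholog is present in fewer than ``min_species`` species."""
    if matrix.presence is None:
        raise NormalizationError("presence mask not populated")
    counts = matrix.species_presence_counts()
    removed = counts.index[counts < min_species].tolist()
    keep = [g for g in matrix.gene_ids if g not in set(removed)]
    return matrix.subset_genes(keep), removed


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> float:
    """Weighted trimmed mean of M values of one sample against the reference."""
    ok = ~(np.isnan(obs) | np.isnan(ref))
    obs, ref = obs[ok], ref[ok]
    n_obs, n_ref = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / n_obs) / (ref / n_ref))
        a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
        w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, w = m[finite], a[finite], w[finite]
    if len(m) == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # identical up to depth: no trimming needed
        return 1.0
    n = len(m)
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rm = sps.rankdata(m)
    ra = sps.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f) if np.isfinite(f) else 1.0


def tmm_factors(
    matrix: ExpressionMatrix,
    reference: str = "auto",
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors, normalized to product 1.

    The reference sample is the one whose upper-quartile of depth-scaled
    counts is closest to the mean upper-quartile (or a named sample).
    """
    _require_counts(matrix)
    vals = matrix.values
    if vals.shape[1] < 2:
        raise NormalizationError("TMM needs at least two samples")
    lib = vals.sum(axis=0, skipna=True)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise NormalizationError(f"samples with all-zero counts: {bad}")
    if reference == "auto":
        uq = vals.div(lib, axis=1).quantile(0.75)
        ref_id = (uq - uq.mean()).abs().idxmin()
    else:
        if reference not in vals.columns:
            raise NormalizationError(f"unknown reference sample {reference!r}")
        ref_id = reference
    ref = vals[ref_id].to_numpy(dtype=float)
    factors = pd.Series(
        {
            s: _tmm_pair(
                vals[s].to_numpy(dtype=float), ref, log_ratio_trim, abs_expr_trim
            )
            for s in vals.columns
        }
    )
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1 -> product 1
    return factors


def log2_tmm_rpkm(
    matrix: ExpressionMatrix, gene_lengths: pd.Series, factors: pd.Series
) -> ExpressionMatrix:
    """log2(TMM-scaled RPKM + 1); lengths in bp, human-reference per gene."""
    _require_counts(matrix)
    missing = [g for g in matrix.gene_ids if g not in gene_lengths.index]
    if missing:
        raise NormalizationError(f"missing gene lengths: {missing[:5]}")
    lengths = gene_lengths.loc[matrix.gene_ids].astype(float)
    if (lengths <= 0).any():
        raise NormalizationError("gene lengths must be positive")
    lib = matrix.values.sum(axis=0, skipna=True)
    eff_lib = lib * factors.loc[matrix.sample_ids]
    rpkm = matrix.values.mul(1e9).div(eff_lib, axis=1).div(lengths, axis=0)
    logged = np.log2(rpkm + 1.0)
    return ExpressionMatrix(
        logged, matrix.presence, LOG2_TMM_RPKM, matrix.samples
    )


# ---------------------------------------------------------------------------
# aggregation and specificity


def species_mean(
    matrix: ExpressionMatrix, samples: SampleTable, tissue: str
) -> pd.DataFrame:
    """Mean log expression over replicates per species for one tissue.

    Returns a species x gene frame; a species is NaN for a gene when every
    replicate is masked.
    """
    if matrix.scale_tag != LOG2_TMM_RPKM:
        raise NormalizationError("species_mean expects log-normalized values")
    sub = samples.samples_for(tissue)
    cols = [s for s in matrix.sample_ids if s in sub.index]
    vals = matrix.values[cols]
    species = sub.loc[cols, "species"]
    return vals.T.groupby(species.values).mean().rename_axis("species")


@dataclass
class TauResult:
    gene: str
    tau: float
    n_species: int
    tau_class: str  # broad / intermediate / specific


def tau_index(
    per_species_values,
    gene: str = "",
    broad: float = 0.2,
    specific: float = 0.8,
) -> TauResult:
    """Specificity index tau = sum_i (1 - v_i / max v) / (N - 1).

    Masked species are excluded from N. tau is 0 for uniform expression and
    1 when a single species carries all expression. All-zero vectors have
    no defined tau and raise.
    """
    v = pd.Series(per_species_values).dropna().astype(float)
    if (v < 0).any():
        raise NormalizationError("tau requires non-negative values")
    n = len(v)
    if n < 2:
        raise NormalizationError("tau needs at least two observed species")
    vmax = v.max()
    if vmax == 0:
        raise NormalizationError("tau undefined for an all-zero vector")
    tau = float((1.0 - v / vmax).sum() / (n - 1))
    if tau < broad:
        cls = "broad"
    elif tau > specific:
        cls = "specific"
    else:
        cls = "intermediate"
    return TauResult(gene=gene, tau=tau, n_species=n, tau_class=cls)


def tau_table(
    per_species: pd.DataFrame, broad: float = 0.2, specific: float = 0.8
) -> pd.DataFrame:
    """tau per gene from a species x gene frame; undefined taus are flagged."""
    rows = []
    for gene in per_species.columns:
        try:
            r = tau_index(per_species[gene], gene, broad, specific)
            rows.append(
                {"gene": r.gene, "tau": r.tau, "n_species": r.n_species,
                 "tau_class": r.tau_class}
            )
        except NormalizationError as exc:
            rows.append(
                {"gene": gene, "tau": np.nan, "n_species": 0,
                 "tau_class": f"undefined ({exc})"}
            )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# PCA


def pca_top_variance(
    matrix: ExpressionMatrix | pd.DataFrame, n_top: int = 5000
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the ``n_top`` highest-variance genes.

    Masked cells are mean-completed per gene for the decomposition only.
    Returns (sample scores, explained-variance fractions, non-increasing).
    """
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if vals.shape[1] < 2:
        raise NormalizationError("PCA needs at least two samples")
    variances = vals.var(axis=1, ddof=1, skipna=True).fillna(0.0)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top]
    X = vals.loc[top]
    X = X.T.fillna(X.mean(axis=1)).T  # per-gene mean completion, masked cells only
    centered = X.sub(X.mean(axis=1), axis=0).to_numpy(dtype=float)
    # samples are the observations: decompose the gene x sample matrix
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    n_pc = min(len(s), vals.shape[1])
    scores = pd.DataFrame(
        (Vt[:n_pc].T * s[:n_pc]),
        index=vals.columns,
        columns=[f"PC{i + 1}" for i in range(n_pc)],
    )
    return scores, evr[:n_pc]


def pc1_batch_diagnostic(scores: pd.DataFrame, samples: SampleTable) -> dict:
    """Kruskal-Wallis of PC1 by batch label, emitted as a QA number only."""
    batches = samples.frame.loc[scores.index, "batch"]
    groups = [g["PC1"].to_numpy() for _, g in scores.groupby(batches)]
    if len(groups) < 2:
        return {"statistic": float("nan"), "pvalue": float("nan"), "n_batches": len(groups)}
    stat, p = sps.kruskal(*groups)
    return {"statistic": float(stat), "pvalue": float(p), "n_batches": len(groups)}
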