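"""Polygenic sum-statistic gene-set enrichment and Fisher category tests.

A gene set's score (SUMSTAT) is the plain sum of its members' gene
scores. Directional scoring zeroes the sign not under test, so one-sided
(greater) P values are the default. Score-vs-covariate confounding
(gene length, species count) is removed by within-quantile-bin
standardization before summing. Set P values come from a normal
approximation when the scores pass a KS normality check, otherwise from
an empirical null of random same-size sets drawn without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "directional_scores",
    "rescale_bins",
    "set_sumstat",
    "empirical_set_pvalue",
    "EnrichmentResult",
    "enrich_gene_sets",
    "fisher_category_enrichment",
    "build_categories",
]


class EnrichmentError(ValueError):
    pass


def directional_scores(coefficients: pd.Series, direction: str) -> pd.Series:
    """Directional SUMSTAT contributions from signed coefficients.

    ``positive``: negatives -> 0. ``negative``: positives -> 0, then
    absolute value. Scores are untouched otherwise.
    """
    c = coefficients.astype(float)
    if direction == "positive":
        return c.clip(lower=0.0)
    if direction == "negative":
        return (-c).clip(lower=0.0)
    raise EnrichmentError(f"unknown direction {direction!r}")


def rescale_bins(
    scores: pd.Series, covariate: pd.Series, n_bins: int = 10
) -> tuple[pd.Series, pd.Series]:
    """Standardize scores to mean 0 / unit variance within covariate bins.

    Genes are binned by covariate quantiles; bins that end up with fewer
    than 2 genes are merged into their lower neighbor. Returns
    (rescaled scores, bin assignment).
    """
    if n_bins < 1:
        raise EnrichmentError("n_bins must be >= 1")
    cov = covariate.reindex(scores.index)
    if cov.isna().any():
        missing = cov.index[cov.isna()][:5].tolist()
        raise EnrichmentError(f"covariate missing for genes {missing}")
    if n_bins == 1:
        bins = pd.Series(0, index=scores.index)
    else:
        bins = pd.qcut(cov.rank(method="first"), q=n_bins, labels=False)
        bins = pd.Series(bins, index=scores.index)
        # merge undersized bins downward
        counts = bins.value_counts()
        for b in sorted(counts.index):
            if counts[b] < 2:
                target = b - 1 if b > 0 else b + 1
                bins[bins == b] = target
                counts = bins.value_counts()
    out = scores.astype(float).copy()
    for b, idx in out.groupby(bins).groups.items():
        vals = out.loc[idx]
        sd = vals.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            out.loc[idx] = 0.0
        else:
            out.loc[idx] = (vals - vals.mean()) / sd
    return out, bins


def set_sumstat(set_members, scores: pd.Series) -> float:
    """Sum of member scores; members without a score are dropped (warned)."""
    members = [g for g in set_members if g in scores.index]
    if not members:
        raise EnrichmentError("gene set has no overlap with scored genes")
    dropped = len(list(set_members)) - len(members)
    if dropped:
        import warnings

        warnings.warn(f"{dropped} set members lack scores and were dropped")
    return float(scores.loc[members].sum())


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    sumstat: float
    pvalue: float
    null_method: str  # normal / empirical
    n_draws: int


def _normal_sum_pvalue(observed: float, scores: np.ndarray, m: int) -> float:
    """One-sided P of a size-m sum under without-replacement sampling."""
    N = len(scores)
    mu, var = scores.mean(), scores.var(ddof=0)
    mean_s = m * mu
    var_s = m * var * (N - m) / max(N - 1, 1)
    if var_s <= 0:
        return 1.0
    z = (observed - mean_s) / np.sqrt(var_s)
    return float(sps.norm.sf(z))


def _empirical_sum_pvalue(
    observed: float, scores: np.ndarray, m: int, n_draws: int, rng
) -> float:
    """P from random same-size sets drawn uniformly without replacement."""
    N = len(scores)
    count = 0
    chunk = max(1, min(n_draws, int(2e7 / max(N, 1))))
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        sums = scores[idx].sum(axis=1)
        count += int((sums >= observed - 1e-12).sum())
        done += b
    return (count + 1.0) / (n_draws + 1.0)


def empirical_set_pvalue(
    set_members,
    scores: pd.Series,
    n_draws: int = 400_000,
    seed: int = 0,
    mode: str = "auto",
    normality_alpha: float = 0.05,
) -> EnrichmentResult:
    """One-sided enrichment P for one gene set.

    ``auto`` runs a KS normality check on the scores and uses the normal
    finite-population approximation when compatible, otherwise the
    empirical null (never returning P below 1/(n_draws+1)).
    """
    vals = scores.astype(float)
    requested = list(dict.fromkeys(set_members))
    if len(requested) > len(vals):
        raise EnrichmentError("set size exceeds score universe")
    members = [g for g in requested if g in vals.index]
    if not members:
        raise EnrichmentError("gene set has no overlap with scored genes")
    m = len(members)
    observed = float(vals.loc[members].sum())
    arr = vals.to_numpy()
    if mode == "auto":
        sd = arr.std(ddof=0)
        if sd == 0:
            use = "empirical"
        else:
            _, ks_p = sps.kstest(arr, "norm", args=(arr.mean(), sd))
            use = "normal" if ks_p > normality_alpha else "empirical"
    elif mode in ("normal", "empirical"):
        use = mode
    else:
        raise EnrichmentError(f"unknown mode {mode!r}")
    if use == "normal":
        p = _normal_sum_pvalue(observed, arr, m)
        return EnrichmentResult(
            getattr(set_members, "name", ""), m, observed, p, "normal", 0
        )
    rng = np.random.default_rng(seed)
    # sorted universe: the sampled P depends only on the multiset of scores,
    # so permuting gene order changes nothing (exchangeability)
    p = _empirical_sum_pvalue(observed, np.sort(arr), m, n_draws, rng)
    return EnrichmentResult(
        getattr(set_members, "name", ""), m, observed, p, "empirical", n_draws
    )


def enrich_gene_sets(
    gene_sets: dict,
    scores: pd.Series,
    n_draws: int = 400_000,
    seed: int = 0,
    mode: str = "auto",
) -> pd.DataFrame:
    """Run :func:`empirical_set_pvalue` over a GMT-style set collection.

    Adds a BH-adjusted convenience column; raw P values are the primary
    output.
    """
    rows = []
    for name, members in gene_sets.items():
        try:
            r = empirical_set_pvalue(members, scores, n_draws, seed, mode)
        except EnrichmentError as exc:
            rows.append(
                {"set_name": name, "set_size": 0, "sumstat": np.nan,
                 "pvalue": np.nan, "null_method": f"skipped ({exc})", "n_draws": 0}
            )
            continue
        rows.append(
            {"set_name": name, "set_size": r.set_size, "sumstat": r.sumstat,
             "pvalue": r.pvalue, "null_method": r.null_method,
             "n_draws": r.n_draws}
        )
    out = pd.DataFrame(rows).set_index("set_name")
    ok = out["pvalue"].notna()
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        adj = np.full(len(out), np.nan)
        adj[ok.to_numpy()] = multipletests(out.loc[ok, "pvalue"], method="fdr_bh")[1]
        out["pvalue_bh"] = adj
    return out


# ---------------------------------------------------------------------------
# Fisher category enrichment


def fisher_category_enrichment(
    hits, category, universe, alternative: str = "greater"
) -> dict:
    """Fisher's exact test of hit genes against a boolean category.

    Builds the 2x2 (hit / non-hit) x (in / out of category) table over the
    universe. Returns the sample odds ratio (NaN-flagged when a margin is
    empty) and the exact hypergeometric P.
    """
    universe = set(universe)
    if not universe:
        raise EnrichmentError("empty universe")
    hits = set(hits) & universe
    category = set(category) & universe
    a = len(hits & category)
    b = len(hits - category)
    c = len(category - hits)
    d = len(universe - hits - category)
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    or_defined = b > 0 and c > 0
    if b == 0 or c == 0:
        # degenerate margin (e.g. category == universe): OR undefined
        odds = float("nan") if (a == 0 or d == 0) else float("inf")
    return {
        "odds_ratio": float(odds) if odds == odds else float("nan"),
        "pvalue": float(p),
        "table": (a, b, c, d),
        "or_defined": bool(or_defined),
    }


def build_categories(annotations: pd.DataFrame) -> dict[str, set]:
    """Named boolean gene categories from per-gene annotation columns.

    essential: pLI > 0.9 (strict). haplo_insufficient / haplo_sufficient:
    top / bottom quartile of the HI score. young / old from ``age_class``;
    disease / cancer from boolean flags. Only categories whose source
    columns exist are emitted; an all-absent annotation raises.
    """
    cats: dict[str, set] = {}
    if "pLI" in annotations.columns:
        s = annotations["pLI"].astype(float)
        cats["essential"] = set(s.index[s > 0.9])
    if "HI" in annotations.columns:
        s = annotations["HI"].astype(float).dropna()
        q1, q3 = s.quantile(0.25), s.quantile(0.75)
        cats["haplo_insufficient"] = set(s.index[s > q3])
        cats["haplo_sufficient"] = set(s.index[s < q1])
    if "age_class" in annotations.columns:
        s = annotations["age_class"].astype(str)
        cats["young"] = set(s.index[s == "young"])
        cats["old"] = set(s.index[s == "old"])
    for flag in ("disease", "cancer"):
        if flag in annotations.columns:
            cats[flag] = set(annotations.index[annotations[flag].astype(bool)])
    if not cats:
        raise EnrichmentError("no recognized annotation columns (pLI, HI, age_class, disease, cancer)")
    return cats


def category_enrichment_table(
    up, down, universe, categories: dict[str, set], alternative: str = "greater"
) -> pd.DataFrame:
    """Fisher enrichment of Up, Down, and Both gene lists per category."""
    lists = {"Up": set(up), "Down": set(down), "Both": set(up) | set(down)}
    rows = []
    for cat_name, cat in categories.items():
        for list_name, genes in lists.items():
            r = fisher_category_enrichment(genes, cat, universe, alternative)
            rows.append(
                {"category": cat_name, "gene_list": list_name,
                 "odds_ratio": r["odds_ratio"], "pvalue": r["pvalue"],
                 "a": r["table"][0], "b": r["table"][1],
                 "c": r["table"][2], "d": r["table"][3]}
            )
    return pd.DataFrame(rows)
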