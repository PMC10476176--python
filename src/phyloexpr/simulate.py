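"""Synthetic data with the statistical structure the pipeline assumes.

Everything here is a pure function of (parameters, seed): trees, allometric
life-history traits with Brownian residuals, expression matrices in which a
configurable fraction of genes tracks a trait under iid/BM/OU residuals,
negative-binomial counts with library-size and gene-length effects,
selection-intensity (k) tables, and the three missingness mechanisms used
by the imputation benchmark (MCAR, weight-dependent, distance-dependent).

Ground truth is serialized alongside every output so downstream calling
steps can be scored without re-reading generator parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, LifeHistoryTable, SampleTable, COUNTS, LOG2_TMM_RPKM
from .pgls import ou_covariance
from .trees import Phylogeny, bm_covariance, patristic_distances

__all__ = [
    "SimulationTruth",
    "simulate_tree",
    "simulate_life_history",
    "inject_missingness",
    "simulate_expression",
    "simulate_counts",
    "simulate_selection_table",
]

# empirically observed split of missing life-history values between
# small- and large-bodied species (small-weight share first)
DEFAULT_SPLIT_WEIGHTS = {"ML": (0.8243, 0.1757), "FTM": (0.6234, 0.3766)}


@dataclass
class SimulationTruth:
    """Ground truth for one simulation: per-gene and per-species tables."""

    genes: pd.DataFrame | None = None
    species: pd.DataFrame | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    def write(self, prefix) -> None:
        if self.genes is not None:
            self.genes.to_csv(f"{prefix}.genes.tsv", sep="\t", na_rep="NA")
        if self.species is not None:
            self.species.to_csv(f"{prefix}.species.tsv", sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# trees


class _Node:
    __slots__ = ("name", "children", "length")

    def __init__(self, name=None):
        self.name = name
        self.children = []
        self.length = 0.0

    def newick(self):
        if not self.children:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10g}"


def simulate_tree(
    n_tips: int,
    model: str = "birth_death",
    seed: int = 0,
    depth: float = 150.0,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
) -> Phylogeny:
    """Random ultrametric tree rescaled to the requested root-to-tip depth.

    ``birth_death`` runs a forward birth–death process until ``n_tips``
    extant lineages exist (restarting on extinction); ``coalescent`` merges
    random lineage pairs at exponential waiting times.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    if model == "coalescent":
        nodes = [(_Node(f"sp{i + 1}"), 0.0) for i in range(n_tips)]
        t = 0.0
        while len(nodes) > 1:
            k = len(nodes)
            t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
            i, j = rng.choice(k, size=2, replace=False)
            (a, ta), (b, tb) = nodes[i], nodes[j]
            parent = _Node()
            a.length, b.length = t - ta, t - tb
            parent.children = [a, b]
            nodes = [nodes[m] for m in range(k) if m not in (i, j)] + [(parent, t)]
        root, t_root = nodes[0]
        total = t_root
    elif model == "birth_death":
        if death_rate >= birth_rate:
            raise ValueError("death_rate must be below birth_rate")
        while True:  # restart on full extinction
            root = _Node()
            a, b = _Node(), _Node()
            root.children = [a, b]
            active = {id(a): (a, 0.0), id(b): (b, 0.0)}
            t = 0.0
            extinct = False
            while len(active) < n_tips:
                k = len(active)
                t += rng.exponential(1.0 / (k * (birth_rate + death_rate)))
                keys = list(active)
                key = keys[rng.integers(k)]
                node, born = active.pop(key)
                if rng.random() < death_rate / (birth_rate + death_rate):
                    node.name = "extinct"
                    node.length = t - born
                    if not active:
                        extinct = True
                        break
                    continue
                node.length = t - born
                c1, c2 = _Node(), _Node()
                node.children = [c1, c2]
                active[id(c1)] = (c1, t)
                active[id(c2)] = (c2, t)
            if not extinct:
                break
        # extend extant lineages to the present
        t += rng.exponential(1.0 / (n_tips * birth_rate))
        for i, (node, born) in enumerate(active.values()):
            node.name = f"sp{i + 1}"
            node.length = t - born
        _prune_extinct(root)
        total = t
    else:
        raise ValueError(f"unknown tree model {model!r}")
    scale = depth / total
    _scale_lengths(root, scale)
    phy = Phylogeny.from_newick(root.newick() + ";")
    assert phy.n_tips == n_tips
    return phy


def _scale_lengths(node: _Node, s: float) -> None:
    node.length *= s
    for c in node.children:
        _scale_lengths(c, s)


def _prune_extinct(node: _Node) -> bool:
    """Drop extinct subtrees and splice out unifurcations; True if node survives."""
    if not node.children:
        return node.name != "extinct"
    node.children = [c for c in node.children if _prune_extinct(c)]
    if not node.children:
        return False
    if len(node.children) == 1:
        child = node.children[0]
        node.name = child.name
        node.length += child.length
        node.children = child.children
    return True


# ---------------------------------------------------------------------------
# life history


def _bm_draw(rng, C: np.ndarray, tip_sd: float) -> np.ndarray:
    """MVN draw with BM correlation and the given tip-level SD."""
    if tip_sd == 0:
        return np.zeros(len(C))
    scale = tip_sd**2 / float(np.mean(np.diag(C)))
    L = np.linalg.cholesky(scale * C + 1e-12 * np.eye(len(C)))
    return L @ rng.standard_normal(len(C))


def simulate_life_history(
    tree: Phylogeny,
    allometric_slope: float = 0.2,
    allometric_intercept: float = 1.0,
    bm_sigma: float = 0.3,
    seed: int = 0,
    aw_log_mean: float = 7.0,
    aw_sigma: float = 2.0,
    ftm_slope: float = 0.25,
    ftm_intercept: float = -1.5,
    ftm_sigma: float = 0.3,
) -> tuple[LifeHistoryTable, SimulationTruth]:
    """Log-allometric traits with BM-distributed residuals on the tree.

    log AW evolves by BM; log ML = intercept + slope * log AW + BM residual
    with tip-level SD ``bm_sigma``; FTM analogous. ``bm_sigma=0`` puts ML
    exactly on the allometric line. All values back-transform positive.
    """
    for v in (allometric_slope, allometric_intercept, bm_sigma, ftm_sigma, aw_sigma):
        if not math.isfinite(v):
            raise ValueError("non-finite simulation parameter")
    if bm_sigma < 0 or ftm_sigma < 0 or aw_sigma <= 0:
        raise ValueError("variance parameters must be positive")
    rng = np.random.default_rng(seed)
    taxa = tree.tip_labels
    C = bm_covariance(tree, taxa)
    log_aw = aw_log_mean + _bm_draw(rng, C, aw_sigma)
    log_ml = allometric_intercept + allometric_slope * log_aw + _bm_draw(rng, C, bm_sigma)
    log_ftm = ftm_intercept + ftm_slope * log_aw + _bm_draw(rng, C, ftm_sigma)
    frame = pd.DataFrame(
        {"AW": np.exp(log_aw), "ML": np.exp(log_ml), "FTM": np.exp(log_ftm)},
        index=pd.Index(taxa, name="species"),
    )
    table = LifeHistoryTable(frame)
    truth = SimulationTruth(
        species=frame.copy(),
        seed=seed,
        params={
            "allometric_slope": allometric_slope,
            "allometric_intercept": allometric_intercept,
            "bm_sigma": bm_sigma,
            "ftm_slope": ftm_slope,
            "ftm_intercept": ftm_intercept,
            "ftm_sigma": ftm_sigma,
        },
    )
    return table, truth


def inject_missingness(
    table: LifeHistoryTable,
    mechanism: str = "MCAR",
    proportion: float = 0.2,
    split_weights: dict | None = None,
    seed: int = 0,
    traits=("ML", "FTM"),
    tree: Phylogeny | None = None,
    reference_species: str | None = None,
) -> LifeHistoryTable:
    """Blank trait cells under MCAR, MAR_AW (weight) or MAR_HD (distance).

    Under MCAR each target cell goes missing independently with probability
    ``proportion``. Under the MAR mechanisms the same expected number of
    missing cells divides between two species groups per ``split_weights``
    (per-trait (group1, group2) shares; group1 is the small-weight group
    for MAR_AW and the far-from-reference group for MAR_HD).
    """
    if not 0 <= proportion <= 0.9:
        raise ValueError("proportion must lie in [0, 0.9]")
    out = table.copy()
    if proportion == 0:
        return out
    rng = np.random.default_rng(seed)
    species = out.species
    n = len(species)
    if mechanism == "MCAR":
        for t in traits:
            mask = rng.random(n) < proportion
            out.frame.loc[mask, t] = np.nan
            out.status.loc[mask, t] = "missing"
        return out
    if mechanism == "MAR_AW":
        aw = table.frame["AW"]
        if aw.isna().any():
            raise ValueError("MAR_AW needs complete AW")
        group1 = aw <= aw.median()  # small-weight species
    elif mechanism == "MAR_HD":
        if tree is None:
            raise ValueError("MAR_HD needs a tree")
        if reference_species is None:
            human_like = [s for s in species if "human" in s.lower() or s == "Homo_sapiens"]
            reference_species = human_like[0] if human_like else sorted(species)[0]
        D = patristic_distances(tree, species)
        dref = pd.Series(D[species.index(reference_species)], index=species)
        group1 = dref > dref.max() / 2.0  # far-from-reference species
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    weights = dict(DEFAULT_SPLIT_WEIGHTS)
    if split_weights:
        weights.update(split_weights)
    idx1 = np.where(group1.to_numpy())[0]
    idx2 = np.where(~group1.to_numpy())[0]
    for t in traits:
        w1, w2 = weights.get(t, (0.5, 0.5))
        total = int(round(proportion * n))
        n1 = min(int(round(total * w1 / (w1 + w2))), len(idx1))
        n2 = min(total - n1, len(idx2))
        chosen = np.concatenate(
            [
                rng.choice(idx1, size=n1, replace=False),
                rng.choice(idx2, size=n2, replace=False),
            ]
        )
        out.frame.iloc[chosen, out.frame.columns.get_loc(t)] = np.nan
        out.status.iloc[chosen, out.status.columns.get_loc(t)] = "missing"
    return out


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    tree: Phylogeny,
    trait_vector: pd.Series,
    n_genes: int = 200,
    frac_associated: float = 0.1,
    slope_range: tuple[float, float] = (0.4, 0.8),
    residual_model: str = "bm",
    presence_rate: float = 1.0,
    seed: int = 0,
    residual_sd: float = 0.5,
    ou_alpha: float | None = None,
    baseline_mean: float = 5.0,
    n_replicates: int = 1,
    replicate_sd: float = 0.0,
    presence_floor: int = 6,
    sign_mix: float = 0.0,
    tissue: str = "liver",
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Per-gene expression tracking (or not) a species trait.

    Associated genes get expression ``a + b*trait + residual`` with the
    residual drawn iid, BM, or OU(alpha) on the tree; the rest are residual
    only. A fraction ``sign_mix`` of associated genes take negative slopes.
    Per-gene species presence is thinned to ``presence_rate`` but never
    below ``presence_floor`` species. Replicates add iid noise of SD
    ``replicate_sd``.
    """
    if not 0 <= frac_associated <= 1:
        raise ValueError("frac_associated must lie in [0, 1]")
    taxa = tree.tip_labels
    trait = trait_vector.reindex(taxa)
    if trait.isna().any():
        raise ValueError("trait vector must cover every tip")
    rng = np.random.default_rng(seed)
    n_sp = len(taxa)
    C = bm_covariance(tree, taxa)
    if residual_model == "iid":
        cov_chol = None
    elif residual_model == "bm":
        scale = residual_sd**2 / float(np.mean(np.diag(C)))
        cov_chol = np.linalg.cholesky(scale * C + 1e-12 * np.eye(n_sp))
    elif residual_model == "ou":
        if ou_alpha is None:
            ou_alpha = 5.0 / tree.depth()
        V = ou_covariance(C, ou_alpha)
        scale = residual_sd**2 / float(np.mean(np.diag(V)))
        cov_chol = np.linalg.cholesky(scale * V + 1e-12 * np.eye(n_sp))
    else:
        raise ValueError(f"unknown residual model {residual_model!r}")

    n_assoc = int(round(frac_associated * n_genes))
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    x = trait.to_numpy(dtype=float)
    values = np.empty((n_genes, n_sp))
    truth_rows = []
    for gi, gene in enumerate(genes):
        associated = gi < n_assoc
        if associated:
            b = rng.uniform(*slope_range)
            if rng.random() < sign_mix:
                b = -b
        else:
            b = 0.0
        a = baseline_mean + rng.normal(0, 1)
        if cov_chol is None:
            resid = residual_sd * rng.standard_normal(n_sp)
        else:
            resid = cov_chol @ rng.standard_normal(n_sp)
        values[gi] = a + b * x + resid
        truth_rows.append(
            {
                "gene": gene,
                "associated": associated,
                "target_trait": trait_vector.name or "trait",
                "true_slope": b,
                "residual_model": residual_model,
                "ou_alpha": ou_alpha if residual_model == "ou" else np.nan,
                "residual_sd": residual_sd,
            }
        )

    # per-gene presence thinning with a floor so the min-species filter bites
    presence = rng.random((n_genes, n_sp)) < presence_rate
    for gi in range(n_genes):
        short = presence_floor - presence[gi].sum()
        if short > 0:
            absent = np.where(~presence[gi])[0]
            revive = rng.choice(absent, size=short, replace=False)
            presence[gi, revive] = True

    sample_ids, sample_species = [], []
    for sp in taxa:
        for r in range(n_replicates):
            sample_ids.append(f"{sp}__{tissue}__r{r + 1}")
            sample_species.append(sp)
    cols = np.repeat(np.arange(n_sp), n_replicates)
    mat = values[:, cols] + replicate_sd * rng.standard_normal(
        (n_genes, len(sample_ids))
    )
    mat[~presence[:, cols]] = np.nan
    frame = pd.DataFrame(mat, index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "species": sample_species,
            "tissue": tissue,
            "replicate": [int(s.rsplit("r", 1)[1]) for s in sample_ids],
            "batch": "sim",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    samples = SampleTable(meta)
    pres_frame = pd.DataFrame(presence, index=genes, columns=taxa)
    expr = ExpressionMatrix(frame, pres_frame, LOG2_TMM_RPKM, samples)
    truth = SimulationTruth(
        genes=pd.DataFrame(truth_rows).set_index("gene"),
        species=pd.DataFrame({"trait": x}, index=pd.Index(taxa, name="species")),
        seed=seed,
        params={"frac_associated": frac_associated, "residual_model": residual_model,
                "presence_rate": presence_rate, "slope_range": list(slope_range)},
    )
    return expr, truth


def simulate_counts(
    log_expression: ExpressionMatrix,
    library_sizes: pd.Series,
    gene_lengths: pd.Series,
    seed: int = 0,
    dispersion: float = 0.0,
) -> ExpressionMatrix:
    """Integer counts with expectation ~ 2^logexpr * length_kb * lib_millions.

    Negative-binomial noise with the given dispersion (Poisson at 0);
    masked cells stay masked.
    """
    lib = library_sizes.reindex(log_expression.sample_ids)
    lens = gene_lengths.reindex(log_expression.gene_ids)
    if lib.isna().any() or (lib <= 0).any():
        raise ValueError("library sizes must be positive and cover all samples")
    if lens.isna().any() or (lens <= 0).any():
        raise ValueError("gene lengths must be positive and cover all genes")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    mu = (
        np.power(2.0, log_expression.values.to_numpy(dtype=float))
        * (lens.to_numpy()[:, None] / 1e3)
        * (lib.to_numpy()[None, :] / 1e6)
    )
    mask = np.isnan(mu)
    mu_safe = np.where(mask, 1.0, mu)
    if dispersion == 0:
        counts = rng.poisson(mu_safe).astype(float)
    else:
        # NB as gamma-Poisson: shape r = 1/dispersion, mean mu
        r = 1.0 / dispersion
        lam = rng.gamma(shape=r, scale=mu_safe / r)
        counts = rng.poisson(lam).astype(float)
    counts[mask] = np.nan
    frame = pd.DataFrame(
        counts, index=log_expression.gene_ids, columns=log_expression.sample_ids
    )
    return ExpressionMatrix(
        frame, log_expression.presence, COUNTS, log_expression.samples
    )


# ---------------------------------------------------------------------------
# selection tables


def simulate_selection_table(
    truth: SimulationTruth,
    coupling: float = 0.0,
    seed: int = 0,
    logk_sd: float = 1.0,
    coupling_scale: float = 1.0,
) -> pd.DataFrame:
    """Per-gene relaxation parameter k, log-normal around coupling * direction.

    ``coupling`` in [-1, 1] links a gene's association direction to log k:
    positive coupling pushes positively-associated genes toward k > 1.
    """
    if not -1 <= coupling <= 1:
        raise ValueError("coupling must lie in [-1, 1]")
    if truth.genes is None:
        raise ValueError("truth table lacks per-gene rows")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    direction = np.sign(genes["true_slope"].to_numpy()) * genes[
        "associated"
    ].to_numpy().astype(float)
    logk = coupling * coupling_scale * direction + logk_sd * rng.standard_normal(
        len(genes)
    )
    k = np.exp(logk)
    pvals = rng.uniform(size=len(genes))
    omega1 = rng.uniform(0.01, 0.8, size=len(genes))
    omega2 = np.ones(len(genes))
    omega3 = rng.uniform(1.0, 5.0, size=len(genes))
    return pd.DataFrame(
        {
            "gene": genes.index,
            "k": k,
            "p": pvals,
            "omega1": omega1,
            "omega2": omega2,
            "omega3": omega3,
        }
    ).set_index("gene")
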