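"""Lifespan clustering and integration of selection-intensity tables.

Selection-intensity records (relaxation parameter k per gene, as produced
by an external branch-model test) are inputs with a fixed TSV schema:
``gene  k  p  omega1  omega2  omega3``. The paper-defined computation here
is downstream: partitioning lifespans into long/non-long-lived groups with
exact one-dimensional PAM, crossing association direction with selection
regime into the IU / RU / ID / RD classes, and per-group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "pam_partition",
    "classify_genes",
    "summarize_selection",
    "read_selection_table",
]


class SelectionError(ValueError):
    pass


SELECTION_COLUMNS = ("k", "p", "omega1", "omega2", "omega3")


def read_selection_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in ("k",) if c not in frame.columns]
    if missing:
        raise SelectionError(f"selection table missing columns {missing}")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise SelectionError(f"duplicate genes in selection table: {dupes}")
    if (frame["k"] <= 0).any():
        raise SelectionError("relaxation parameter k must be positive")
    return frame


@dataclass
class PamResult:
    labels: pd.Series  # 0 = low-value cluster, 1 = high-value cluster
    medoids: tuple[float, float]
    boundary: float
    total_cost: float
    degenerate: bool = False


def pam_partition(lifespans, k_clusters: int = 2) -> PamResult:
    """Exact one-dimensional partitioning around medoids, k = 2.

    Scans every medoid pair over the sorted values, minimizing total
    absolute deviation; deterministic, with clusters identified by value
    range (low / high), and the boundary at the midpoint between the
    clusters' adjacent extremes.
    """
    if k_clusters != 2:
        raise SelectionError("only k_clusters=2 is supported")
    vals = pd.Series(lifespans).astype(float)
    if vals.isna().any():
        raise SelectionError("lifespans contain missing values")
    n = len(vals)
    if n < 2 * k_clusters:
        raise SelectionError(f"need at least {2 * k_clusters} values")
    v = np.sort(vals.to_numpy())
    if v[0] == v[-1]:
        labels = pd.Series(0, index=vals.index)
        return PamResult(labels, (v[0], v[0]), v[0], 0.0, degenerate=True)
    # nearest-medoid assignment in 1-D is a threshold, so the optimum is a
    # contiguous split with each part's medoid at its median element;
    # scan all n-1 splits with prefix sums (equals the exhaustive pair scan)
    csum = np.concatenate([[0.0], np.cumsum(v)])

    def seg_cost(lo: int, hi: int) -> tuple[float, float]:
        # sum |v[t] - median| over t in [lo, hi); returns (cost, medoid)
        mid = (lo + hi - 1) // 2
        med = v[mid]
        left = med * (mid - lo + 1) - (csum[mid + 1] - csum[lo])
        right = (csum[hi] - csum[mid + 1]) - med * (hi - mid - 1)
        return left + right, med

    best = (np.inf, 0.0, 0.0)
    for s in range(1, n):
        c_lo, m1 = seg_cost(0, s)
        c_hi, m2 = seg_cost(s, n)
        cost = c_lo + c_hi
        if cost < best[0] - 1e-12:
            best = (cost, m1, m2)
    cost, m_lo, m_hi = best
    assign_hi = np.abs(vals.to_numpy() - m_hi) < np.abs(vals.to_numpy() - m_lo)
    labels = pd.Series(assign_hi.astype(int), index=vals.index)
    lo_max = vals[labels == 0].max()
    hi_min = vals[labels == 1].min()
    boundary = float((lo_max + hi_min) / 2.0)
    return PamResult(labels, (float(m_lo), float(m_hi)), boundary, float(cost))


def classify_genes(
    associations: pd.DataFrame,
    selection_table: pd.DataFrame,
    k_strong_high: float = 10.0,
    k_strong_low: float = 0.1,
    p_cut: float | None = None,
    drop_conflicts: bool = True,
) -> pd.DataFrame:
    """Cross association direction with selection intensity.

    (positive, k>1) -> IU; (positive, k<1) -> RU; (negative, k>1) -> ID;
    (negative, k<1) -> RD; k == 1 stays unclassified. ``strong`` flags
    k >= 10 or k <= 0.1. ``associations`` needs columns ``gene`` and
    ``direction`` (positive / negative / conflict); conflicting directions
    are flagged and excluded by default.
    """
    req = {"gene", "direction"}
    if not req <= set(associations.columns):
        raise SelectionError(f"associations need columns {sorted(req)}")
    if associations["gene"].duplicated().any():
        raise SelectionError("duplicated gene rows in associations")
    sel = selection_table
    if "gene" in sel.columns:
        sel = sel.set_index("gene")
    if sel.index.has_duplicates:
        raise SelectionError("duplicated genes in selection table")
    rows = []
    for _, arec in associations.iterrows():
        gene = arec["gene"]
        if gene not in sel.index:
            continue
        direction = arec["direction"]
        conflict = direction == "conflict"
        if conflict and drop_conflicts:
            rows.append(
                {"gene": gene, "direction": direction, "selection": "",
                 "gene_class": "conflict", "strong": False, "k": sel.at[gene, "k"]}
            )
            continue
        if direction not in ("positive", "negative"):
            continue
        k = float(sel.at[gene, "k"])
        if p_cut is not None and "p" in sel.columns and sel.at[gene, "p"] >= p_cut:
            continue
        if k == 1.0:
            cls, regime = "unclassified", "boundary"
        elif k > 1.0:
            regime = "intensified"
            cls = "IU" if direction == "positive" else "ID"
        else:
            regime = "relaxed"
            cls = "RU" if direction == "positive" else "RD"
        strong = k >= k_strong_high or k <= k_strong_low
        rows.append(
            {"gene": gene, "direction": direction, "selection": regime,
             "gene_class": cls, "strong": bool(strong), "k": k}
        )
    return pd.DataFrame(
        rows, columns=["gene", "direction", "selection", "gene_class", "strong", "k"]
    )


def summarize_selection(
    selection_table: pd.DataFrame,
    group_definitions: dict | None = None,
    k_strong_high: float = 10.0,
    k_strong_low: float = 0.1,
) -> pd.DataFrame:
    """Per-group intensified / relaxed fractions from a selection table.

    ``group_definitions`` maps group name -> gene collection (supporting
    e.g. lifespan-stratum tables); ``None`` summarizes everything as one
    group. Fractions of intensified (k>1), relaxed (k<1), and boundary
    (k==1) genes sum to 1 within each group.
    """
    sel = selection_table
    if "gene" in sel.columns:
        sel = sel.set_index("gene")
    if group_definitions is None:
        group_definitions = {"all": list(sel.index)}
    rows = []
    for name, genes in group_definitions.items():
        genes = [g for g in genes if g in sel.index]
        if not genes:
            raise SelectionError(f"group {name!r} is empty")
        k = sel.loc[genes, "k"].astype(float)
        n = len(k)
        rows.append(
            {
                "group": name,
                "n": n,
                "frac_intensified": float((k > 1).sum() / n),
                "frac_relaxed": float((k < 1).sum() / n),
                "frac_boundary": float((k == 1).sum() / n),
                "frac_strong": float(
                    ((k >= k_strong_high) | (k <= k_strong_low)).sum() / n
                ),
            }
        )
    return pd.DataFrame(rows).set_index("group")
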