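"""Domain tables, TSV/GMT readers, and run configuration.

All tabular formats are plain TSV. Species names are normalized by
replacing spaces with underscores; after normalization, matching between
expression data, life-history tables, and tree tips is exact-string, and
mismatches are errors rather than warnings (silent drops would corrupt
per-gene species masks).

Absent orthologs are a first-class masked state (NaN + presence=False),
distinct from a zero count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "LifeHistoryTable",
    "Config",
    "read_expression",
    "read_life_history",
    "read_gmt",
    "normalize_species_name",
]

COUNTS = "counts"
LOG2_TMM_RPKM = "log2_tmm_rpkm"


def normalize_species_name(name: str) -> str:
    """Documented normalization: strip and replace spaces with underscores."""
    return name.strip().replace(" ", "_")


@dataclass
class SampleTable:
    """Per-sample metadata: species, tissue, replicate, batch."""

    frame: pd.DataFrame  # index: sample_id; columns: species, tissue, replicate, batch

    REQUIRED = ("species", "tissue")

    def __post_init__(self):
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"sample table missing column {col!r}")
        self.frame = self.frame.copy()
        self.frame["species"] = self.frame["species"].map(normalize_species_name)
        if "replicate" not in self.frame.columns:
            self.frame["replicate"] = (
                self.frame.groupby(["species", "tissue"]).cumcount() + 1
            )
        if "batch" not in self.frame.columns:
            self.frame["batch"] = "batch1"

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def species_of(self, sample_id: str) -> str:
        return self.frame.at[sample_id, "species"]

    def samples_for(self, tissue: str | None = None) -> pd.DataFrame:
        if tissue is None:
            return self.frame
        sub = self.frame[self.frame["tissue"] == tissue]
        if sub.empty:
            raise ValueError(f"no samples for tissue {tissue!r}")
        return sub

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample_id")


class ExpressionMatrix:
    """Gene x sample numeric matrix with a per-(gene, species) presence mask.

    ``values`` holds NaN where a gene's ortholog is absent in the sample's
    species; ``presence`` records the same information at species
    resolution. ``scale_tag`` is ``"counts"`` or ``"log2_tmm_rpkm"``.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        presence: pd.DataFrame | None = None,
        scale_tag: str = COUNTS,
        samples: SampleTable | None = None,
    ):
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = values.astype(float)
        if scale_tag == COUNTS:
            with np.errstate(invalid="ignore"):
                if (vals.to_numpy() < 0).any():
                    raise ValueError("negative counts")
        self.values = vals
        self.scale_tag = scale_tag
        self.samples = samples
        if presence is None and samples is not None:
            presence = self._presence_from_values(vals, samples)
        self.presence = presence

    @staticmethod
    def _presence_from_values(vals: pd.DataFrame, samples: SampleTable) -> pd.DataFrame:
        sp = samples.frame.loc[vals.columns, "species"]
        observed = vals.notna()
        # present in a species iff observed in at least one of its samples
        pres = observed.T.groupby(sp.values).any().T
        pres.columns.name = None
        return pres

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def species_presence_counts(self) -> pd.Series:
        if self.presence is None:
            raise ValueError("presence mask not populated")
        return self.presence.sum(axis=1)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        pres = self.presence.loc[genes] if self.presence is not None else None
        return ExpressionMatrix(
            self.values.loc[genes], pres, self.scale_tag, self.samples
        )

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def read_expression(path, metadata_path) -> tuple[ExpressionMatrix, SampleTable]:
    """Read a gene x sample TSV plus a sample-metadata TSV, cross-validated.

    Missing cells (empty or ``NA``) become masked entries, never zeros.
    Raises on duplicate ids, samples without metadata, or non-numeric cells.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    vals = raw.replace({"NA": np.nan, "": np.nan, "nan": np.nan})
    try:
        vals = vals.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in expression matrix: {exc}") from None
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    if "replicate" in meta.columns:
        meta["replicate"] = meta["replicate"].astype(int)
    table = SampleTable(meta)
    missing = [s for s in vals.columns if s not in table.frame.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    extra = [s for s in table.frame.index if s not in vals.columns]
    if extra:
        raise ValueError(f"metadata samples absent from matrix: {extra}")
    table.frame = table.frame.loc[vals.columns]
    mat = ExpressionMatrix(vals, scale_tag=COUNTS, samples=table)
    return mat, table


@dataclass
class LifeHistoryTable:
    """Per-species life-history traits and their allometric residuals.

    Columns: AW (adult weight, g), ML (maximum lifespan, yr), FTM (female
    time to maturity, yr); MLres / FTMres appear only after residual
    computation. ``status`` mirrors the trait columns with one of
    ``observed`` / ``missing`` / ``imputed`` per cell.
    """

    frame: pd.DataFrame  # index: species
    status: pd.DataFrame | None = None

    TRAITS = ("AW", "ML", "FTM")

    def __post_init__(self):
        self.frame = self.frame.copy()
        self.frame.index = [normalize_species_name(s) for s in self.frame.index]
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate species in life-history table")
        for t in self.TRAITS:
            if t not in self.frame.columns:
                raise ValueError(f"life-history table missing column {t!r}")
            bad = self.frame[t].dropna() <= 0
            if bad.any():
                raise ValueError(
                    f"non-positive {t} for species {self.frame.index[bad][:3].tolist()}"
                )
        if self.status is None:
            self.status = pd.DataFrame(
                np.where(self.frame[list(self.TRAITS)].notna(), "observed", "missing"),
                index=self.frame.index,
                columns=list(self.TRAITS),
            )
        else:
            self.status = self.status.copy()
            self.status.index = [normalize_species_name(s) for s in self.status.index]

    @property
    def species(self) -> list[str]:
        return self.frame.index.tolist()

    def copy(self) -> "LifeHistoryTable":
        return LifeHistoryTable(self.frame.copy(), self.status.copy())

    def trait(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise KeyError(name)
        return self.frame[name]

    def write(self, path) -> None:
        out = self.frame.copy()
        for t in self.TRAITS:
            out[f"{t}_status"] = self.status[t]
        out.to_csv(path, sep="\t", index_label="species", na_rep="NA")


def read_life_history(path) -> LifeHistoryTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    status_cols = [c for c in frame.columns if c.endswith("_status")]
    status = None
    if status_cols:
        status = frame[status_cols].rename(
            columns=lambda c: c[: -len("_status")]
        )
        frame = frame.drop(columns=status_cols)
    return LifeHistoryTable(frame, status)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *genes = parts
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = [g for g in genes if g]
    return sets


@dataclass
class Config:
    """Pipeline thresholds and sizes; every run logs the full config."""

    seed: int = 0
    tau_broad: float = 0.2
    tau_specific: float = 0.8
    p_robust_cut: float = 0.005
    p_max_cut: float = 0.05
    min_species: int = 68
    long_lived_ml: float = 30.0
    k_strong: float = 10.0
    low_expr_min_value: float = 10.0
    low_expr_min_samples: int = 4
    dominant_share: float = 0.05
    n_top_variance: int = 5000
    n_permutations: int = 1000
    n_null_draws: int = 400_000
    n_bins: int = 10
    min_species_robust: int = 6

    def __post_init__(self):
        if not 0 <= self.tau_broad < self.tau_specific <= 1:
            raise ValueError("tau thresholds must satisfy 0 <= broad < specific <= 1")
        for name in ("p_robust_cut", "p_max_cut", "dominant_share"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_species < 1 or self.min_species_robust < 4:
            raise ValueError("species minima out of range")
        if self.k_strong <= 1:
            raise ValueError("k_strong must exceed 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def write_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
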