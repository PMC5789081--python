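"""Data model and readers/writers for expression matrices, sample sheets,
TF-target knowledge bases and gene-set collections.

All on-disk formats are plain text: expression and knowledge bases are TSV,
gene-set collections are GMT. Expression values are assumed to be on the
log2 scale and already normalized; no normalization is performed here.

Gene identifiers are case-preserved strings and matching between the
knowledge base and the expression matrix is exact by default; a
case-insensitive mode is available where symbol tables mix cases.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

SAMPLE_SHEET_COLUMNS = ("sample_id", "condition", "time_h", "replicate")


@dataclass
class SampleSheet:
    """Experimental design: one row per array/sample.

    Columns: sample_id (unique), condition (categorical label), time_h
    (hours, positive), replicate (positive integer).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataError(f"sample sheet missing columns: {missing}")
        ids = self.df["sample_id"].astype(str)
        dup = ids[ids.duplicated()].tolist()
        if dup:
            raise DataError(f"duplicate sample_id(s) in sample sheet: {dup}")
        if (self.df["time_h"] <= 0).any():
            raise DataError("time_h must be positive")
        if (self.df["replicate"] < 1).any():
            raise DataError("replicate must be a positive integer")
        self.df = self.df.reset_index(drop=True)
        self.df["sample_id"] = ids.values

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].unique())

    @property
    def times(self) -> list[float]:
        return sorted(self.df["time_h"].unique())

    def samples_for(self, condition: str, time_h: float) -> list[str]:
        sel = (self.df["condition"] == condition) & (self.df["time_h"] == time_h)
        return self.df.loc[sel, "sample_id"].tolist()


@dataclass
class ExpressionMatrix:
    """Log2-scale gene-by-sample expression bound to its sample sheet."""

    values: pd.DataFrame  # index: gene symbols, columns: sample_ids
    samples: SampleSheet

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataError(
                f"duplicate gene symbols (collapse probes first): {dups[:5]}"
            )
        sheet_ids = self.samples.sample_ids
        missing = [s for s in sheet_ids if s not in self.values.columns]
        if missing:
            raise DataError(f"sample(s) in sheet but not in matrix: {missing}")
        extra = [s for s in self.values.columns if s not in sheet_ids]
        if extra:
            raise DataError(f"sample(s) in matrix but not in sheet: {extra}")
        # align column order to the sheet
        self.values = self.values.loc[:, sheet_ids]
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("expression matrix contains non-numeric cells")
        if not np.isfinite(arr).all():
            raise DataError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def group(self, condition: str, time_h: float) -> pd.DataFrame:
        """Gene x replicate sub-matrix for one (condition, time) cell."""
        cols = self.samples.samples_for(condition, time_h)
        if not cols:
            raise DataError(f"no samples for condition={condition!r}, time_h={time_h}")
        return self.values.loc[:, cols]


@dataclass
class TFKnowledgeBase:
    """Ranked transcription-factor -> target-gene edges (ORTI-style).

    Lower rank means stronger evidence. Duplicate (tf, tg) pairs keep the
    best (lowest) rank.
    """

    edges: pd.DataFrame  # columns: tf, tg, rank

    def __post_init__(self) -> None:
        need = {"tf", "tg", "rank"}
        if not need.issubset(self.edges.columns):
            raise DataError(f"knowledge base needs columns {sorted(need)}")
        if len(self.edges) == 0:
            raise DataError("empty knowledge base")
        self.edges = (
            self.edges.sort_values("rank", kind="stable")
            .drop_duplicates(subset=["tf", "tg"], keep="first")
            .reset_index(drop=True)
        )

    @property
    def tfs(self) -> set[str]:
        return set(self.edges["tf"])

    @property
    def target_genes(self) -> set[str]:
        return set(self.edges["tg"])

    def targets_of(self, tf: str) -> set[str]:
        return set(self.edges.loc[self.edges["tf"] == tf, "tg"])

    def targets_by_tf(self) -> dict[str, set[str]]:
        return {tf: set(grp["tg"]) for tf, grp in self.edges.groupby("tf")}

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf"], self.edges["tg"]))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) filtered to a minimum size."""

    sets: dict[str, frozenset[str]]
    min_size: int = 1

    def __post_init__(self) -> None:
        self.sets = {
            name: frozenset(members)
            for name, members in self.sets.items()
            if len(frozenset(members)) >= self.min_size
        }

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# readers / writers


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.df.to_csv(path, sep="\t", index=False)


def read_expression(matrix_path: str | Path, sample_sheet_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample log2 expression TSV plus its sample sheet.

    The TSV's first column must be named ``gene``; the remaining header
    fields are sample ids matched against the sheet. Duplicate gene rows
    are rejected: probe-level tables go through :func:`collapse_probes`.
    """
    sheet = read_sample_sheet(sample_sheet_path)
    df = pd.read_csv(matrix_path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "gene":
        raise DataError("expression TSV must have 'gene' as its first column")
    df = df.set_index("gene")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise DataError(f"non-numeric cell(s) in sample column {col!r}")
    return ExpressionMatrix(df, sheet)


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path,
                     sample_sheet_path: str | Path | None = None) -> None:
    out = expr.values.copy()
    out.index.name = "gene"
    # 17 significant digits round-trips IEEE doubles bit-exactly
    out.to_csv(matrix_path, sep="\t", float_format="%.17g")
    if sample_sheet_path is not None:
        write_sample_sheet(expr.samples, sample_sheet_path)


def collapse_probes(probe_values: pd.DataFrame, probe_to_gene: Mapping[str, str],
                    sheet: SampleSheet, method: str = "per_sample_median") -> ExpressionMatrix:
    """Collapse a probe x sample matrix to one row per gene symbol.

    method="per_sample_median" (default): for genes with several probes the
    representative row is the per-sample median across the gene's probes,
    preserving sample-wise temporal structure. method="median_average_probe"
    instead picks the single probe whose across-sample average is the median
    of the gene's probe averages (the literal reading of selecting the
    median-average probe).
    """
    missing = [p for p in probe_values.index if p not in probe_to_gene]
    if missing:
        raise DataError(f"probe(s) without gene mapping: {missing[:5]}")
    genes = pd.Series({p: probe_to_gene[p] for p in probe_values.index}, name="gene")
    if method == "per_sample_median":
        collapsed = probe_values.groupby(genes, sort=True).median()
    elif method == "median_average_probe":
        rows = {}
        for gene, grp in probe_values.groupby(genes, sort=True):
            avgs = grp.mean(axis=1).sort_values(kind="stable")
            rep_probe = avgs.index[(len(avgs) - 1) // 2]  # lower median probe
            rows[gene] = probe_values.loc[rep_probe]
        collapsed = pd.DataFrame(rows).T
        collapsed.index.name = probe_values.index.name
    else:
        raise DataError(f"unknown probe-collapse method: {method!r}")
    collapsed.index.name = "gene"
    return ExpressionMatrix(collapsed, sheet)


def read_tf_kb(path: str | Path, max_rank: int = 2) -> TFKnowledgeBase:
    """Read a TF->TG edge TSV (columns tf, tg, rank), keeping rank <= max_rank.

    Mirrors restricting an ORTI-style repository to its top evidence tiers.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"tf", "tg", "rank"}
    if not need.issubset(df.columns):
        raise DataError(f"knowledge base TSV needs columns {sorted(need)}")
    if df[["tf", "tg", "rank"]].isna().any().any():
        raise DataError("malformed knowledge-base row (missing field)")
    kept = df[df["rank"] <= max_rank]
    if len(kept) == 0:
        raise DataError(f"no edges remain at max_rank={max_rank}")
    return TFKnowledgeBase(kept[["tf", "tg", "rank"]].copy())


def write_tf_kb(kb: TFKnowledgeBase, path: str | Path) -> None:
    kb.edges.to_csv(path, sep="\t", index=False)


def read_gene_sets(gmt_path: str | Path, min_size: int = 1) -> GeneSetCollection:
    """Read a GMT file (name, description, members...), dropping sets
    with fewer than ``min_size`` unique members."""
    sets: dict[str, frozenset[str]] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            members = frozenset(g for g in fields[2:] if g)
            sets[name] = members
    return GeneSetCollection(sets, min_size=min_size)


def write_gene_sets(collection: GeneSetCollection, gmt_path: str | Path,
                    description: str = "na") -> None:
    with open(gmt_path, "w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, description, *members]) + "\n")
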