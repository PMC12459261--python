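"""Core containers and readers/writers for the formats the pipeline touches.

The universal input is an :class:`ExpressionAtlas`: a genes x cells count
matrix with per-cell annotations (cell type, tissue, donor, platform, and
optionally age group and sex).  Gene sets travel as GMT files, cell-type
markers and gene-damage-index (GDI) scores as TSV tables, and chromatin
accessibility as BED-like peak/TSS tables.  All genomic intervals are stored
0-based half-open (BED convention); a flag on the readers declares 1-based
inputs, which are shifted on ``start`` only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "ValidationError",
    "FormatError",
    "ExpressionAtlas",
    "GeneSetCollection",
    "MarkerTable",
    "GDITable",
    "PeakTable",
    "TSSAnnotation",
    "read_atlas",
    "write_atlas",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_marker_table",
    "read_gdi_table",
    "read_peaks",
    "read_tss",
]

GDI_CATEGORIES = ("low", "medium", "high")

#: cell_meta columns that must be present
REQUIRED_CELL_COLUMNS = ("cell_id", "cell_type")
#: optional cell_meta columns recognised by downstream stages
OPTIONAL_CELL_COLUMNS = ("tissue", "donor", "platform", "age_group", "sex")


class ValidationError(ValueError):
    """Input violates a container invariant (duplicates, negatives, ...)."""


class FormatError(ValueError):
    """File cannot be parsed as the declared format."""


@dataclasses.dataclass
class ExpressionAtlas:
    """Genes x cells count matrix plus gene and cell annotations.

    Parameters
    ----------
    gene_ids
        Ordered unique gene identifiers (opaque strings, case-sensitive).
    counts
        Non-negative (genes, cells) matrix; sparse CSR or dense ndarray.
    cell_meta
        One row per cell; must contain ``cell_id`` (unique) and
        ``cell_type``.  ``tissue``, ``donor``, ``platform``, ``age_group``
        and ``sex`` are recognised when present.
    normalized
        True once counts have been library-size normalised / log-transformed.
    """

    gene_ids: list[str]
    counts: sp.spmatrix | np.ndarray
    cell_meta: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        if not sp.issparse(self.counts):
            self.counts = np.asarray(self.counts)
        else:
            self.counts = self.counts.tocsr()
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_meta):
            raise ValidationError(
                f"matrix has {n_cells} columns but {len(self.cell_meta)} cell records"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Series(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids: {dupes}")
        for col in REQUIRED_CELL_COLUMNS:
            if col not in self.cell_meta.columns:
                raise ValidationError(f"cell_meta missing required column {col!r}")
        if self.cell_meta["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell ids")
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        if data.size and float(np.min(data)) < 0:
            raise ValidationError("negative values in count matrix")
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def dense(self) -> np.ndarray:
        """Counts as a dense float array (genes x cells)."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def subset_genes(self, genes) -> "ExpressionAtlas":
        """Atlas restricted to ``genes`` (kept in the atlas' own order)."""
        keep = [g for g in self.gene_ids if g in set(genes)]
        idx = self.gene_index.get_indexer(keep)
        return ExpressionAtlas(keep, self.counts[idx, :], self.cell_meta.copy(),
                               normalized=self.normalized)

    def subset_cells(self, mask) -> "ExpressionAtlas":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionAtlas(
            list(self.gene_ids),
            self.counts[:, idx],
            self.cell_meta.iloc[idx].reset_index(drop=True),
            normalized=self.normalized,
        )

    def cells_of_type(self, cell_type: str) -> "ExpressionAtlas":
        mask = (self.cell_meta["cell_type"] == cell_type).to_numpy()
        if not mask.any():
            raise ValidationError(f"cell type {cell_type!r} not present")
        return self.subset_cells(mask)

    def cell_types(self) -> list[str]:
        return sorted(self.cell_meta["cell_type"].unique())

    def to_anndata(self):
        """Optional convenience: cells x genes AnnData view of the atlas."""
        import anndata  # local import: optional dependency

        return anndata.AnnData(
            X=self.counts.T.tocsr() if sp.issparse(self.counts) else self.counts.T.copy(),
            obs=self.cell_meta.set_index("cell_id"),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty sets."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = set(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


@dataclasses.dataclass
class MarkerTable:
    """(gene, cell_type) marker records emulating a PanglaoDB-style table."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("gene", "cell_type"):
            if col not in self.table.columns:
                raise ValidationError(f"marker table missing column {col!r}")
        if self.table.duplicated(subset=["gene", "cell_type"]).any():
            raise ValidationError("duplicate (gene, cell_type) marker pairs")
        self.table = self.table.reset_index(drop=True)

    def marker_celltype_counts(self) -> pd.Series:
        """Number of cell types listing each gene as a marker (m_g)."""
        return self.table.groupby("gene")["cell_type"].nunique()


@dataclasses.dataclass
class GDITable:
    """Per-gene Phred-scaled gene damage index with low/medium/high category."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("gene", "gdi_phred", "category"):
            if col not in self.table.columns:
                raise ValidationError(f"GDI table missing column {col!r}")
        bad = set(self.table["category"]) - set(GDI_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown GDI categories: {sorted(bad)}")
        if (self.table["gdi_phred"] < 0).any():
            raise ValidationError("negative Phred-scaled GDI values")
        self.table = self.table.reset_index(drop=True)

    def genes_in(self, category: str) -> list[str]:
        return self.table.loc[self.table["category"] == category, "gene"].tolist()


@dataclasses.dataclass
class PeakTable:
    """Accessibility peaks: (chrom, start, end) 0-based half-open plus one
    non-negative accessibility column per cell type."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chrom", "start", "end"):
            if col not in self.table.columns:
                raise ValidationError(f"peak table missing column {col!r}")
        if (self.table["start"] >= self.table["end"]).any():
            bad = self.table[self.table["start"] >= self.table["end"]]
            raise ValidationError(
                f"peak intervals with start >= end at rows {bad.index.tolist()}"
            )
        vals = self.table[self.value_columns()]
        if (vals.to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative accessibility values")
        self.table = self.table.reset_index(drop=True)

    def value_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("chrom", "start", "end")]


@dataclasses.dataclass
class TSSAnnotation:
    """Transcription start sites: (chrom, tss, strand, gene)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chrom", "tss", "strand", "gene"):
            if col not in self.table.columns:
                raise ValidationError(f"TSS table missing column {col!r}")
        if (self.table["tss"] < 0).any():
            raise ValidationError("negative TSS coordinates")
        self.table = self.table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_atlas(matrix_path, genes_path, cells_path) -> ExpressionAtlas:
    """Read a genes x cells Matrix Market file with TSV sidecars.

    The genes TSV needs a ``gene`` column (or a single unnamed column); the
    cells TSV needs at least ``cell_id`` and ``cell_type``.  Dimension
    mismatches raise :class:`FormatError` naming the offending file.
    """
    counts = mmread(str(matrix_path))
    if sp.issparse(counts):
        counts = counts.tocsr()
    genes = pd.read_csv(genes_path, sep="\t")
    if "gene" not in genes.columns:
        if genes.shape[1] == 1:
            genes.columns = ["gene"]
        else:
            raise FormatError(f"{genes_path}: no 'gene' column")
    cells = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str})
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"{matrix_path}: {counts.shape[0]} rows but {genes_path} lists "
            f"{len(genes)} genes"
        )
    if counts.shape[1] != len(cells):
        raise FormatError(
            f"{matrix_path}: {counts.shape[1]} columns but {cells_path} lists "
            f"{len(cells)} cells"
        )
    meta_cols = [c for c in cells.columns
                 if c in REQUIRED_CELL_COLUMNS + OPTIONAL_CELL_COLUMNS]
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise FormatError(f"{cells_path}: missing columns {missing}")
    return ExpressionAtlas(genes["gene"].astype(str).tolist(), counts, cells[meta_cols])


def write_atlas(atlas: ExpressionAtlas, out_dir) -> dict[str, Path]:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    counts = atlas.counts
    if not sp.issparse(counts):
        counts = sp.coo_matrix(counts)
    mmwrite(str(paths["matrix"]), counts)
    pd.DataFrame({"gene": atlas.gene_ids}).to_csv(paths["genes"], sep="\t", index=False)
    atlas.cell_meta.to_csv(paths["cells"], sep="\t", index=False)
    return paths


def read_atlas_dir(directory) -> ExpressionAtlas:
    """Read an atlas written by :func:`write_atlas`."""
    d = Path(directory)
    return read_atlas(d / "matrix.mtx", d / "genes.tsv", d / "cells.tsv")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields raises :class:`FormatError` with its line number.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(g for g in genes if g)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gene_list(path) -> set[str]:
    """Plain-text gene list, one symbol per line, blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_marker_table(path) -> MarkerTable:
    table = pd.read_csv(path, sep="\t")
    return MarkerTable(table)


def read_gdi_table(path) -> GDITable:
    table = pd.read_csv(path, sep="\t")
    return GDITable(table)


def read_peaks(path, one_based: bool = False) -> PeakTable:
    """BED-like TSV with header: chrom, start, end, then one value column per
    cell type.  ``one_based=True`` shifts start by -1 (1-based inclusive ->
    0-based half-open)."""
    table = pd.read_csv(path, sep="\t")
    if one_based:
        table = table.assign(start=table["start"] - 1)
    return PeakTable(table)


def read_tss(path, one_based: bool = False) -> TSSAnnotation:
    """BED-style TSS annotation: chrom, tss, strand, gene (with header)."""
    table = pd.read_csv(path, sep="\t")
    if one_based:
        table = table.assign(tss=table["tss"] - 1)
    return TSSAnnotation(table)
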