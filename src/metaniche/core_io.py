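"""Data model, standard-format I/O, and quality-control filters.

The central container is :class:`CountMatrix`: a sparse genes x cells
integer count matrix with gene/cell identifiers and per-cell metadata
(sample, pathology group, tissue, cell type).  Matrices are exchanged on
disk as Matrix Market ``.mtx`` plus ``genes.tsv`` / ``cells.tsv``
sidecars, gene sets as GMT.

Quality control follows the standard droplet scRNA-seq recipe: cells are
kept when they express between 200 and 8000 genes (inclusive at both
bounds) and carry at most 10% mitochondrial counts.  "Expressed" means
count > 0; the mitochondrial fraction is computed on raw counts.
Mitochondrial and ribosomal genes are recognised by the conventional
``MT-`` and ``RPL``/``RPS`` name prefixes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

MITO_PREFIX = "MT-"
RIBO_PREFIXES = ("RPL", "RPS")

CELL_META_COLUMNS = ("sample", "group", "tissue", "celltype")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ConfigError(ValueError):
    """A configuration value violates its contract."""


@dataclass
class CountMatrix:
    """Sparse genes x cells count matrix with aligned metadata.

    Parameters
    ----------
    counts
        Nonnegative integer counts, shape (n_genes, n_cells).
    gene_ids, cell_ids
        Unique identifiers for the rows / columns.
    cell_meta
        DataFrame indexed by cell id with columns ``sample``, ``group``,
        ``tissue``, ``celltype``.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        G, N = self.counts.shape
        if G != len(self.gene_ids) or N != len(self.cell_ids):
            raise FormatError(
                f"matrix is {G}x{N} but sidecars list {len(self.gene_ids)} "
                f"genes and {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != G:
            raise FormatError("duplicate gene ids")
        if len(set(self.cell_ids)) != N:
            raise FormatError("duplicate cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        if not self.cell_meta.index.equals(pd.Index(self.cell_ids)):
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)
        missing = [c for c in CELL_META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise FormatError(f"cell_meta missing columns {missing}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """New matrix restricted to genes where ``keep`` is True / indexed."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            cell_meta=self.cell_meta.copy(),
        )

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        cells = [self.cell_ids[i] for i in idx]
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=cells,
            cell_meta=self.cell_meta.loc[cells].copy(),
        )

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None


@dataclass
class QCReport:
    """Per-cell QC metrics and the retain/remove decision."""

    cell_ids: list[str]
    detected_genes: np.ndarray
    mito_fraction: np.ndarray
    passed: np.ndarray
    thresholds: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "detected_genes": self.detected_genes,
                "mito_fraction": self.mito_fraction,
                "pass": self.passed,
            },
            index=pd.Index(self.cell_ids, name="cell_id"),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "n_cells": len(self.cell_ids),
            "n_pass": int(self.passed.sum()),
            "cells": self.to_frame().reset_index().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics), optionally over a fixed universe."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if self.universe is not None:
                stray = set(members) - set(self.universe)
                if stray:
                    raise FormatError(
                        f"gene set {name!r} has members outside the universe: "
                        f"{sorted(stray)[:5]}"
                    )

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Matrix Market + sidecar I/O
# ---------------------------------------------------------------------------

def read_mtx(counts_path, genes_path, cells_path) -> CountMatrix:
    """Read a genes x cells matrix from MTX with TSV sidecars.

    ``genes.tsv`` has a ``gene_id`` column; ``cells.tsv`` has ``cell_id``
    plus the metadata columns sample/group/tissue/celltype.  The sidecar
    ordering is authoritative.  Explicit stored zeros in the MTX file are
    dropped.
    """
    mat = mmread(str(counts_path))
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    if "gene_id" not in genes.columns:
        raise FormatError("genes.tsv must have a gene_id column")
    if "cell_id" not in cells.columns:
        raise FormatError("cells.tsv must have a cell_id column")
    G, N = mat.shape
    if len(genes) != G:
        raise FormatError(
            f"MTX header declares {G} genes but genes sidecar has {len(genes)} rows"
        )
    if len(cells) != N:
        raise FormatError(
            f"MTX header declares {N} cells but cells sidecar has {len(cells)} rows"
        )
    counts = sp.csr_matrix(mat)
    counts.eliminate_zeros()
    meta = cells.set_index("cell_id")
    return CountMatrix(
        counts=counts,
        gene_ids=genes["gene_id"].tolist(),
        cell_ids=cells["cell_id"].tolist(),
        cell_meta=meta,
    )


def write_mtx(m: CountMatrix, outdir) -> dict[str, Path]:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "matrix.mtx",
        "genes": outdir / "genes.tsv",
        "cells": outdir / "cells.tsv",
    }
    mmwrite(str(paths["counts"]), sp.coo_matrix(m.counts), field="integer")
    pd.DataFrame({"gene_id": m.gene_ids}).to_csv(paths["genes"], sep="\t", index=False)
    meta = m.cell_meta.copy()
    meta.insert(0, "cell_id", m.cell_ids)
    meta.to_csv(paths["cells"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def qc_metrics(m: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (detected genes, mitochondrial fraction) on raw counts."""
    detected = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    total = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    is_mito = np.array([g.startswith(MITO_PREFIX) for g in m.gene_ids])
    if is_mito.any():
        mito = np.asarray(m.counts[is_mito, :].sum(axis=0)).ravel().astype(float)
    else:
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
    return detected, frac


def qc_filter(
    m: CountMatrix,
    min_genes: int = 200,
    max_genes: int = 8000,
    max_mito: float = 0.10,
) -> tuple[CountMatrix, QCReport]:
    """Drop low-quality cells; the gene axis is untouched.

    A cell is retained iff ``min_genes <= detected <= max_genes`` and its
    mitochondrial count fraction is at most ``max_mito`` — the bounds are
    inclusive on the retain side.
    """
    detected, mito_frac = qc_metrics(m)
    passed = (detected >= min_genes) & (detected <= max_genes) & (mito_frac <= max_mito)
    report = QCReport(
        cell_ids=list(m.cell_ids),
        detected_genes=detected,
        mito_fraction=mito_frac,
        passed=passed,
        thresholds={
            "min_genes": min_genes,
            "max_genes": max_genes,
            "max_mito": max_mito,
        },
    )
    if not passed.any():
        warnings.warn("QC removed every cell; returning an empty matrix")
    return m.subset_cells(passed), report


def strip_mito_ribo(m: CountMatrix) -> CountMatrix:
    """Remove mitochondrial (MT-) and ribosomal (RPL/RPS) genes."""
    keep = np.array(
        [
            not (g.startswith(MITO_PREFIX) or g.startswith(RIBO_PREFIXES))
            for g in m.gene_ids
        ]
    )
    if keep.all():
        return m
    return m.subset_genes(keep)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and at "
                f"least one member ({len(fields)} fields found)"
            )
        name, desc, *members = fields
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        seen: list[str] = []
        for g in members:
            if g and g not in seen:
                seen.append(g)
        sets[name] = seen
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(coll: GeneSetCollection, path) -> None:
    lines = []
    for name, members in coll.sets.items():
        desc = coll.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")
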