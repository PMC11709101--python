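"""Readers, writers, normalization and QC filters.

The pipeline's on-disk formats are deliberately plain: MatrixMarket sparse
counts with sidecar gene/barcode lists (or a dense delimited matrix), signed
gene sets as GMT or two-column text, and Visium-style ``tissue_positions``
CSVs for spatial spot layouts.  Everything downstream assumes the QC and
log-normalization conventions implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SignedGeneSet",
    "SpotGrid",
    "read_expression",
    "write_expression",
    "read_geneset",
    "write_geneset",
    "read_spot_table",
    "write_spot_table",
    "read_spot_expression",
    "qc_filter_cells",
    "qc_filter_spots",
    "log_normalize",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x cells expression with raw-count and log-normalized layers.

    ``counts`` holds non-negative integer UMI counts, ``lognorm`` (once
    computed) holds ``ln(1 + scale * count / cell_total)`` values on the same
    genes-x-cells grid.  ``meta`` carries free-form per-cell annotations
    indexed by cell barcode.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix
    lognorm: sp.csr_matrix | None = None
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"gene axis mismatch: {len(self.gene_ids)} ids for {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"cell axis mismatch: {len(self.cell_ids)} ids for {n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise FormatError("non-integer counts")
        if self.meta.empty:
            self.meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def lognorm_row(self, gene: str) -> np.ndarray:
        """Dense log-normalized values of one gene across all cells."""
        if self.lognorm is None:
            raise ValueError("lognorm layer not computed; call log_normalize first")
        return np.asarray(self.lognorm[self.gene_index(gene)].todense()).ravel()

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in keep],
            counts=self.counts[:, keep],
            lognorm=None if self.lognorm is None else self.lognorm[:, keep],
            meta=self.meta.iloc[keep].copy(),
        )


@dataclass
class SignedGeneSet:
    """A named gene set where each gene carries an expected direction.

    Directions are "up" (expected higher in the phenotype of interest) or
    "down".  The up-gene count m and down-gene count k are the normalizers of
    the composite score.
    """

    name: str
    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise FormatError(f"gene set {self.name!r} is empty")
        seen: set[str] = set()
        for sym, direction in self.entries:
            if direction not in ("up", "down"):
                raise FormatError(
                    f"unknown direction {direction!r} for gene {sym!r} in set {self.name!r}"
                )
            if sym in seen:
                raise FormatError(f"duplicate gene {sym!r} in set {self.name!r}")
            seen.add(sym)

    @property
    def up_genes(self) -> list[str]:
        return [g for g, d in self.entries if d == "up"]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, d in self.entries if d == "down"]

    @property
    def m(self) -> int:
        return len(self.up_genes)

    @property
    def k(self) -> int:
        return len(self.down_genes)

    def negated(self) -> "SignedGeneSet":
        flip = {"up": "down", "down": "up"}
        return SignedGeneSet(self.name, [(g, flip[d]) for g, d in self.entries])


@dataclass
class SpotGrid:
    """Spots of one spatial sample on a hexagonally packed array.

    Array coordinates follow the Visium convention: integer ``array_row`` /
    ``array_col`` with ``row + col`` even on every spot (odd rows are offset
    half a spot).  ``expr`` holds normalized expression of the query genes,
    spots x genes.
    """

    spot_ids: list[str]
    array_row: np.ndarray
    array_col: np.ndarray
    pixel_x: np.ndarray | None = None
    pixel_y: np.ndarray | None = None
    expr: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        n = len(self.spot_ids)
        if len(self.array_row) != n or len(self.array_col) != n:
            raise FormatError("spot coordinate arrays do not match spot_ids length")
        bad = np.flatnonzero((self.array_row + self.array_col) % 2 != 0)
        if bad.size:
            raise FormatError(
                f"hex parity violated at spot {self.spot_ids[bad[0]]!r} "
                f"(row={self.array_row[bad[0]]}, col={self.array_col[bad[0]]})"
            )
        coords = set(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(coords) != n:
            raise FormatError("duplicate (array_row, array_col) pairs")
        if not self.expr.empty:
            vals = self.expr.to_numpy()
            if not np.all(np.isfinite(vals)) or vals.min() < 0:
                raise FormatError("spot expression must be finite and >= 0")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def subset(self, keep: np.ndarray) -> "SpotGrid":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SpotGrid(
            spot_ids=[self.spot_ids[i] for i in keep],
            array_row=self.array_row[keep],
            array_col=self.array_col[keep],
            pixel_x=None if self.pixel_x is None else np.asarray(self.pixel_x)[keep],
            pixel_y=None if self.pixel_y is None else np.asarray(self.pixel_y)[keep],
            expr=self.expr.iloc[keep].copy() if not self.expr.empty else pd.DataFrame(),
            sample_id=self.sample_id,
        )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _read_id_list(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def _dedupe(symbols: Sequence[str]) -> list[str]:
    """Suffix repeated symbols with -1, -2, ... keeping the first occurrence."""
    seen: dict[str, int] = {}
    out = []
    dupes = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}-{seen[s]}")
            dupes.append(s)
        else:
            seen[s] = 0
            out.append(s)
    if dupes:
        warnings.warn(
            f"de-duplicated {len(dupes)} repeated gene symbol(s) by suffixing "
            f"(e.g. {dupes[0]!r})",
            stacklevel=3,
        )
    return out


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x cells count matrix.

    ``.mtx`` files are read as MatrixMarket with sidecar gene/barcode lists
    (one id per line; extra tab-separated columns ignored).  Any other
    extension is read as a dense delimited matrix with gene ids in the first
    column and cell ids in the header; the delimiter (tab or comma) is
    auto-detected from the header line.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise FormatError("MatrixMarket input requires genes_path and cells_path")
        mat = sp.csr_matrix(spio.mmread(matrix_path))
        genes = _read_id_list(Path(genes_path))
        cells = _read_id_list(Path(cells_path))
        if len(genes) != mat.shape[0]:
            raise FormatError(
                f"gene axis mismatch: {len(genes)} ids in {Path(genes_path).name} "
                f"for {mat.shape[0]} matrix rows"
            )
        if len(cells) != mat.shape[1]:
            raise FormatError(
                f"cell axis mismatch: {len(cells)} ids in {Path(cells_path).name} "
                f"for {mat.shape[1]} matrix columns"
            )
    else:
        with open(matrix_path) as fh:
            header = fh.readline()
        delim = "," if header.count(",") >= header.count("\t") else "\t"
        df = pd.read_csv(matrix_path, sep=delim, index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        mat = sp.csr_matrix(df.to_numpy())
    if mat.nnz and np.any(mat.data != np.round(mat.data)):
        raise FormatError(f"non-integer counts in {matrix_path.name}")
    mat = mat.astype(np.int64)
    return ExpressionMatrix(gene_ids=_dedupe(genes), cell_ids=_dedupe(cells), counts=mat)


def write_expression(
    m: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    """Write counts as MatrixMarket plus gene/barcode sidecar lists."""
    spio.mmwrite(str(matrix_path), sp.coo_matrix(m.counts), field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in m.gene_ids))
    Path(cells_path).write_text("".join(f"{c}\n" for c in m.cell_ids))


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def mito_gene_mask(gene_ids: Sequence[str], mito_prefix: str = "MT-") -> np.ndarray:
    prefix = mito_prefix.upper()
    return np.array([g.upper().startswith(prefix) for g in gene_ids])


def qc_filter_cells(
    m: ExpressionMatrix,
    max_genes: int = 5000,
    max_mito_frac: float = 0.05,
    mito_prefix: str = "MT-",
) -> ExpressionMatrix:
    """Drop suspected doublets and apoptotic cells.

    Removes cells expressing strictly more than ``max_genes`` genes (doublet
    proxy) or with a mitochondrial read fraction strictly above
    ``max_mito_frac`` (apoptosis proxy).  The gene axis is untouched.
    """
    n_expressed = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    mito = mito_gene_mask(m.gene_ids, mito_prefix)
    if mito.any():
        mito_counts = np.asarray(m.counts[mito].sum(axis=0)).ravel().astype(float)
    else:
        mito_counts = np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep = (n_expressed <= max_genes) & (mito_frac <= max_mito_frac)
    if not keep.any():
        raise ValueError("no cells pass QC")
    if keep.all():
        return m
    return m.subset_cells(keep)


def qc_filter_spots(
    g: SpotGrid,
    counts_per_spot: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    max_mito_frac: float = 0.30,
    min_genes: int = 200,
) -> SpotGrid:
    """Drop low-quality spots using a per-spot counts summary.

    ``counts_per_spot`` maps spot id to ``n_genes`` (detected genes) and
    ``mito_frac``; spots with mito fraction strictly above ``max_mito_frac``
    or with fewer than ``min_genes`` detected genes are removed.
    """
    summary = pd.DataFrame(counts_per_spot).T if not isinstance(
        counts_per_spot, pd.DataFrame
    ) else counts_per_spot
    n_genes = summary.loc[g.spot_ids, "n_genes"].to_numpy(dtype=float)
    mito = summary.loc[g.spot_ids, "mito_frac"].to_numpy(dtype=float)
    keep = (mito <= max_mito_frac) & (n_genes >= min_genes)
    if not keep.any():
        raise ValueError("no spots pass QC")
    if keep.all():
        return g
    return g.subset(keep)


def log_normalize(m: ExpressionMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Compute ``ln(1 + scale * count / cell_total)`` per gene and cell.

    Cells with zero total count get all-zero log-normalized values.  Returns
    a new matrix sharing the counts layer, with the lognorm layer filled in.
    """
    if m.counts.nnz and m.counts.data.min() < 0:
        raise ValueError("negative counts")
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    if not (totals > 0).any():
        raise ValueError("log_normalize requires at least one cell with positive total")
    inv = np.zeros_like(totals)
    pos = totals > 0
    inv[pos] = scale / totals[pos]
    ln = sp.csr_matrix(m.counts.astype(float).multiply(inv[np.newaxis, :]))
    ln.data = np.log1p(ln.data)
    return replace(m, lognorm=ln)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def read_geneset(
    path: str | Path,
    format: str = "two_column",
    down_genes: Iterable[str] | None = None,
) -> list[SignedGeneSet]:
    """Parse signed gene sets.

    ``two_column``: one set per file, rows of ``symbol<TAB>direction`` where
    direction is ``up`` or ``down`` (a header row ``gene  direction`` is
    tolerated).  ``gmt``: one set per row (name, description, symbols...);
    directions default to up unless the symbol is listed in ``down_genes``.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise FormatError(f"{path.name} is empty")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if format == "two_column":
        entries: list[tuple[str, str]] = []
        for i, line in enumerate(lines):
            parts = line.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) < 2:
                raise FormatError(f"{path.name} line {i + 1}: expected symbol and direction")
            sym, direction = parts[0], parts[1].lower()
            if i == 0 and direction not in ("up", "down") and sym.lower() in (
                "gene",
                "symbol",
                "gene_symbol",
            ):
                continue  # header row
            if direction not in ("up", "down"):
                raise FormatError(
                    f"{path.name} line {i + 1}: unknown direction {parts[1]!r}"
                )
            entries.append((sym, direction))
        return [SignedGeneSet(name=path.stem, entries=entries)]
    if format == "gmt":
        down = {g for g in (down_genes or ())}
        sets = []
        for i, line in enumerate(lines):
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 3:
                raise FormatError(f"{path.name} line {i + 1}: GMT needs name, desc, genes")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            sets.append(
                SignedGeneSet(
                    name=name,
                    entries=[(g, "down" if g in down else "up") for g in genes],
                )
            )
        return sets
    raise ValueError(f"unknown gene set format {format!r}")


def write_geneset(gs: SignedGeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdirection\n")
        for sym, direction in gs.entries:
            fh.write(f"{sym}\t{direction}\n")


# ---------------------------------------------------------------------------
# spatial spot tables
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = ("barcode", "in_tissue", "array_row", "array_col")


def read_spot_table(path: str | Path, sample_id: str | None = None) -> SpotGrid:
    """Read a Visium-style tissue-positions CSV.

    Requires columns barcode, in_tissue, array_row, array_col; pixel columns
    (``pxl_row_in_fullres``/``pxl_col_in_fullres``) are optional.  Only
    in-tissue spots are retained; hex parity is enforced on those.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {', '.join(missing)}")
    df = df[df["in_tissue"] == 1].reset_index(drop=True)
    px = py = None
    if "pxl_col_in_fullres" in df.columns and "pxl_row_in_fullres" in df.columns:
        px = df["pxl_col_in_fullres"].to_numpy(dtype=float)
        py = df["pxl_row_in_fullres"].to_numpy(dtype=float)
    return SpotGrid(
        spot_ids=[str(b) for b in df["barcode"]],
        array_row=df["array_row"].to_numpy(),
        array_col=df["array_col"].to_numpy(),
        pixel_x=px,
        pixel_y=py,
        sample_id=sample_id or path.stem,
    )


def write_spot_table(g: SpotGrid, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "barcode": g.spot_ids,
            "in_tissue": 1,
            "array_row": g.array_row,
            "array_col": g.array_col,
        }
    )
    if g.pixel_x is not None and g.pixel_y is not None:
        df["pxl_row_in_fullres"] = g.pixel_y
        df["pxl_col_in_fullres"] = g.pixel_x
    df.to_csv(path, index=False)


def read_spot_expression(path: str | Path) -> pd.DataFrame:
    """Read a spots x genes normalized-expression table (TSV/CSV, spot ids in
    the first column)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    delim = "," if header.count(",") >= header.count("\t") else "\t"
    df = pd.read_csv(path, sep=delim, index_col=0)
    df.index = df.index.astype(str)
    return df


def attach_expression(g: SpotGrid, expr: pd.DataFrame) -> SpotGrid:
    """Attach a spots x genes expression table, aligned on spot ids."""
    missing = [s for s in g.spot_ids if s not in expr.index]
    if missing:
        raise FormatError(f"expression table missing spot(s): {missing[:3]} ...")
    return replace(g, expr=expr.loc[g.spot_ids].copy())
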