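"""Reading, validation, filtering and pairing of spatial and scRNA-seq count data.

Two modalities are handled:

* image-based spatial transcriptomics -- a pixels x genes count matrix with
  2-D pixel coordinates, where a "pixel" is a single measurement location
  (one cell in seqFISH/STARmap/osmFISH/MERFISH-style assays);
* scRNA-seq -- a cells x genes count matrix with a cell-type label per cell.

Counts stay raw throughout: the model consumes integer counts with a per-pixel
size factor ``N_i`` (total counts across genes) as the Poisson offset, so no
normalisation is applied here beyond the explicit preprocessing rules
(depth/label filtering of cells, optional rescaling of already-normalised data
back to integer counts, optional low-expression gene filtering).

Supported on-disk formats: dense TSV/CSV tables (genes in columns, a leading
id column) or MatrixMarket ``.mtx`` with one-column sidecar row/column name
files; coordinates as a ``pixel_id, x, y`` table; annotations as a
``cell_id, cell_type`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class DataError(ValueError):
    """Malformed or invalid input data."""


class PairingError(DataError):
    """The two modalities cannot be paired (no shared genes)."""


def _clean_names(names) -> list[str]:
    """Single documented normalisation: trim surrounding whitespace.

    Matching elsewhere is exact and case-sensitive; no alias/ortholog
    resolution is attempted.
    """
    return [str(n).strip() for n in names]


def _check_unique(names: list[str], what: str) -> None:
    if len(set(names)) != len(names):
        seen, dups = set(), set()
        for n in names:
            if n in seen:
                dups.add(n)
            seen.add(n)
        raise DataError(f"duplicate {what}: {sorted(dups)[:5]}")


def _check_counts(counts: np.ndarray, what: str) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise DataError(f"{what} must be a 2-D matrix, got shape {counts.shape}")
    if not np.issubdtype(counts.dtype, np.number):
        raise DataError(f"{what} must be numeric")
    if np.any(~np.isfinite(counts.astype(float))):
        raise DataError(f"{what} contains non-finite entries")
    if np.any(counts < 0):
        i, j = np.argwhere(counts < 0)[0]
        raise DataError(f"{what} contains a negative entry at row {i}, column {j}")
    if not np.all(np.equal(np.mod(counts, 1), 0)):
        i, j = np.argwhere(np.mod(counts, 1) != 0)[0]
        raise DataError(f"{what} contains a non-integer entry at row {i}, column {j}")
    return counts.astype(np.int64)


@dataclass
class SpatialDataset:
    """Pixels x genes count matrix with coordinates and per-pixel size factors.

    ``size_factors`` defaults to the row sums of ``counts`` (the total number
    of counts across all genes for each pixel, the Poisson offset N_i).  A
    gene-subset slice of a wider dataset may carry the parent's size factors
    explicitly so the offset still reflects the full measured transcriptome.
    """

    counts: np.ndarray
    coords: np.ndarray
    pixel_ids: list[str]
    gene_names: list[str]
    size_factors: np.ndarray = None

    def __post_init__(self):
        self.counts = _check_counts(self.counts, "spatial counts")
        self.coords = np.asarray(self.coords, dtype=float)
        self.pixel_ids = _clean_names(self.pixel_ids)
        self.gene_names = _clean_names(self.gene_names)
        n, q = self.counts.shape
        if n < 2:
            raise DataError(f"need at least 2 pixels, got {n}")
        if self.coords.shape != (n, 2):
            raise DataError(f"coords must be {n}x2, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise DataError("coords contain non-finite values")
        if len(self.pixel_ids) != n or len(self.gene_names) != q:
            raise DataError("name lengths do not match the count matrix")
        _check_unique(self.pixel_ids, "pixel ids")
        _check_unique(self.gene_names, "gene names")
        if self.size_factors is None:
            self.size_factors = self.counts.sum(axis=1).astype(float)
        else:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if self.size_factors.shape != (n,):
                raise DataError("size_factors length mismatch")
        if np.any(self.size_factors <= 0):
            bad = [self.pixel_ids[i] for i in np.flatnonzero(self.size_factors <= 0)]
            raise DataError(
                f"{len(bad)} pixel(s) with nonpositive size factor (e.g. {bad[:3]}); "
                "drop empty pixels first (from_arrays does this automatically)"
            )

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_arrays(cls, counts, coords, pixel_ids, gene_names,
                    size_factors=None) -> "SpatialDataset":
        """Build a dataset, dropping pixels with zero total counts (warned).

        The model's offset requires N_i > 0, so empty pixels cannot enter a fit.
        """
        counts = _check_counts(np.asarray(counts), "spatial counts")
        sf = (counts.sum(axis=1).astype(float) if size_factors is None
              else np.asarray(size_factors, dtype=float))
        keep = sf > 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} pixel(s) with zero total counts",
                stacklevel=2,
            )
        coords = np.asarray(coords, dtype=float)
        pixel_ids = list(pixel_ids)
        return cls(
            counts=counts[keep],
            coords=coords[keep],
            pixel_ids=[p for p, k in zip(pixel_ids, keep) if k],
            gene_names=list(gene_names),
            size_factors=sf[keep] if size_factors is not None else None,
        )

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in spatial dataset") from None

    def gene_counts(self, gene: str) -> np.ndarray:
        return self.counts[:, self.gene_index(gene)]

    def subset_genes(self, genes, keep_size_factors: bool = False) -> "SpatialDataset":
        """Restrict to ``genes`` (order preserved as given).

        By default size factors are recomputed from the retained genes (so a
        cross-validation training subset never sees held-out counts); with
        ``keep_size_factors=True`` the current offsets are carried over.
        Pixels left with zero counts are dropped with a warning.
        """
        idx = [self.gene_index(g) for g in genes]
        return SpatialDataset.from_arrays(
            self.counts[:, idx], self.coords, self.pixel_ids,
            [self.gene_names[i] for i in idx],
            size_factors=self.size_factors if keep_size_factors else None,
        )


@dataclass
class SCDataset:
    """Cells x genes scRNA-seq count matrix with one cell-type label per cell."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_names: list[str]
    cell_types: list[str]

    def __post_init__(self):
        self.counts = _check_counts(self.counts, "scRNA-seq counts")
        self.cell_ids = _clean_names(self.cell_ids)
        self.gene_names = _clean_names(self.gene_names)
        self.cell_types = _clean_names(self.cell_types)
        m, p = self.counts.shape
        if m < 1:
            raise DataError("need at least one cell")
        if len(self.cell_ids) != m or len(self.cell_types) != m:
            raise DataError("cell id/type lengths do not match the count matrix")
        if len(self.gene_names) != p:
            raise DataError("gene name length does not match the count matrix")
        if any(t == "" for t in self.cell_types):
            raise DataError("empty cell-type label")
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_names, "gene names")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def depths(self) -> np.ndarray:
        """Read depth per cell: total counts across genes."""
        return self.counts.sum(axis=1)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in scRNA-seq dataset") from None

    def gene_counts(self, gene: str) -> np.ndarray:
        return self.counts[:, self.gene_index(gene)]


@dataclass
class PairedData:
    """A spatial dataset and an scRNA-seq dataset joined on shared genes."""

    spatial: SpatialDataset
    sc: SCDataset
    shared_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.shared_genes:
            raise PairingError("shared_genes is empty")


def load_counts(path, layout: str = "auto", row_names_path=None,
                col_names_path=None):
    """Load a count matrix plus row/column names.

    ``layout`` is ``"mtx"`` (MatrixMarket triplet with two one-column sidecar
    name files, defaulting to ``<stem>_rows.txt`` / ``<stem>_cols.txt``),
    ``"dense"`` (delimited table, header row of column names, first column of
    row names), or ``"auto"`` (by file suffix).

    Returns ``(matrix, row_names, col_names)`` with an int64 matrix; negative
    or non-numeric entries are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if layout == "auto":
        layout = "mtx" if path.suffix == ".mtx" else "dense"
    if layout == "mtx":
        rows = Path(row_names_path) if row_names_path else path.with_name(path.stem + "_rows.txt")
        cols = Path(col_names_path) if col_names_path else path.with_name(path.stem + "_cols.txt")
        for p in (rows, cols):
            if not p.exists():
                raise DataError(f"missing MatrixMarket sidecar name file: {p}")
        try:
            raw = mmread(path)
        except Exception as exc:  # scipy raises assorted types on malformed files
            raise DataError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
        row_names = _read_name_column(rows)
        col_names = _read_name_column(cols)
        if mat.shape != (len(row_names), len(col_names)):
            raise DataError(
                f"matrix shape {mat.shape} does not match sidecar name counts "
                f"({len(row_names)}, {len(col_names)})"
            )
        return _check_counts(mat, str(path)), row_names, col_names
    if layout == "dense":
        sep = "," if path.suffix == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise DataError(f"cannot parse {path}: {exc}") from exc
        numeric = df.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().values.any():
            r, c = np.argwhere(numeric.isna().values)[0]
            raise DataError(
                f"{path}: non-numeric entry at line {r + 2}, column {df.columns[c]!r}"
            )
        return (_check_counts(numeric.values, str(path)),
                _clean_names(df.index), _clean_names(df.columns))
    raise DataError(f"unknown layout {layout!r}")


def _read_name_column(path: Path) -> list[str]:
    names = [line.strip() for line in Path(path).read_text().splitlines()]
    return [n for n in names if n]


def write_counts(matrix, row_names, col_names, path, layout: str = "dense") -> None:
    """Write a count matrix in a form ``load_counts`` reads back exactly."""
    path = Path(path)
    matrix = np.asarray(matrix)
    if layout == "dense":
        sep = "," if path.suffix == ".csv" else "\t"
        pd.DataFrame(matrix, index=list(row_names), columns=list(col_names)).to_csv(
            path, sep=sep)
    elif layout == "mtx":
        mmwrite(str(path), coo_matrix(matrix))
        path.with_name(path.stem + "_rows.txt").write_text(
            "\n".join(map(str, row_names)) + "\n")
        path.with_name(path.stem + "_cols.txt").write_text(
            "\n".join(map(str, col_names)) + "\n")
    else:
        raise DataError(f"unknown layout {layout!r}")


def load_coords(path, pixel_ids=None) -> np.ndarray:
    """Read a ``pixel_id, x, y`` table; reorder to ``pixel_ids`` if given."""
    df = pd.read_csv(path, sep="\t")
    for col in ("pixel_id", "x", "y"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    df["pixel_id"] = df["pixel_id"].astype(str).str.strip()
    df = df.set_index("pixel_id")
    if pixel_ids is not None:
        missing = [p for p in pixel_ids if p not in df.index]
        if missing:
            raise DataError(f"{path}: coordinates missing for pixels {missing[:5]}")
        df = df.loc[list(pixel_ids)]
    return df[["x", "y"]].to_numpy(dtype=float)


def load_cell_types(path, cell_ids=None) -> list[str]:
    """Read a ``cell_id, cell_type`` table; reorder to ``cell_ids`` if given."""
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_id", "cell_type"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    df["cell_id"] = df["cell_id"].astype(str).str.strip()
    df = df.set_index("cell_id")
    if cell_ids is not None:
        missing = [c for c in cell_ids if c not in df.index]
        if missing:
            raise DataError(f"{path}: cell types missing for cells {missing[:5]}")
        df = df.loc[list(cell_ids)]
    return [str(t) for t in df["cell_type"]]


def load_spatial_dataset(counts_path, coords_path, layout: str = "auto",
                         **kwargs) -> SpatialDataset:
    counts, pixel_ids, gene_names = load_counts(counts_path, layout, **kwargs)
    coords = load_coords(coords_path, pixel_ids=_clean_names(pixel_ids))
    return SpatialDataset.from_arrays(counts, coords, pixel_ids, gene_names)


def load_sc_dataset(counts_path, cell_types_path, layout: str = "auto",
                    **kwargs) -> SCDataset:
    counts, cell_ids, gene_names = load_counts(counts_path, layout, **kwargs)
    cell_types = load_cell_types(cell_types_path, cell_ids=_clean_names(cell_ids))
    return SCDataset(counts, cell_ids, gene_names, cell_types)


def write_spatial_dataset(ds: SpatialDataset, out_dir, layout: str = "dense") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = "mtx" if layout == "mtx" else "tsv"
    write_counts(ds.counts, ds.pixel_ids, ds.gene_names,
                 out / f"spatial_counts.{suffix}", layout)
    pd.DataFrame({"pixel_id": ds.pixel_ids,
                  "x": ds.coords[:, 0], "y": ds.coords[:, 1]}).to_csv(
        out / "coords.tsv", sep="\t", index=False, float_format="%.10g")


def write_sc_dataset(ds: SCDataset, out_dir, layout: str = "dense") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = "mtx" if layout == "mtx" else "tsv"
    write_counts(ds.counts, ds.cell_ids, ds.gene_names,
                 out / f"sc_counts.{suffix}", layout)
    pd.DataFrame({"cell_id": ds.cell_ids, "cell_type": ds.cell_types}).to_csv(
        out / "cell_types.tsv", sep="\t", index=False)


def filter_cells(sc: SCDataset, min_depth: int = 10,
                 excluded_labels=()) -> SCDataset:
    """Remove low-depth and excluded-label cells; the gene set is unchanged.

    Cells with total read count strictly below ``min_depth`` are removed
    (a depth exactly at the threshold is retained), as are cells whose label
    is in ``excluded_labels`` (e.g. "No class", "Low Quality", "Ambiguous",
    "Unstable") regardless of depth.
    """
    if min_depth < 0:
        raise DataError("min_depth must be >= 0")
    excluded = set(excluded_labels)
    keep = (sc.depths >= min_depth) & np.array(
        [t not in excluded for t in sc.cell_types])
    if not keep.any():
        raise DataError("cell filtering removed every cell")
    return SCDataset(
        counts=sc.counts[keep],
        cell_ids=[c for c, k in zip(sc.cell_ids, keep) if k],
        gene_names=sc.gene_names,
        cell_types=[t for t, k in zip(sc.cell_types, keep) if k],
    )


def rescale_normalized_to_counts(values, scale: float = 1000.0, volume=None,
                                 volume_adjust: str = "before") -> np.ndarray:
    """Convert already-normalised expression values back to integer counts.

    ``ceil(values * scale)`` elementwise (zeros map to zeros).  An optional
    per-row ``volume`` divisor supports volume adjustment; whether division
    happens ``"before"`` or ``"after"`` the scaling is the caller's choice
    (for a pure elementwise scale-then-ceil the order only matters because
    the ceiling is taken once, at the end).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise DataError("rescale input must be nonnegative")
    if scale <= 0:
        raise DataError("scale must be positive")
    if volume is not None:
        volume = np.asarray(volume, dtype=float)
        if np.any(volume <= 0):
            raise DataError("volume divisors must be positive")
        vol = volume.reshape(-1, 1) if values.ndim == 2 else volume
        if volume_adjust == "before":
            values = values / vol
        elif volume_adjust == "after":
            pass  # applied after scaling below
        else:
            raise DataError("volume_adjust must be 'before' or 'after'")
    scaled = values * scale
    if volume is not None and volume_adjust == "after":
        scaled = scaled / vol
    return np.ceil(scaled).astype(np.int64)


def pair_datasets(spatial: SpatialDataset, sc: SCDataset) -> PairedData:
    """Join modalities on exact (whitespace-trimmed, case-sensitive) gene names.

    ``shared_genes`` is the intersection in deterministic lexicographic order.
    """
    shared = sorted(set(spatial.gene_names) & set(sc.gene_names))
    if not shared:
        raise PairingError("spatial and scRNA-seq datasets share no genes")
    return PairedData(spatial=spatial, sc=sc, shared_genes=shared)


def filter_low_expression_genes(spatial: SpatialDataset,
                                min_nonzero_fraction: float = 0.01) -> SpatialDataset:
    """Drop spatial genes with nonzero counts in fewer than a fraction of pixels.

    Sparse genes carry little pattern information and are recommended for
    removal before fitting; the default keeps genes detected in at least 1%
    of pixels.
    """
    frac = (spatial.counts > 0).mean(axis=0)
    keep = [g for g, f in zip(spatial.gene_names, frac)
            if f >= min_nonzero_fraction]
    if not keep:
        raise DataError("low-expression filter removed every gene")
    return spatial.subset_genes(keep)
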