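"""Readers and writers for the on-disk formats the pipeline consumes.

Count matrices travel as 10X-style directories (MatrixMarket ``matrix.mtx``
with genes as rows, plus ``features.tsv`` and ``barcodes.tsv``, optionally
gzipped).  Cell-level metadata comes from a sample sheet TSV, cell-type
markers from a binary gene-by-type TSV, prior gene-gene links from a
two-column edge TSV, and gene sets from GMT files.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "read_10x_mtx",
    "write_10x_mtx",
    "read_sample_sheet",
    "attach_sample_sheet",
    "read_marker_panel",
    "read_edge_list",
    "read_gmt",
]

SAMPLE_SHEET_COLUMNS = ("barcode", "sample", "participant", "condition")
CONDITIONS = ("pre", "post")


def _find(dir_path: Path, stem: str) -> Path:
    """Locate ``stem`` or ``stem.gz`` inside *dir_path*."""
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{dir_path}: expected {stem}[.gz]")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_lines(path: Path) -> list[list[str]]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def read_10x_mtx(dir_path: str | Path) -> ad.AnnData:
    """Read a 10X-style directory into an AnnData (cells x genes, CSR counts).

    The MatrixMarket file stores genes as rows; the returned AnnData follows
    the cells-as-observations convention, so the matrix is transposed on
    load.  Gene identifiers come from the first column of ``features.tsv``;
    a second column, if present, is kept as ``var['gene_symbol']``.

    Raises
    ------
    ValueError
        If the matrix header dimensions disagree with the number of lines in
        ``features.tsv`` / ``barcodes.tsv`` (the offending file is named).
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    feat_path = _find(dir_path, "features.tsv")
    bc_path = _find(dir_path, "barcodes.tsv")

    with _open_text(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.coo_matrix(mat)

    features = _read_tsv_lines(feat_path)
    barcodes = _read_tsv_lines(bc_path)
    n_genes, n_cells = mat.shape
    if len(features) != n_genes:
        raise ValueError(
            f"{feat_path.name}: {len(features)} feature lines but matrix "
            f"declares {n_genes} rows"
        )
    if len(barcodes) != n_cells:
        raise ValueError(
            f"{bc_path.name}: {len(barcodes)} barcode lines but matrix "
            f"declares {n_cells} columns"
        )

    var = pd.DataFrame(index=pd.Index([f[0] for f in features], name="gene"))
    if features and len(features[0]) > 1:
        var["gene_symbol"] = [f[1] for f in features]
    obs = pd.DataFrame(index=pd.Index([b[0] for b in barcodes], name="barcode"))
    adata = ad.AnnData(X=mat.T.tocsr().astype(np.float32), obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    return adata


def write_10x_mtx(adata: ad.AnnData, dir_path: str | Path) -> None:
    """Write counts as ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``.

    Genes are stored as rows in coordinate format with 1-based indices;
    explicit zeros are dropped so sparsity is preserved on round-trip.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    mat = sp.coo_matrix(sp.csr_matrix(counts).T)
    mat.eliminate_zeros()
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), mat, field="integer")
    symbols = (
        adata.var["gene_symbol"]
        if "gene_symbol" in adata.var
        else pd.Series(adata.var_names, index=adata.var_names)
    )
    with open(dir_path / "features.tsv", "w") as fh:
        for gid, sym in zip(adata.var_names, symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        fh.writelines(f"{bc}\n" for bc in adata.obs_names)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the per-cell sample sheet (barcode, sample, participant, condition)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {missing}")
    bad = sorted(set(df["condition"]) - set(CONDITIONS))
    if bad:
        raise ValueError(
            f"sample sheet {path}: condition values must be in {CONDITIONS}, got {bad}"
        )
    if df["barcode"].duplicated().any():
        dups = df.loc[df["barcode"].duplicated(), "barcode"].head(5).tolist()
        raise ValueError(f"sample sheet {path}: duplicated barcodes, e.g. {dups}")
    return df.set_index("barcode")


def attach_sample_sheet(adata: ad.AnnData, sheet: pd.DataFrame) -> ad.AnnData:
    """Attach sample/participant/condition columns to ``adata.obs``.

    Every barcode in the matrix must appear in the sheet; the first offenders
    are listed otherwise.
    """
    missing = adata.obs_names.difference(sheet.index)
    if len(missing):
        head = list(missing[:5])
        raise ValueError(
            f"{len(missing)} matrix barcodes absent from sample sheet, "
            f"first offenders: {head}"
        )
    for col in ("sample", "participant", "condition"):
        adata.obs[col] = sheet.loc[adata.obs_names, col].to_numpy()
    return adata


def read_marker_panel(path: str | Path) -> pd.DataFrame:
    """Read a binary genes x cell-types marker table.

    Values must be strictly 0/1; rows are marker genes, columns cell types.
    """
    panel = pd.read_csv(path, sep="\t", index_col=0)
    values = panel.to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = values[~np.isin(values, (0, 1))][:3]
        raise ValueError(f"marker panel {path}: non-binary entries {bad.tolist()}")
    return panel.astype(np.int8)


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column gene-pair TSV, deduplicated as unordered pairs.

    Self-loops are dropped.  Pair order within a tuple is lexicographic so
    the result is deterministic.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"edge list {path}: expected two tab-separated columns")
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    for a, b in df.iloc[:, :2].itertuples(index=False):
        if a == b:
            continue
        pair = (a, b) if a <= b else (b, a)
        if pair not in seen:
            seen.add(pair)
            edges.append(pair)
    return edges


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file into ``{set_name: {genes}}``."""
    sets: dict[str, set[str]] = {}
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need name, description, >=1 gene"
                )
            name, genes = parts[0], {g for g in parts[2:] if g}
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return sets
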