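"""Single-cell QC filtering and marker-based lineage-origin classification.

Gut endoderm cells of extraembryonic origin co-express a marker pair
(Rhox5 and Trap1a in mouse) that embryonic-origin cells lack. After
standard QC (mitochondrial read fraction, genes detected), cells with
detected expression of both markers are classed extraembryonic, cells
with neither are embryonic, and single-marker cells are discarded; the
extraembryonic fraction per group is reported over classified
(non-discarded) cells with a Wilson score 95% interval.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse
from statsmodels.stats.proportion import proportion_confint

from .config import ThresholdConfig
from .errors import ValidationError

logger = logging.getLogger("exmeth.cell_origin")

MITO_PATTERN = r"^(mt|MT)-"

ORIGIN_LABELS = ("extraembryonic", "embryonic", "discarded")


@dataclass
class CellMatrix:
    """Cells x genes raw counts with per-cell QC metadata.

    ``counts`` is cell-major (cells in rows). ``meta`` (same index)
    carries ``mito_frac``, ``n_genes_detected`` and optionally ``group``.
    ``n_genes_detected`` is recomputed from the counts unless supplied —
    a supplied column is kept so that panel submatrices can carry QC
    metadata from the full experiment.
    """

    counts: pd.DataFrame = field(repr=False)
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        meta = self.meta.copy()
        if not counts.index.equals(meta.index):
            meta = meta.reindex(counts.index)
            if meta.isna().all(axis=1).any():
                raise ValidationError("metadata missing for some cells")
        if "n_genes_detected" not in meta.columns:
            meta["n_genes_detected"] = (counts > 0).sum(axis=1)
        meta["n_genes_detected"] = meta["n_genes_detected"].astype(int)
        if "mito_frac" not in meta.columns:
            mito_genes = [g for g in counts.columns if re.match(MITO_PATTERN, str(g))]
            if not mito_genes:
                raise ValidationError(
                    "mito_frac absent and no gene matches the mitochondrial name pattern"
                )
            total = counts.sum(axis=1)
            meta["mito_frac"] = counts[mito_genes].sum(axis=1) / total.replace(0, np.nan)
            meta["mito_frac"] = meta["mito_frac"].fillna(0.0)
        bad = (meta["mito_frac"] < 0) | (meta["mito_frac"] > 1)
        if bad.any():
            raise ValidationError("mito_frac outside [0, 1]")
        self.meta = meta

    @property
    def cells(self) -> pd.Index:
        return self.counts.index

    def n_cells(self) -> int:
        return len(self.counts)


def qc_filter_cells(matrix: CellMatrix, cfg: ThresholdConfig) -> CellMatrix:
    """Remove cells with mito_frac >= ``mito_max_frac`` (inclusive) or
    n_genes_detected < ``min_genes_per_cell`` (strict)."""
    meta = matrix.meta
    fail = (meta["mito_frac"] >= cfg.mito_max_frac) | (
        meta["n_genes_detected"] < cfg.min_genes_per_cell
    )
    kept = matrix.cells[~fail]
    logger.info("QC removed %d of %d cells", int(fail.sum()), len(meta))
    return CellMatrix(counts=matrix.counts.loc[kept], meta=meta.loc[kept])


def classify_cell_origin(
    matrix: CellMatrix,
    marker_a: str = "Rhox5",
    marker_b: str = "Trap1a",
    min_count: int = 1,
) -> pd.Series:
    """Two-marker co-expression rule for lineage origin.

    Both markers detected (count >= ``min_count``) -> extraembryonic;
    neither detected -> embryonic; exactly one -> discarded. The rule is
    symmetric in the two markers.
    """
    for marker in (marker_a, marker_b):
        if marker not in matrix.counts.columns:
            raise ValidationError(f"marker {marker!r} not in the gene index")
    a = matrix.counts[marker_a].to_numpy() >= min_count
    b = matrix.counts[marker_b].to_numpy() >= min_count
    labels = np.where(a & b, "extraembryonic", np.where(a | b, "discarded", "embryonic"))
    return pd.Series(labels, index=matrix.cells, name="origin")


def extraembryonic_fraction(
    labels: pd.Series, groups: Mapping[str, str] | pd.Series | None = None
) -> pd.DataFrame:
    """Per-group extraembryonic fraction with Wilson 95% interval.

    Discarded cells are excluded from the denominator. Groups with zero
    classified cells yield a missing fraction with a warning.
    """
    if groups is None:
        grp = pd.Series("all", index=labels.index)
    else:
        grp = pd.Series(groups).reindex(labels.index)
    rows = []
    for name, idx in labels.groupby(grp).groups.items():
        sub = labels.loc[idx]
        n_exe = int((sub == "extraembryonic").sum())
        n_emb = int((sub == "embryonic").sum())
        n = n_exe + n_emb
        if n == 0:
            logger.warning("group %r has no classified cells", name)
            rows.append({"group": name, "fraction": np.nan, "n": 0, "ci_low": np.nan, "ci_high": np.nan})
            continue
        lo, hi = proportion_confint(n_exe, n, alpha=0.05, method="wilson")
        rows.append(
            {"group": name, "fraction": n_exe / n, "n": n, "ci_low": float(lo), "ci_high": float(hi)}
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# I/O


def read_cell_matrix_mtx(
    mtx_path, genes_path, barcodes_path, meta_path=None, orientation: str = "gene_by_cell"
) -> CellMatrix:
    """Read a MatrixMarket triple (matrix + gene list + barcode list).

    ``orientation`` names the stored layout; the matrix is held
    cell-major internally. Optional per-cell metadata TSV (cell_id,
    mito_frac, n_genes_detected, group) is joined by barcode.
    """
    mat = scipy_io.mmread(mtx_path)
    if sparse.issparse(mat):
        mat = mat.toarray()
    genes = [line.split("\t")[0].strip() for line in open(genes_path) if line.strip()]
    barcodes = [line.strip() for line in open(barcodes_path) if line.strip()]
    if orientation == "gene_by_cell":
        mat = mat.T
    elif orientation != "cell_by_gene":
        raise ValidationError(f"unknown orientation {orientation!r}")
    if mat.shape != (len(barcodes), len(genes)):
        raise ValidationError(
            f"matrix shape {mat.shape} does not match {len(barcodes)} cells x {len(genes)} genes"
        )
    counts = pd.DataFrame(np.asarray(mat), index=barcodes, columns=genes)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    else:
        meta = pd.DataFrame(index=counts.index)
    return CellMatrix(counts=counts, meta=meta)


def read_cell_matrix_tsv(path, meta_path=None, orientation: str = "cell_by_gene") -> CellMatrix:
    """Read a dense TSV count matrix (row index in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "gene_by_cell":
        df = df.T
    elif orientation != "cell_by_gene":
        raise ValidationError(f"unknown orientation {orientation!r}")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path else pd.DataFrame(index=df.index)
    return CellMatrix(counts=df.astype(int), meta=meta)


def write_labels_tsv(labels: pd.Series, path) -> None:
    labels.rename_axis("cell_id").to_frame().to_csv(path, sep="\t")


def write_fractions_tsv(fractions: pd.DataFrame, path) -> None:
    fractions.to_csv(path, sep="\t", float_format="%.6f")
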