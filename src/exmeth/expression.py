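"""Expression-side thresholding, gene sets, enrichment, clustering, and
integration of promoter methylation with differential expression.

The differential-expression engine itself is not re-implemented: an
externally produced per-gene (log2FC, adjusted P) table is a first-class
input, and :func:`simple_de_test` provides a plain two-group location
test (Welch's t on log2(TPM+1) with Benjamini-Hochberg correction) for
synthetic runs. The bespoke logic — strict thresholds, set construction,
X-enrichment, and the methylation-delta vs fold-change integration —
lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .config import ThresholdConfig
from .errors import ValidationError
from .meth_io import FeatureSet

logger = logging.getLogger("exmeth.expression")


@dataclass
class ExpressionTable:
    """Genes x samples TPM matrix with per-gene metadata.

    ``tpm`` is indexed by gene_id with one column per sample; ``meta``
    (same index) carries at least ``chrom`` and ``is_protein_coding``.
    """

    tpm: pd.DataFrame = field(repr=False)
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValidationError("negative TPM value")
        missing = self.tpm.index.difference(self.meta.index)
        if len(missing):
            raise ValidationError(f"genes missing from metadata: {list(missing[:3])}...")
        self.meta = self.meta.loc[self.tpm.index]

    @property
    def genes(self) -> pd.Index:
        return self.tpm.index

    @property
    def samples(self) -> pd.Index:
        return self.tpm.columns


def filter_expressed_genes(
    expr: ExpressionTable,
    tpm_min: float = 1.0,
    min_samples: int = 4,
    drop_chroms: Iterable[str] = ("chrY", "Y"),
    protein_coding_only: bool = True,
) -> pd.Index:
    """Genes with TPM > ``tpm_min`` (strict) in at least ``min_samples``
    samples, minus the excluded chromosomes, restricted to protein-coding."""
    if min_samples > expr.tpm.shape[1]:
        raise ValidationError(
            f"min_samples={min_samples} exceeds sample count {expr.tpm.shape[1]}"
        )
    detected = (expr.tpm > tpm_min).sum(axis=1) >= min_samples
    keep = detected
    keep &= ~expr.meta["chrom"].isin(set(drop_chroms))
    if protein_coding_only and "is_protein_coding" in expr.meta.columns:
        keep &= expr.meta["is_protein_coding"].astype(bool)
    return expr.genes[keep]


def classify_de_genes(de: pd.DataFrame, cfg: ThresholdConfig) -> pd.DataFrame:
    """Three-way high/low/ns classification with strict cutoffs.

    ``de`` needs columns ``log2fc`` and ``padj`` indexed by gene. high:
    log2fc > cutoff and padj < alpha; low: log2fc < -cutoff and padj <
    alpha; anything else (including missing padj, with a warning) is ns.
    """
    log2fc = de["log2fc"].astype(float)
    padj = de["padj"].astype(float)
    n_missing = int(padj.isna().sum())
    if n_missing:
        logger.warning("%d genes lack an adjusted P and are classed ns", n_missing)
    sig = padj < cfg.padj_cutoff
    cls = pd.Series("ns", index=de.index, name="class")
    cls[sig & (log2fc > cfg.lfc_cutoff)] = "high"
    cls[sig & (log2fc < -cfg.lfc_cutoff)] = "low"
    out = de.copy()
    out["class"] = cls
    return out


def simple_de_test(expr: ExpressionTable, group_labels: Mapping[str, str]) -> pd.DataFrame:
    """Two-group comparison on log2(TPM+1): Welch's t, BH-adjusted.

    ``group_labels`` maps sample -> "test"/"ref". log2fc is the mean
    log2(TPM+1) difference (test minus ref). This is a plain location
    test for synthetic data, not a count-model fit.
    """
    groups: dict[str, list[str]] = {"test": [], "ref": []}
    for s in expr.samples:
        g = group_labels.get(str(s))
        if g in groups:
            groups[g].append(str(s))
    if len(groups["test"]) < 2 or len(groups["ref"]) < 2:
        raise ValidationError("each group needs at least 2 samples")
    log_tpm = np.log2(expr.tpm + 1.0)
    a = log_tpm[groups["test"]].to_numpy()
    b = log_tpm[groups["ref"]].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "padj": padj}, index=expr.genes
    )


def flag_exon_dmr_overlap(exons: FeatureSet, dmrs: pd.DataFrame) -> pd.Series:
    """Per-gene flag: does any exon overlap a DMR interval?

    ``exons`` carries gene ids in an ``attributes``-style ``gene_id``
    column (falling back to ``feature_id``); ``dmrs`` needs columns
    chrom/start/end.
    """
    edf = exons.df
    gene_col = "gene_id" if "gene_id" in edf.columns else "feature_id"
    flags: dict[str, bool] = {g: False for g in edf[gene_col].unique()}
    by_chrom = {str(c): g for c, g in dmrs.groupby("chrom")}
    for row in edf.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        hit = (sub["start"].to_numpy() < row.end) & (sub["end"].to_numpy() > row.start)
        if hit.any():
            flags[getattr(row, gene_col)] = True
    return pd.Series(flags, name="exon_dmr_overlap")


def define_methylation_sensitive_genes(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    cfg: ThresholdConfig,
    group_label: str = "group3",
) -> set[str]:
    """Union of two knockout-derived criteria for methylation sensitivity.

    Criterion A: upregulated (log2fc > cutoff, padj < alpha) with an exon
    overlapping a hypomethylated DMR (boolean ``exon_dmr_overlap``).
    Criterion B: upregulated with a highly methylated CpG-rich promoter
    class (``promoter_group == group_label``).
    """
    def upreg(df: pd.DataFrame) -> pd.Series:
        return (df["log2fc"] > cfg.lfc_cutoff) & (df["padj"] < cfg.padj_cutoff)

    set_a = set(de_a.index[upreg(de_a) & de_a["exon_dmr_overlap"].astype(bool)])
    set_b = set(de_b.index[upreg(de_b) & (de_b["promoter_group"] == group_label)])
    return set_a | set_b


def enrichment_test(
    hit_set: Iterable[str], universe: Iterable[str], flagged: Iterable[str]
) -> tuple[np.ndarray, float, float]:
    """Two-sided exact test of a per-gene flag within a hit set.

    Returns the 2x2 table [[flagged hits, unflagged hits], [flagged
    non-hits, unflagged non-hits]], the odds ratio and the two-sided
    Fisher exact P.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    hits = set(hit_set) & universe
    flagged = set(flagged) & universe
    a = len(hits & flagged)
    b = len(hits) - a
    c = len(flagged) - a
    d = len(universe) - len(hits) - c
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)


def overrepresentation(
    hit_set: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    cfg: ThresholdConfig,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation over a set collection.

    Sets are restricted to the universe; sets outside
    [``ora_min_set``, ``ora_max_set``] are excluded. Returns all tested
    sets with BH q-values and a ``top`` flag marking the ``ora_top``
    smallest-p sets.
    """
    universe = set(universe)
    hits = set(hit_set) & universe
    if not hits:
        raise ValidationError("hit set does not intersect the universe")
    rows = []
    for name, members in collection.items():
        members = set(members) & universe
        if not (cfg.ora_min_set <= len(members) <= cfg.ora_max_set):
            continue
        overlap = len(hits & members)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(hits)))
        rows.append({"set": name, "n_set": len(members), "overlap": overlap, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q=pd.Series(dtype=float), top=pd.Series(dtype=bool))
    _, q, _, _ = multipletests(df["p"], method="fdr_bh")
    df["q"] = q
    df = df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    df["top"] = False
    df.loc[: cfg.ora_top - 1, "top"] = True
    return df


def exclude_x_escape_genes(genes: Iterable[str], escape_list: Iterable[str]) -> set[str]:
    """Plain set difference against a user-supplied X-inactivation escape list."""
    return set(genes) - set(escape_list)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores; constant rows are dropped with a warning."""
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant rows dropped before z-scoring", int(constant.sum()))
    kept = matrix.loc[~constant]
    vals = kept.to_numpy(dtype=float)
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=0, keepdims=True)
    return pd.DataFrame(z, index=kept.index, columns=kept.columns)


def zscore_kmeans(
    matrix: pd.DataFrame,
    k: int,
    iters: int = 1000,
    starts: int = 100,
    seed: int = 0,
) -> pd.Series:
    """k-means on row z-scores; best of ``starts`` random initializations.

    Deterministic under a fixed seed. Raises when fewer than k
    non-constant rows remain.
    """
    z = zscore_rows(matrix)
    if k > len(z):
        raise ValidationError(f"k={k} exceeds the {len(z)} non-constant rows")
    km = KMeans(
        n_clusters=k, n_init=starts, max_iter=iters, random_state=seed, algorithm="lloyd"
    )
    labels = km.fit_predict(z.to_numpy())
    return pd.Series(labels, index=z.index, name="cluster")


def integrate_delta_vs_lfc(
    de: pd.DataFrame,
    promoter_test: pd.DataFrame,
    promoter_ref: pd.DataFrame,
    e65_direction: pd.Series | None = None,
) -> tuple[pd.DataFrame, float, float, int]:
    """Join differential expression with promoter methylation deltas.

    ``de`` is a classified table (log2fc, padj, class); the promoter
    frames are per-gene level tables (gene_id, level, density_class).
    Returns the per-gene table over high+low genes, the Spearman rank
    correlation (rho, p) between delta promoter methylation (test minus
    reference) and log2FC over those genes, and the number of
    differential genes excluded for missing promoter levels.
    """
    diff = de[de["class"].isin(["high", "low"])]
    if diff.empty:
        raise ValidationError("no differential genes")
    pt = promoter_test.set_index("gene_id") if "gene_id" in promoter_test.columns else promoter_test
    pr = promoter_ref.set_index("gene_id") if "gene_id" in promoter_ref.columns else promoter_ref
    rows = []
    n_excluded = 0
    for gene in diff.index:
        if gene not in pt.index or gene not in pr.index:
            n_excluded += 1
            continue
        lt, lr = float(pt.loc[gene, "level"]), float(pr.loc[gene, "level"])
        if np.isnan(lt) or np.isnan(lr):
            n_excluded += 1
            continue
        row = {
            "gene_id": gene,
            "log2fc": float(diff.loc[gene, "log2fc"]),
            "class": diff.loc[gene, "class"],
            "delta_promoter": lt - lr,
            "density_class": pt.loc[gene].get("density_class", "unclassified"),
        }
        if e65_direction is not None:
            row["e65_direction"] = e65_direction.get(gene, "neither")
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene_id")
    if len(table) < 2:
        raise ValidationError("fewer than 2 differential genes with promoter levels")
    rho, p = stats.spearmanr(table["delta_promoter"], table["log2fc"])
    return table, float(rho), float(p), n_excluded
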