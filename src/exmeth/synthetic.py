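"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the qualitative structure of the biological
contrast the analysis targets: an embryonic-type methylome with high
global methylation and unmethylated CGIs, an extraembryonic-type
methylome with intermediate global methylation and a planted subset of
hypermethylated CGIs, binomial read sampling at realistic coverage,
expression coupled to promoter methylation (unmethylated test-tissue
promoters for planted high genes, hypermethylated CGI promoters for
planted low genes), and a rare cell population co-expressing the two
origin markers. Distributional choices (Beta mixtures for per-CpG
rates, over-dispersed coverage, zero-truncated Poisson marker counts)
are the module's own; all knobs live in :class:`SimConfig` and the same
seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .cell_origin import CellMatrix
from .errors import ConfigError, ValidationError
from .expression import ExpressionTable
from .meth_io import (
    CpGCallTable,
    FeatureSet,
    write_chrom_sizes,
    write_cpg_calls,
    write_features,
)


@dataclass
class SimConfig:
    """All parameters of the synthetic study.

    Methylation states are (mean, concentration) pairs of Beta
    distributions for per-CpG true rates; coverage is an over-dispersed
    count distribution (1 + negative binomial) with the given mean.
    """

    seed: int = 0
    n_autosomes: int = 3
    include_x: bool = True
    chrom_length: int = 2_000_000
    background_cpg_spacing: float = 100.0   # geometric mean, bp
    n_cgis: int = 300
    cgi_cpg_spacing: float = 12.0           # mean bp between CpGs inside a CGI
    cgi_len_min: int = 200
    cgi_len_max: int = 1500
    cgi_min_cpgs: int = 15
    n_genes: int = 400
    cgi_promoter_frac: float = 0.6          # fraction of genes with TSS at a CGI
    gene_length: int = 5000
    # per-CpG true methylation (mean, concentration)
    emb_background_meth: tuple = (0.80, 10.0)
    emb_cgi_meth: tuple = (0.05, 40.0)
    exe_background_meth: tuple = (0.55, 10.0)
    exe_hyper_cgi_meth: tuple = (0.45, 20.0)
    planted_hyper_fraction: float = 0.30
    replicate_jitter_conc: float = 200.0    # Beta concentration of replicate noise
    coverage_mean: float = 15.0
    coverage_dispersion: float = 5.0        # NB shape; smaller = more over-dispersed
    n_replicates: int = 2
    # expression: 4 tissues x 4 replicates = 16 samples
    n_expr_replicates: int = 4
    n_high_genes: int = 40
    n_low_genes: int = 40
    x_share_high: float = 0.2
    fold_log2_min: float = 2.0              # planted fold change 2^U(min, max)
    fold_log2_max: float = 4.0
    tpm_baseline_log_mean: float = float(np.log(10.0))
    tpm_baseline_log_sd: float = 1.0
    tpm_noise_log_sd: float = 0.15
    # cells
    n_cells: int = 2000
    exe_cell_fraction: float = 0.04
    marker_mean_count: float = 3.0
    ambient_noise_frac: float = 0.01        # embryonic cells gaining one marker
    n_panel_genes: int = 100
    qc_fail_frac: float = 0.05
    marker_a: str = "Rhox5"
    marker_b: str = "Trap1a"

    def __post_init__(self) -> None:
        for name in (
            "cgi_promoter_frac", "planted_hyper_fraction", "x_share_high",
            "exe_cell_fraction", "ambient_noise_frac", "qc_fail_frac",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_high_genes + self.n_low_genes > self.n_genes:
            raise ConfigError("planted gene counts exceed n_genes")
        if self.cgi_len_min < self.cgi_min_cpgs:
            raise ConfigError("CGIs too short to hold the minimum CpG count")
        needed = self.n_cgis / max(self.n_autosomes + int(self.include_x), 1)
        if needed * (self.cgi_len_max + 10_000) > self.chrom_length:
            raise ConfigError("CGI density infeasible for the chromosome length")


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    cpg_pos: dict[str, np.ndarray]          # all CpG positions, sorted
    cgis: FeatureSet
    genes: FeatureSet
    gene_cgi: dict[str, str | None]         # promoter CGI per gene (None = LCP)
    cgi_cpg_index: dict[str, tuple[str, int, int]]  # cgi -> (chrom, lo, hi) slice


@dataclass
class TruthManifest:
    """Planted ground truth, id-resolvable against the emitted files."""

    hyper_cgi_ids: list[str] = field(default_factory=list)
    gene_truth: pd.DataFrame = field(default_factory=pd.DataFrame)  # class, promoter state
    cell_origin: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def _beta(rng: np.random.Generator, mean: float, conc: float, size) -> np.ndarray:
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=size)


def simulate_genome(cfg: SimConfig) -> Genome:
    """Chromosomes, CpG positions, non-overlapping CGIs and genes.

    CGIs are spread over equal-sized blocks per chromosome (so they never
    overlap) and each contains at least ``cgi_min_cpgs`` CpGs placed
    uniformly at the configured density. A configurable fraction of
    genes put their TSS at a CGI midpoint; the rest (LCP genes) are
    placed so that their promoter overlaps no CGI. CGI O/E ratios are
    drawn so that planted HCP promoters exceed the HCP cutoff.
    """
    rng = _rng(cfg, 1)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_autosomes)]
    if cfg.include_x:
        chroms.append("chrX")
    chrom_sizes = {c: cfg.chrom_length for c in chroms}

    # --- CGIs, round-robin over chromosomes, one per block
    n_chroms = len(chroms)
    cgi_chrom = [chroms[i % n_chroms] for i in range(cfg.n_cgis)]
    per_chrom: dict[str, int] = {c: cgi_chrom.count(c) for c in chroms}
    cgi_rows = []
    cgi_cpgs: dict[str, np.ndarray] = {}
    idx = 0
    for chrom in chroms:
        k = per_chrom[chrom]
        if k == 0:
            continue
        block = cfg.chrom_length // k
        margin = cfg.cgi_len_max + 2000
        if block <= 2 * margin:
            raise ConfigError("CGI density infeasible for the chromosome length")
        for b in range(k):
            length = int(rng.integers(cfg.cgi_len_min, cfg.cgi_len_max + 1))
            start = b * block + int(rng.integers(margin, block - margin - length))
            end = start + length
            n_cpg = max(cfg.cgi_min_cpgs, int(round(length / cfg.cgi_cpg_spacing)))
            offs = np.sort(rng.choice(length, size=n_cpg, replace=False))
            cgi_id = f"CGI_{idx:04d}"
            idx += 1
            cgi_rows.append(
                {
                    "feature_id": cgi_id,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": ".",
                    "kind": "cgi",
                    "obs_exp": np.nan,  # filled after gene planting
                }
            )
            cgi_cpgs[cgi_id] = (start + offs).astype(np.int64)
    cgi_df = pd.DataFrame(cgi_rows)

    # --- background CpGs with geometric spacing, outside CGIs
    cpg_pos: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n_draw = int(cfg.chrom_length / cfg.background_cpg_spacing * 1.3) + 100
        gaps = rng.geometric(1.0 / cfg.background_cpg_spacing, size=n_draw)
        pos = np.cumsum(gaps)
        pos = pos[pos < cfg.chrom_length].astype(np.int64)
        sub = cgi_df[cgi_df["chrom"] == chrom]
        mask = np.ones(len(pos), dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            mask &= ~((pos >= s) & (pos < e))
        inside = np.concatenate(
            [cgi_cpgs[cid] for cid in sub["feature_id"]]
        ) if len(sub) else np.empty(0, dtype=np.int64)
        merged = np.unique(np.concatenate([pos[mask], inside]))
        cpg_pos[chrom] = merged

    # index each CGI's CpG slice in the merged per-chromosome arrays
    cgi_cpg_index: dict[str, tuple[str, int, int]] = {}
    for row in cgi_df.itertuples(index=False):
        arr = cpg_pos[row.chrom]
        lo = int(np.searchsorted(arr, row.start, side="left"))
        hi = int(np.searchsorted(arr, row.end, side="left"))
        cgi_cpg_index[row.feature_id] = (row.chrom, lo, hi)

    # --- genes
    n_cgi_genes = int(round(cfg.cgi_promoter_frac * cfg.n_genes))
    n_cgi_genes = min(n_cgi_genes, cfg.n_cgis)
    chosen_cgis = rng.choice(cgi_df["feature_id"].to_numpy(), size=n_cgi_genes, replace=False)
    cgi_lookup = cgi_df.set_index("feature_id")
    gene_rows = []
    gene_cgi: dict[str, str | None] = {}
    gid = 0
    for cgi_id in chosen_cgis:
        row = cgi_lookup.loc[cgi_id]
        tss = int((row["start"] + row["end"]) // 2)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = tss, min(tss + cfg.gene_length, cfg.chrom_length)
        else:
            start, end = max(0, tss - cfg.gene_length), tss
        gene_id = f"gene_{gid:04d}"
        gid += 1
        gene_rows.append(
            {"feature_id": gene_id, "chrom": row["chrom"], "start": start,
             "end": end, "strand": strand, "kind": "gene"}
        )
        gene_cgi[gene_id] = str(cgi_id)
    # LCP genes: promoters clear of every CGI
    n_lcp = cfg.n_genes - n_cgi_genes
    lcp_chroms = [chroms[i % n_chroms] for i in range(n_lcp)]
    cgi_by_chrom = {c: cgi_df[cgi_df["chrom"] == c] for c in chroms}
    for chrom in lcp_chroms:
        sub = cgi_by_chrom[chrom]
        starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
        for _ in range(1000):
            tss = int(rng.integers(2000, cfg.chrom_length - 2000))
            if not ((starts < tss + 600) & (ends > tss - 600)).any():
                break
        else:  # pragma: no cover - density made infeasible
            raise ValidationError("could not place an LCP gene clear of CGIs")
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = tss, min(tss + cfg.gene_length, cfg.chrom_length)
        else:
            start, end = max(0, tss - cfg.gene_length), tss
        gene_id = f"gene_{gid:04d}"
        gid += 1
        gene_rows.append(
            {"feature_id": gene_id, "chrom": chrom, "start": start,
             "end": end, "strand": strand, "kind": "gene"}
        )
        gene_cgi[gene_id] = None
    gene_df = pd.DataFrame(gene_rows)

    # --- O/E ratios: promoter CGIs split into planted HCP/ICP halves
    oe = pd.Series(index=cgi_df["feature_id"], dtype=float)
    promoter_cgis = list(map(str, chosen_cgis))
    half = len(promoter_cgis) // 2
    hcp_cgis = promoter_cgis[:half]
    icp_cgis = promoter_cgis[half:]
    oe.loc[hcp_cgis] = rng.uniform(0.85, 1.20, size=len(hcp_cgis))
    oe.loc[icp_cgis] = rng.uniform(0.50, 0.80, size=len(icp_cgis))
    rest = oe.index[oe.isna()]
    oe.loc[rest] = rng.uniform(0.50, 1.10, size=len(rest))
    cgi_df["obs_exp"] = oe.to_numpy()

    return Genome(
        chrom_sizes=chrom_sizes,
        cpg_pos=cpg_pos,
        cgis=FeatureSet(cgi_df),
        genes=FeatureSet(gene_df),
        gene_cgi=gene_cgi,
        cgi_cpg_index=cgi_cpg_index,
    )


def simulate_methylomes(
    cfg: SimConfig, genome: Genome
) -> tuple[dict[str, list[CpGCallTable]], list[str]]:
    """Per-tissue replicate call tables plus the planted hyper-CGI ids.

    Tissues are ``exe`` (extraembryonic-type, test) and ``emb``
    (embryonic/epiblast-type, reference). Hyper CGIs are planted on
    autosomes, where the CGI classification operates.
    """
    rng = _rng(cfg, 2)
    cgi_df = genome.cgis.df
    autosomal = cgi_df.loc[cgi_df["chrom"] != "chrX", "feature_id"].to_numpy()
    n_hyper = int(round(cfg.planted_hyper_fraction * cfg.n_cgis))
    if n_hyper > len(autosomal):
        raise ConfigError("not enough autosomal CGIs for the planted hyper fraction")
    hyper_ids = sorted(rng.choice(autosomal, size=n_hyper, replace=False).tolist())
    hyper_set = set(hyper_ids)

    # per-CpG context: 0 = background, 1 = CGI, 2 = planted-hyper CGI
    context: dict[str, np.ndarray] = {
        c: np.zeros(len(p), dtype=np.int8) for c, p in genome.cpg_pos.items()
    }
    for cgi_id, (chrom, lo, hi) in genome.cgi_cpg_index.items():
        context[chrom][lo:hi] = 2 if cgi_id in hyper_set else 1

    def true_rates(tissue: str, ctx: np.ndarray) -> np.ndarray:
        n = len(ctx)
        out = np.empty(n)
        if tissue == "emb":
            bg, cgi, hyper = cfg.emb_background_meth, cfg.emb_cgi_meth, cfg.emb_cgi_meth
        else:
            bg, cgi, hyper = cfg.exe_background_meth, cfg.emb_cgi_meth, cfg.exe_hyper_cgi_meth
        for code, (mean, conc) in ((0, bg), (1, cgi), (2, hyper)):
            mask = ctx == code
            out[mask] = _beta(rng, mean, conc, int(mask.sum()))
        return out

    nb_n = cfg.coverage_dispersion
    nb_mean = cfg.coverage_mean - 1.0
    nb_p = nb_n / (nb_n + nb_mean)
    tables: dict[str, list[CpGCallTable]] = {"exe": [], "emb": []}
    for tissue in ("emb", "exe"):
        rates = {c: true_rates(tissue, ctx) for c, ctx in context.items()}
        for rep in range(1, cfg.n_replicates + 1):
            frames = []
            for chrom in genome.cpg_pos:
                r = np.clip(rates[chrom], 1e-3, 1 - 1e-3)
                kappa = cfg.replicate_jitter_conc
                r_rep = rng.beta(r * kappa, (1 - r) * kappa)
                total = 1 + rng.negative_binomial(nb_n, nb_p, size=len(r))
                meth = rng.binomial(total, r_rep)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": genome.cpg_pos[chrom],
                            "rate": meth / total,
                            "meth": meth,
                            "total": total,
                        }
                    )
                )
            df = pd.concat(frames, ignore_index=True)
            tables[tissue].append(CpGCallTable(sample_id=f"{tissue}_rep{rep}", df=df))
    return tables, hyper_ids


def simulate_expression(
    cfg: SimConfig, genome: Genome, hyper_cgi_ids: list[str]
) -> tuple[ExpressionTable, pd.DataFrame]:
    """TPM table (4 tissues x replicates) with methylation-coupled planting.

    Planted low genes sit on planted hyper CGIs (promoter gains
    methylation in the test tissue, expression drops); planted high
    genes are LCP genes (promoter follows the globally lower test-tissue
    background, expression rises), with the configured share of them
    X-linked. Neutral genes differ only by noise.
    """
    rng = _rng(cfg, 3)
    hyper_set = set(hyper_cgi_ids)
    genes = genome.genes.df.set_index("feature_id")
    gene_ids = list(genes.index)

    low_pool = [g for g, c in genome.gene_cgi.items() if c in hyper_set]
    if len(low_pool) < cfg.n_low_genes:
        raise ValidationError(
            f"only {len(low_pool)} genes sit on planted hyper CGIs; "
            f"{cfg.n_low_genes} planted low genes requested"
        )
    low_genes = sorted(rng.choice(low_pool, size=cfg.n_low_genes, replace=False).tolist())

    lcp_pool = [g for g, c in genome.gene_cgi.items() if c is None]
    n_high_x = int(round(cfg.x_share_high * cfg.n_high_genes))
    x_pool = [g for g in lcp_pool if genes.loc[g, "chrom"] == "chrX"]
    a_pool = [g for g in lcp_pool if genes.loc[g, "chrom"] != "chrX"]
    if len(x_pool) < n_high_x or len(a_pool) < cfg.n_high_genes - n_high_x:
        raise ValidationError("not enough LCP genes to plant the high set")
    high_genes = sorted(
        rng.choice(x_pool, size=n_high_x, replace=False).tolist()
        + rng.choice(a_pool, size=cfg.n_high_genes - n_high_x, replace=False).tolist()
    )

    tissues = ["ex_mid", "ex_hind", "em_mid", "em_hind"]
    samples = [f"{t}_rep{i}" for t in tissues for i in range(1, cfg.n_expr_replicates + 1)]
    base = rng.lognormal(cfg.tpm_baseline_log_mean, cfg.tpm_baseline_log_sd, size=len(gene_ids))
    base = pd.Series(base, index=gene_ids)
    fold = pd.Series(1.0, index=gene_ids)
    high_fold = 2.0 ** rng.uniform(cfg.fold_log2_min, cfg.fold_log2_max, size=len(high_genes))
    low_fold = 2.0 ** rng.uniform(cfg.fold_log2_min, cfg.fold_log2_max, size=len(low_genes))
    fold.loc[high_genes] = high_fold
    fold.loc[low_genes] = 1.0 / low_fold

    cols = {}
    for s in samples:
        is_test = s.startswith("ex_")
        mean = base * fold if is_test else base
        noise = rng.lognormal(0.0, cfg.tpm_noise_log_sd, size=len(gene_ids))
        cols[s] = mean.to_numpy() * noise
    tpm = pd.DataFrame(cols, index=gene_ids)
    meta = pd.DataFrame(
        {"chrom": genes["chrom"], "is_protein_coding": True}, index=genes.index
    )

    cls = pd.Series("neutral", index=gene_ids, name="planted_class")
    cls.loc[high_genes] = "high"
    cls.loc[low_genes] = "low"
    promoter_state = pd.Series("cgi_stable", index=gene_ids, name="planted_promoter")
    for g in gene_ids:
        cgi = genome.gene_cgi[g]
        if cgi is None:
            promoter_state.loc[g] = "lcp_background"
        elif cgi in hyper_set:
            promoter_state.loc[g] = "cgi_hyper"
    gene_truth = pd.DataFrame(
        {"planted_class": cls, "planted_promoter": promoter_state,
         "chrom": genes["chrom"]}
    )
    return ExpressionTable(tpm=tpm, meta=meta), gene_truth


def simulate_cells(cfg: SimConfig) -> tuple[CellMatrix, pd.Series]:
    """Cell x gene counts with planted origins and QC structure.

    Exactly ``round(exe_cell_fraction * n_cells)`` cells are
    extraembryonic; they draw both markers from a zero-truncated Poisson
    (mean ``marker_mean_count``) so that a planted cell is always
    detectable, while embryonic cells carry structural zeros at both
    markers. A small configurable fraction of embryonic cells gains one
    ambient marker count (these become "discarded"), and an
    origin-independent share of cells is drawn to fail QC. The panel
    matrix carries full-experiment QC metadata (n_genes_detected,
    mito_frac) drawn per cell.
    """
    rng = _rng(cfg, 4)
    n = cfg.n_cells
    cell_ids = [f"cell_{i:05d}" for i in range(n)]
    n_exe = int(round(cfg.exe_cell_fraction * n))
    exe_idx = rng.choice(n, size=n_exe, replace=False)
    origin = np.full(n, "embryonic", dtype=object)
    origin[exe_idx] = "extraembryonic"

    panel = [cfg.marker_a, cfg.marker_b] + [
        f"pan_{i:03d}" for i in range(cfg.n_panel_genes - 2)
    ]
    gene_means = rng.lognormal(np.log(2.0), 1.0, size=len(panel) - 2)
    counts = np.zeros((n, len(panel)), dtype=np.int64)
    counts[:, 2:] = rng.poisson(gene_means, size=(n, len(panel) - 2))
    # zero-truncated Poisson markers in extraembryonic cells
    lam = max(cfg.marker_mean_count - 1.0, 0.0)
    counts[exe_idx, 0] = 1 + rng.poisson(lam, size=n_exe)
    counts[exe_idx, 1] = 1 + rng.poisson(lam, size=n_exe)
    # ambient single-marker noise in embryonic cells
    emb_idx = np.setdiff1d(np.arange(n), exe_idx)
    n_ambient = int(round(cfg.ambient_noise_frac * len(emb_idx)))
    if n_ambient:
        amb = rng.choice(emb_idx, size=n_ambient, replace=False)
        which = rng.integers(0, 2, size=n_ambient)
        counts[amb, which] = 1

    # QC metadata, independent of origin
    n_genes_meta = np.maximum(
        2100, np.round(rng.normal(4500, 800, size=n)).astype(int)
    )
    mito = rng.uniform(0.0, 0.10, size=n)
    n_fail = int(round(cfg.qc_fail_frac * n))
    if n_fail:
        fail_idx = rng.choice(n, size=n_fail, replace=False)
        mode = rng.random(n_fail) < 0.5
        n_genes_meta[fail_idx[mode]] = rng.integers(500, 2000, size=int(mode.sum()))
        mito[fail_idx[~mode]] = rng.uniform(0.15, 0.60, size=int((~mode).sum()))
    organ = np.where(rng.random(n) < 0.5, "colon", "small_intestine")

    meta = pd.DataFrame(
        {
            "mito_frac": mito,
            "n_genes_detected": n_genes_meta,
            "group": organ,
        },
        index=cell_ids,
    )
    matrix = CellMatrix(
        counts=pd.DataFrame(counts, index=cell_ids, columns=panel), meta=meta
    )
    truth = pd.Series(origin, index=cell_ids, name="planted_origin")
    return matrix, truth


@dataclass
class SimResult:
    config: SimConfig
    genome: Genome
    methylomes: dict[str, list[CpGCallTable]]
    expression: ExpressionTable
    gene_truth: pd.DataFrame
    cells: CellMatrix
    truth: TruthManifest


def simulate_all(cfg: SimConfig) -> SimResult:
    """Run every generator stage under one seed."""
    genome = simulate_genome(cfg)
    methylomes, hyper_ids = simulate_methylomes(cfg, genome)
    expression, gene_truth = simulate_expression(cfg, genome, hyper_ids)
    cells, cell_truth = simulate_cells(cfg)
    truth = TruthManifest(
        hyper_cgi_ids=hyper_ids, gene_truth=gene_truth, cell_origin=cell_truth
    )
    return SimResult(
        config=cfg,
        genome=genome,
        methylomes=methylomes,
        expression=expression,
        gene_truth=gene_truth,
        cells=cells,
        truth=truth,
    )


def write_simulation(result: SimResult, out_dir) -> None:
    """Emit the full simulated study as plain-text files.

    Layout: chrom.sizes, cgis.bed, genes.bed, <tissue>_rep<k>.methcalls.tsv,
    tpm.tsv, gene_meta.tsv, cells.mtx (+ cells_genes.tsv, cells_barcodes.tsv,
    cell_meta.tsv), truth/*.tsv and sim_config.yaml.
    """
    import yaml

    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(result.genome.chrom_sizes, out / "chrom.sizes")
    write_features(result.genome.cgis, out / "cgis.bed")
    write_features(result.genome.genes, out / "genes.bed")
    for tissue, reps in result.methylomes.items():
        for table in reps:
            write_cpg_calls(table, out / f"{table.sample_id}.methcalls.tsv")
    result.expression.tpm.rename_axis("gene_id").to_csv(
        out / "tpm.tsv", sep="\t", float_format="%.4f"
    )
    result.expression.meta.rename_axis("gene_id").to_csv(out / "gene_meta.tsv", sep="\t")
    mat = sparse.coo_matrix(result.cells.counts.to_numpy())
    scipy_io.mmwrite(str(out / "cells.mtx"), mat)
    with open(out / "cells_genes.tsv", "wt") as fh:
        fh.write("".join(f"{g}\n" for g in result.cells.counts.columns))
    with open(out / "cells_barcodes.tsv", "wt") as fh:
        fh.write("".join(f"{c}\n" for c in result.cells.counts.index))
    result.cells.meta.rename_axis("cell_id").to_csv(
        out / "cell_meta.tsv", sep="\t", float_format="%.6f"
    )
    with open(out / "truth" / "hyper_cgis.tsv", "wt") as fh:
        fh.write("cgi_id\n")
        fh.write("".join(f"{c}\n" for c in result.truth.hyper_cgi_ids))
    result.truth.gene_truth.rename_axis("gene_id").to_csv(
        out / "truth" / "genes.tsv", sep="\t"
    )
    result.truth.cell_origin.rename_axis("cell_id").to_frame().to_csv(
        out / "truth" / "cells.tsv", sep="\t"
    )
    with open(out / "sim_config.yaml", "wt") as fh:
        yaml.safe_dump(
            {"simulation": _config_as_plain_dict(result.config)}, fh, sort_keys=True
        )


def _config_as_plain_dict(cfg: SimConfig) -> dict:
    data = asdict(cfg)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}


def simconfig_from_mapping(data: dict) -> SimConfig:
    """Build a SimConfig from a dict, rejecting unknown keys."""
    import dataclasses

    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown simulation key(s): {', '.join(unknown)}")
    clean = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return SimConfig(**clean)
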