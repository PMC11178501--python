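"""End-to-end orchestration: simulate -> aggregate -> hyper-CGI ->
promoters -> differential expression -> integration -> cells.

The demo pipeline writes every stage result as a tab-separated file and
a machine-readable ``manifest.json`` recording inputs, thresholds with
provenance, stage counts and output checksums. Runs are deterministic
under a fixed seed: the manifest contains no timestamps or absolute
paths, so two runs with the same seed produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_origin import (
    classify_cell_origin,
    extraembryonic_fraction,
    qc_filter_cells,
    read_cell_matrix_mtx,
    write_fractions_tsv,
    write_labels_tsv,
)
from .config import ThresholdConfig, resolved_thresholds
from .errors import ExmethError
from .expression import (
    ExpressionTable,
    classify_de_genes,
    enrichment_test,
    filter_expressed_genes,
    integrate_delta_vs_lfc,
    simple_de_test,
    zscore_kmeans,
)
from .feature_methylation import (
    aggregate_feature_methylation,
    annotate_promoters,
    classify_promoter_direction,
    promoter_levels_table,
)
from .genome_features import assign_promoter_cgis, define_promoters, make_tiles
from .hypercgi import hyper_cgi_pipeline, hyper_results_frame
from .meth_io import (
    CoverageFilter,
    FeatureSet,
    filter_coverage,
    merge_replicates,
    read_chrom_sizes,
    read_cpg_calls,
    read_features,
    write_features,
)
from .synthetic import SimConfig, simulate_all, write_simulation

logger = logging.getLogger("exmeth.pipeline")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    out_dir,
    thresholds: ThresholdConfig | None = None,
    sim_config: SimConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full demo analysis on freshly simulated data.

    Returns the manifest dict (also written to ``manifest.json``).
    Every simulated file is written to disk and read back through the
    package's own readers before analysis, exercising the I/O contract.
    """
    th = thresholds or ThresholdConfig()
    sim = sim_config or SimConfig()
    if seed is not None:
        sim = SimConfig(**{**_sim_dict(sim), "seed": int(seed)})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = out / "sim"
    sim_dir.mkdir(exist_ok=True)

    # --- simulate and round-trip through files
    result = simulate_all(sim)
    write_simulation(result, sim_dir)
    chrom_sizes = read_chrom_sizes(sim_dir / "chrom.sizes")
    cgis = read_features(sim_dir / "cgis.bed", kind="cgi")
    genes = read_features(sim_dir / "genes.bed", kind="gene")
    calls = {}
    for tissue in ("exe", "emb"):
        calls[tissue] = [
            read_cpg_calls(sim_dir / f"{tissue}_rep{i}.methcalls.tsv", f"{tissue}_rep{i}")
            for i in range(1, sim.n_replicates + 1)
        ]

    # --- genome-wide aggregation over 1 kb tiles (summary statistics)
    filt = CoverageFilter(th.min_reads_merged, th.max_reads)
    merged = {
        t: filter_coverage(merge_replicates(calls[t], t), filt) for t in ("exe", "emb")
    }
    tiles = make_tiles(chrom_sizes, th.tile_width, th.tile_step)
    tile_means = {}
    for t in ("exe", "emb"):
        agg = aggregate_feature_methylation(
            merged[t], tiles, th.min_cpgs_per_feature, th.autosomes_only
        )
        tile_means[t] = float(agg.passing(th.min_cpgs_per_feature)["mean_rate"].mean())

    # --- hyper-CGI classification (test = exe, reference = emb)
    results, dmrs, delta = hyper_cgi_pipeline(calls["exe"], calls["emb"], cgis, th)
    res_df = hyper_results_frame(results)
    hyper_ids = res_df.loc[res_df["is_hyper"], "cgi_id"].tolist()
    write_features(cgis.subset(hyper_ids), out / "hyper_cgis.bed")
    res_df.to_csv(out / "cgi_classification.tsv", sep="\t", index=False, float_format="%.6f")
    pd.DataFrame([vars(d) for d in dmrs]).to_csv(
        out / "dmrs.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # --- promoter annotation and methylation levels (X kept: promoter
    # analysis spans all chromosomes, with the female-X caveat logged)
    promoters = define_promoters(genes, th.promoter_up, th.promoter_down, chrom_sizes)
    assignment = assign_promoter_cgis(promoters, cgis, th.overlap_frac)
    cgi_meth_frames = []
    for t in ("exe", "emb"):
        cgi_meth_frames.append(
            aggregate_feature_methylation(
                merged[t], cgis, th.min_cpgs_per_feature, autosomes_only=False
            ).df
        )
    from .feature_methylation import FeatureMethylation

    cgi_meth_all = FeatureMethylation(pd.concat(cgi_meth_frames, ignore_index=True))
    annotations = annotate_promoters(
        promoters, assignment, cgis, cgi_meth_all, ["exe", "emb"],
        th.min_cpgs_per_feature, th.oe_hcp_cutoff,
    )
    levels = {
        t: promoter_levels_table(annotations, cgi_meth_all, merged[t])
        for t in ("exe", "emb")
    }
    prom_out = levels["exe"].set_index("gene_id")[["level", "source", "density_class"]].rename(
        columns={"level": "level_test"}
    )
    prom_out["level_ref"] = levels["emb"].set_index("gene_id")["level"]
    prom_out["delta"] = prom_out["level_test"] - prom_out["level_ref"]
    prom_out["direction"] = prom_out["delta"].map(
        lambda d: classify_promoter_direction(d, th.promoter_delta)
    )
    ann_df = pd.DataFrame(
        [
            {
                "gene_id": a.gene_id, "chrom": a.chrom, "start": a.start, "end": a.end,
                "strand": a.strand, "cgi_ids": ",".join(a.used_cgi_ids) or ".",
                "density_class": a.density_class, "methylation_source": a.methylation_source,
            }
            for a in annotations
        ]
    ).set_index("gene_id")
    ann_df = ann_df.join(prom_out[["level_test", "level_ref", "delta", "direction"]])
    ann_df.to_csv(out / "promoters.tsv", sep="\t", float_format="%.6f")

    # --- expression: filtering, stand-in DE test, classification
    expr = ExpressionTable(
        tpm=pd.read_csv(sim_dir / "tpm.tsv", sep="\t", index_col=0),
        meta=pd.read_csv(sim_dir / "gene_meta.tsv", sep="\t", index_col=0),
    )
    universe = filter_expressed_genes(expr, th.tpm_min, th.tpm_min_samples)
    sub = ExpressionTable(tpm=expr.tpm.loc[universe], meta=expr.meta.loc[universe])
    labels = {s: ("test" if s.startswith("ex_") else "ref") for s in map(str, expr.samples)}
    de = simple_de_test(sub, labels)
    de = classify_de_genes(de, th)

    # k-means clustering of differential genes on per-tissue means
    diff_genes = de.index[de["class"] != "ns"]
    tissue_means = pd.DataFrame(
        {
            t: sub.tpm.loc[diff_genes, [c for c in sub.tpm.columns if c.startswith(t)]]
            .pipe(lambda d: np.log2(d + 1).mean(axis=1))
            for t in ("ex_mid", "ex_hind", "em_mid", "em_hind")
        }
    )
    clusters = zscore_kmeans(
        tissue_means, th.kmeans_k, th.kmeans_iter, th.kmeans_starts, seed=sim.seed
    )
    de_out = de.copy()
    de_out["cluster"] = clusters.reindex(de.index).astype("Int64")
    de_out.rename_axis("gene_id").to_csv(out / "de_classes.tsv", sep="\t", float_format="%.6g")

    # --- methylation-expression integration
    integration, rho, rho_p, n_excluded = integrate_delta_vs_lfc(
        de, levels["exe"], levels["emb"]
    )
    integration.to_csv(out / "integration.tsv", sep="\t", float_format="%.6f")

    # --- X-chromosome enrichment of high genes
    x_genes = expr.meta.index[expr.meta["chrom"] == "chrX"]
    high = set(de.index[de["class"] == "high"])
    table, odds, p_enrich = enrichment_test(high, universe, x_genes)

    # --- cells: QC, origin classification, per-group fractions
    cells = read_cell_matrix_mtx(
        sim_dir / "cells.mtx",
        sim_dir / "cells_genes.tsv",
        sim_dir / "cells_barcodes.tsv",
        sim_dir / "cell_meta.tsv",
        orientation="cell_by_gene",
    )
    qc = qc_filter_cells(cells, th)
    origin = classify_cell_origin(qc, sim.marker_a, sim.marker_b, th.marker_min_count)
    fractions = extraembryonic_fraction(origin, qc.meta["group"])
    write_labels_tsv(origin, out / "cell_labels.tsv")
    write_fractions_tsv(fractions, out / "cell_fractions.tsv")

    # --- manifest
    n_classified = len(res_df)
    n_excluded_cgis = int(res_df["excluded"].sum())
    counts = {
        "cgis_total": len(cgis),
        "cgis_classified": n_classified,
        "cgis_excluded": n_excluded_cgis,
        "cgis_not_excluded": n_classified - n_excluded_cgis,
        "hyper_cgis": len(hyper_ids),
        "dmrs": len(dmrs),
        "genes_total": int(expr.tpm.shape[0]),
        "genes_expressed": int(len(universe)),
        "de_high": int((de["class"] == "high").sum()),
        "de_low": int((de["class"] == "low").sum()),
        "integration_genes": int(len(integration)),
        "integration_excluded": int(n_excluded),
        "cells_total": cells.n_cells(),
        "cells_qc_pass": qc.n_cells(),
        "cells_extraembryonic": int((origin == "extraembryonic").sum()),
        "cells_embryonic": int((origin == "embryonic").sum()),
        "cells_discarded": int((origin == "discarded").sum()),
    }
    outputs = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "seed": sim.seed,
        "thresholds": resolved_thresholds(th),
        "simulation": _sim_dict(sim),
        "counts": counts,
        "tile_mean_methylation": tile_means,
        "spearman_delta_vs_lfc": {"rho": rho, "p": rho_p},
        "x_enrichment": {
            "table": np.asarray(table).tolist(), "odds_ratio": odds, "p": p_enrich,
        },
        "fractions": {
            str(g): {
                "fraction": None if np.isnan(row["fraction"]) else round(float(row["fraction"]), 6),
                "n": int(row["n"]),
            }
            for g, row in fractions.iterrows()
        },
        "checksums": {name: _sha256(out / name) for name in outputs},
    }
    _check_manifest_consistency(manifest)
    with open(out / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _check_manifest_consistency(manifest: dict) -> None:
    c = manifest["counts"]
    if not (
        c["hyper_cgis"] <= c["cgis_not_excluded"] <= c["cgis_classified"] <= c["cgis_total"]
    ):
        raise ExmethError("inconsistent stage counts: hyper <= non-excluded <= classified <= all")
    if (
        c["cells_extraembryonic"] + c["cells_embryonic"] + c["cells_discarded"]
        != c["cells_qc_pass"]
    ):
        raise ExmethError("origin labels do not partition the QC-passing cells")


def _sim_dict(sim: SimConfig) -> dict:
    from .synthetic import _config_as_plain_dict

    return _config_as_plain_dict(sim)
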