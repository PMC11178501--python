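"""Within-CGI differentially methylated regions and hyper-CGI calling.

A CGI is called *hyper* in the test tissue when (i) its mean methylation
gain over the reference exceeds ``hyper_delta``, (ii) either more than
half of its CpGs individually gain at least ``majority_cpg_delta`` or it
contains a DMR with higher methylation in the test tissue, and (iii) it
is not already methylated in the reference (mean >= ``epiblast_exclusion``).

The DMR caller operates on CpGs inside CGIs only. Candidate regions are
maximal runs of CpGs covered in both groups with inter-CpG gaps at most
``dmr_max_gap`` bp; within a run the contiguous segment of at least
``dmr_min_cpgs`` CpGs maximizing the absolute mean group difference is
located by exact search (all contiguous windows are scored via prefix
sums), the search recursing on the flanks to pick up further segments.
Segments reaching ``dmr_min_diff`` are tested by a two-sided rank-sum
comparison of the two groups' per-CpG rates and Benjamini-Hochberg
corrected across all candidate segments of the run. This caller is
metilene-like only in its CpG-count / effect / gap parameters; it is not
a reimplementation of that tool's statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ThresholdConfig
from .errors import ValidationError
from .feature_methylation import (
    DeltaTable,
    FeatureMethylation,
    aggregate_feature_methylation,
    delta_methylation,
)
from .meth_io import CoverageFilter, CpGCallTable, FeatureSet, filter_coverage, merge_replicates

logger = logging.getLogger("exmeth.hypercgi")


@dataclass
class DMR:
    """A differentially methylated region inside a CGI."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_diff: float
    p_value: float
    q_value: float
    parent_cgi_id: str


@dataclass
class HyperCGIResult:
    """Per-CGI outcome of the compound hyper-CGI classification."""

    cgi_id: str
    delta: float
    frac_cpgs_above: float
    has_dmr: bool
    epiblast_mean: float
    excluded: bool
    is_hyper: bool


def best_segment(diff: np.ndarray, min_len: int) -> tuple[int, int, float] | None:
    """Contiguous window of >= min_len values maximizing |mean|.

    Ties break toward the longer window, then the leftmost start.
    Returns (i, j, mean) over the half-open index window [i, j), or None
    when fewer than ``min_len`` values are available.
    """
    n = len(diff)
    if n < min_len:
        return None
    csum = np.concatenate([[0.0], np.cumsum(diff)])
    best: tuple[float, int, int] | None = None  # (|mean|, length, -start)
    arg = (0, min_len)
    for length in range(min_len, n + 1):
        means = (csum[length:] - csum[: n - length + 1]) / length
        k = int(np.argmax(np.abs(means)))
        score = (abs(float(means[k])), length, -k)
        if best is None or score > best:
            best = score
            arg = (k, k + length)
    i, j = arg
    return i, j, float((csum[j] - csum[i]) / (j - i))


def _segment_run(diff: np.ndarray, offset: int, min_len: int, min_diff: float) -> list[tuple[int, int, float]]:
    """Recursively extract non-overlapping segments passing the effect cutoff."""
    found = best_segment(diff, min_len)
    if found is None:
        return []
    i, j, mean = found
    if abs(mean) < min_diff:
        return []
    out = [(offset + i, offset + j, mean)]
    out.extend(_segment_run(diff[:i], offset, min_len, min_diff))
    out.extend(_segment_run(diff[j:], offset + j, min_len, min_diff))
    out.sort()
    return out


def _group_rates(tables: Sequence[CpGCallTable], group_id: str) -> CpGCallTable:
    if not tables:
        raise ValidationError(f"group {group_id!r} has no replicates")
    if len(tables) == 1:
        return tables[0]
    return merge_replicates(tables, group_id)


def call_dmrs_within_cgis(
    calls_test: Sequence[CpGCallTable],
    calls_ref: Sequence[CpGCallTable],
    cgis: FeatureSet,
    cfg: ThresholdConfig,
) -> list[DMR]:
    """Call DMRs (test minus reference) restricted to CpGs inside CGIs.

    Replicates within a group are first merged at the count level so each
    group contributes one rate per CpG; only CpGs covered in both groups
    are segmented. Returned DMRs pass the q-value cutoff.
    """
    if len(cgis) == 0:
        raise ValidationError("empty CGI set")
    test = _group_rates(calls_test, "test")
    ref = _group_rates(calls_ref, "ref")
    merged = test.df.merge(ref.df, on=["chrom", "pos"], suffixes=("_t", "_r"))
    if merged.empty:
        logger.warning("test and reference share no covered CpGs; no DMRs called")
        return []
    by_chrom = {str(c): g.reset_index(drop=True) for c, g in merged.groupby("chrom")}

    candidates: list[DMR] = []
    pvals: list[float] = []
    for cgi in cgis.df.itertuples(index=False):
        sub = by_chrom.get(cgi.chrom)
        if sub is None:
            continue
        pos_all = sub["pos"].to_numpy()
        i0 = np.searchsorted(pos_all, cgi.start, side="left")
        i1 = np.searchsorted(pos_all, cgi.end, side="left")
        if i1 - i0 < cfg.dmr_min_cpgs:
            continue
        pos = pos_all[i0:i1]
        rt = sub["rate_t"].to_numpy()[i0:i1]
        rr = sub["rate_r"].to_numpy()[i0:i1]
        # maximal runs with inter-CpG gap <= dmr_max_gap
        breaks = np.flatnonzero(np.diff(pos) > cfg.dmr_max_gap) + 1
        for run_lo, run_hi in zip(
            np.concatenate([[0], breaks]), np.concatenate([breaks, [len(pos)]])
        ):
            d = rt[run_lo:run_hi] - rr[run_lo:run_hi]
            for si, sj, mean in _segment_run(d, run_lo, cfg.dmr_min_cpgs, cfg.dmr_min_diff):
                a, b = rt[si:sj], rr[si:sj]
                if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
                    p = 1.0
                else:
                    p = float(
                        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
                    )
                candidates.append(
                    DMR(
                        chrom=cgi.chrom,
                        start=int(pos[si]),
                        end=int(pos[sj - 1]) + 1,
                        n_cpgs=sj - si,
                        mean_diff=mean,
                        p_value=p,
                        q_value=np.nan,
                        parent_cgi_id=cgi.feature_id,
                    )
                )
                pvals.append(p)
    if not candidates:
        return []
    # BH pooled across all candidate segments of the run
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for dmr, q in zip(candidates, qvals):
        dmr.q_value = float(q)
        if q < cfg.dmr_q:
            out.append(dmr)
    return out


def classify_hyper_cgis(
    delta_table: DeltaTable,
    ref_meth: FeatureMethylation,
    dmrs: Sequence[DMR],
    cfg: ThresholdConfig,
    ref_sample_id: str | None = None,
    all_cgi_ids: Sequence[str] | None = None,
) -> list[HyperCGIResult]:
    """Apply the compound hyper-CGI rule to a CGI delta table.

    is_hyper = (reference mean < ``epiblast_exclusion``) AND
    (delta > ``hyper_delta``, strict) AND (more than half the shared CpGs
    gain >= ``majority_cpg_delta`` OR the CGI contains a positive DMR).
    CGIs absent from the delta table are skipped with a warning.
    """
    ref_id = ref_sample_id if ref_sample_id is not None else delta_table.reference_id
    ref_tab = ref_meth.sample(ref_id)
    positive_dmr_parents = {d.parent_cgi_id for d in dmrs if d.mean_diff > 0}
    indexed = delta_table.df.set_index("feature_id")
    ids = list(all_cgi_ids) if all_cgi_ids is not None else list(indexed.index)
    results: list[HyperCGIResult] = []
    n_skipped = 0
    for cgi_id in ids:
        if cgi_id not in indexed.index:
            n_skipped += 1
            continue
        row = indexed.loc[cgi_id]
        delta = float(row["delta"])
        frac = float(row["frac_cpgs_above"])
        ref_mean = float(ref_tab.loc[cgi_id, "mean_rate"]) if cgi_id in ref_tab.index else np.nan
        excluded = bool(ref_mean >= cfg.epiblast_exclusion) if not np.isnan(ref_mean) else False
        has_dmr = cgi_id in positive_dmr_parents
        majority = (not np.isnan(frac)) and frac > 0.5
        is_hyper = (not excluded) and (delta > cfg.hyper_delta) and (majority or has_dmr)
        results.append(
            HyperCGIResult(
                cgi_id=cgi_id,
                delta=delta,
                frac_cpgs_above=frac,
                has_dmr=has_dmr,
                epiblast_mean=ref_mean,
                excluded=excluded,
                is_hyper=is_hyper,
            )
        )
    if n_skipped:
        logger.warning("%d CGIs missing from delta table were skipped", n_skipped)
    return results


def hyper_results_frame(results: Sequence[HyperCGIResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def hyper_cgi_pipeline(
    calls_test_reps: Sequence[CpGCallTable],
    calls_ref_reps: Sequence[CpGCallTable],
    cgis: FeatureSet,
    cfg: ThresholdConfig,
) -> tuple[list[HyperCGIResult], list[DMR], DeltaTable]:
    """Replicate merging -> coverage filter -> aggregation -> DMRs -> rule.

    Replicates are merged at the count level per tissue, the merged
    tables are depth-filtered (``min_reads_merged``..``max_reads``), CGI
    methylation and deltas are aggregated, DMRs are called on the same
    filtered tables, and the compound rule is applied.
    """
    filt = CoverageFilter(cfg.min_reads_merged, cfg.max_reads)
    test = filter_coverage(_group_rates(list(calls_test_reps), "test"), filt)
    ref = filter_coverage(_group_rates(list(calls_ref_reps), "ref"), filt)
    test_meth = aggregate_feature_methylation(
        test, cgis, cfg.min_cpgs_per_feature, cfg.autosomes_only
    )
    ref_meth = aggregate_feature_methylation(
        ref, cgis, cfg.min_cpgs_per_feature, cfg.autosomes_only
    )
    delta = delta_methylation(
        test_meth,
        ref_meth,
        test,
        ref,
        cgis,
        above=cfg.majority_cpg_delta,
        min_cpgs=cfg.min_cpgs_per_feature,
    )
    dmrs = call_dmrs_within_cgis([test], [ref], cgis, cfg)
    results = classify_hyper_cgis(delta, ref_meth, dmrs, cfg, ref_sample_id=ref.sample_id)
    return results, dmrs, delta
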