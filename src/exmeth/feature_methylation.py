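"""Aggregation of per-CpG methylation over genomic features.

Per-feature methylation is the unweighted mean of the per-CpG rates of
the covered CpGs inside the feature (coverage adequacy is handled
upstream by read-depth filtering, so no read-count weighting is applied).
Feature-level summaries exclude features with fewer than
``min_cpgs_per_feature`` covered CpGs, and — when ``autosomes_only`` is
set — features on sex or mitochondrial chromosomes, since X-inactivation
in female samples inflates promoter methylation levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_features import PromoterAnnotation, classify_promoter_density
from .meth_io import CpGCallTable, FeatureSet, is_autosome

logger = logging.getLogger("exmeth.feature_methylation")


@dataclass
class FeatureMethylation:
    """Per-(feature, sample) mean methylation with covered-CpG counts.

    ``df`` holds columns ``feature_id``, ``sample_id``, ``mean_rate``
    (NaN when ``n_cpgs == 0``) and ``n_cpgs``.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        df["n_cpgs"] = df["n_cpgs"].astype(np.int64)
        covered = df["n_cpgs"] > 0
        rates = df.loc[covered, "mean_rate"]
        if ((rates < 0) | (rates > 1)).any():
            raise ValidationError("mean_rate outside [0, 1]")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def sample(self, sample_id: str) -> pd.DataFrame:
        """Rows for one sample, indexed by feature_id."""
        sub = self.df[self.df["sample_id"] == sample_id]
        return sub.set_index("feature_id")

    def passing(self, min_cpgs: int) -> pd.DataFrame:
        """Summary view: only entries with at least ``min_cpgs`` covered CpGs."""
        return self.df[self.df["n_cpgs"] >= min_cpgs].reset_index(drop=True)

    def get(self, feature_id: str, sample_id: str) -> tuple[float, int]:
        sub = self.df[
            (self.df["feature_id"] == feature_id) & (self.df["sample_id"] == sample_id)
        ]
        if sub.empty:
            raise KeyError((feature_id, sample_id))
        row = sub.iloc[0]
        return float(row["mean_rate"]), int(row["n_cpgs"])


@dataclass
class DeltaTable:
    """Per-feature test-minus-reference methylation differences.

    ``df`` columns: ``feature_id``, ``delta`` (mean_rate difference),
    ``frac_cpgs_above`` (fraction of CpGs covered in both samples whose
    per-CpG difference is >= the configured minimum; NaN when too few
    shared CpGs), ``n_shared_cpgs``.
    """

    df: pd.DataFrame = field(repr=False)
    test_id: str = ""
    reference_id: str = ""

    def __len__(self) -> int:
        return len(self.df)


def aggregate_feature_methylation(
    calls: CpGCallTable,
    features: FeatureSet,
    min_cpgs: int = 3,
    autosomes_only: bool = True,
) -> FeatureMethylation:
    """Average per-CpG rates over each feature interval.

    Every retained feature gets an entry; features with no covered CpG
    carry ``n_cpgs == 0`` and a missing mean. ``min_cpgs`` is recorded for
    summary filtering via :meth:`FeatureMethylation.passing`, not applied
    here. With ``autosomes_only`` features on sex/mito chromosomes are
    dropped; disabling it can bias X-linked levels in female samples.
    """
    fdf = features.df
    if autosomes_only:
        keep = fdf["chrom"].map(is_autosome)
        fdf = fdf[keep]
    else:
        logger.warning(
            "autosomes_only disabled: X-linked methylation may be inflated in female samples"
        )
    calls_by_chrom = calls.by_chrom()
    rows = []
    for chrom, group in fdf.groupby("chrom", sort=True):
        sub = calls_by_chrom.get(str(chrom))
        if sub is None:
            pos = np.empty(0, dtype=np.int64)
            csum = np.zeros(1)
        else:
            pos = sub["pos"].to_numpy()
            csum = np.concatenate([[0.0], np.cumsum(sub["rate"].to_numpy())])
        i0 = np.searchsorted(pos, group["start"].to_numpy(), side="left")
        i1 = np.searchsorted(pos, group["end"].to_numpy(), side="left")
        n = i1 - i0
        total = csum[i1] - csum[i0]
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
        for fid, nn, mm in zip(group["feature_id"], n, mean):
            rows.append((fid, calls.sample_id, mm if nn > 0 else np.nan, int(nn)))
    out = pd.DataFrame(rows, columns=["feature_id", "sample_id", "mean_rate", "n_cpgs"])
    return FeatureMethylation(out)


def annotate_promoters(
    promoters: FeatureSet,
    assignment: Mapping[str, Sequence[str]],
    cgis: FeatureSet,
    cgi_meth: FeatureMethylation,
    sample_ids: Sequence[str],
    min_cpgs: int = 3,
    oe_hcp_cutoff: float = 0.8,
) -> list[PromoterAnnotation]:
    """Couple CGI assignment, CGI coverage and density classing per promoter.

    An assigned CGI is *used* for the promoter methylation level only if
    it has at least ``min_cpgs`` covered CpGs in every sample under
    analysis; a promoter with no usable CGI falls back to region-level
    methylation and is therefore an LCP.
    """
    oe_col = cgis.df.set_index("feature_id")["obs_exp"] if "obs_exp" in cgis.df.columns else None
    cov: dict[str, pd.DataFrame] = {s: cgi_meth.sample(s) for s in sample_ids}
    out = []
    for prom in promoters.df.itertuples(index=False):
        assigned = list(assignment.get(prom.feature_id, []))
        used = []
        for cgi_id in assigned:
            ok = True
            for s in sample_ids:
                tab = cov[s]
                if cgi_id not in tab.index or int(tab.loc[cgi_id, "n_cpgs"]) < min_cpgs:
                    ok = False
                    break
            if ok:
                used.append(cgi_id)
        source = "cgi" if used else "region"
        if source == "cgi":
            oes = None
            if oe_col is not None:
                oes = [float(oe_col.get(c, np.nan)) for c in used]
            density = classify_promoter_density(oes, "cgi", oe_hcp_cutoff)
        else:
            density = "LCP"
        out.append(
            PromoterAnnotation(
                gene_id=prom.feature_id,
                chrom=prom.chrom,
                start=int(prom.start),
                end=int(prom.end),
                strand=prom.strand,
                assigned_cgi_ids=assigned,
                used_cgi_ids=used,
                density_class=density,
                methylation_source=source,
            )
        )
    return out


def promoter_methylation_level(
    annotation: PromoterAnnotation,
    cgi_meth: FeatureMethylation,
    calls: CpGCallTable,
) -> tuple[float, str]:
    """Promoter methylation level for one sample.

    With usable CGI(s): the unweighted mean of their CGI-level mean
    rates. Otherwise: the mean per-CpG rate across the promoter region.
    Returns (level, source); level is NaN when nothing is covered.
    """
    if annotation.methylation_source == "cgi":
        sample_tab = cgi_meth.sample(calls.sample_id)
        vals = [
            float(sample_tab.loc[c, "mean_rate"])
            for c in annotation.used_cgi_ids
            if c in sample_tab.index and sample_tab.loc[c, "n_cpgs"] > 0
        ]
        if vals:
            return float(np.mean(vals)), "cgi"
        return float("nan"), "cgi"
    sub = calls.df[
        (calls.df["chrom"] == annotation.chrom)
        & (calls.df["pos"] >= annotation.start)
        & (calls.df["pos"] < annotation.end)
    ]
    if sub.empty:
        return float("nan"), "region"
    return float(sub["rate"].mean()), "region"


def promoter_levels_table(
    annotations: Sequence[PromoterAnnotation],
    cgi_meth: FeatureMethylation,
    calls: CpGCallTable,
) -> pd.DataFrame:
    """Per-gene promoter levels for one sample; flags uncovered genes."""
    rows = []
    for ann in annotations:
        level, source = promoter_methylation_level(ann, cgi_meth, calls)
        rows.append(
            {
                "gene_id": ann.gene_id,
                "sample_id": calls.sample_id,
                "level": level,
                "source": source,
                "density_class": ann.density_class,
                "covered": not np.isnan(level),
            }
        )
    return pd.DataFrame(rows)


def delta_methylation(
    test: FeatureMethylation,
    reference: FeatureMethylation,
    calls_test: CpGCallTable,
    calls_ref: CpGCallTable,
    features: FeatureSet,
    above: float = 0.1,
    min_cpgs: int = 3,
) -> DeltaTable:
    """Per-feature methylation difference (test minus reference).

    Only features passing the min-CpG filter in BOTH samples are kept.
    ``frac_cpgs_above`` is computed over CpGs covered in both samples
    inside the feature and is missing when fewer than ``min_cpgs`` CpGs
    are shared.
    """
    t = test.sample(calls_test.sample_id)
    r = reference.sample(calls_ref.sample_id)
    common = t.index.intersection(r.index)
    if len(common) == 0:
        raise ValidationError("test and reference share no features")
    t = t.loc[common]
    r = r.loc[common]
    ok = (t["n_cpgs"] >= min_cpgs) & (r["n_cpgs"] >= min_cpgs)
    kept = common[ok]

    # per-CpG differences over positions covered in both samples
    merged = calls_test.df.merge(
        calls_ref.df, on=["chrom", "pos"], suffixes=("_t", "_r")
    )
    diff_by_chrom = {
        str(c): g.reset_index(drop=True) for c, g in merged.groupby("chrom")
    }
    fdf = features.df.set_index("feature_id")
    rows = []
    for fid in kept:
        feat = fdf.loc[fid]
        delta = float(t.loc[fid, "mean_rate"]) - float(r.loc[fid, "mean_rate"])
        sub = diff_by_chrom.get(str(feat["chrom"]))
        if sub is None:
            n_shared, frac = 0, np.nan
        else:
            pos = sub["pos"].to_numpy()
            i0 = np.searchsorted(pos, feat["start"], side="left")
            i1 = np.searchsorted(pos, feat["end"], side="left")
            n_shared = int(i1 - i0)
            if n_shared >= min_cpgs:
                d = sub["rate_t"].to_numpy()[i0:i1] - sub["rate_r"].to_numpy()[i0:i1]
                frac = float(np.mean(d >= above))
            else:
                frac = np.nan
        rows.append((fid, delta, frac, n_shared))
    df = pd.DataFrame(rows, columns=["feature_id", "delta", "frac_cpgs_above", "n_shared_cpgs"])
    return DeltaTable(df=df, test_id=calls_test.sample_id, reference_id=calls_ref.sample_id)


def classify_promoter_direction(delta: float, cutoff: float = 0.1) -> str:
    """hyper if delta > cutoff, hypo if delta < -cutoff, else neither (strict)."""
    if np.isnan(delta):
        return "neither"
    if delta > cutoff:
        return "hyper"
    if delta < -cutoff:
        return "hypo"
    return "neither"
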