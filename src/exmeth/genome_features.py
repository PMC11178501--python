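"""Construction and classification of genomic features.

Covers fixed-width genome tiling, promoter definition around the TSS,
reciprocal-overlap assignment of CpG islands (CGIs) to promoters, the
observed/expected CpG ratio, and the LCP/ICP/HCP promoter CpG-density
classes. Promoter density classing is coupled to how the promoter's
methylation level is obtained: a promoter whose level comes from the
promoter region itself (no covered CGI) is by definition a low CpG
density promoter (LCP); otherwise the O/E ratio of the CGI(s) used
decides ICP vs HCP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .meth_io import FeatureSet

logger = logging.getLogger("exmeth.genome_features")

DENSITY_CLASSES = ("LCP", "ICP", "HCP", "unclassified")


@dataclass
class PromoterAnnotation:
    """Per-gene promoter interval, CGI assignment and density class.

    ``density_class == "LCP"`` iff ``methylation_source == "region"``:
    the class and the source of the methylation level are one decision.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    assigned_cgi_ids: list[str] = field(default_factory=list)
    used_cgi_ids: list[str] = field(default_factory=list)
    density_class: str = "unclassified"
    methylation_source: str = "region"

    def __post_init__(self) -> None:
        if self.density_class not in DENSITY_CLASSES:
            raise ValidationError(f"invalid density class {self.density_class!r}")
        if self.methylation_source not in ("cgi", "region"):
            raise ValidationError(f"invalid methylation source {self.methylation_source!r}")
        if (self.density_class == "LCP") != (self.methylation_source == "region"):
            raise ValidationError("LCP class and region-level methylation must coincide")


def make_tiles(chrom_sizes: Mapping[str, int], width: int = 1000, step: int = 1000) -> FeatureSet:
    """Segment the genome into tiles ``[k*step, k*step + width)``.

    The trailing partial tile is emitted, clipped at the chromosome end
    (the behaviour of standard window-making tools).
    """
    if width <= 0 or step <= 0:
        raise ValidationError("tile width and step must be positive")
    rows = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValidationError(f"non-positive length for chromosome {chrom}")
        k = 0
        while k * step < length:
            start = k * step
            end = min(start + width, length)
            rows.append(
                {
                    "feature_id": f"tile_{chrom}_{start}_{end}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": ".",
                    "kind": "tile",
                }
            )
            k += 1
    return FeatureSet(pd.DataFrame(rows))


def define_promoters(
    genes: FeatureSet,
    up: int = 500,
    down: int = 500,
    chrom_sizes: Mapping[str, int] | None = None,
    assume_plus: bool = False,
) -> FeatureSet:
    """Promoters as ``up`` bp upstream and ``down`` bp downstream of the TSS.

    The TSS is the gene's 5' end by strand (start for +, end for -);
    intervals are clamped to [0, chromosome length). Strand "." is an
    error unless ``assume_plus`` is set.
    """
    rows = []
    for row in genes.df.itertuples(index=False):
        strand = row.strand
        if strand == ".":
            if not assume_plus:
                raise ValidationError(f"gene {row.feature_id} has no strand; set assume_plus")
            strand = "+"
        if strand == "+":
            tss = row.start
            start, end = tss - up, tss + down
        else:
            tss = row.end
            start, end = tss - down, tss + up
        start = max(0, start)
        if chrom_sizes is not None and row.chrom in chrom_sizes:
            end = min(end, chrom_sizes[row.chrom])
        if start >= end:
            raise ValidationError(f"empty promoter for gene {row.feature_id}")
        rows.append(
            {
                "feature_id": row.feature_id,
                "chrom": row.chrom,
                "start": start,
                "end": end,
                "strand": row.strand,
                "kind": "promoter",
            }
        )
    return FeatureSet(pd.DataFrame(rows))


def assign_promoter_cgis(
    promoters: FeatureSet, cgis: FeatureSet, frac: float = 0.2
) -> dict[str, list[str]]:
    """Assign CGIs to promoters by reciprocal fractional overlap.

    A CGI is assigned iff the overlap covers at least ``frac`` of the CGI
    OR at least ``frac`` of the promoter (either condition suffices).
    Returns gene_id -> all qualifying CGI ids (possibly empty).
    """
    out: dict[str, list[str]] = {pid: [] for pid in promoters.df["feature_id"]}
    cgi_by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("start").reset_index(drop=True)
        for c, g in cgis.df.groupby("chrom")
    }
    for prom in promoters.df.itertuples(index=False):
        cand = cgi_by_chrom.get(prom.chrom)
        if cand is None:
            continue
        starts = cand["start"].to_numpy()
        ends = cand["end"].to_numpy()
        ov = np.minimum(ends, prom.end) - np.maximum(starts, prom.start)
        lens = ends - starts
        plen = prom.end - prom.start
        hit = (ov > 0) & ((ov >= frac * lens) | (ov >= frac * plen))
        if hit.any():
            out[prom.feature_id] = [
                str(x) for x in cand.loc[hit, "feature_id"].tolist()
            ]
    return out


def compute_oe_ratio(sequence: str) -> float:
    """Observed/expected CpG ratio: ``n_CG * L / (n_C * n_G)``.

    Returns 0 when the sequence contains no C or no G.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = seq.count("CG")
    return n_cg * len(seq) / (n_c * n_g)


def classify_promoter_density(
    used_cgi_obs_exp: Sequence[float] | None,
    methylation_source: str,
    oe_hcp_cutoff: float = 0.8,
) -> str:
    """LCP / ICP / HCP classification of a promoter.

    Region-sourced methylation (no covered CGI) -> LCP. Otherwise HCP if
    the maximum O/E ratio among the CGIs actually used exceeds the cutoff
    (strict >), else ICP; missing O/E values -> unclassified.
    """
    if methylation_source == "region":
        return "LCP"
    if methylation_source != "cgi":
        raise ValidationError(f"invalid methylation source {methylation_source!r}")
    vals = [v for v in (used_cgi_obs_exp or []) if v is not None and not np.isnan(v)]
    if not vals:
        logger.warning("promoter uses CGI methylation but no O/E ratio is available")
        return "unclassified"
    return "HCP" if max(vals) > oe_hcp_cutoff else "ICP"
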