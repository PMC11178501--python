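"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as a direct transcription of the rule being
checked (per-element loops, exhaustive enumeration, closed-form sums)
and shares no code with the package internals.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd


def aggregate_oracle(
    calls: pd.DataFrame, features: pd.DataFrame
) -> dict[str, tuple[float, int]]:
    """Per-feature mean of per-CpG rates by an explicit loop."""
    out = {}
    for _, f in features.iterrows():
        rates = []
        for _, c in calls.iterrows():
            if c["chrom"] == f["chrom"] and f["start"] <= c["pos"] < f["end"]:
                rates.append(c["rate"])
        out[f["feature_id"]] = (
            float(np.mean(rates)) if rates else float("nan"),
            len(rates),
        )
    return out


def overlap_assign_oracle(
    promoters: pd.DataFrame, cgis: pd.DataFrame, frac: float
) -> dict[str, set[str]]:
    """All-pairs reciprocal-fraction overlap assignment."""
    out: dict[str, set[str]] = {p["feature_id"]: set() for _, p in promoters.iterrows()}
    for _, p in promoters.iterrows():
        for _, c in cgis.iterrows():
            if p["chrom"] != c["chrom"]:
                continue
            ov = min(p["end"], c["end"]) - max(p["start"], c["start"])
            if ov <= 0:
                continue
            if ov >= frac * (c["end"] - c["start"]) or ov >= frac * (p["end"] - p["start"]):
                out[p["feature_id"]].add(c["feature_id"])
    return out


def best_segment_oracle(diff: np.ndarray, min_len: int):
    """Exhaustive enumeration of all contiguous segments of >= min_len.

    Maximizes |mean|, breaking ties toward longer and then leftmost
    segments; returns (i, j, mean) or None.
    """
    n = len(diff)
    best = None
    for i in range(n):
        for j in range(i + min_len, n + 1):
            mean = float(np.mean(diff[i:j]))
            key = (abs(mean), j - i, -i)
            if best is None or key > best[0]:
                best = (key, (i, j, mean))
    return None if best is None else best[1]


def hypergeom_tail_oracle(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return total / comb(N, n)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P by enumerating tables with fixed margins."""
    N = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(N, col1)
    p_obs = comb(row1, a) * comb(N - row1, col1 - a) / denom
    p = 0.0
    for x in range(max(0, col1 - (N - row1)), min(row1, col1) + 1):
        px = comb(row1, x) * comb(N - row1, col1 - x) / denom
        if px <= p_obs * (1 + 1e-9):
            p += px
    return p


def promoter_density_oracle(used_oes: list[float] | None, source: str) -> str:
    if source == "region":
        return "LCP"
    if not used_oes:
        return "unclassified"
    return "HCP" if max(used_oes) > 0.8 else "ICP"
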