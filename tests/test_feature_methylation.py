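import numpy as np
import pandas as pd
import pytest

from exmeth.errors import ValidationError
from exmeth.feature_methylation import (
    FeatureMethylation,
    aggregate_feature_methylation,
    annotate_promoters,
    classify_promoter_direction,
    delta_methylation,
    promoter_methylation_level,
)
from exmeth.genome_features import PromoterAnnotation
from exmeth.meth_io import FeatureSet

from conftest import make_calls
from oracles import aggregate_oracle


def _features(rows, kind="tile"):
    df = pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end"])
    df["strand"] = "."
    df["kind"] = kind
    return FeatureSet(df)


def _random_instance(rng, n_features=20, n_cpgs=500):
    chroms = ["chr1", "chr2"]
    feats = []
    for i in range(n_features):
        s = int(rng.integers(0, 4000))
        feats.append((f"f{i}", chroms[int(rng.integers(2))], s, s + int(rng.integers(50, 1200))))
    seen = set()
    recs = []
    while len(recs) < n_cpgs:
        key = (chroms[int(rng.integers(2))], int(rng.integers(0, 5200)))
        if key in seen:
            continue
        seen.add(key)
        total = int(rng.integers(1, 40))
        recs.append((key[0], key[1], int(rng.integers(0, total + 1)), total))
    return _features(feats), make_calls(recs)


class TestAggregate:
    def test_unweighted_mean(self):
        calls = make_calls([("chr1", 10, 1, 5), ("chr1", 20, 2, 5), ("chr1", 30, 3, 5)])
        feats = _features([("t", "chr1", 0, 100)])
        fm = aggregate_feature_methylation(calls, feats, min_cpgs=3)
        rate, n = fm.get("t", "s1")
        assert (rate, n) == (pytest.approx(0.4), 3)

    def test_below_min_present_but_excluded_from_summary(self):
        calls = make_calls([("chr1", 10, 1, 2), ("chr1", 20, 1, 2)])
        feats = _features([("t", "chr1", 0, 100)])
        fm = aggregate_feature_methylation(calls, feats, min_cpgs=3)
        assert fm.get("t", "s1")[1] == 2
        assert len(fm.passing(3)) == 0

    def test_uncovered_feature_has_no_mean(self):
        calls = make_calls([("chr1", 500, 1, 2)])
        feats = _features([("t", "chr1", 0, 100)])
        fm = aggregate_feature_methylation(calls, feats)
        rate, n = fm.get("t", "s1")
        assert n == 0 and np.isnan(rate)

    def test_non_autosomes_dropped_when_flagged(self):
        calls = make_calls([("chrX", 10, 1, 2), ("chr1", 10, 1, 2)])
        feats = _features([("a", "chr1", 0, 100), ("x", "chrX", 0, 100)])
        fm = aggregate_feature_methylation(calls, feats, autosomes_only=True)
        assert set(fm.df["feature_id"]) == {"a"}
        fm2 = aggregate_feature_methylation(calls, feats, autosomes_only=False)
        assert set(fm2.df["feature_id"]) == {"a", "x"}

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(8):
            feats, calls = _random_instance(rng)
            fm = aggregate_feature_methylation(calls, feats, autosomes_only=False)
            want = aggregate_oracle(calls.df, feats.df)
            for fid, (mean, n) in want.items():
                got_mean, got_n = fm.get(fid, "s1")
                assert got_n == n
                if n:
                    assert got_mean == pytest.approx(mean)

    def test_record_order_invariance(self, rng):
        feats, calls = _random_instance(rng, 10, 200)
        shuffled = calls.df.sample(frac=1, random_state=0)
        calls2 = make_calls(
            [tuple(r) for r in shuffled[["chrom", "pos", "meth", "total"]].itertuples(index=False)]
        )
        a = aggregate_feature_methylation(calls, feats, autosomes_only=False).df
        b = aggregate_feature_methylation(calls2, feats, autosomes_only=False).df
        pd.testing.assert_frame_equal(a, b)

    def test_constant_rate_propagates_exactly(self):
        calls = make_calls([("chr1", i * 10, 3, 4) for i in range(50)])
        feats = _features([("a", "chr1", 0, 200), ("b", "chr1", 200, 499)])
        fm = aggregate_feature_methylation(calls, feats)
        for fid in ("a", "b"):
            assert fm.get(fid, "s1")[0] == 0.75


def _ann(source, used, density):
    return PromoterAnnotation(
        gene_id="g", chrom="chr1", start=0, end=1000, strand="+",
        assigned_cgi_ids=used, used_cgi_ids=used,
        density_class=density, methylation_source=source,
    )


class TestPromoterLevel:
    def _cgi_meth(self, entries):
        return FeatureMethylation(
            pd.DataFrame(entries, columns=["feature_id", "sample_id", "mean_rate", "n_cpgs"])
        )

    def test_single_cgi(self):
        cm = self._cgi_meth([("c1", "s1", 0.30, 10)])
        calls = make_calls([("chr1", 10, 0, 1)])
        assert promoter_methylation_level(_ann("cgi", ["c1"], "ICP"), cm, calls) == (
            pytest.approx(0.30), "cgi",
        )

    def test_two_cgis_unweighted_mean(self):
        cm = self._cgi_meth([("c1", "s1", 0.2, 30), ("c2", "s1", 0.4, 3)])
        calls = make_calls([("chr1", 10, 0, 1)])
        level, src = promoter_methylation_level(_ann("cgi", ["c1", "c2"], "ICP"), cm, calls)
        assert (level, src) == (pytest.approx(0.30), "cgi")

    def test_region_fallback(self):
        cm = self._cgi_meth([("c1", "s1", np.nan, 0)])
        calls = make_calls([("chr1", 100, 4, 5), ("chr1", 200, 1, 1), ("chr1", 5000, 0, 5)])
        level, src = promoter_methylation_level(_ann("region", [], "LCP"), cm, calls)
        assert (level, src) == (pytest.approx(0.9), "region")

    def test_uncovered_promoter_flagged_missing(self):
        cm = self._cgi_meth([("c1", "s1", np.nan, 0)])
        calls = make_calls([("chr2", 100, 1, 2)])
        level, _ = promoter_methylation_level(_ann("region", [], "LCP"), cm, calls)
        assert np.isnan(level)


class TestAnnotatePromoters:
    def test_uncovered_cgi_forces_region_and_lcp(self):
        proms = _features([("g1", "chr1", 0, 1000)], "promoter")
        cgis = FeatureSet(
            pd.DataFrame(
                {
                    "feature_id": ["c1"], "chrom": ["chr1"], "start": [100],
                    "end": [500], "strand": ["."], "kind": ["cgi"], "obs_exp": [0.95],
                }
            )
        )
        meth_covered = FeatureMethylation(
            pd.DataFrame(
                [("c1", "t", 0.1, 10), ("c1", "r", 0.1, 10)],
                columns=["feature_id", "sample_id", "mean_rate", "n_cpgs"],
            )
        )
        anns = annotate_promoters(proms, {"g1": ["c1"]}, cgis, meth_covered, ["t", "r"])
        assert anns[0].density_class == "HCP"
        # same CGI with too few covered CpGs in one sample of the pair
        meth_thin = FeatureMethylation(
            pd.DataFrame(
                [("c1", "t", 0.1, 10), ("c1", "r", 0.1, 2)],
                columns=["feature_id", "sample_id", "mean_rate", "n_cpgs"],
            )
        )
        anns = annotate_promoters(proms, {"g1": ["c1"]}, cgis, meth_thin, ["t", "r"])
        assert anns[0].methylation_source == "region"
        assert anns[0].density_class == "LCP"


class TestDelta:
    def _pair(self, rates_t, rates_r):
        t = make_calls([("chr1", i * 10, int(round(r * 20)), 20) for i, r in enumerate(rates_t)], "t")
        r = make_calls([("chr1", i * 10, int(round(r * 20)), 20) for i, r in enumerate(rates_r)], "r")
        feats = _features([("f", "chr1", 0, 10 * len(rates_t))], "cgi")
        mt = aggregate_feature_methylation(t, feats)
        mr = aggregate_feature_methylation(r, feats)
        return delta_methylation(mt, mr, t, r, feats, above=0.1)

    def test_subtraction(self):
        dt = self._pair([0.3] * 5, [0.05] * 5)
        assert dt.df.iloc[0]["delta"] == pytest.approx(0.25)

    def test_identity_gives_zero(self):
        dt = self._pair([0.4] * 6, [0.4] * 6)
        assert dt.df.iloc[0]["delta"] == 0
        assert dt.df.iloc[0]["frac_cpgs_above"] == 0

    def test_frac_counts_shared_cpgs(self):
        rates_t = [0.5] * 6 + [0.0] * 4
        rates_r = [0.0] * 10
        dt = self._pair(rates_t, rates_r)
        assert dt.df.iloc[0]["frac_cpgs_above"] == pytest.approx(0.6)
        assert dt.df.iloc[0]["n_shared_cpgs"] == 10

    def test_disjoint_feature_sets_rejected(self):
        t = make_calls([("chr1", 0, 1, 10)], "t")
        r = make_calls([("chr1", 0, 1, 10)], "r")
        fa = _features([("a", "chr1", 0, 10)], "cgi")
        fb = _features([("b", "chr1", 0, 10)], "cgi")
        ma = aggregate_feature_methylation(t, fa)
        mb = aggregate_feature_methylation(r, fb)
        with pytest.raises(ValidationError, match="no features"):
            delta_methylation(ma, mb, t, r, fa)

    def test_features_failing_min_cpgs_in_either_sample_dropped(self):
        t = make_calls([("chr1", 0, 5, 10), ("chr1", 10, 5, 10), ("chr1", 20, 5, 10)], "t")
        r = make_calls([("chr1", 0, 5, 10)], "r")
        feats = _features([("f", "chr1", 0, 100)], "cgi")
        mt = aggregate_feature_methylation(t, feats)
        mr = aggregate_feature_methylation(r, feats)
        dt = delta_methylation(mt, mr, t, r, feats, min_cpgs=3)
        assert len(dt.df) == 0


class TestPromoterDirection:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (0.25, "hyper"),
            (-0.25, "hypo"),
            (0.1, "neither"),   # strict >
            (-0.1, "neither"),  # strict <
            (0.0, "neither"),
            (float("nan"), "neither"),
        ],
    )
    def test_boundaries(self, delta, expected):
        assert classify_promoter_direction(delta, 0.1) == expected
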