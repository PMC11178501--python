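import numpy as np
import pandas as pd
import pytest

from exmeth.config import ThresholdConfig
from exmeth.errors import ValidationError
from exmeth.expression import (
    ExpressionTable,
    classify_de_genes,
    define_methylation_sensitive_genes,
    enrichment_test,
    filter_expressed_genes,
    flag_exon_dmr_overlap,
    integrate_delta_vs_lfc,
    overrepresentation,
    simple_de_test,
    zscore_kmeans,
    zscore_rows,
)

CFG = ThresholdConfig()


def _expr(tpm_rows, chroms=None, index=None):
    tpm = pd.DataFrame(tpm_rows, index=index)
    tpm.columns = [f"s{i}" for i in range(tpm.shape[1])]
    meta = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["chr1"] * len(tpm),
            "is_protein_coding": True,
        },
        index=tpm.index,
    )
    return ExpressionTable(tpm=tpm, meta=meta)


class TestFilterExpressed:
    def test_detected_in_enough_samples_retained(self):
        expr = _expr([[1.2] * 4 + [0.0] * 12], index=["g"])
        assert list(filter_expressed_genes(expr, 1.0, 4)) == ["g"]

    def test_threshold_is_strict(self):
        expr = _expr([[1.0] * 16], index=["g"])
        assert len(filter_expressed_genes(expr, 1.0, 4)) == 0

    def test_y_genes_removed(self):
        expr = _expr([[5.0] * 16], chroms=["chrY"], index=["g"])
        assert len(filter_expressed_genes(expr, 1.0, 4)) == 0

    def test_non_coding_removed(self):
        expr = _expr([[5.0] * 16], index=["g"])
        expr.meta["is_protein_coding"] = False
        assert len(filter_expressed_genes(expr, 1.0, 4)) == 0

    def test_min_samples_exceeding_width_rejected(self):
        expr = _expr([[5.0] * 3], index=["g"])
        with pytest.raises(ValidationError):
            filter_expressed_genes(expr, 1.0, 4)


class TestClassifyDE:
    @pytest.mark.parametrize(
        "lfc,padj,expected",
        [
            (1.5, 0.01, "high"),
            (-2.0, 0.20, "ns"),
            (1.0, 0.01, "ns"),    # strict >
            (-1.0, 0.01, "ns"),   # strict <
            (-1.01, 0.01, "low"),
            (2.0, 0.05, "ns"),    # strict < on padj
        ],
    )
    def test_rule(self, lfc, padj, expected):
        de = pd.DataFrame({"log2fc": [lfc], "padj": [padj]}, index=["g"])
        assert classify_de_genes(de, CFG)["class"].iloc[0] == expected

    def test_negating_lfc_swaps_high_and_low(self, rng):
        de = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 100), "padj": rng.uniform(0, 0.1, 100)},
            index=[f"g{i}" for i in range(100)],
        )
        a = classify_de_genes(de, CFG)["class"]
        b = classify_de_genes(de.assign(log2fc=-de["log2fc"]), CFG)["class"]
        assert ((a == "high") == (b == "low")).all()
        assert ((a == "low") == (b == "high")).all()

    def test_high_low_disjoint(self, rng):
        de = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 200), "padj": rng.uniform(0, 1, 200)},
            index=[f"g{i}" for i in range(200)],
        )
        out = classify_de_genes(de, CFG)
        assert ((out["class"] == "high") & (out["class"] == "low")).sum() == 0

    def test_missing_padj_is_ns(self):
        de = pd.DataFrame({"log2fc": [3.0], "padj": [np.nan]}, index=["g"])
        assert classify_de_genes(de, CFG)["class"].iloc[0] == "ns"


class TestSimpleDeTest:
    def test_identical_groups_have_zero_lfc(self):
        tpm = [[3.0, 3.0, 3.0, 3.0]] * 5
        expr = _expr(tpm, index=[f"g{i}" for i in range(5)])
        out = simple_de_test(expr, {"s0": "test", "s1": "test", "s2": "ref", "s3": "ref"})
        assert (out["log2fc"] == 0).all()

    def test_planted_fourfold_gene_recovered(self, rng):
        n = 200
        base = rng.lognormal(np.log(10), 0.5, n)
        tpm = np.outer(base, np.ones(8)) * rng.lognormal(0, 0.05, (n, 8))
        # plant a 4x effect on gene 0 so log2(TPM+1) shifts by ~2
        tpm[0, :4] = (4 * base[0] + 3) * rng.lognormal(0, 0.02, 4)
        expr = _expr(tpm, index=[f"g{i}" for i in range(n)])
        labels = {f"s{i}": ("test" if i < 4 else "ref") for i in range(8)}
        out = simple_de_test(expr, labels)
        assert out.loc["g0", "log2fc"] == pytest.approx(2.0, abs=0.3)
        assert out.loc["g0", "padj"] < 0.05

    def test_label_permutation_within_group_is_inert(self):
        tpm = np.arange(40, dtype=float).reshape(5, 8)
        expr = _expr(tpm, index=[f"g{i}" for i in range(5)])
        l1 = {f"s{i}": ("test" if i < 4 else "ref") for i in range(8)}
        l2 = dict(l1)
        l2["s0"], l2["s1"] = l2["s1"], l2["s0"]
        pd.testing.assert_frame_equal(simple_de_test(expr, l1), simple_de_test(expr, l2))

    def test_small_group_rejected(self):
        expr = _expr([[1, 2, 3]], index=["g"])
        with pytest.raises(ValidationError):
            simple_de_test(expr, {"s0": "test", "s1": "ref", "s2": "ref"})


class TestMethylationSensitiveGenes:
    def _tables(self):
        de_a = pd.DataFrame(
            {
                "log2fc": [2.0, 2.0, 0.5],
                "padj": [0.01, 0.01, 0.01],
                "exon_dmr_overlap": [True, False, True],
            },
            index=["a_only", "both", "weak"],
        )
        de_b = pd.DataFrame(
            {
                "log2fc": [2.0, 2.0, 3.0],
                "padj": [0.01, 0.01, 0.01],
                "promoter_group": ["group1", "group3", "group1"],
            },
            index=["a_only", "both", "no_criteria"],
        )
        return de_a, de_b

    def test_union_semantics(self):
        de_a, de_b = self._tables()
        got = define_methylation_sensitive_genes(de_a, de_b, CFG)
        assert got == {"a_only", "both"}

    def test_exon_dmr_overlap_flags(self):
        from exmeth.meth_io import FeatureSet

        exons = FeatureSet(
            pd.DataFrame(
                {
                    "feature_id": ["e1", "e2"],
                    "gene_id": ["g1", "g2"],
                    "chrom": ["chr1", "chr1"],
                    "start": [100, 1000],
                    "end": [200, 1100],
                    "kind": ["gene", "gene"],
                }
            )
        )
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [260]})
        flags = flag_exon_dmr_overlap(exons, dmrs)
        assert flags["g1"] and not flags["g2"]


class TestEnrichment:
    def test_matches_fisher_oracle_on_small_tables(self, rng):
        from oracles import fisher_two_sided_oracle

        for _ in range(25):
            N = int(rng.integers(10, 60))
            genes = [f"g{i}" for i in range(N)]
            hits = list(rng.choice(genes, size=int(rng.integers(1, N // 2 + 1)), replace=False))
            flagged = list(rng.choice(genes, size=int(rng.integers(1, N // 2 + 1)), replace=False))
            table, _, p = enrichment_test(hits, genes, flagged)
            a, b = table[0]
            c, d = table[1]
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-6)

    def test_null_composition(self):
        genes = [f"g{i}" for i in range(100)]
        flagged = genes[:50]
        hits = genes[:5] + genes[50:55]  # same 50% composition
        _, odds, p = enrichment_test(hits, genes, flagged)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_fully_concentrated_hits(self):
        from oracles import hypergeom_tail_oracle

        genes = [f"g{i}" for i in range(20)]
        flagged = genes[:5]
        hits = genes[:5]
        _, _, p = enrichment_test(hits, genes, flagged)
        assert p == pytest.approx(hypergeom_tail_oracle(20, 5, 5, 5), rel=1e-6)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_test(["a"], [], ["a"])


class TestOverrepresentation:
    def test_size_filters(self):
        universe = [f"g{i}" for i in range(600)]
        collection = {
            "too_small": universe[:9],
            "ok": universe[:20],
            "too_big": universe[:501],
        }
        out = overrepresentation(universe[:15], collection, universe, CFG)
        assert set(out["set"]) == {"ok"}

    def test_dominant_set_ranks_first(self):
        universe = [f"g{i}" for i in range(200)]
        collection = {"target": universe[:20], "other": universe[100:140]}
        out = overrepresentation(universe[:10], collection, universe, CFG)
        assert out.iloc[0]["set"] == "target"
        assert out.iloc[0]["top"]

    def test_overlaps_match_set_intersection(self, rng):
        universe = [f"g{i}" for i in range(300)]
        hits = list(rng.choice(universe, 40, replace=False))
        collection = {
            f"s{k}": list(rng.choice(universe, int(rng.integers(10, 100)), replace=False))
            for k in range(8)
        }
        out = overrepresentation(hits, collection, universe, CFG).set_index("set")
        for name, members in collection.items():
            if name in out.index:
                assert out.loc[name, "overlap"] == len(set(hits) & set(members))

    def test_bh_q_at_least_p_and_monotone(self, rng):
        universe = [f"g{i}" for i in range(300)]
        hits = list(rng.choice(universe, 40, replace=False))
        collection = {
            f"s{k}": list(rng.choice(universe, 30, replace=False)) for k in range(10)
        }
        out = overrepresentation(hits, collection, universe, CFG)
        assert (out["q"] >= out["p"] - 1e-12).all()
        assert (out.sort_values("p")["q"].diff().dropna() >= -1e-12).all()

    def test_disjoint_hits_rejected(self):
        with pytest.raises(ValidationError):
            overrepresentation(["x"], {"s": ["g1"]}, ["g1", "g2"], CFG)


class TestZscoreKmeans:
    def test_rows_are_standardized(self, rng):
        m = pd.DataFrame(rng.normal(2, 3, (20, 6)))
        z = zscore_rows(m)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-9)

    def test_two_planted_groups_recovered(self, rng):
        up = np.tile([1.0, 1.0, -1.0, -1.0], (15, 1)) + rng.normal(0, 0.05, (15, 4))
        down = -np.tile([1.0, 1.0, -1.0, -1.0], (15, 1)) + rng.normal(0, 0.05, (15, 4))
        m = pd.DataFrame(np.vstack([up, down]), index=[f"g{i}" for i in range(30)])
        labels = zscore_kmeans(m, k=2, starts=10, seed=0)
        assert labels.iloc[:15].nunique() == 1
        assert labels.iloc[15:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_one_puts_everything_together(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (5, 4)))
        assert zscore_kmeans(m, k=1, starts=2, seed=0).nunique() == 1

    def test_k_exceeding_rows_rejected(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (3, 4)))
        with pytest.raises(ValidationError):
            zscore_kmeans(m, k=5, starts=2, seed=0)

    def test_deterministic_under_seed(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (30, 5)))
        a = zscore_kmeans(m, k=3, starts=5, seed=42)
        b = zscore_kmeans(m, k=3, starts=5, seed=42)
        pd.testing.assert_series_equal(a, b)


class TestIntegrate:
    def _levels(self, mapping):
        return pd.DataFrame(
            [
                {"gene_id": g, "level": v, "source": "cgi", "density_class": "ICP"}
                for g, v in mapping.items()
            ]
        )

    def test_sign_bookkeeping(self):
        de = pd.DataFrame(
            {"log2fc": [3.0, -2.0], "padj": [0.01, 0.01], "class": ["high", "low"]},
            index=["up", "down"],
        )
        table, rho, _, n_excl = integrate_delta_vs_lfc(
            de,
            self._levels({"up": 0.1, "down": 0.5}),
            self._levels({"up": 0.6, "down": 0.1}),
        )
        assert table.loc["up", "delta_promoter"] == pytest.approx(-0.5)
        assert table.loc["down", "delta_promoter"] == pytest.approx(0.4)
        assert rho == pytest.approx(-1.0)
        assert n_excl == 0

    def test_no_differential_genes_rejected(self):
        de = pd.DataFrame({"log2fc": [0.1], "padj": [0.9], "class": ["ns"]}, index=["g"])
        with pytest.raises(ValidationError, match="no differential genes"):
            integrate_delta_vs_lfc(de, self._levels({"g": 0.1}), self._levels({"g": 0.1}))

    def test_missing_levels_counted(self):
        de = pd.DataFrame(
            {"log2fc": [3.0, -2.0, 2.5], "padj": [0.01] * 3, "class": ["high", "low", "high"]},
            index=["a", "b", "c"],
        )
        table, _, _, n_excl = integrate_delta_vs_lfc(
            de,
            self._levels({"a": 0.1, "b": 0.5}),
            self._levels({"a": 0.6, "b": 0.1}),
        )
        assert n_excl == 1
        assert set(table.index) == {"a", "b"}
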