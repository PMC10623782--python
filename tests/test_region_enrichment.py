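import numpy as np
import pandas as pd
import pytest

from chm_atlas import region_enrichment as re_


def iv(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def per_base_observed(regions, feature, genome_length):
    """Brute-force per-base membership oracle (single chromosome 'c')."""
    in_r = np.zeros(genome_length, dtype=bool)
    in_f = np.zeros(genome_length, dtype=bool)
    for _, s, e in regions.itertuples(index=False):
        in_r[s:e] = True
    for _, s, e in feature.itertuples(index=False):
        in_f[s:e] = True
    return (in_r & in_f).sum() / in_r.sum(), in_f.sum() / genome_length


class TestEnrichmentScore:
    def test_stated_arithmetic_example(self):
        # 1000 bp of regions, 500 bp inside a 250 kb feature, 1 Mb genome
        regions = iv([("c", 0, 1000)])
        feature = iv([("c", 500, 250_500)])
        r = re_.enrichment_score(regions, feature, 1_000_000)
        assert r.observed_ratio == pytest.approx(0.5)
        assert r.expected_ratio == pytest.approx(0.25)
        assert r.score == pytest.approx(1.0)
        assert r.enriched

    def test_observed_equals_expected_scores_zero(self):
        regions = iv([("c", 0, 1000)])
        feature = iv([("c", 0, 500), ("c", 10_000, 510_000)])
        # observed = 0.5; expected = 510000-500+500... compute directly
        r = re_.enrichment_score(regions, feature, 1_000_000)
        obs, exp = per_base_observed(regions, feature, 1_000_000)
        assert r.score == pytest.approx(np.log2(obs / exp))

    def test_zero_overlap_is_neg_inf_not_enriched(self):
        r = re_.enrichment_score(iv([("c", 0, 100)]), iv([("c", 5000, 6000)]),
                                 1_000_000)
        assert r.score == float("-inf")
        assert not r.enriched

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            re_.enrichment_score(iv([]), iv([("c", 0, 100)]), 1000)
        with pytest.raises(ValueError):
            re_.enrichment_score(iv([("c", 0, 100)]), iv([]), 1000)

    def test_matches_per_base_oracle_on_100kb_toys(self):
        rng = np.random.default_rng(11)
        G = 100_000
        for _ in range(5):
            regions = iv([("c", int(s), int(s) + int(l))
                          for s, l in zip(rng.integers(0, G - 500, 25),
                                          rng.integers(50, 500, 25))])
            feature = iv([("c", int(s), int(s) + int(l))
                          for s, l in zip(rng.integers(0, G - 500, 15),
                                          rng.integers(100, 500, 15))])
            r = re_.enrichment_score(regions, feature, G)
            obs, exp = per_base_observed(regions, feature, G)
            assert r.observed_ratio == pytest.approx(obs, abs=0)
            assert r.expected_ratio == pytest.approx(exp, abs=0)

    def test_invariant_to_interval_splitting(self):
        regions = iv([("c", 0, 1000), ("c", 5000, 7000)])
        split = iv([("c", 0, 400), ("c", 400, 1000), ("c", 5000, 6000),
                    ("c", 6000, 7000)])
        feature = iv([("c", 500, 6000)])
        a = re_.enrichment_score(regions, feature, 100_000)
        b = re_.enrichment_score(split, feature, 100_000)
        assert a.score == b.score

    def test_doubling_genome_adds_one_to_score(self):
        regions = iv([("c", 0, 1000)])
        feature = iv([("c", 500, 20_500)])
        a = re_.enrichment_score(regions, feature, 1_000_000)
        b = re_.enrichment_score(regions, feature, 2_000_000)
        assert b.score == pytest.approx(a.score + 1.0)


class TestSubfamilyEnrichment:
    def _repeats(self):
        rows = [("c", 0, 1000, "partA", "ERVK"), ("c", 5000, 6000, "partA", "ERVK"),
                ("c", 50_000, 51_000, "partB", "ERV1"),
                ("c", 60_000, 61_000, "partB", "ERV1")]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "part", "family"])

    def test_fully_contained_part_has_ratio_one(self):
        regions = iv([("c", 0, 10_000)])
        out = re_.subfamily_enrichment(regions, self._repeats(), 1_000_000)
        row = out.set_index("part").loc["partA"]
        assert row["overlap_ratio"] == 1.0
        assert row["flagged"]

    def test_untouched_part_not_flagged(self):
        regions = iv([("c", 0, 10_000)])
        out = re_.subfamily_enrichment(regions, self._repeats(), 1_000_000)
        row = out.set_index("part").loc["partB"]
        assert row["overlap_ratio"] == 0.0
        assert not row["flagged"]

    def test_planted_young_ltr_flagged_on_synthetic(self, small_report):
        sub = pd.DataFrame(small_report["enrichment"]["subfamilies"])
        iap = sub.set_index("part").loc["sIAPEz-int"]
        assert iap["score"] >= 1.0
        assert iap["overlap_ratio"] > 0.10
        assert iap["flagged"]
        assert not sub.set_index("part").loc["sRLTR-old1", "flagged"]


class TestConservationCompare:
    def _cons(self, repeats, values):
        rows = [(r.chrom, r.start, r.end, v)
                for r, v in zip(repeats.itertuples(), values)]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])

    def _repeats(self):
        rows = [("c", i * 10_000, i * 10_000 + 1000,
                 "young" if i < 4 else "old", "LTR") for i in range(8)]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "part", "family"])

    def _enrich(self, enriched_parts):
        return pd.DataFrame({"part": ["young", "old"],
                             "enriched": [p in enriched_parts for p in ("young", "old")]})

    def test_constant_scores_not_significant(self):
        reps = self._repeats()
        out = re_.conservation_compare(reps, self._enrich({"young"}),
                                       self._cons(reps, [0.4] * 8))
        assert out["median_enriched"] == out["median_non_enriched"] == 0.4
        assert out["pvalue"] > 0.05

    def test_lower_conservation_in_enriched_group(self):
        reps = self._repeats()
        cons = self._cons(reps, [0.1, 0.12, 0.09, 0.11, 0.5, 0.55, 0.52, 0.48])
        out = re_.conservation_compare(reps, self._enrich({"young"}), cons)
        assert out["median_enriched"] < out["median_non_enriched"]

    def test_uncovered_elements_counted(self):
        reps = self._repeats()
        cons = self._cons(reps.iloc[:6], [0.1, 0.1, 0.1, 0.1, 0.5, 0.5])
        out = re_.conservation_compare(reps, self._enrich({"young"}), cons)
        assert out["n_uncovered"] == 2

    def test_empty_group_raises(self):
        reps = self._repeats()
        with pytest.raises(ValueError):
            re_.conservation_compare(reps, self._enrich(set()),
                                     self._cons(reps, [0.4] * 8))


class TestAssignTargets:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                           "strand"])

    def test_window_boundary_inclusive(self):
        regions = iv([("c", 50_000, 52_000)])
        # region's last base is 51,999; distance is min |tss - q|
        genes = self._genes([
            ("in9999", "c", 61_998, 63_000, "+"),   # TSS 9,999 bp away
            ("at10000", "c", 61_999, 63_000, "+"),  # exactly 10,000
            ("out10001", "c", 62_000, 63_000, "+"),
            ("inside", "c", 51_000, 53_000, "+"),
        ])
        tes = iv([])
        ta = re_.assign_targets(regions, genes, tes)
        assert set(ta.target_gene_ids) == {"in9999", "at10000", "inside"}
        d = dict(zip(ta.gene_targets["gene_id"], ta.gene_targets["distance"]))
        assert d["inside"] == 0
        assert d["in9999"] == 9999

    def test_minus_strand_tss_is_five_prime_end(self):
        regions = iv([("c", 0, 1000)])
        # minus-strand gene spanning [2000, 4000): TSS at 3999
        genes = self._genes([("gm", "c", 2000, 4000, "-")])
        ta = re_.assign_targets(regions, genes, iv([]))
        assert ta.nearest_tss_distance[0] == 3999 - 999  # to region's last base

    def test_te_needs_true_overlap(self):
        regions = iv([("c", 0, 1000)])
        tes = iv([("c", 999, 2000), ("c", 1000, 2000)])  # 1-bp overlap vs touching
        ta = re_.assign_targets(regions, self._genes([("g", "c", 0, 10, "+")]), tes)
        assert len(ta.te_targets) == 1
        assert ta.te_targets.iloc[0]["start"] == 999

    def test_strandless_gene_is_input_error(self):
        with pytest.raises(ValueError):
            re_.assign_targets(iv([("c", 0, 100)]),
                               self._genes([("g", "c", 0, 10, ".")]), iv([]))

    def test_matches_all_pairs_distance_oracle(self):
        rng = np.random.default_rng(3)
        G = 500_000
        regions = iv(sorted(("c", int(s), int(s) + 1000)
                            for s in rng.integers(0, G - 1000, 20)))
        genes = self._genes([(f"g{i}", "c", int(p), int(p) + 100, "+")
                             for i, p in enumerate(rng.integers(0, G - 100, 300))])
        ta = re_.assign_targets(regions, genes, iv([]))
        rs = regions["start"].to_numpy()
        re_nd = regions["end"].to_numpy()
        for gi, g in enumerate(genes.itertuples()):
            tss = g.start
            # oracle: explicit min over all regions of min |tss - q|
            d = min((0 if (s <= tss < e) else (s - tss if tss < s else tss - (e - 1)))
                    for s, e in zip(rs, re_nd))
            assert ta.nearest_tss_distance[gi] == d
            assert (f"g{gi}" in set(ta.target_gene_ids)) == (d <= 10_000)


class TestCompareExpression:
    def _tpm(self, gene_vals):
        rows = [(g, "p1", "s1", v) for g, v in gene_vals.items()]
        return pd.DataFrame(rows, columns=["gene_id", "process", "stage", "tpm"])

    def test_log2_tpm_plus_one_values(self):
        tpm = self._tpm({"a": 0.0, "b": 7.0})
        vals = re_.expression_values(["a", "b"], tpm)
        assert vals["a"] == 0.0
        assert vals["b"] == pytest.approx(3.0)

    def test_stage_averaging(self):
        rows = [("a", "p1", "s1", 1.0), ("a", "p1", "s2", 3.0)]
        tpm = pd.DataFrame(rows, columns=["gene_id", "process", "stage", "tpm"])
        assert re_.expression_values(["a"], tpm)["a"] == pytest.approx(
            (np.log2(2) + np.log2(4)) / 2)

    def test_missing_genes_counted(self):
        tpm = self._tpm({"a": 1.0, "b": 2.0, "c": 1.0, "d": 1.0})
        out = re_.compare_expression(
            {"x": ["a", "b", "ghost"], "y": ["c", "d"]}, tpm)
        assert out["n_missing_expression"]["x"] == 1

    def test_planted_repression_direction(self, small_report):
        expr = small_report["expression"]
        assert expr["medians"]["universalCHM"] < expr["medians"]["cpgRichNonCHM"]
        pair = [p for p in expr["pairwise"]
                if {p["class_a"], p["class_b"]} == {"universalCHM", "cpgRichNonCHM"}][0]
        assert pair["pvalue"] < 0.05
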