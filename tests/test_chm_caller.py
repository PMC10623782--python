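import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chm_atlas import chm_caller as cc
from chm_atlas.chm_caller import CallerThresholds
from chm_atlas.intervals import bins_of


def bin_frame(rows):
    """rows: (chrom, start, cpg_count, rpm, meth)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "cpg_count", "rpm", "meth"])
    df["end"] = df["start"] + 1000
    return df[["chrom", "start", "end", "cpg_count", "rpm", "meth"]]


FIXED = CallerThresholds(h_high=2.0, h_low=1.0, m_high=0.5, m_low=0.2)


class TestCallCandidates:
    def test_cpg_count_exactly_30_not_eligible(self):
        # eligibility is strict: more than 30 CpGs
        bins = bin_frame([("c", 0, 30, 10.0, 0.9)])
        assert len(cc.call_candidates(bins, FIXED)) == 0

    @pytest.mark.parametrize("rpm,meth,expected", [
        (3.0, 0.9, "CHM"),
        (3.0, 0.05, "CHnonM"),
        (0.5, 0.9, "CMnonH"),
        (2.0, 0.5, "CHM"),      # ties at thresholds are inclusive
        (1.5, 0.9, None),       # between h_low and h_high
        (3.0, 0.35, None),      # between m_low and m_high
    ])
    def test_threshold_rules(self, rpm, meth, expected):
        bins = bin_frame([("c", 0, 35, rpm, meth)])
        out = cc.call_candidates(bins, FIXED)
        if expected is None:
            assert len(out) == 0
        else:
            assert list(out["cls"]) == [expected]

    def test_adjacent_same_class_bins_fused(self):
        bins = bin_frame([("c", 0, 35, 3.0, 0.9), ("c", 1000, 35, 3.0, 0.9),
                          ("c", 3000, 35, 3.0, 0.9)])
        out = cc.call_candidates(bins, FIXED)
        assert len(out) == 2
        assert out.iloc[0]["end"] - out.iloc[0]["start"] == 2000

    def test_default_thresholds_from_genome_mean(self):
        # mean RPM = 1.02 -> h_high = 2.04: only the rpm=3 bin qualifies
        rows = [("c", i * 1000, 5, 1.0, 0.5) for i in range(98)]
        rows += [("c", 98_000, 35, 3.0, 0.9), ("c", 99_000, 35, 1.9, 0.9)]
        bins = bin_frame(rows)
        thr = CallerThresholds().resolve(bins)
        out = cc.call_candidates(bins, CallerThresholds())
        assert thr.h_high == pytest.approx(2.0 * bins["rpm"].mean())
        # only the bin at/above 2x the mean is a CHM
        assert list(out["cls"]) == ["CHM"]
        assert out.iloc[0]["start"] == 98_000

    def test_missing_rpm_is_input_error(self):
        bins = bin_frame([("c", 0, 35, np.nan, 0.9)])
        with pytest.raises(ValueError):
            cc.call_candidates(bins, FIXED)

    @given(rpm=st.floats(0, 10, allow_nan=False),
           meth=st.floats(0, 1, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_classes_mutually_exclusive(self, rpm, meth):
        bins = bin_frame([("c", 0, 35, rpm, meth)])
        out = cc.call_candidates(bins, FIXED)
        assert len(out) <= 1


class TestStabilityFilter:
    def _stage(self, present, cls="CHM"):
        if not present:
            return pd.DataFrame(columns=["chrom", "start", "end", "cls"])
        return pd.DataFrame({"chrom": "c", "start": [0], "end": [1000], "cls": cls})

    @pytest.mark.parametrize("n_present,n_stages,stable", [
        (6, 6, True),    # all stages
        (5, 6, True),    # 5 > 4
        (4, 6, False),   # 4 = 2/3 of 6, not strictly more
        (3, 4, True),    # 3 > 8/3
        (2, 4, False),
    ])
    def test_strict_two_thirds_rule(self, n_present, n_stages, stable):
        stages = [self._stage(i < n_present) for i in range(n_stages)]
        out, nonubiq = cc.stability_filter(stages, n_stages)
        assert (len(out["CHM"]) == 1) is stable
        assert (len(nonubiq["CHM"]) == 1) is (not stable and n_present > 0)

    def test_gte_rule_admits_exact_two_thirds(self):
        stages = [self._stage(i < 4) for i in range(6)]
        out, _ = cc.stability_filter(stages, 6, rule="gte")
        assert len(out["CHM"]) == 1

    def test_classes_tracked_independently(self):
        stages = [self._stage(True, "CHM") for _ in range(3)]
        out, _ = cc.stability_filter(stages, 3)
        assert len(out["CHM"]) == 1 and len(out["CHnonM"]) == 0


class TestMergeRegions:
    def test_gap_1999_merges(self):
        df = pd.DataFrame({"chrom": "c", "start": [0, 2999], "end": [1000, 4000]})
        assert len(cc.merge_regions(df, gap=2000)) == 1

    def test_gap_2000_merges_inclusive(self):
        df = pd.DataFrame({"chrom": "c", "start": [0, 3000], "end": [1000, 4000]})
        assert len(cc.merge_regions(df, gap=2000)) == 1

    def test_gap_2001_stays_split(self):
        df = pd.DataFrame({"chrom": "c", "start": [0, 3001], "end": [1000, 4000]})
        assert len(cc.merge_regions(df, gap=2000)) == 2

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 10)),
                    min_size=1, max_size=12))
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_order_invariant(self, raw):
        df = pd.DataFrame([("c", s * 100, (s + w) * 100) for s, w in raw],
                          columns=["chrom", "start", "end"])
        once = cc.merge_regions(df, gap=2000)
        twice = cc.merge_regions(once, gap=2000)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = df.sample(frac=1, random_state=0)
        pd.testing.assert_frame_equal(once, cc.merge_regions(shuffled, gap=2000))


def region(chrom, start, end):
    return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})


class TestClassifyAcrossProcesses:
    def _sets(self, presence):
        """presence: dict process -> list of region tuples."""
        return {p: pd.DataFrame(v, columns=["chrom", "start", "end"])
                for p, v in presence.items()}

    def test_universal_specific_and_neither(self):
        r = ("c", 0, 2000)
        other = ("c", 50_000, 52_000)
        three = ("c", 100_000, 102_000)
        sets = {f"p{i}": [r] for i in range(6)}
        sets["p0"] = [r, other]
        for i in range(3):
            sets[f"p{i}"].append(three)
        cat = cc.classify_across_processes(self._sets(sets))
        assert len(cat.universal) == 1
        assert tuple(cat.universal.iloc[0]) == r
        assert len(cat.specific["p0"]) == 1
        assert tuple(cat.specific["p0"].iloc[0]) == other
        # region in 3 of 6 processes: non-universal but not specific
        nu = set(map(tuple, cat.non_universal.itertuples(index=False)))
        assert three in nu and other in nu
        assert all(len(cat.specific[f"p{i}"]) == 0 for i in range(1, 6))

    def test_universal_and_non_universal_partition(self):
        sets = {"p1": [("c", 0, 2000), ("c", 9000, 10_000)],
                "p2": [("c", 0, 2000)]}
        cat = cc.classify_across_processes(self._sets(sets))
        all_regions = pd.concat([cat.universal, cat.non_universal])
        assert len(all_regions) == len(cat.processes_per_region)
        assert len(cat.universal.merge(cat.non_universal)) == 0

    def test_requires_two_processes(self):
        with pytest.raises(ValueError):
            cc.classify_across_processes({"p1": region("c", 0, 1000)})


class TestCpgRichNonChms:
    def _rich_bins(self, starts):
        return pd.DataFrame({"chrom": "c", "start": starts,
                             "end": [s + 1000 for s in starts],
                             "cpg_count": 40})

    def test_candidate_2500_bp_away_keeps_bin(self):
        cands = pd.DataFrame({"chrom": ["c"], "start": [3500], "end": [4500],
                              "cls": ["CHM"]})
        out = cc.define_cpg_rich_nonchms(self._rich_bins([0]), cands)
        assert len(out) == 1

    def test_candidate_within_2kb_excludes_bin(self):
        for cand_start in (1000, 2900):  # overlap-adjacent and 1.9 kb away
            cands = pd.DataFrame({"chrom": ["c"], "start": [cand_start],
                                  "end": [cand_start + 1000], "cls": ["CHM"]})
            assert len(cc.define_cpg_rich_nonchms(self._rich_bins([0]), cands)) == 0

    def test_exactly_2000_bp_excludes_inclusive(self):
        cands = pd.DataFrame({"chrom": ["c"], "start": [3000], "end": [4000],
                              "cls": ["CHM"]})
        assert len(cc.define_cpg_rich_nonchms(self._rich_bins([0]), cands)) == 0

    def test_no_candidates_keeps_everything(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "cls"])
        out = cc.define_cpg_rich_nonchms(self._rich_bins([0, 5000]), empty)
        assert len(out) == 2

    def test_only_chm_class_candidates_exclude(self):
        cands = pd.DataFrame({"chrom": ["c"], "start": [1500], "end": [2500],
                              "cls": ["CHnonM"]})
        out = cc.define_cpg_rich_nonchms(self._rich_bins([0]), cands)
        assert len(out) == 1


class TestNearbyCandidateFraction:
    def test_all_overlap_gives_100(self):
        el = region("c", 0, 1000)
        assert cc.nearby_candidate_fraction(el, region("c", 500, 600)) == 100.0

    def test_half_within_flank(self):
        el = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 10_000],
                           "end": [100, 10_100]})
        cand = region("c", 150, 250)
        assert cc.nearby_candidate_fraction(el, cand, flank=2000) == 50.0

    def test_zero_flank_is_plain_overlap(self):
        el = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 300],
                           "end": [100, 400]})
        cand = region("c", 50, 80)
        assert cc.nearby_candidate_fraction(el, cand, flank=0) == 50.0

    def test_empty_elements_error(self):
        with pytest.raises(ValueError):
            cc.nearby_candidate_fraction(
                pd.DataFrame(columns=["chrom", "start", "end"]),
                region("c", 0, 10))


def test_planted_marked_classes_never_called_chm(small_data, small_config):
    """CH-nonM / CM-nonH planted regions must not surface as CHMs."""
    from chm_atlas import pipeline, track_engine
    sequences, truth, tracks, _ = small_data
    bins = track_engine.count_cpgs(sequences)
    called = pipeline.call_all_processes(tracks, bins, CallerThresholds(),
                                         small_config)
    catalog = pipeline.build_catalog(called, bins)
    chm_bins = set()
    for d in called["per_process"].values():
        chm_bins |= bins_of(d["chms"], 1000)
    for cls in ("CHnonM", "CMnonH"):
        planted = bins_of(truth.by_class(cls), 1000)
        assert not planted & chm_bins
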