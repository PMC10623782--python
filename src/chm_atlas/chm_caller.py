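"""CHM candidate calling and cross-stage / cross-process classification.

The caller operates on the fixed 1-kb bin lattice. Per stage, CpG-rich bins
(strictly more than `cpg_min` CpGs) are classified by simple threshold rules
on mean H3K9me3 RPM and mean methylation:

  CHM      RPM >= h_high  and  meth >= m_high
  CHnonM   RPM >= h_high  and  meth <= m_low
  CMnonH   RPM <= h_low   and  meth >= m_high

h_high / h_low default to 2x / 1x the genome-wide mean bin RPM of the stage
being called. The classes are mutually exclusive for any thresholds with
h_low < h_high and m_low < m_high. Cross-stage stability requires a bin to
be a candidate in strictly more than two-thirds of a process's stages;
stable regions within 2 kb of each other are merged. Cross-process identity
is resolved on the bin lattice: a region is universal when it exists in all
processes and process-specific when it exists in exactly one.

NOTE: the original published analyses used an external caller whose internal
thresholds are not part of this package; the rules above re-specify the
candidate definitions explicitly and every threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (BED_COLS, bins_of, bins_to_intervals, merge_intervals,
                        overlaps_any)

CANDIDATE_CLASSES = ("CHM", "CHnonM", "CMnonH")


@dataclass
class CallerThresholds:
    """Candidate-calling thresholds; None means derive from the stage."""

    cpg_min: int = 30          # strict: a bin needs > cpg_min CpGs
    h_high: float | None = None   # default 2x genome-wide mean bin RPM
    h_low: float | None = None    # default genome-wide mean bin RPM
    m_high: float = 0.5
    m_low: float = 0.2

    def resolve(self, bins: pd.DataFrame) -> "CallerThresholds":
        mean_rpm = float(bins["rpm"].mean())
        h_high = 2.0 * mean_rpm if self.h_high is None else self.h_high
        h_low = mean_rpm if self.h_low is None else self.h_low
        out = CallerThresholds(cpg_min=self.cpg_min, h_high=h_high,
                               h_low=h_low, m_high=self.m_high, m_low=self.m_low)
        out.validate()
        return out

    def validate(self) -> None:
        if self.h_high is not None and self.h_low is not None \
                and not self.h_low < self.h_high:
            raise ValueError("h_low must be < h_high")
        if not self.m_low < self.m_high:
            raise ValueError("m_low must be < m_high")


def call_candidates(bins: pd.DataFrame,
                    thresholds: CallerThresholds | None = None) -> pd.DataFrame:
    """Classify CpG-rich bins of one stage and fuse adjacent same-class bins.

    `bins` is a bin_signal frame (chrom, start, end, cpg_count, rpm, meth).
    Returns candidate intervals with columns chrom, start, end, cls. Bins at
    exact thresholds are included (>= / <= as written in the rules).
    """
    if "rpm" not in bins.columns or bins["rpm"].isna().any():
        raise ValueError("bins must carry a complete rpm column")
    thr = (thresholds or CallerThresholds()).resolve(bins)
    rich = bins["cpg_count"] > thr.cpg_min
    # a CpG-rich bin always has CpGs, hence a defined methylation mean
    meth = bins["meth"]
    rpm = bins["rpm"]
    label = np.full(len(bins), "", dtype=object)
    label[(rich & (rpm >= thr.h_high) & (meth >= thr.m_high)).to_numpy()] = "CHM"
    label[(rich & (rpm >= thr.h_high) & (meth <= thr.m_low)).to_numpy()] = "CHnonM"
    label[(rich & (rpm <= thr.h_low) & (meth >= thr.m_high)).to_numpy()] = "CMnonH"
    out = []
    called = bins[label != ""].assign(cls=label[label != ""])
    for (chrom, cls), sub in called.groupby(["chrom", "cls"]):
        fused = merge_intervals(sub[BED_COLS], gap=0)
        fused["cls"] = cls
        out.append(fused)
    if not out:
        return pd.DataFrame(columns=BED_COLS + ["cls"])
    return pd.concat(out, ignore_index=True) \
        .sort_values(["chrom", "start", "cls"]).reset_index(drop=True)


def stability_filter(stage_candidates: Sequence[pd.DataFrame], n_stages: int,
                     bin_size: int = 1000, rule: str = "strict"
                     ) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Cross-stage filter at bin resolution.

    A bin is stable for a class when it is a candidate of that class in
    strictly more than 2/3 of the process's stages ("strict"; pass
    rule="gte" for >=, for sensitivity analysis). Returns
    (stable regions per class, non-ubiquitous regions per class), each with
    adjacent bins fused.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    if len(stage_candidates) != n_stages:
        raise ValueError("one candidate frame per stage required")
    cutoff = 2.0 * n_stages / 3.0
    stable: dict[str, pd.DataFrame] = {}
    nonubiq: dict[str, pd.DataFrame] = {}
    for cls in CANDIDATE_CLASSES:
        counts: dict[tuple[str, int], int] = {}
        for cand in stage_candidates:
            sub = cand[cand["cls"] == cls]
            for b in bins_of(sub, bin_size):
                counts[b] = counts.get(b, 0) + 1
        if rule == "strict":
            keep = {b for b, c in counts.items() if c > cutoff}
        elif rule == "gte":
            keep = {b for b, c in counts.items() if c >= cutoff}
        else:
            raise ValueError("rule must be 'strict' or 'gte'")
        stable[cls] = bins_to_intervals(keep, bin_size)
        nonubiq[cls] = bins_to_intervals(set(counts) - keep, bin_size)
    return stable, nonubiq


def merge_regions(regions: pd.DataFrame, gap: int = 2000) -> pd.DataFrame:
    """Merge neighboring regions whose edge gap is <= `gap` bp (inclusive)."""
    return merge_intervals(regions, gap=gap)


@dataclass
class RegionCatalog:
    """Classified region sets for the whole study."""

    per_process_chms: dict[str, pd.DataFrame]
    universal: pd.DataFrame
    non_universal: pd.DataFrame
    specific: dict[str, pd.DataFrame]         # process -> its specific CHMs
    processes_per_region: pd.DataFrame        # chrom,start,end,n_processes
    chnonm_universal: pd.DataFrame = field(default_factory=pd.DataFrame)
    cmnonh_universal: pd.DataFrame = field(default_factory=pd.DataFrame)
    cpg_rich_nonchm: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> dict:
        n_all = len(self.universal) + len(self.non_universal)
        return {
            "n_chms": n_all,
            "n_universal": len(self.universal),
            "n_non_universal": len(self.non_universal),
            "pct_universal": round(100.0 * len(self.universal) / n_all, 2) if n_all else 0.0,
            "specific_counts": {p: len(df) for p, df in self.specific.items()},
            "n_cpg_rich_nonchm": len(self.cpg_rich_nonchm),
        }


def classify_across_processes(process_chms: Mapping[str, pd.DataFrame],
                              bin_size: int = 1000, gap: int = 2000
                              ) -> RegionCatalog:
    """Partition CHMs into universal / non-universal / process-specific.

    Cross-process regions are the 2-kb-merged cover of the union of all
    processes' CHMs; a region exists in a process when it overlaps at least
    one of that process's CHM bins.
    """
    if len(process_chms) < 2:
        raise ValueError("need >= 2 processes to classify across processes")
    union = pd.concat([df[BED_COLS] for df in process_chms.values()],
                      ignore_index=True)
    if len(union) == 0:
        empty = pd.DataFrame(columns=BED_COLS)
        return RegionCatalog(per_process_chms=dict(process_chms), universal=empty,
                             non_universal=empty.copy(),
                             specific={p: empty.copy() for p in process_chms},
                             processes_per_region=pd.DataFrame(
                                 columns=BED_COLS + ["n_processes"]))
    regions = merge_intervals(union, gap=gap)
    presence = np.zeros((len(regions), len(process_chms)), dtype=bool)
    names = list(process_chms)
    for j, p in enumerate(names):
        presence[:, j] = overlaps_any(regions, process_chms[p])
    n_proc = presence.sum(axis=1)
    ppr = regions.assign(n_processes=n_proc)
    universal = regions[n_proc == len(names)].reset_index(drop=True)
    non_universal = regions[n_proc < len(names)].reset_index(drop=True)
    specific = {p: regions[(n_proc == 1) & presence[:, j]].reset_index(drop=True)
                for j, p in enumerate(names)}
    return RegionCatalog(per_process_chms=dict(process_chms), universal=universal,
                         non_universal=non_universal, specific=specific,
                         processes_per_region=ppr)


def define_cpg_rich_nonchms(cpg_rich_bins: pd.DataFrame,
                            all_candidates: pd.DataFrame,
                            flank: int = 2000) -> pd.DataFrame:
    """CpG-rich bins with no CHM candidate within `flank` bp (inclusive,
    edge-to-edge), candidates pooled across every stage of every process.

    Returns the surviving bins fused into maximal regions.
    """
    chm_cands = all_candidates[all_candidates["cls"] == "CHM"] \
        if "cls" in all_candidates.columns else all_candidates
    if len(chm_cands) == 0:
        keep = cpg_rich_bins
    else:
        near = overlaps_any(cpg_rich_bins, chm_cands, flank=flank)
        keep = cpg_rich_bins[~near]
    return merge_intervals(keep[BED_COLS], gap=0)


def nearby_candidate_fraction(elements: pd.DataFrame, candidates: pd.DataFrame,
                              flank: int = 2000) -> float:
    """Percentage of elements overlapping or within `flank` bp of >= 1
    candidate."""
    if len(elements) == 0:
        raise ValueError("element set is empty")
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    hit = overlaps_any(elements, candidates, flank=flank)
    return 100.0 * float(hit.mean())
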