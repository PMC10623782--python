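"""Sorted-sweep interval arithmetic on (chrom, start, end) DataFrames.

All coordinates are 0-based half-open (BED convention). The helpers here are
the primitives behind region merging, enrichment overlap lengths and
neighbor/distance queries; each is checked against brute-force per-base
oracles in the test suite.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

BED_COLS = ["chrom", "start", "end"]


def as_frame(intervals: Iterable[tuple] | pd.DataFrame) -> pd.DataFrame:
    """Coerce an iterable of (chrom, start, end[, ...]) tuples to a frame."""
    if isinstance(intervals, pd.DataFrame):
        return intervals
    return pd.DataFrame(list(intervals), columns=BED_COLS)


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Transitive closure of the "edge gap <= `gap`" relation, per chromosome.

    gap=0 fuses touching/overlapping intervals only. Output is sorted and
    non-overlapping; idempotent and independent of input row order.
    """
    if len(df) == 0:
        return pd.DataFrame(columns=BED_COLS)
    df = sort_intervals(df[BED_COLS])
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLS)


def total_length(df: pd.DataFrame, merged: bool = False) -> int:
    """Total bp covered; self-overlaps collapsed unless `merged` is known."""
    if not merged:
        df = merge_intervals(df)
    if len(df) == 0:
        return 0
    return int((df["end"] - df["start"]).sum())


def overlap_length(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """bp of overlap between the merged covers of two interval sets."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    total = 0
    for chrom, sub_a in a.groupby("chrom"):
        sub_b = b[b["chrom"] == chrom]
        if len(sub_b) == 0:
            continue
        sa, ea = sub_a["start"].to_numpy(), sub_a["end"].to_numpy()
        sb, eb = sub_b["start"].to_numpy(), sub_b["end"].to_numpy()
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += hi - lo
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return int(total)


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame, flank: int = 0) -> np.ndarray:
    """Boolean per query row: is some subject interval within `flank` bp?

    Edge-to-edge distance, inclusive: a subject exactly `flank` bp away
    counts. With flank=0 this is overlap-or-touching (edge distance 0).
    """
    result = np.zeros(len(query), dtype=bool)
    subject = merge_intervals(subject)
    by_chrom = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
                for c, sub in subject.groupby("chrom")}
    chroms = query["chrom"].to_numpy()
    starts = query["start"].to_numpy()
    ends = query["end"].to_numpy()
    for idx in range(len(query)):
        hit = by_chrom.get(chroms[idx])
        if hit is None:
            continue
        ss, ee = hit
        qs = starts[idx] - flank
        qe = ends[idx] + flank
        # first subject interval with end >= qs
        j = int(np.searchsorted(ee, qs, side="left"))
        result[idx] = j < len(ss) and ss[j] <= qe
    return result


def edge_distances(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Edge-to-edge distance (bp, 0 if touching/overlapping) to nearest subject.

    Returns inf for query rows on chromosomes with no subject interval.
    """
    subject = merge_intervals(subject)
    by_chrom = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
                for c, sub in subject.groupby("chrom")}
    out = np.full(len(query), np.inf)
    chroms = query["chrom"].to_numpy()
    starts = query["start"].to_numpy()
    ends = query["end"].to_numpy()
    for idx in range(len(query)):
        hit = by_chrom.get(chroms[idx])
        if hit is None:
            continue
        ss, ee = hit
        qs, qe = starts[idx], ends[idx]
        j = int(np.searchsorted(ss, qe))
        best = np.inf
        if j < len(ss):
            best = min(best, max(0, ss[j] - qe))
        if j > 0:
            best = min(best, max(0, qs - ee[j - 1]))
        out[idx] = best
    return out


def point_to_interval_distances(chroms: np.ndarray, positions: np.ndarray,
                                subject: pd.DataFrame) -> np.ndarray:
    """Distance from points (e.g. TSSs) to the nearest subject interval:
    min |p - q| over contained positions q, hence 0 for a point inside."""
    subject = merge_intervals(subject)
    by_chrom = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
                for c, sub in subject.groupby("chrom")}
    out = np.full(len(positions), np.inf)
    for idx in range(len(positions)):
        hit = by_chrom.get(chroms[idx])
        if hit is None:
            continue
        ss, ee = hit
        p = positions[idx]
        j = int(np.searchsorted(ss, p, side="right"))
        best = np.inf
        if j > 0:
            best = 0 if p < ee[j - 1] else p - (ee[j - 1] - 1)
        if best > 0 and j < len(ss):
            best = min(best, ss[j] - p)
        out[idx] = best
    return out


def bins_of(df: pd.DataFrame, bin_size: int) -> set[tuple[str, int]]:
    """Set of lattice bins (chrom, bin_index) overlapped by the intervals."""
    bins: set[tuple[str, int]] = set()
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        bins.update((chrom, b) for b in range(int(start) // bin_size,
                                              (int(end) - 1) // bin_size + 1))
    return bins


def bins_to_intervals(bins: set[tuple[str, int]], bin_size: int) -> pd.DataFrame:
    """Fuse a set of lattice bins back into sorted maximal intervals."""
    rows = [(c, b * bin_size, (b + 1) * bin_size) for c, b in bins]
    return merge_intervals(pd.DataFrame(rows, columns=BED_COLS)) if rows else \
        pd.DataFrame(columns=BED_COLS)
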