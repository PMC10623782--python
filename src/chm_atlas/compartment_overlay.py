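"""A/B compartment consistency of region sets across five cell types.

Each cell type contributes a compartment map (disjoint A and B intervals;
everything else is "neither"). A region's per-cell-type label is the
compartment with the greatest overlapped length (exact A/B tie -> neither).
Across the five cell types a region is A or B when all five agree, "other"
when it is outside A/B in all five, and "inconsistent" for any mixture
involving A or B — so the four labels partition any region set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import merge_intervals

CONSISTENCY_LABELS = ("A", "B", "inconsistent", "other")
N_CELL_TYPES = 5


@dataclass
class CompartmentMap:
    """One cell type's A/B intervals (label column holds 'A' or 'B')."""

    cell_type: str
    intervals: pd.DataFrame  # chrom, start, end, label

    def __post_init__(self) -> None:
        bad = set(self.intervals["label"]) - {"A", "B"}
        if bad:
            raise ValueError(f"unexpected compartment labels: {bad}")

    @classmethod
    def from_bed(cls, cell_type: str, path) -> "CompartmentMap":
        df = pd.read_csv(path, sep="\t", header=None,
                         usecols=[0, 1, 2, 3],
                         names=["chrom", "start", "end", "label"])
        return cls(cell_type=cell_type, intervals=df)


def _overlap_per_region(regions: pd.DataFrame, comp: pd.DataFrame) -> np.ndarray:
    """bp of overlap of each region with a merged interval set."""
    comp = merge_intervals(comp)
    by_chrom = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
                for c, sub in comp.groupby("chrom")}
    out = np.zeros(len(regions), dtype=np.int64)
    for i, (chrom, qs, qe) in enumerate(zip(regions["chrom"], regions["start"],
                                            regions["end"])):
        hit = by_chrom.get(chrom)
        if hit is None:
            continue
        ss, ee = hit
        lo = int(np.searchsorted(ee, qs, side="right"))
        hi = int(np.searchsorted(ss, qe, side="left"))
        for j in range(lo, hi):
            out[i] += max(0, min(qe, ee[j]) - max(qs, ss[j]))
    return out


def region_compartment(regions: pd.DataFrame, cmap: CompartmentMap) -> np.ndarray:
    """Per-region label in {A, B, neither} by majority overlapped length.

    Zero A+B overlap (including regions on chromosomes absent from the map)
    gives "neither"; an exact A/B tie also gives "neither" rather than
    inventing a preference.
    """
    if ((regions["end"] - regions["start"]) <= 0).any():
        raise ValueError("regions must have positive length")
    a_len = _overlap_per_region(regions, cmap.intervals[cmap.intervals["label"] == "A"])
    b_len = _overlap_per_region(regions, cmap.intervals[cmap.intervals["label"] == "B"])
    out = np.full(len(regions), "neither", dtype=object)
    out[a_len > b_len] = "A"
    out[b_len > a_len] = "B"
    return out


def consistency(regions: pd.DataFrame,
                maps: Sequence[CompartmentMap]) -> np.ndarray:
    """Per-region consistency label across exactly N_CELL_TYPES maps.

    Permutation-invariant over cell types.
    """
    if len(maps) != N_CELL_TYPES:
        raise ValueError(f"expected {N_CELL_TYPES} compartment maps, got {len(maps)}")
    labels = np.stack([region_compartment(regions, m) for m in maps])
    out = np.full(len(regions), "inconsistent", dtype=object)
    out[(labels == "A").all(axis=0)] = "A"
    out[(labels == "B").all(axis=0)] = "B"
    out[(labels == "neither").all(axis=0)] = "other"
    return out


def tabulate(catalog: Mapping[str, pd.DataFrame],
             maps: Sequence[CompartmentMap]) -> pd.DataFrame:
    """Counts and percentages of consistency labels per region class.

    Percentages are 100 * count / class total, rounded to 2 decimals.
    """
    rows = []
    for cls, regions in catalog.items():
        total = len(regions)
        if total == 0:
            for lab in CONSISTENCY_LABELS:
                rows.append({"region_class": cls, "label": lab, "count": 0,
                             "percent": 0.0})
            continue
        labels = consistency(regions, maps)
        for lab in CONSISTENCY_LABELS:
            n = int((labels == lab).sum())
            rows.append({"region_class": cls, "label": lab, "count": n,
                         "percent": round(100.0 * n / total, 2)})
    return pd.DataFrame(rows)
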