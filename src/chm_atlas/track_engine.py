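"""Binned-track numerics for H3K9me3 / DNA-methylation co-occupancy analysis.

Everything downstream aggregates onto a fixed 1-kb bin lattice per
chromosome: CpG counts per bin, the DNAme-amount sliding-window track
(methylation level x CpG number per 1-kb window, 10-bp step), per-bin mean
RPM and methylation, meta-profiles around region sets, and the
CpG-count-class correlation between the two marks.

Coordinates are 0-based half-open. A CpG site is the C of a CG dinucleotide
on the forward strand; the two strands' cytosines are pooled into that one
site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_C = ord("C")
_G = ord("G")


def _seq_bytes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    if isinstance(seq, str):
        seq = seq.encode()
    return np.frombuffer(bytes(seq).upper(), dtype=np.uint8)


def cpg_positions(seq) -> np.ndarray:
    """Forward-strand positions of the C in each CG dinucleotide."""
    b = _seq_bytes(seq)
    if len(b) < 2:
        return np.empty(0, dtype=np.int64)
    return np.where((b[:-1] == _C) & (b[1:] == _G))[0].astype(np.int64)


@dataclass
class BinnedGenome:
    """Fixed tiling of a genome with per-bin CpG counts.

    The last bin of each chromosome may be partial (shorter than bin_size);
    it is retained and its true length is recoverable from chrom_sizes.
    """

    bin_size: int
    chrom_sizes: dict[str, int]
    cpg: dict[str, np.ndarray]  # per-chrom int array, one entry per bin

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)

    def bin_length(self, chrom: str, idx: int) -> int:
        return min(self.bin_size, self.chrom_sizes[chrom] - idx * self.bin_size)

    def bins_df(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.chrom_sizes):
            n = self.n_bins(chrom)
            starts = np.arange(n, dtype=np.int64) * self.bin_size
            ends = np.minimum(starts + self.bin_size, self.chrom_sizes[chrom])
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": ends,
                "cpg_count": self.cpg[chrom].astype(np.int64),
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class StageData:
    """One developmental stage: per-CpG methylation plus H3K9me3 RPM signal.

    meth maps chrom -> (positions, levels); levels are fractional in [0, 1].
    signal maps chrom -> dense per-step RPM array (step bp per entry).
    """

    process_id: str
    stage_id: str
    meth: dict[str, tuple[np.ndarray, np.ndarray]]
    signal: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    step: int = 10

    def validate(self) -> None:
        for chrom, (pos, lev) in self.meth.items():
            if len(pos) and (lev.min() < 0 or lev.max() > 1):
                raise ValueError(f"methylation level outside [0,1] on {chrom}")
        for chrom, sig in self.signal.items():
            if not np.all(np.isfinite(sig)):
                raise ValueError(f"non-finite RPM on {chrom}")


def count_cpgs(sequences: Mapping[str, str], bin_size: int = 1000) -> BinnedGenome:
    """Per-bin CG-dinucleotide counts; a CG straddling a bin boundary is
    assigned to the bin containing its C."""
    sizes: dict[str, int] = {}
    cpg: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        b = _seq_bytes(seq)
        sizes[chrom] = len(b)
        n = max(1, -(-len(b) // bin_size)) if len(b) else 0
        pos = cpg_positions(b)
        counts = np.bincount(pos // bin_size, minlength=n) if n else np.empty(0, int)
        cpg[chrom] = counts.astype(np.int64)
    return BinnedGenome(bin_size=bin_size, chrom_sizes=sizes, cpg=cpg)


def dname_amount(stage: StageData, cpg_pos: Mapping[str, np.ndarray] | None = None,
                 window: int = 1000, step: int = 10) -> pd.DataFrame:
    """DNAme-amount track: per sliding window, mean per-CpG methylation level
    times CpG count, emitted at the window's center position.

    Windows of zero CpGs emit amount 0 (dense track). Returns a frame with
    columns chrom, position (window center), level, cpg_count, amount.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    frames = []
    for chrom in sorted(stage.meth):
        pos, lev = stage.meth[chrom]
        if cpg_pos is not None:
            gpos = np.asarray(cpg_pos[chrom])
        else:
            gpos = pos
        size = stage.chrom_sizes[chrom]
        if size < window:
            continue
        starts = np.arange(0, size - window + 1, step, dtype=np.int64)
        # genomic CpG count per window
        n_cpg = np.searchsorted(gpos, starts + window) - np.searchsorted(gpos, starts)
        # covered methylation sum per window
        csum = np.concatenate([[0.0], np.cumsum(lev)])
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, starts + window)
        m_sum = csum[hi] - csum[lo]
        m_n = hi - lo
        with np.errstate(invalid="ignore"):
            level = np.where(m_n > 0, m_sum / np.maximum(m_n, 1), 0.0)
        amount = level * n_cpg
        frames.append(pd.DataFrame({
            "chrom": chrom, "position": starts + window // 2,
            "level": level, "cpg_count": n_cpg, "amount": amount,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "position", "level", "cpg_count", "amount"])
    return pd.concat(frames, ignore_index=True)


def bin_signal(stage: StageData, bins: BinnedGenome) -> pd.DataFrame:
    """Aggregate a stage's tracks onto the bin lattice.

    Returns one row per bin: chrom, start, end, cpg_count, rpm
    (length-weighted mean over the dense signal), meth (mean per-CpG level,
    NaN when the bin has no covered CpG).
    """
    if bins.bin_size % stage.step != 0:
        raise ValueError("bin_size must be a multiple of the signal step")
    missing = set(bins.chrom_sizes) - set(stage.signal)
    if missing:
        raise ValueError(f"signal missing for chromosomes: {sorted(missing)}")
    out = bins.bins_df()
    rpm = np.empty(len(out))
    meth = np.full(len(out), np.nan)
    offset = 0
    for chrom in sorted(bins.chrom_sizes):
        n = bins.n_bins(chrom)
        size = bins.chrom_sizes[chrom]
        sig = stage.signal[chrom]
        n_rec = -(-size // stage.step)
        if len(sig) != n_rec:
            raise ValueError(f"signal length mismatch on {chrom}")
        rec_start = np.arange(n_rec, dtype=np.int64) * stage.step
        cov = np.minimum(stage.step, size - rec_start).astype(float)
        bidx = rec_start // bins.bin_size
        wsum = np.bincount(bidx, weights=sig * cov, minlength=n)
        wtot = np.bincount(bidx, weights=cov, minlength=n)
        rpm[offset:offset + n] = wsum / wtot
        pos, lev = stage.meth.get(chrom, (np.empty(0, int), np.empty(0)))
        if len(pos):
            mb = pos // bins.bin_size
            msum = np.bincount(mb, weights=lev, minlength=n)
            mcnt = np.bincount(mb, minlength=n)
            has = mcnt > 0
            meth[offset:offset + n][has] = msum[has] / mcnt[has]
        offset += n
    out["rpm"] = rpm
    out["meth"] = meth
    return out


def profile_around(regions: pd.DataFrame, track: Mapping[str, np.ndarray],
                   chrom_sizes: Mapping[str, int], step: int = 10,
                   flank: int = 50_000, n_body: int = 50,
                   n_flank: int = 50) -> pd.DataFrame:
    """Mean signal meta-profile: fixed-bp flanks, body scaled to n_body points.

    Positions outside the chromosome are masked (NaN) rather than erroring,
    so regions near chromosome edges contribute truncated profiles.
    Returns a frame with columns x (bp from region start; body points use
    scaled coordinates) and mean.
    """
    if len(regions) == 0:
        raise ValueError("profile_around requires a non-empty region set")
    n_pts = n_flank + n_body + n_flank
    mat = np.full((len(regions), n_pts), np.nan)
    for i, (chrom, start, end) in enumerate(
            zip(regions["chrom"], regions["start"], regions["end"])):
        arr = track.get(chrom)
        if arr is None:
            continue
        size = chrom_sizes[chrom]
        left = start - flank + (np.arange(n_flank) + 0.5) * flank / n_flank
        body = start + (np.arange(n_body) + 0.5) * (end - start) / n_body
        right = end + (np.arange(n_flank) + 0.5) * flank / n_flank
        pts = np.concatenate([left, body, right])
        ok = (pts >= 0) & (pts < size)
        idx = np.minimum(pts[ok].astype(np.int64) // step, len(arr) - 1)
        mat[i, ok] = arr[idx]
    x = np.concatenate([
        -flank + (np.arange(n_flank) + 0.5) * flank / n_flank,
        (np.arange(n_body) + 0.5) / n_body,        # body in region-relative units
        (np.arange(n_flank) + 0.5) * flank / n_flank,
    ])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(mat, axis=0)
    seg = np.array(["flank5"] * n_flank + ["body"] * n_body + ["flank3"] * n_flank)
    return pd.DataFrame({"x": x, "segment": seg, "mean": mean})


DEFAULT_CLASS_BOUNDS = (10, 30)


def cpg_class_correlation(bins: pd.DataFrame,
                          class_bounds: tuple[int, int] = DEFAULT_CLASS_BOUNDS,
                          min_bins: int = 3) -> pd.DataFrame:
    """Spearman correlation of per-bin RPM vs methylation within CpG-count
    classes (poor <= lo, mid lo+1..hi, rich > hi).

    Bins with missing methylation are dropped. Classes with a constant
    vector get rho = NaN (flagged undefined).
    """
    lo, hi = class_bounds
    usable = bins.dropna(subset=["rpm", "meth"])
    labels = np.where(usable["cpg_count"] <= lo, "cpg_poor",
                      np.where(usable["cpg_count"] <= hi, "cpg_mid", "cpg_rich"))
    rows = []
    for name in ("cpg_poor", "cpg_mid", "cpg_rich"):
        sub = usable[labels == name]
        if len(sub) < min_bins:
            raise ValueError(f"class {name} has fewer than {min_bins} usable bins")
        if sub["rpm"].nunique() < 2 or sub["meth"].nunique() < 2:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(sub["rpm"], sub["meth"])
        rows.append({"cpg_class": name, "n": len(sub), "rho": rho, "pvalue": p})
    return pd.DataFrame(rows)
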