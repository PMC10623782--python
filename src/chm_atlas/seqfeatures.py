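"""Sequence-level features: canonical k-mers, discrimination AUC, CpG
frequency and methylated ZFP57-motif counts.

k-mers (1 <= k <= 6) are keyed by their canonical form — the
lexicographic minimum of the k-mer and its reverse complement — so a
sequence and its reverse complement produce identical tables by
construction. The canonical universe for k in 1..6 has 2,772 members.

The per-k-mer AUC between two sequence classes is the normalized
Mann-Whitney U (probability that a class-1 frequency exceeds a class-0
frequency, ties half credit), identical to the area under the ROC curve of
the frequency used as a score. AUC is symmetric under reverse complement
because the frequencies are.

ZFP57 binds the methylated motif TGCmCGC, i.e. the hexamer TGCCGC with the
methyl mark on its internal CpG; hits are scanned on both strands and count
as methylated when that CpG's level is >= 0.5 in strictly more than 2/3 of
stages.
"""

from __future__ import annotations

from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_COMP = str.maketrans("ACGT", "TGCA")
ZFP57_HEXAMER = "TGCCGC"


def revcomp(kmer: str) -> str:
    return kmer.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def all_canonical_kmers(k_max: int = 6) -> list[str]:
    """All canonical k-mers for k in 1..k_max (2,772 for k_max=6)."""
    out: list[str] = []
    for k in range(1, k_max + 1):
        seen = set()
        for tup in product("ACGT", repeat=k):
            km = "".join(tup)
            c = canonical(km)
            if c not in seen:
                seen.add(c)
                out.append(c)
    return out


def _seq_counts(seq: str, k: int) -> tuple[dict[str, int], int]:
    """Canonical k-mer counts and the number of valid positions.

    Positions whose k-mer overlaps a non-ACGT character are skipped and
    removed from the denominator.
    """
    counts: dict[str, int] = {}
    valid = 0
    n = len(seq)
    for i in range(n - k + 1):
        km = seq[i:i + k]
        if any(ch not in "ACGT" for ch in km):
            continue
        valid += 1
        c = canonical(km)
        counts[c] = counts.get(c, 0) + 1
    return counts, valid


def kmer_frequencies(sequences: Sequence[str], k_max: int = 6) -> pd.DataFrame:
    """Canonical k-mer frequency table: rows = canonical k-mers, columns =
    sequence index, frequency = count / valid positions.

    Overlapping occurrences are counted; a k-mer and its reverse complement
    pool under one canonical key (equivalent to scanning both strands of
    one orientation).
    """
    kmers = all_canonical_kmers(k_max)
    index = {km: i for i, km in enumerate(kmers)}
    mat = np.zeros((len(kmers), len(sequences)))
    for j, seq in enumerate(sequences):
        seq = seq.upper()
        if len(seq) < 1:
            raise ValueError("sequences must be non-empty")
        for k in range(1, k_max + 1):
            if len(seq) < k:
                continue
            counts, valid = _seq_counts(seq, k)
            if valid == 0:
                continue
            for km, c in counts.items():
                mat[index[km], j] = c / valid
    return pd.DataFrame(mat, index=pd.Index(kmers, name="kmer"))


def kmer_auc(table_class1: pd.DataFrame, table_class0: pd.DataFrame) -> pd.DataFrame:
    """Per-k-mer AUC for class-1 (labeled 1) vs class-0 frequencies.

    Returns kmer, auc, discriminative_auc = max(auc, 1-auc), direction.
    Exactly equals the normalized Mann-Whitney U with half credit for ties;
    all-tied k-mers give 0.5.
    """
    if table_class1.shape[1] < 2 or table_class0.shape[1] < 2:
        raise ValueError("each class needs >= 2 sequences")
    if not table_class1.index.equals(table_class0.index):
        raise ValueError("k-mer tables must share one index")
    n1 = table_class1.shape[1]
    n0 = table_class0.shape[1]
    x = np.hstack([table_class1.to_numpy(), table_class0.to_numpy()])
    ranks = stats.rankdata(x, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    disc = np.maximum(auc, 1.0 - auc)
    direction = np.where(auc >= 0.5, "class1-high", "class0-high")
    return pd.DataFrame({"kmer": table_class1.index, "auc": auc,
                         "discriminative_auc": disc, "direction": direction}) \
        .reset_index(drop=True)


def top_k(aucs: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Top-n k-mers by discriminative AUC; ties break lexicographically."""
    if len(aucs) == 0:
        raise ValueError("empty AUC table")
    ordered = aucs.sort_values(["discriminative_auc", "kmer"],
                               ascending=[False, True], kind="mergesort")
    out = ordered.head(n).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def region_bin_sequences(regions: pd.DataFrame, sequences: Mapping[str, str],
                         bin_size: int = 1000) -> pd.DataFrame:
    """Explode regions into their 1-kb lattice bins with sequences.

    Returns region_idx, chrom, start, end, seq — the unit on which CpG
    frequency, motif counts and k-mer tables are computed.
    """
    rows = []
    for i, (chrom, start, end) in enumerate(zip(regions["chrom"],
                                                regions["start"], regions["end"])):
        size = len(sequences[chrom])
        b0, b1 = int(start) // bin_size, (int(end) - 1) // bin_size + 1
        for b in range(b0, b1):
            s = b * bin_size
            e = min(s + bin_size, size)
            rows.append((i, chrom, s, e, sequences[chrom][s:e]))
    return pd.DataFrame(rows, columns=["region_idx", "chrom", "start", "end", "seq"])


def cpg_frequency(regions: pd.DataFrame, sequences: Mapping[str, str],
                  bin_size: int = 1000) -> pd.Series:
    """Per-region CpG frequency: CG count / possible dinucleotide starts per
    1-kb bin, bins of one region averaged to a single value."""
    bins = region_bin_sequences(regions, sequences, bin_size)
    freq = np.array([
        sum(1 for i in range(len(s) - 1) if s[i:i + 2] == "CG") / max(1, len(s) - 1)
        for s in bins["seq"]])
    return pd.Series(freq).groupby(bins["region_idx"].to_numpy()).mean()


def _motif_cpg_positions(seq: str, offset: int) -> list[int]:
    """Absolute forward-strand C positions of the CpG in each ZFP57 motif hit
    on either strand (forward hit at i -> CpG C at i+3; reverse-strand hit,
    seen as GCGGCA on the forward strand, -> CpG C at i+1)."""
    out = []
    rc = revcomp(ZFP57_HEXAMER)  # GCGGCA
    for i in range(len(seq) - 5):
        hex_ = seq[i:i + 6]
        if hex_ == ZFP57_HEXAMER:
            out.append(offset + i + 3)
        if hex_ == rc:
            out.append(offset + i + 1)
    return out


def zfp57_motif_count(regions: pd.DataFrame, sequences: Mapping[str, str],
                      stage_meth: Sequence[Mapping[str, tuple[np.ndarray, np.ndarray]]],
                      bin_size: int = 1000,
                      level_min: float = 0.5) -> tuple[pd.Series, int]:
    """Methylated ZFP57-motif count per region (bins averaged as in
    cpg_frequency) plus the number of motif CpGs without track coverage.

    A hit counts when its CpG has level >= level_min in strictly more than
    2/3 of the supplied stages; CpGs absent from any stage's track are
    excluded and tallied as uncovered.
    """
    n_stages = len(stage_meth)
    if n_stages == 0:
        raise ValueError("need >= 1 stage methylation track")
    cutoff = 2.0 * n_stages / 3.0
    lookup = []
    for meth in stage_meth:
        lookup.append({c: (pos, lev) for c, (pos, lev) in meth.items()})
    bins = region_bin_sequences(regions, sequences, bin_size)
    uncovered = 0
    counts = np.zeros(len(bins))
    for bi, row in enumerate(bins.itertuples()):
        n_meth = 0
        for cpos in _motif_cpg_positions(row.seq, row.start):
            levels = []
            covered = True
            for meth in lookup:
                pos, lev = meth.get(row.chrom, (np.empty(0, int), np.empty(0)))
                j = int(np.searchsorted(pos, cpos))
                if j < len(pos) and pos[j] == cpos:
                    levels.append(lev[j])
                else:
                    covered = False
                    break
            if not covered:
                uncovered += 1
                continue
            if sum(1 for v in levels if v >= level_min) > cutoff:
                n_meth += 1
        counts[bi] = n_meth
    per_region = pd.Series(counts).groupby(bins["region_idx"].to_numpy()).mean()
    return per_region, uncovered
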