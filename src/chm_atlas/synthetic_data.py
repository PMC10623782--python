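"""Synthetic multi-process epigenome with planted ground-truth region classes.

The generator emits everything the co-occupancy pipeline consumes — genome
FASTA, per-stage per-CpG methylation and per-10-bp H3K9me3 RPM tracks,
feature/repeat/compartment annotations, gene models and a TPM table — with
known planted 1-kb-lattice regions of five classes:

  universalCHM    CpG-rich, high H3K9me3 + high methylation in every stage
                  of every process
  processCHM      as above but in exactly one process
  CHnonM          CpG-rich, high H3K9me3, low methylation (all processes)
  CMnonH          CpG-rich, high methylation, H3K9me3-depleted (all processes)
  cpgRichNonCHM   CpG-rich, both marks low/depleted (all processes)

Background bins are CpG-poor (Poisson CpG counts) so planted regions are the
only CpG-rich bins with overwhelming probability. All randomness flows from
one numpy Generator seeded by SimConfig.seed, so outputs are bit-identical
for identical configs.

Design notes on the signal regimes (why these shapes):
  * H3K9me3 RPM is Gamma(shape=2) per 10-bp record — right-skewed and
    strictly positive like ChIP pileup RPM. Marked bins scale the mean by
    the configured SNR; methylation-only and unmarked CpG-rich bins are
    *depleted* (0.3x background) the way unbound CpG islands are in real
    ChIP tracks.
  * Per-CpG methylation is a clipped Gaussian around a class mean; genomic
    background CpGs sit at a high mean, as in most somatic tissues.
  * Planted CHM-like regions carry a G/T-biased filler composition and
    (universal CHMs) planted TGCCGC motifs, so sequence-level classifiers
    have a real signal to find; unmarked CpG-rich regions are A/C-biased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .track_engine import StageData, cpg_positions

CLASSES = ("universalCHM", "processCHM", "CHnonM", "CMnonH", "cpgRichNonCHM")
CELL_TYPES = ("ESC", "NPC", "CN", "ncxNPC", "ncxCN")

_A, _C, _G, _T = (ord(x) for x in "ACGT")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

BACKGROUND_FILLER = (0.30, 0.20, 0.20, 0.30)   # A C G T
CHM_FILLER = (0.15, 0.15, 0.35, 0.35)          # G/T rich
NONCHM_FILLER = (0.35, 0.35, 0.15, 0.15)       # A/C rich
ZFP57_MOTIF = b"TGCCGC"


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a 10-Mb two-chromosome genome, six developmental processes
    with 4-6 stages each, and planted region classes sized so the full
    pipeline runs in a few minutes on one CPU.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    n_processes: int = 6
    stages_per_process: tuple[int, ...] = (4, 5, 6, 4, 5, 6)
    # planted counts per class
    n_universal_chm: int = 50
    n_process_chm: int = 12          # spread round-robin over processes
    n_chnonm: int = 30
    n_cmnonh: int = 30
    n_cpgrich_nonchm: int = 40
    region_bins: int = 2             # planted region length in 1-kb bins
    bin_size: int = 1000
    # sequence regimes
    cpg_rich_density: tuple[int, int] = (35, 45)   # CpG per kb in planted bins
    background_cpg_density: float = 8.0            # Poisson mean per kb
    zfp57_motifs_per_chm_bin: int = 3
    # signal regimes
    h3k9me3_background: float = 0.1   # mean background RPM
    h3k9me3_snr: float = 5.0          # marked-bin mean / background mean
    h3k9me3_depletion: float = 0.3    # unmarked CpG-island mean / background
    signal_step: int = 10
    meth_high: float = 0.85
    meth_low: float = 0.15
    meth_background: float = 0.75
    noise_sd: float = 0.05
    # annotations / expression
    fraction_ltr_overlap: float = 0.9
    compartment_block: int = 100_000
    compartment_flip_rate: float = 0.1
    tpm_logmu_chm_target: float = 0.0
    tpm_logmu_nonchm_target: float = 3.0
    tpm_logmu_other: float = 1.5
    tpm_sigma: float = 0.5

    # layout
    slot_stride: int = 8000
    margin: int = 60_000

    def validate(self) -> None:
        counts = (self.n_universal_chm, self.n_process_chm, self.n_chnonm,
                  self.n_cmnonh, self.n_cpgrich_nonchm)
        if any(c < 0 for c in counts):
            raise ValueError("planted counts must be >= 0")
        if len(self.stages_per_process) != self.n_processes:
            raise ValueError("stages_per_process must list one count per process")
        if any(s < 1 for s in self.stages_per_process):
            raise ValueError("every process needs >= 1 stage")
        for v in (self.meth_high, self.meth_low, self.meth_background):
            if not 0.0 <= v <= 1.0:
                raise ValueError("methylation means must be in [0,1]")
        if self.region_bins < 1:
            raise ValueError("region_bins must be >= 1")
        if self.slot_stride < self.region_bins * self.bin_size + 5000:
            raise ValueError("slot_stride leaves planted regions < 5 kb apart")

    @property
    def n_planted(self) -> int:
        return (self.n_universal_chm + self.n_process_chm + self.n_chnonm
                + self.n_cmnonh + self.n_cpgrich_nonchm)

    def processes(self) -> list[str]:
        return [f"proc{i + 1}" for i in range(self.n_processes)]

    def stages(self, process_idx: int) -> list[str]:
        return [f"stage{j + 1}" for j in range(self.stages_per_process[process_idx])]


@dataclass
class GroundTruth:
    """Planted regions: sorted, non-overlapping, with intended class and the
    processes/stages where the marks were written."""

    regions: pd.DataFrame  # chrom, start, end, cls, processes (tuple)

    def by_class(self, cls: str) -> pd.DataFrame:
        return self.regions[self.regions["cls"] == cls].reset_index(drop=True)

    def to_json(self, path: str | Path) -> None:
        recs = self.regions.copy()
        recs["processes"] = recs["processes"].map(list)
        Path(path).write_text(json.dumps(recs.to_dict("records"), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        recs = json.loads(Path(path).read_text())
        df = pd.DataFrame(recs, columns=["chrom", "start", "end", "cls", "processes"])
        df["processes"] = df["processes"].map(tuple)
        return cls(regions=df)


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def _place_regions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign planted regions to lattice-aligned slots >= 5 kb apart."""
    region_len = config.region_bins * config.bin_size
    slots = []
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        hi = size - config.margin - region_len
        if hi > config.margin:
            for s in range(config.margin, hi + 1, config.slot_stride):
                slots.append((chrom, s))
    if config.n_planted > len(slots):
        raise ValueError(
            f"cannot fit {config.n_planted} planted regions into "
            f"{len(slots)} slots; enlarge the genome or reduce counts")
    order = rng.permutation(len(slots))[:config.n_planted]
    chosen = [slots[i] for i in np.sort(order)]
    labels = (["universalCHM"] * config.n_universal_chm
              + ["processCHM"] * config.n_process_chm
              + ["CHnonM"] * config.n_chnonm
              + ["CMnonH"] * config.n_cmnonh
              + ["cpgRichNonCHM"] * config.n_cpgrich_nonchm)
    labels = list(np.array(labels)[rng.permutation(len(labels))])
    procs = config.processes()
    rows = []
    spec_i = 0
    for (chrom, start), cls in zip(chosen, labels):
        if cls == "processCHM":
            present = (procs[spec_i % len(procs)],)
            spec_i += 1
        else:
            present = tuple(procs)
        rows.append((chrom, start, start + region_len, cls, present))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cls", "processes"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _fill_letters(seq: np.ndarray, lo: int, hi: int, probs, rng) -> None:
    seq[lo:hi] = _BASES[rng.choice(4, size=hi - lo, p=list(probs))]


def _destroy_cg(seq: np.ndarray) -> None:
    """Remove every CG dinucleotide by mutating the G; one pass suffices
    because a C followed by A can seed no new CG."""
    idx = np.where((seq[:-1] == _C) & (seq[1:] == _G))[0]
    seq[idx + 1] = _A


def generate_genome(config: SimConfig) -> tuple[dict[str, str], GroundTruth]:
    """Emit the genome sequence and the planted ground truth.

    Every 1-kb bin of a planted region receives an exact CpG count drawn
    from cpg_rich_density (always > 30); background bins receive Poisson
    counts around background_cpg_density. CpGs are written at even offsets
    after all CG dinucleotides in the random filler are destroyed, so bin
    CpG counts are exact by construction.
    """
    config.validate()
    rng = _rng(config, 1)
    truth_df = _place_regions(config, rng)
    lo_d, hi_d = config.cpg_rich_density
    sequences: dict[str, str] = {}
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        seq = _BASES[rng.choice(4, size=size, p=list(BACKGROUND_FILLER))]
        sub = truth_df[truth_df["chrom"] == chrom]
        for start, end, cls in zip(sub["start"], sub["end"], sub["cls"]):
            probs = CHM_FILLER if cls in ("universalCHM", "processCHM", "CHnonM") \
                else NONCHM_FILLER if cls == "cpgRichNonCHM" else BACKGROUND_FILLER
            _fill_letters(seq, start, end, probs, rng)
        _destroy_cg(seq)
        # per-bin CpG planting
        n_bins = -(-size // config.bin_size)
        target = rng.poisson(config.background_cpg_density, size=n_bins)
        motifs = np.zeros(n_bins, dtype=int)
        for start, end, cls in zip(sub["start"], sub["end"], sub["cls"]):
            b0, b1 = start // config.bin_size, end // config.bin_size
            target[b0:b1] = rng.integers(lo_d, hi_d + 1, size=b1 - b0)
            if cls == "universalCHM":
                motifs[b0:b1] = config.zfp57_motifs_per_chm_bin
        for b in range(n_bins):
            blo = b * config.bin_size
            bhi = min(blo + config.bin_size, size)
            blocked = np.zeros(bhi - blo, dtype=bool)
            n_motif = motifs[b] if bhi - blo >= config.bin_size else 0
            if n_motif:
                # motif anchors on a coarse grid so spans never collide
                anchors = rng.choice(np.arange(8, (bhi - blo) - 16, 16),
                                     size=n_motif, replace=False)
                for a in np.sort(anchors):
                    seq[blo + a: blo + a + 6] = np.frombuffer(ZFP57_MOTIF, dtype=np.uint8)
                    if seq[blo + a + 6] == _G:   # guard trailing C+G junction
                        seq[blo + a + 6] = _A
                    blocked[max(0, a - 1): a + 7] = True
            k = int(target[b]) - n_motif
            if k <= 0:
                continue
            even = np.arange(0, (bhi - blo) - 1, 2)
            avail = even[~(blocked[even] | blocked[even + 1])]
            k = min(k, len(avail))
            picks = rng.choice(avail, size=k, replace=False)
            seq[blo + picks] = _C
            seq[blo + picks + 1] = _G
        sequences[chrom] = seq.tobytes().decode()
    return sequences, GroundTruth(regions=truth_df)


def _marked_mask(config: SimConfig, truth: GroundTruth, chrom: str,
                 process: str) -> tuple[np.ndarray, np.ndarray]:
    """(h3k9me3 multiplier per 10-bp record, meth mean per bp) for one chrom."""
    size = config.chrom_sizes[chrom]
    n_rec = -(-size // config.signal_step)
    mult = np.ones(n_rec)
    meth_mean = np.full(size, config.meth_background)
    sub = truth.regions[truth.regions["chrom"] == chrom]
    for start, end, cls, procs in zip(sub["start"], sub["end"], sub["cls"],
                                      sub["processes"]):
        r0, r1 = start // config.signal_step, -(-end // config.signal_step)
        h_high = cls in ("universalCHM", "CHnonM") or (
            cls == "processCHM" and process in procs)
        m_high = cls in ("universalCHM", "CMnonH") or (
            cls == "processCHM" and process in procs)
        if h_high:
            mult[r0:r1] = config.h3k9me3_snr
        elif cls in ("CMnonH", "cpgRichNonCHM") or cls == "processCHM":
            mult[r0:r1] = config.h3k9me3_depletion
        if m_high:
            meth_mean[start:end] = config.meth_high
        elif cls in ("CHnonM", "cpgRichNonCHM") or cls == "processCHM":
            meth_mean[start:end] = config.meth_low
    return mult, meth_mean


def generate_stage_tracks(sequences: Mapping[str, str], truth: GroundTruth,
                          config: SimConfig) -> dict[tuple[str, str], StageData]:
    """Per-(process, stage) methylation + H3K9me3 tracks honoring the truth.

    Methylation: clipped Gaussian around the class mean per CpG per stage.
    H3K9me3: Gamma(shape=2) per 10-bp record with mean = background x class
    multiplier (SNR in marked bins, depletion in methylation-only/unmarked
    CpG-rich bins).
    """
    cpgs = {c: cpg_positions(s) for c, s in sequences.items()}
    out: dict[tuple[str, str], StageData] = {}
    for pi, process in enumerate(config.processes()):
        for si, stage in enumerate(config.stages(pi)):
            rng = _rng(config, 1000 + pi * 100 + si)
            meth: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            signal: dict[str, np.ndarray] = {}
            for chrom in sorted(config.chrom_sizes):
                mult, meth_mean = _marked_mask(config, truth, chrom, process)
                pos = cpgs[chrom]
                mu = meth_mean[pos]
                if config.noise_sd > 0:
                    lev = rng.normal(mu, config.noise_sd)
                else:
                    lev = mu.astype(float).copy()
                np.clip(lev, 0.0, 1.0, out=lev)
                meth[chrom] = (pos, lev)
                mean_rpm = config.h3k9me3_background * mult
                signal[chrom] = rng.gamma(2.0, mean_rpm / 2.0)
            sd = StageData(process_id=process, stage_id=stage, meth=meth,
                           signal=signal, chrom_sizes=dict(config.chrom_sizes),
                           step=config.signal_step)
            out[(process, stage)] = sd
    return out


@dataclass
class Annotations:
    """Feature/repeat/compartment annotations plus gene models and TPM."""

    genes: pd.DataFrame          # gene_id, chrom, start, end, strand, role
    features: dict[str, pd.DataFrame]   # cgi/promoter/gene_body/exon/intron/ltr/line/sine
    repeats: pd.DataFrame        # chrom, start, end, part, family
    conservation: pd.DataFrame   # chrom, start, end, score
    compartments: dict[str, pd.DataFrame]  # cell type -> chrom,start,end,label
    tpm: pd.DataFrame            # gene_id, process, stage, tpm


def _gene_rows(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    rows = []
    for i, r in truth.regions.iterrows():
        size = config.chrom_sizes[r.chrom]
        # near gene: TSS 3 kb from the region edge (inside the 10-kb window)
        if i % 2 == 0:
            tss = r.end + 3000
            g = (f"g{i:04d}n", r.chrom, tss, tss + 2000, "+")
        else:
            tss = r.start - 3001
            g = (f"g{i:04d}n", r.chrom, tss - 1999, tss + 1, "-")
        rows.append(g + (r.cls, "near"))
        # far gene: TSS 20 kb away (outside the window)
        tss = r.end + 20_000
        if tss + 2000 < size:
            rows.append((f"g{i:04d}f", r.chrom, tss, tss + 2000, "+", r.cls, "far"))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "region_cls", "role"])


def generate_annotations_and_expression(sequences: Mapping[str, str],
                                        truth: GroundTruth,
                                        config: SimConfig) -> Annotations:
    """Annotations + expression with planted downstream effects.

    * One synthetic young-LTR subfamily part ("sIAPEz-int", family ERVK)
      overlaps fraction_ltr_overlap of the universal CHMs; three older LTR
      subfamilies sit in background sequence. Conservation is drawn lower
      for the young subfamily.
    * Each planted region gets a gene with TSS 3 kb away (a target) and one
      20 kb away (not a target); CHM-target genes draw TPM from a lower
      log-normal than unmarked-CpG-island-target genes.
    * Compartment maps tile the genome in blocks; cell types share a base
      A/B pattern with independent flips at compartment_flip_rate.
    """
    rng = _rng(config, 2)
    genes = _gene_rows(truth, config)

    # ---- repeats -------------------------------------------------------
    region_len = config.region_bins * config.bin_size
    uchm = truth.by_class("universalCHM")
    n_over = int(round(config.fraction_ltr_overlap * len(uchm)))
    over_idx = np.sort(rng.permutation(len(uchm))[:n_over]) if len(uchm) else []
    rep_rows = []
    for i in over_idx:
        r = uchm.iloc[int(i)]
        rep_rows.append((r.chrom, r.start + 300, r.start + 300 + min(1200, region_len - 300),
                         "sIAPEz-int", "ERVK"))
    # free slots (background) for non-overlapping elements
    used = set(zip(truth.regions["chrom"], truth.regions["start"]))
    free = []
    for chrom in sorted(config.chrom_sizes):
        hi = config.chrom_sizes[chrom] - config.margin - region_len
        # offset so background elements sit > 2 kb from any planted region
        for s in range(config.margin + 4400, hi, config.slot_stride):
            free.append((chrom, s))
    free = [f for f in free if f not in used]
    rng.shuffle(free)
    fi = 0
    for part, fam, n in (("sIAPEz-int", "ERVK", 3),       # members away from CHMs
                         ("sRLTR-old1", "ERV1", 8), ("sMTA-old", "ERVL", 8),
                         ("sORR1-old", "ERVL-MaLR", 8),
                         ("sL1Md-A", "L1", 10), ("sB1-Mus", "Alu", 10)):
        for _ in range(n):
            if fi >= len(free):   # tiny genomes: place what fits
                break
            chrom, s = free[fi]
            fi += 1
            rep_rows.append((chrom, s, s + 1200, part, fam))
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "part", "family"]) \
        .sort_values(["chrom", "start"]).reset_index(drop=True)

    # ---- conservation (per 100-bp record over repeat elements) ---------
    cons_rows = []
    for r in repeats.itertuples():
        mean = 0.08 if r.part == "sIAPEz-int" else 0.5
        for s in range(r.start, r.end, 100):
            e = min(s + 100, r.end)
            cons_rows.append((r.chrom, s, e,
                              float(np.clip(rng.normal(mean, 0.02), 0, 1))))
    conservation = pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "score"])

    # ---- features ------------------------------------------------------
    cgi = truth.regions[["chrom", "start", "end"]].copy()
    prom, body, exon, intron = [], [], [], []
    for g in genes.itertuples():
        tss = g.start if g.strand == "+" else g.end - 1
        prom.append((g.chrom, max(0, tss - 1000), tss + 1000))
        body.append((g.chrom, g.start, g.end))
        if g.strand == "+":
            exon.append((g.chrom, g.start, g.start + 500))
            intron.append((g.chrom, g.start + 500, g.end))
        else:
            exon.append((g.chrom, g.end - 500, g.end))
            intron.append((g.chrom, g.start, g.end - 500))
    ltr_fams = ("ERVK", "ERV1", "ERVL", "ERVL-MaLR")
    features = {
        "CGI": cgi,
        "promoter": pd.DataFrame(prom, columns=["chrom", "start", "end"]),
        "gene_body": pd.DataFrame(body, columns=["chrom", "start", "end"]),
        "exon": pd.DataFrame(exon, columns=["chrom", "start", "end"]),
        "intron": pd.DataFrame(intron, columns=["chrom", "start", "end"]),
        "LTR": repeats[repeats["family"].isin(ltr_fams)][["chrom", "start", "end"]],
        "LINE": repeats[repeats["family"] == "L1"][["chrom", "start", "end"]],
        "SINE": repeats[repeats["family"] == "Alu"][["chrom", "start", "end"]],
    }
    features = {k: v.sort_values(["chrom", "start"]).reset_index(drop=True)
                for k, v in features.items()}

    # ---- compartments --------------------------------------------------
    base_cycle = ("A", "A", "B", "B", None)   # None = neither
    compartments: dict[str, pd.DataFrame] = {}
    flip = {"A": "B", "B": "A"}
    for cell in CELL_TYPES:
        rows = []
        for chrom in sorted(config.chrom_sizes):
            size = config.chrom_sizes[chrom]
            n_blk = -(-size // config.compartment_block)
            for b in range(n_blk):
                label = base_cycle[b % len(base_cycle)]
                if label is not None and rng.random() < config.compartment_flip_rate:
                    label = flip[label]
                if label is not None:
                    rows.append((chrom, b * config.compartment_block,
                                 min((b + 1) * config.compartment_block, size), label))
        compartments[cell] = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])

    # ---- expression ----------------------------------------------------
    tpm_rows = []
    for g in genes.itertuples():
        if g.role == "near" and g.region_cls in ("universalCHM", "processCHM"):
            mu = config.tpm_logmu_chm_target
        elif g.role == "near" and g.region_cls == "cpgRichNonCHM":
            mu = config.tpm_logmu_nonchm_target
        else:
            mu = config.tpm_logmu_other
        for pi, process in enumerate(config.processes()):
            for stage in config.stages(pi):
                tpm_rows.append((g.gene_id, process, stage,
                                 float(rng.lognormal(mu, config.tpm_sigma))))
    tpm = pd.DataFrame(tpm_rows, columns=["gene_id", "process", "stage", "tpm"])

    return Annotations(genes=genes, features=features, repeats=repeats,
                       conservation=conservation, compartments=compartments,
                       tpm=tpm)


# --------------------------------------------------------------------------
# on-disk formats (FASTA / bedGraph / BED6 / TSV / JSON) and their readers
# --------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    recs = [SeqRecord(Seq(sequences[c]), id=c, description="") for c in sorted(sequences)]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_meth_bedgraph(stage: StageData, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(stage.meth):
            pos, lev = stage.meth[chrom]
            for p, v in zip(pos, lev):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{v:.6g}\n")


def write_signal_bedgraph(stage: StageData, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(stage.signal):
            sig = stage.signal[chrom]
            size = stage.chrom_sizes[chrom]
            for i, v in enumerate(sig):
                s = i * stage.step
                fh.write(f"{chrom}\t{s}\t{min(s + stage.step, size)}\t{v:.6g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"])


def read_stage_data(meth_path: str | Path, signal_path: str | Path,
                    chrom_sizes: Mapping[str, int], process_id: str = "",
                    stage_id: str = "", step: int = 10) -> StageData:
    """Rebuild a StageData from bedGraph files.

    The signal reader expands records onto the dense per-step lattice, so
    the result is invariant to record order and to splitting a record in
    two at a step boundary.
    """
    meth_df = read_bedgraph(meth_path)
    meth: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in meth_df.groupby("chrom"):
        order = np.argsort(sub["start"].to_numpy())
        meth[chrom] = (sub["start"].to_numpy()[order].astype(np.int64),
                       sub["value"].to_numpy()[order].astype(float))
    sig_df = read_bedgraph(signal_path)
    signal: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        n_rec = -(-size // step)
        arr = np.zeros(n_rec)
        sub = sig_df[sig_df["chrom"] == chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[s // step: -(-e // step)] = v
        signal[chrom] = arr
    return StageData(process_id=process_id, stage_id=stage_id, meth=meth,
                     signal=signal, chrom_sizes=dict(chrom_sizes), step=step)


def write_bed(df: pd.DataFrame, path: str | Path, name_col: str | None = None,
              score_col: str | None = None) -> None:
    out = df[["chrom", "start", "end"]].copy()
    out["name"] = df[name_col] if name_col else "."
    out["score"] = df[score_col] if score_col else 0
    out["strand"] = df["strand"] if "strand" in df.columns else "."
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    return df


def write_dataset(outdir: str | Path, sequences: Mapping[str, str],
                  truth: GroundTruth,
                  tracks: Mapping[tuple[str, str], StageData],
                  annotations: Annotations) -> None:
    """Write the whole dataset in its external formats under outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(sequences, out / "genome.fa")
    truth.to_json(out / "ground_truth.json")
    (out / "tracks").mkdir(exist_ok=True)
    for (process, stage), sd in tracks.items():
        write_meth_bedgraph(sd, out / "tracks" / f"{process}.{stage}.meth.bedGraph")
        write_signal_bedgraph(sd, out / "tracks" / f"{process}.{stage}.h3k9me3.bedGraph")
    (out / "annotations").mkdir(exist_ok=True)
    for name, df in annotations.features.items():
        write_bed(df, out / "annotations" / f"feature.{name}.bed")
    rep = annotations.repeats.copy()
    rep["name"] = rep["part"] + "|" + rep["family"]
    write_bed(rep, out / "annotations" / "repeats.bed", name_col="name")
    for cell, df in annotations.compartments.items():
        write_bed(df, out / "annotations" / f"compartment.{cell}.bed", name_col="label")
    annotations.genes.to_csv(out / "annotations" / "genes.tsv", sep="\t", index=False)
    annotations.tpm.to_csv(out / "annotations" / "tpm.tsv", sep="\t", index=False)
    annotations.conservation.to_csv(out / "annotations" / "conservation.bedGraph",
                                    sep="\t", header=False, index=False)


def simulate(config: SimConfig) -> tuple[dict[str, str], GroundTruth,
                                         dict[tuple[str, str], StageData],
                                         Annotations]:
    """Generate the full dataset in memory."""
    sequences, truth = generate_genome(config)
    tracks = generate_stage_tracks(sequences, truth, config)
    annotations = generate_annotations_and_expression(sequences, truth, config)
    return sequences, truth, tracks, annotations
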