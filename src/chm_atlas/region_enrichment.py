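"""Feature / repeat-subfamily enrichment, conservation, targets, expression.

The enrichment score for a region set in a feature is

    score = log2( observed / expected )

with observed = (bp of region-feature overlap) / (total region bp) and
expected = (total feature bp) / (genome bp). Overlap lengths are computed on
merged (self-non-overlapping) interval covers so nothing is double counted.
A score >= 1 (i.e. at least 2-fold over expectation) flags a feature as
enriched; for repeat element parts the fraction of the part's elements hit
by >= 1 region ("overlap ratio") is reported alongside, and parts with
score >= 1 and overlap ratio > 10% are called out, mirroring how young
IAP/ERVK element parts behave in universal CHMs.

Potential target genes are those whose strand-aware TSS lies within 10 kb
of a region (edge distance, 0 when contained); target TEs overlap by >= 1
bp. Expression is compared between target sets as log2(TPM+1) averaged over
stages, with a two-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (edge_distances, overlap_length, overlaps_any,
                        point_to_interval_distances, total_length)

NEG_INF = float("-inf")


def significance_stars(p: float) -> str:
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class EnrichmentResult:
    feature_name: str
    observed_ratio: float
    expected_ratio: float
    score: float
    overlap_ratio: float | None = None  # fraction of feature elements hit
    enriched: bool = False


def enrichment_score(regions: pd.DataFrame, feature: pd.DataFrame,
                     genome_length: int, feature_name: str = "") -> EnrichmentResult:
    """Observed/expected overlapping-length enrichment of regions in a feature."""
    region_bp = total_length(regions)
    feature_bp = total_length(feature)
    if region_bp <= 0:
        raise ValueError("total region length must be > 0")
    if feature_bp <= 0:
        raise ValueError("total feature length must be > 0")
    observed = overlap_length(regions, feature) / region_bp
    expected = feature_bp / genome_length
    score = np.log2(observed / expected) if observed > 0 else NEG_INF
    return EnrichmentResult(feature_name=feature_name, observed_ratio=observed,
                            expected_ratio=expected, score=score,
                            enriched=bool(score >= 1.0))


def feature_enrichment_table(regions: pd.DataFrame,
                             features: dict[str, pd.DataFrame],
                             genome_length: int) -> pd.DataFrame:
    rows = []
    for name, feat in features.items():
        r = enrichment_score(regions, feat, genome_length, feature_name=name)
        rows.append({"feature": name, "observed": r.observed_ratio,
                     "expected": r.expected_ratio, "score": r.score,
                     "enriched": r.enriched})
    return pd.DataFrame(rows)


def subfamily_enrichment(regions: pd.DataFrame, repeats: pd.DataFrame,
                         genome_length: int,
                         min_overlap_ratio: float = 0.10) -> pd.DataFrame:
    """Per element part: enrichment score, element overlap ratio, flags.

    `repeats` carries one row per element with a `part` column (and
    optionally `family`). Parts whose total length is zero are skipped with
    a warning column rather than raising.
    """
    rows = []
    for part, sub in repeats.groupby("part"):
        part_bp = total_length(sub)
        if part_bp <= 0:
            continue
        res = enrichment_score(regions, sub, genome_length, feature_name=part)
        hit = overlaps_any(sub[["chrom", "start", "end"]], regions)
        # require a true >= 1 bp overlap (not mere touching)
        if hit.any():
            touch = sub[hit]
            real = np.array([
                overlap_length(touch.iloc[[i]], regions) > 0
                for i in range(len(touch))])
            n_hit = int(real.sum())
        else:
            n_hit = 0
        ratio = n_hit / len(sub)
        family = sub["family"].iloc[0] if "family" in sub.columns else ""
        rows.append({
            "part": part, "family": family, "n_elements": len(sub),
            "observed": res.observed_ratio, "expected": res.expected_ratio,
            "score": res.score, "overlap_ratio": ratio,
            "enriched": res.enriched,
            "flagged": bool(res.enriched and ratio > min_overlap_ratio),
        })
    return pd.DataFrame(rows).sort_values("score", ascending=False) \
        .reset_index(drop=True)


def element_conservation(repeats: pd.DataFrame,
                         conservation: pd.DataFrame) -> pd.Series:
    """Length-weighted mean conservation per element; NaN when uncovered."""
    out = np.full(len(repeats), np.nan)
    by_chrom = {c: sub.sort_values("start") for c, sub in conservation.groupby("chrom")}
    for i, (chrom, qs, qe) in enumerate(zip(repeats["chrom"], repeats["start"],
                                            repeats["end"])):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        ss = sub["start"].to_numpy()
        ee = sub["end"].to_numpy()
        vv = sub["score"].to_numpy()
        lo = int(np.searchsorted(ee, qs, side="right"))
        hi = int(np.searchsorted(ss, qe, side="left"))
        w = np.maximum(0, np.minimum(qe, ee[lo:hi]) - np.maximum(qs, ss[lo:hi]))
        if w.sum() > 0:
            out[i] = float((vv[lo:hi] * w).sum() / w.sum())
    return pd.Series(out, index=repeats.index, name="conservation")


def conservation_compare(repeats: pd.DataFrame, enrichment: pd.DataFrame,
                         conservation: pd.DataFrame) -> dict:
    """Compare per-element conservation between enriched and non-enriched
    element parts (two-sided Mann-Whitney rank-sum).

    `enrichment` is a subfamily_enrichment table; elements of parts flagged
    enriched form one group, the rest the other. Elements without
    conservation coverage are excluded (count reported).
    """
    enriched_parts = set(enrichment.loc[enrichment["enriched"], "part"])
    cons = element_conservation(repeats, conservation)
    is_enriched = repeats["part"].isin(enriched_parts)
    covered = cons.notna()
    g1 = cons[is_enriched & covered]
    g0 = cons[~is_enriched & covered]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both enriched and non-enriched groups must be non-empty")
    if g1.nunique() == 1 and g0.nunique() == 1 and g1.iloc[0] == g0.iloc[0]:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(g1, g0, alternative="two-sided").pvalue)
    return {
        "median_enriched": float(g1.median()),
        "median_non_enriched": float(g0.median()),
        "n_enriched": int(len(g1)), "n_non_enriched": int(len(g0)),
        "n_uncovered": int((~covered).sum()),
        "pvalue": p, "stars": significance_stars(p),
    }


@dataclass
class TargetAssignment:
    """Potential targets of a region set."""

    gene_targets: pd.DataFrame     # gene_id, distance (TSS edge distance, bp)
    te_targets: pd.DataFrame       # te_id (or index), overlapping flag
    nearest_tss_distance: np.ndarray   # per gene, distance to nearest region
    nearest_te_distance: np.ndarray    # per TE, distance to nearest region
    target_gene_ids: list = field(default_factory=list)


def assign_targets(regions: pd.DataFrame, genes: pd.DataFrame,
                   tes: pd.DataFrame, window: int = 10_000) -> TargetAssignment:
    """Genes with TSS within `window` bp (inclusive) and TEs overlapping >= 1 bp.

    Genes must carry a strand column; the TSS is the strand-aware 5' end
    (start for +, end-1 for -). Distances are edge distances, 0 when the
    TSS lies inside a region.
    """
    if "strand" not in genes.columns or genes["strand"].isin(["+", "-"]).sum() != len(genes):
        raise ValueError("genes must carry strand (+/-) to locate TSSs")
    tss = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    gene_dist = point_to_interval_distances(genes["chrom"].to_numpy(), tss, regions)
    is_target = gene_dist <= window
    gene_targets = pd.DataFrame({
        "gene_id": genes.loc[is_target, "gene_id"].to_numpy(),
        "distance": gene_dist[is_target],
    })
    te_hit = overlaps_any(tes, regions)
    if te_hit.any():
        idx = np.where(te_hit)[0]
        real = np.array([overlap_length(tes.iloc[[i]], regions) > 0 for i in idx])
        te_hit = np.zeros(len(tes), dtype=bool)
        te_hit[idx[real]] = True
    te_dist = edge_distances(tes, regions)
    te_targets = tes.loc[te_hit].copy()
    return TargetAssignment(gene_targets=gene_targets, te_targets=te_targets,
                            nearest_tss_distance=gene_dist,
                            nearest_te_distance=te_dist,
                            target_gene_ids=list(gene_targets["gene_id"]))


def expression_values(gene_ids, tpm: pd.DataFrame) -> pd.Series:
    """Per-gene expression: mean over (process, stage) of log2(TPM + 1).

    Genes absent from the table are dropped (caller reports the count).
    """
    sub = tpm[tpm["gene_id"].isin(set(gene_ids))].copy()
    sub["log2tpm1"] = np.log2(sub["tpm"] + 1.0)
    return sub.groupby("gene_id")["log2tpm1"].mean()


def compare_expression(target_sets: dict[str, list], tpm: pd.DataFrame) -> dict:
    """Medians per class and pairwise two-sided rank-sum tests.

    target_sets maps region-class name -> list of target gene ids.
    """
    values: dict[str, pd.Series] = {}
    missing: dict[str, int] = {}
    for cls, ids in target_sets.items():
        vals = expression_values(ids, tpm)
        if len(vals) < 2:
            raise ValueError(f"class {cls} has fewer than 2 targets with expression")
        values[cls] = vals
        missing[cls] = len(set(ids)) - len(vals)
    medians = {cls: float(v.median()) for cls, v in values.items()}
    pairs = []
    names = list(values)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            p = float(stats.mannwhitneyu(values[a], values[b],
                                         alternative="two-sided").pvalue)
            pairs.append({"class_a": a, "class_b": b, "pvalue": p,
                          "stars": significance_stars(p),
                          "median_a": medians[a], "median_b": medians[b]})
    return {"medians": medians, "n_targets": {c: int(len(v)) for c, v in values.items()},
            "n_missing_expression": missing, "pairwise": pairs}
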