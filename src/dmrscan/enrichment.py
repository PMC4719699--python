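"""Genomic-feature annotation and enrichment statistics for DMRs.

CpGs are classified against two hierarchies: gene context (promoter over
gene body over intergenic, promoters being +/-2 kb around the strand-aware
TSS) and CpG-island context (island over shore over shelf over sea, each
band extending 2 kb beyond the previous).  Feature enrichment of DMR-CpGs
against the array background uses Pearson's chi-square; motif enrichment in
DMR-associated promoters uses a one-sided Fisher's exact test with
Bonferroni correction and a minimum-prevalence filter; histone-track
enrichment uses a length-preserving within-chromosome permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .dataio import AnnotationTrack

PROMOTER_BP = 2000
SHORE_BP = 2000
SHELF_BP = 2000


@dataclass
class EnrichmentResult:
    label: str
    a: int  # test, in feature
    b: int  # test, out of feature
    c: int  # background, in feature
    d: int  # background, out of feature
    fold_enrichment: float
    statistic: float
    p: float
    p_corrected: float
    method: str
    degenerate: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def _build_trees(track: AnnotationTrack) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in track.intervals.itertuples(index=False):
        trees.setdefault(row.chromosome, IntervalTree()).addi(
            row.start, row.end, row.label
        )
    return trees


def annotate_cpg_features(
    positions: pd.DataFrame,
    genes: AnnotationTrack,
    islands: AnnotationTrack,
) -> pd.DataFrame:
    """Classify CpGs by gene context and island context.

    ``positions`` needs probe_id, chromosome, position (1-based).  Gene
    intervals must carry a strand; the TSS is the interval start on '+' and
    the interval end on '-'.  Returns a frame with gene_label in
    {promoter, gene_body, intergenic} and island_label in
    {island, shore, shelf, sea}.
    """
    if (genes.intervals["strand"].isin([".", ""])).any():
        raise ValueError("gene track requires a strand for every interval")

    body_trees = _build_trees(genes)
    prom_rows = []
    for row in genes.intervals.itertuples(index=False):
        tss = row.start if row.strand == "+" else row.end - 1  # 0-based point
        prom_rows.append(
            (row.chromosome, max(tss - PROMOTER_BP, 0), tss + PROMOTER_BP + 1, ".", row.label)
        )
    prom_track = AnnotationTrack(
        "promoters",
        pd.DataFrame(
            prom_rows, columns=["chromosome", "start", "end", "strand", "label"]
        ),
    )
    prom_trees = _build_trees(prom_track)

    isl_trees = _build_trees(islands)
    shore_rows, shelf_rows = [], []
    for row in islands.intervals.itertuples(index=False):
        shore_rows.append(
            (row.chromosome, max(row.start - SHORE_BP, 0), row.end + SHORE_BP, ".", row.label)
        )
        shelf_rows.append(
            (
                row.chromosome,
                max(row.start - SHORE_BP - SHELF_BP, 0),
                row.end + SHORE_BP + SHELF_BP,
                ".",
                row.label,
            )
        )
    shore_trees = _build_trees(
        AnnotationTrack("shores", pd.DataFrame(shore_rows, columns=islands.intervals.columns))
    ) if shore_rows else {}
    shelf_trees = _build_trees(
        AnnotationTrack("shelves", pd.DataFrame(shelf_rows, columns=islands.intervals.columns))
    ) if shelf_rows else {}

    gene_labels = []
    island_labels = []
    for row in positions.itertuples(index=False):
        point = row.position - 1  # 0-based
        chrom = row.chromosome
        if chrom in prom_trees and prom_trees[chrom].overlaps_point(point):
            gene_labels.append("promoter")
        elif chrom in body_trees and body_trees[chrom].overlaps_point(point):
            gene_labels.append("gene_body")
        else:
            gene_labels.append("intergenic")
        if chrom in isl_trees and isl_trees[chrom].overlaps_point(point):
            island_labels.append("island")
        elif chrom in shore_trees and shore_trees[chrom].overlaps_point(point):
            island_labels.append("shore")
        elif chrom in shelf_trees and shelf_trees[chrom].overlaps_point(point):
            island_labels.append("shelf")
        else:
            island_labels.append("sea")
    return pd.DataFrame(
        {
            "probe_id": positions["probe_id"].to_numpy(),
            "chromosome": positions["chromosome"].to_numpy(),
            "position": positions["position"].to_numpy(),
            "gene_label": gene_labels,
            "island_label": island_labels,
        }
    )


def chisq_feature_enrichment(
    test_labels, background_labels, feature: str
) -> EnrichmentResult:
    """Pearson chi-square (1 df, no continuity correction) for one feature.

    Compares the proportion of test CpGs carrying ``feature`` with the
    background proportion.  Degenerate margins give p = 1 with a flag.
    """
    test_labels = np.asarray(test_labels)
    background_labels = np.asarray(background_labels)
    a = int((test_labels == feature).sum())
    b = int(len(test_labels) - a)
    c = int((background_labels == feature).sum())
    d = int(len(background_labels) - c)
    table = np.array([[a, b], [c, d]], dtype=float)
    fold = np.nan
    if (a + b) > 0 and (c + d) > 0 and c > 0:
        fold = (a / (a + b)) / (c / (c + d))
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return EnrichmentResult(
            feature, a, b, c, d, fold, 0.0, 1.0, 1.0, "chisq", degenerate=True,
            note="degenerate margin",
        )
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(feature, a, b, c, d, fold, float(stat), float(p), float(p), "chisq")


def tfbs_enrichment(
    dmr_promoters: set,
    background_promoters: set,
    motif_map: pd.DataFrame,
    min_frac: float = 0.05,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact motif enrichment in DMR-associated promoters.

    Motifs present in fewer than ``min_frac`` of the test promoters are
    excluded before testing; Bonferroni correction runs over the motifs
    actually tested.  A motif observed in a test promoter missing from the
    background violates the subset precondition and is flagged, not tested.
    """
    dmr_promoters = set(dmr_promoters)
    background_promoters = set(background_promoters)
    if not dmr_promoters:
        raise ValueError("empty test promoter set")
    if not dmr_promoters <= background_promoters:
        raise ValueError("test promoters must be a subset of background promoters")

    by_motif = motif_map.groupby("motif")["promoter"].agg(set)
    n_test = len(dmr_promoters)
    n_bg = len(background_promoters)

    candidates = []
    flagged = []
    for motif, promoters in by_motif.items():
        stray = (promoters & dmr_promoters) - background_promoters
        if stray:
            flagged.append(
                EnrichmentResult(
                    motif, 0, 0, 0, 0, np.nan, np.nan, np.nan, np.nan,
                    "fisher_exact", degenerate=True,
                    note="motif promoters outside background",
                )
            )
            continue
        a = len(promoters & dmr_promoters)
        if a / n_test < min_frac:
            continue
        candidates.append((motif, a, len(promoters & background_promoters)))

    n_tested = len(candidates)
    results = []
    for motif, a, in_bg in candidates:
        b = n_test - a
        c = in_bg
        d = n_bg - in_bg
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        fold = (a / n_test) / (c / n_bg) if c > 0 else np.nan
        results.append(
            EnrichmentResult(
                motif, a, b, c, d, fold, float(a), float(p),
                float(min(p * n_tested, 1.0)), "fisher_exact",
                note="significant" if p * n_tested < alpha else "",
            )
        )
    results.sort(key=lambda r: (r.p_corrected, r.label))
    return results + flagged


def _merged_intervals(track: AnnotationTrack) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = {}
    for chrom, grp in track.intervals.groupby("chromosome"):
        ivs = grp.sort_values("start")[["start", "end"]].to_numpy()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def _overlaps_any(starts: np.ndarray, ends: np.ndarray, s, e):
    """Vectorized: does [s, e) overlap any of the merged intervals?"""
    s = np.asarray(s)
    e = np.asarray(e)
    idx = np.searchsorted(starts, e, side="left")  # intervals with start < e
    prev_end = np.where(idx > 0, ends[np.maximum(idx - 1, 0)], -1)
    return prev_end > s


def permutation_track_enrichment(
    dmrs: pd.DataFrame,
    track: AnnotationTrack,
    chromosome_lengths: dict[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
    n_tracks_tested: int = 1,
) -> EnrichmentResult:
    """Empirical enrichment of DMRs in a track by random re-placement.

    Each permutation re-places every DMR uniformly at random within its own
    chromosome, preserving its length; the statistic is the number of DMRs
    overlapping at least one track interval.  The empirical p-value is
    (1 + #{permutation stat >= observed}) / (1 + n_perm), Bonferroni-scaled
    by ``n_tracks_tested``.
    """
    rng = np.random.default_rng(seed)
    merged = _merged_intervals(track)
    n_dmrs = len(dmrs)
    if n_dmrs == 0:
        raise ValueError("no DMRs supplied")

    observed = 0
    per_chrom: list[tuple[str, int, int]] = []  # (chrom, length, count)
    for row in dmrs.itertuples(index=False):
        length = int(row.end) - int(row.start) + 1  # 1-based inclusive span
        L = chromosome_lengths[row.chromosome]
        if length > L:
            raise ValueError(f"DMR longer than chromosome {row.chromosome}")
        per_chrom.append((row.chromosome, length))
        if row.chromosome in merged:
            starts, ends = merged[row.chromosome]
            if _overlaps_any(starts, ends, int(row.start) - 1, int(row.end)):
                observed += 1

    null_counts = np.zeros(n_perm, dtype=int)
    for chrom, length in per_chrom:
        L = chromosome_lengths[chrom]
        s0 = rng.integers(0, L - length + 1, size=n_perm)
        if chrom in merged:
            starts, ends = merged[chrom]
            null_counts += _overlaps_any(starts, ends, s0, s0 + length)

    p = (1 + int((null_counts >= observed).sum())) / (1 + n_perm)
    expected = float(null_counts.mean())
    fold = observed / expected if expected > 0 else np.nan
    return EnrichmentResult(
        track.name,
        observed,
        n_dmrs - observed,
        int(round(expected)),
        n_dmrs - int(round(expected)),
        fold,
        float(observed),
        float(p),
        float(min(p * n_tracks_tested, 1.0)),
        "permutation",
    )


def gwas_proximity(
    dmrs: pd.DataFrame,
    snps: pd.DataFrame,
    p_max: float = 1e-6,
    windows_bp: tuple[int, ...] = (2_000, 250_000),
) -> dict[int, pd.DataFrame]:
    """List (DMR, SNP) pairs within each distance window.

    SNPs are pre-filtered at association p < p_max (strict).  Distance is 0
    when the SNP lies inside the DMR span, otherwise base pairs to the
    nearer edge; window boundaries are inclusive.
    """
    snps = snps[snps["pvalue"] < p_max]
    out: dict[int, pd.DataFrame] = {}
    for window in windows_bp:
        rows = []
        for di, dmr in dmrs.reset_index(drop=True).iterrows():
            hits = snps[snps["chromosome"] == dmr["chromosome"]]
            for snp in hits.itertuples(index=False):
                if dmr["start"] <= snp.position <= dmr["end"]:
                    dist = 0
                elif snp.position < dmr["start"]:
                    dist = int(dmr["start"] - snp.position)
                else:
                    dist = int(snp.position - dmr["end"])
                if dist <= window:
                    rows.append(
                        {
                            "dmr_index": di,
                            "chromosome": dmr["chromosome"],
                            "dmr_start": int(dmr["start"]),
                            "dmr_end": int(dmr["end"]),
                            "snp_id": snp.snp_id,
                            "snp_position": int(snp.position),
                            "snp_pvalue": float(snp.pvalue),
                            "distance": dist,
                        }
                    )
        out[window] = pd.DataFrame(
            rows,
            columns=[
                "dmr_index", "chromosome", "dmr_start", "dmr_end", "snp_id",
                "snp_position", "snp_pvalue", "distance",
            ],
        )
    return out
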