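"""Seeded synthetic 450K-like cohort generator with known ground truth.

The generator emulates the statistical structure of a case-control bulk-brain
methylation study: a bimodal beta-value landscape (most probe means below 0.2
or above 0.8), planted differentially methylated regions (DMRs) confined to
1 kb spans with a configurable hyper:hypo direction bias, a lower neuronal
proportion (NP) in cases than controls, age-of-death slopes at a subset of
probes, small gender/race/batch effects, sporadic detection failures, and
probes flagged for multimapping or an SNP within 5 bp of the target CpG.

All randomness flows from the single integer ``seed`` in the config through
named ``numpy`` substreams; identical configs yield bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .dataio import AnnotationTrack, BetaMatrix

# substream tags: one generator per stage so ops can re-derive shared layout
_S_LAYOUT, _S_FLAGS, _S_COHORT, _S_TRACKS = 101, 102, 103, 104


@dataclass
class SimulationConfig:
    """Design parameters for one synthetic cohort.

    Defaults encode the study conditions: 34 cases and 34 controls, ages of
    death spanning 66-95 years, NP means 0.247 (case) vs 0.303 (control),
    planted effects of 0.02-0.07 on the beta scale with a 2:1 hyper:hypo
    bias, and a desk-scale array of 20,000 probes over two chromosomes.
    """

    n_probes: int = 20_000
    n_chromosomes: int = 2
    chromosome_length: int = 20_000_000
    n_cases: int = 34
    n_controls: int = 34
    n_planted_dmrs: int = 50
    dmr_cpg_count_range: tuple[int, int] = (3, 8)
    dmr_effect_range: tuple[float, float] = (0.02, 0.07)
    hyper_fraction: float = 2.0 / 3.0
    age_effect_fraction: float = 0.05
    age_effect_slope: float = 0.002
    np_mean_case: float = 0.247
    np_mean_control: float = 0.303
    np_sd: float = 0.05
    np_effect_slope: float = 0.15
    noise_sd: float = 0.02
    detection_failure_rate: float = 0.01
    flagged_probe_fraction: float = 0.05
    celltype_differential_fraction: float = 0.33
    covariate_effect_sd: float = 0.01
    covariate_effect_fraction: float = 0.05
    aod_range: tuple[int, int] = (66, 95)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        fractions = {
            "hyper_fraction": self.hyper_fraction,
            "age_effect_fraction": self.age_effect_fraction,
            "np_mean_case": self.np_mean_case,
            "np_mean_control": self.np_mean_control,
            "detection_failure_rate": self.detection_failure_rate,
            "flagged_probe_fraction": self.flagged_probe_fraction,
            "celltype_differential_fraction": self.celltype_differential_fraction,
            "covariate_effect_fraction": self.covariate_effect_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        lo, hi = self.dmr_effect_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError(f"dmr_effect_range must lie within (0, 0.5), got {self.dmr_effect_range}")
        cmin, cmax = self.dmr_cpg_count_range
        if cmin < 1 or cmax < cmin:
            raise ValueError("dmr_cpg_count_range must satisfy 1 <= min <= max")
        if self.n_planted_dmrs * cmax > self.n_probes:
            raise ValueError("planted DMR CpGs cannot exceed n_probes")
        if self.n_probes > self.n_chromosomes * self.chromosome_length:
            raise ValueError("impossible probe density: n_probes exceeds available positions")
        return self

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated cohort."""

    planted_dmrs: pd.DataFrame  # chromosome,start,end,direction,effect,probe_ids
    age_effects: pd.DataFrame  # probe_id, slope
    true_np: pd.Series  # indexed by sample_id
    covariate_effect_sizes: dict = field(default_factory=dict)


def _chromosome_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def _layout(config: SimulationConfig):
    """Deterministic probe/cluster layout shared by manifest and cohort ops.

    Planted DMR clusters occupy disjoint 3 kb blocks (member CpGs within a
    1 kb span inside the block); remaining probes are uniform over each
    chromosome.  Returns (per-chromosome position arrays, cluster records).
    """
    rng = np.random.default_rng([config.seed, _S_LAYOUT])
    chroms = _chromosome_names(config)
    n_chrom = len(chroms)
    counts = np.full(n_chrom, config.n_probes // n_chrom)
    counts[: config.n_probes % n_chrom] += 1

    dmr_chrom = np.array([i % n_chrom for i in range(config.n_planted_dmrs)])
    cmin, cmax = config.dmr_cpg_count_range
    cluster_sizes = rng.integers(cmin, cmax + 1, size=config.n_planted_dmrs)

    positions: dict[str, np.ndarray] = {}
    clusters = []  # (chrom, member positions)
    block = 3000
    for ci, chrom in enumerate(chroms):
        which = np.where(dmr_chrom == ci)[0]
        n_blocks = config.chromosome_length // block - 2
        if len(which) > n_blocks:
            raise ValueError("chromosome too short for requested planted DMRs")
        block_ids = np.sort(rng.choice(n_blocks, size=len(which), replace=False))
        cluster_pos = []
        for bi, di in zip(block_ids, which):
            start = int(bi) * block + 1000
            k = int(cluster_sizes[di])
            offsets = np.sort(rng.choice(1000, size=k, replace=False))
            members = start + offsets  # span <= 1 kb by construction
            cluster_pos.append(members)
            clusters.append((di, chrom, members))
        n_cluster = int(cluster_sizes[which].sum()) if len(which) else 0
        n_rest = int(counts[ci]) - n_cluster
        if n_rest < 0:
            raise ValueError("planted DMR CpGs exceed per-chromosome probe budget")
        taken = (
            np.concatenate(cluster_pos) if cluster_pos else np.empty(0, dtype=int)
        )
        # draw extras, drop collisions with cluster positions, trim to count
        pool = rng.choice(
            config.chromosome_length, size=min(n_rest * 2 + 100, config.chromosome_length),
            replace=False,
        ) + 1
        pool = pool[~np.isin(pool, taken)][:n_rest]
        if len(pool) < n_rest:
            raise ValueError("impossible probe density on chromosome " + chrom)
        positions[chrom] = np.sort(np.concatenate([taken, pool]).astype(np.int64))
    clusters.sort(key=lambda c: c[0])
    return positions, clusters


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Generate a probe manifest with positions, probe types and QC flags.

    Positions are strictly increasing within each chromosome and probe ids
    are assigned in coordinate order.  Planted-DMR member probes never carry
    exclusion flags (multimap / SNP-within-5bp), so the planted truth
    survives probe filtering; the cell-type-differential flag is assigned at
    the configured rate across all probes.
    """
    config.validate()
    positions, clusters = _layout(config)
    rng = np.random.default_rng([config.seed, _S_FLAGS])

    frames = []
    for chrom in _chromosome_names(config):
        frames.append(pd.DataFrame({"chromosome": chrom, "position": positions[chrom]}))
    manifest = pd.concat(frames, ignore_index=True)
    n = len(manifest)
    manifest.insert(0, "probe_id", [f"cg{i + 1:08d}" for i in range(n)])

    cluster_mask = np.zeros(n, dtype=bool)
    pos_index = {
        (row.chromosome, row.position): i
        for i, row in enumerate(manifest.itertuples(index=False))
    }
    for _, chrom, members in clusters:
        for p in members:
            cluster_mask[pos_index[(chrom, int(p))]] = True

    half = config.flagged_probe_fraction / 2.0
    multimap = (rng.random(n) < half) & ~cluster_mask
    snp = (rng.random(n) < half) & ~cluster_mask
    celltype = rng.random(n) < config.celltype_differential_fraction
    probe_type = np.where(rng.random(n) < 0.28, "I", "II")

    manifest["probe_type"] = probe_type
    manifest["multimap_flag"] = multimap
    manifest["snp_within_5bp_flag"] = snp
    manifest["celltype_differential_flag"] = celltype
    return manifest


def _truncated_normal(rng, mean, sd, lo=0.0, hi=1.0):
    """Per-cell truncated normal via inverse-CDF sampling (vectorized)."""
    if sd == 0:
        return np.clip(mean, lo, hi)
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.uniform(a, b)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return np.clip(mean + sd * ndtri(u), lo, hi)


def generate_cohort(
    manifest: pd.DataFrame, config: SimulationConfig
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate beta values, detection p-values, a sample sheet and truth.

    Per-probe baselines come from a three-component beta mixture concentrated
    near 0 and 1 (background bimodality); planted-DMR probes get mid-range
    baselines so the planted shift is not attenuated by the [0,1] bound.
    Systematic terms (disease effect at planted probes, age slopes, NP slopes
    at cell-type-differential probes, gender/race/batch shifts) are added on
    the beta scale; measurement noise is truncated-normal within [0,1].
    """
    config.validate()
    _, clusters = _layout(config)
    rng = np.random.default_rng([config.seed, _S_COHORT])

    n = len(manifest)
    n_samples = config.n_cases + config.n_controls
    sample_ids = [f"AD{i + 1:02d}" for i in range(config.n_cases)] + [
        f"CT{i + 1:02d}" for i in range(config.n_controls)
    ]
    group = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    is_case = group == "case"

    pos_index = {
        (row.chromosome, row.position): i
        for i, row in enumerate(manifest.itertuples(index=False))
    }

    # --- sample covariates -------------------------------------------------
    aod = rng.integers(config.aod_range[0], config.aod_range[1] + 1, size=n_samples)
    gender = rng.choice(["F", "M"], size=n_samples)
    race = rng.choice(["B", "W"], size=n_samples, p=[0.2, 0.8])
    # 12 samples per chip, groups interleaved as in a balanced chip layout
    order = rng.permutation(n_samples)
    array = np.empty(n_samples, dtype=object)
    for slot, si in enumerate(order):
        array[si] = f"chip{slot // 12 + 1}"
    true_np = np.where(
        is_case,
        rng.normal(config.np_mean_case, config.np_sd, size=n_samples),
        rng.normal(config.np_mean_control, config.np_sd, size=n_samples),
    )
    true_np = np.clip(true_np, 0.0, 1.0)

    # --- per-probe baseline mixture ---------------------------------------
    comp = rng.choice(3, size=n, p=[0.45, 0.45, 0.10])
    baseline = np.empty(n)
    baseline[comp == 0] = rng.beta(2.0, 20.0, size=(comp == 0).sum())
    baseline[comp == 1] = rng.beta(20.0, 2.0, size=(comp == 1).sum())
    baseline[comp == 2] = rng.beta(5.0, 5.0, size=(comp == 2).sum())

    # --- planted DMRs ------------------------------------------------------
    n_dmr = len(clusters)
    directions = np.where(
        rng.random(n_dmr) < config.hyper_fraction, "hyper", "hypo"
    )
    effects = rng.uniform(*config.dmr_effect_range, size=n_dmr)
    dmr_rows = []
    disease_effect = np.zeros(n)
    planted_mask = np.zeros(n, dtype=bool)
    for (di, chrom, members), direction, eff in zip(clusters, directions, effects):
        idx = np.array([pos_index[(chrom, int(p))] for p in members])
        planted_mask[idx] = True
        baseline[idx] = 0.15 + 0.6 * rng.beta(2.0, 2.0, size=len(idx))
        signed = eff if direction == "hyper" else -eff
        disease_effect[idx] = signed
        dmr_rows.append(
            {
                "chromosome": chrom,
                "start": int(members.min()),
                "end": int(members.max()),
                "direction": direction,
                "effect": signed,
                "probe_ids": ",".join(manifest["probe_id"].to_numpy()[idx]),
            }
        )
    planted = pd.DataFrame(
        dmr_rows,
        columns=["chromosome", "start", "end", "direction", "effect", "probe_ids"],
    )

    # --- age effects (disjoint from planted probes) ------------------------
    eligible = np.where(~planted_mask)[0]
    n_age = int(round(config.age_effect_fraction * n))
    age_idx = rng.choice(eligible, size=min(n_age, len(eligible)), replace=False)
    age_slope = np.zeros(n)
    age_slope[age_idx] = config.age_effect_slope * rng.choice([-1.0, 1.0], size=len(age_idx))
    age_effects = pd.DataFrame(
        {
            "probe_id": manifest["probe_id"].to_numpy()[np.sort(age_idx)],
            "slope": age_slope[np.sort(age_idx)],
        }
    )

    # --- NP slopes at cell-type-differential probes -------------------------
    ct_flag = manifest["celltype_differential_flag"].to_numpy(bool)
    np_slope = np.zeros(n)
    np_slope[ct_flag] = config.np_effect_slope * rng.choice(
        [-1.0, 1.0], size=int(ct_flag.sum())
    )

    # --- covariate effects at a sparse probe subset -------------------------
    cov_effects = {}
    cov_shift = np.zeros((n, n_samples))
    for name, indicator in (
        ("gender", (gender == "M").astype(float)),
        ("race", (race == "W").astype(float)),
    ):
        k = int(round(config.covariate_effect_fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        sizes = rng.normal(0.0, config.covariate_effect_sd, size=k)
        cov_shift[idx] += np.outer(sizes, indicator - indicator.mean())
        cov_effects[name] = float(np.mean(np.abs(sizes))) if k else 0.0
    chips = sorted(set(array))
    k = int(round(config.covariate_effect_fraction * n))
    idx = rng.choice(n, size=k, replace=False)
    chip_sizes = rng.normal(0.0, config.covariate_effect_sd, size=(k, len(chips)))
    chip_sizes -= chip_sizes.mean(axis=1, keepdims=True)
    chip_of = np.array([chips.index(a) for a in array])
    cov_shift[idx] += chip_sizes[:, chip_of]
    cov_effects["array"] = float(np.mean(np.abs(chip_sizes))) if k else 0.0

    # --- assemble the beta matrix ------------------------------------------
    mean = (
        baseline[:, None]
        + np.outer(disease_effect, is_case.astype(float))
        + np.outer(age_slope, aod - np.mean(config.aod_range))
        + np.outer(np_slope, true_np - true_np.mean())
        + cov_shift
    )
    mean = np.clip(mean, 0.0, 1.0)
    values = _truncated_normal(rng, mean, config.noise_sd)

    # --- detection p-values -------------------------------------------------
    fails = rng.random((n, n_samples)) < config.detection_failure_rate
    detp = rng.uniform(0.0, 0.005, size=(n, n_samples))
    detp[fails] = rng.uniform(0.02, 0.5, size=int(fails.sum()))

    probe_index = pd.Index(manifest["probe_id"], name="probe_id")
    beta = BetaMatrix(
        pd.DataFrame(values, index=probe_index, columns=sample_ids)
    )
    detp_df = pd.DataFrame(detp, index=probe_index, columns=sample_ids)
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "aod": aod,
            "gender": gender,
            "race": race,
            "array": array,
            "np": true_np,
        }
    )
    truth = SyntheticTruth(
        planted_dmrs=planted,
        age_effects=age_effects,
        true_np=pd.Series(true_np, index=sample_ids, name="np"),
        covariate_effect_sizes=cov_effects,
    )
    return beta, detp_df, sheet, truth


def generate_annotation_tracks(
    manifest: pd.DataFrame,
    config: SimulationConfig,
    truth: SyntheticTruth | None = None,
    n_genes: int = 200,
    n_islands: int = 300,
    n_motifs: int = 40,
    n_gwas_snps: int = 30,
    dmr_overlap_fraction: float = 0.5,
) -> dict:
    """Generate gene/island/histone tracks, a motif map, and a GWAS SNP table.

    A ``dmr_overlap_fraction`` share of planted DMRs is deliberately covered
    by genes (promoters), islands and the first histone track so feature and
    permutation enrichment are detectable on synthetic cohorts.  Intervals
    are BED-convention (0-based half-open) and lie within chromosome bounds.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _S_TRACKS])
    chroms = _chromosome_names(config)
    L = config.chromosome_length

    if truth is not None and len(truth.planted_dmrs):
        span_df = truth.planted_dmrs[["chromosome", "start", "end"]]
    else:
        # re-derive planted spans from the deterministic layout
        _, clusters = _layout(config)
        span_df = pd.DataFrame(
            [
                {"chromosome": chrom, "start": int(m.min()), "end": int(m.max())}
                for _, chrom, m in clusters
            ],
            columns=["chromosome", "start", "end"],
        )
    dmr_spans = list(span_df.itertuples(index=False))
    n_over = int(round(dmr_overlap_fraction * len(dmr_spans)))
    overlap_spans = dmr_spans[:n_over]

    def _random_intervals(count, min_len, max_len):
        rows = []
        for _ in range(count):
            chrom = chroms[rng.integers(len(chroms))]
            length = int(rng.integers(min_len, max_len + 1))
            start = int(rng.integers(0, max(L - length, 1)))
            rows.append((chrom, start, start + length))
        return rows

    # genes: 5-50 kb, random strand; overlap genes put their TSS near a DMR
    gene_rows = []
    for gi in range(n_genes):
        label = f"gene{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(5_000, 50_001))
        if gi < len(overlap_spans):
            span = overlap_spans[gi]
            chrom = span.chromosome
            mid = (span.start + span.end) // 2
            if strand == "+":
                start = max(mid - 500, 0)  # DMR sits in the +/-2kb promoter
            else:
                start = max(mid + 500 - length, 0)
        else:
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, L - length))
        end = min(start + length, L)
        gene_rows.append((chrom, start, end, strand, label))
    genes = AnnotationTrack(
        "genes",
        pd.DataFrame(gene_rows, columns=["chromosome", "start", "end", "strand", "label"]),
    )

    island_rows = []
    for ii in range(n_islands):
        if ii < n_over and ii < len(overlap_spans):
            span = overlap_spans[ii]
            chrom, start = span.chromosome, max(span.start - 200, 0)
            end = min(span.end + 200, L)
        else:
            chrom, start, end = _random_intervals(1, 500, 2000)[0]
        island_rows.append((chrom, start, end, ".", f"island{ii + 1:04d}"))
    islands = AnnotationTrack(
        "cpg_islands",
        pd.DataFrame(island_rows, columns=["chromosome", "start", "end", "strand", "label"]),
    )

    histone = {}
    for ti, mark in enumerate(["H3K4me3", "H3K27me3"]):
        rows = []
        for ii in range(150):
            if ti == 0 and ii < n_over and ii < len(overlap_spans):
                span = overlap_spans[ii]
                chrom, start = span.chromosome, max(span.start - 500, 0)
                end = min(span.end + 500, L)
            else:
                chrom, start, end = _random_intervals(1, 1000, 5000)[0]
            rows.append((chrom, start, end, ".", f"{mark}_{ii + 1}"))
        histone[mark] = AnnotationTrack(
            mark,
            pd.DataFrame(rows, columns=["chromosome", "start", "end", "strand", "label"]),
        )

    # motif -> promoter incidence; motif0 enriched in DMR-overlapping genes
    gene_labels = [r[4] for r in gene_rows]
    dmr_genes = gene_labels[:n_over]
    motif_rows = []
    for mi in range(n_motifs):
        motif = f"motif{mi + 1:03d}"
        base_rate = float(rng.uniform(0.05, 0.3))
        for gi, gene_label in enumerate(gene_labels):
            rate = base_rate
            if mi == 0 and gene_label in dmr_genes:
                rate = min(base_rate * 4.0, 0.95)
            if rng.random() < rate:
                motif_rows.append((motif, gene_label))
    motif_map = pd.DataFrame(motif_rows, columns=["motif", "promoter"])

    # GWAS SNPs: some within 2 kb of a DMR, some ~100 kb away, some decoys
    snp_rows = []
    for si in range(n_gwas_snps):
        if si < min(3, len(dmr_spans)):
            span = dmr_spans[si]
            chrom, pos = span.chromosome, int(span.start) + 500
            p = 1e-8
        elif si < min(6, len(dmr_spans)):
            span = dmr_spans[si]
            chrom = span.chromosome
            pos = min(int(span.end) + 100_000, L)
            p = 1e-8
        else:
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(1, L + 1))
            p = float(rng.choice([1e-8, 1e-7, 1e-5, 1e-4]))
        snp_rows.append((f"rs{si + 1:06d}", chrom, pos, p))
    gwas = pd.DataFrame(snp_rows, columns=["snp_id", "chromosome", "position", "pvalue"])

    return {
        "genes": genes,
        "cpg_islands": islands,
        "histone": histone,
        "motif_map": motif_map,
        "gwas_snps": gwas,
        "chromosome_lengths": {c: L for c in chroms},
    }
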