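"""Age-of-death association, cross-cohort concordance, and orchestration.

The AOD scan asks, in control samples only, whether methylation at the top
CpG of each DMR drifts with age after adjusting for gender, race, array and
neuronal proportion — reported separately for hyper- and hypo-DMR CpGs.
Cross-cohort concordance counts shared CpGs replicating with the same
directional change (one-tailed p < 0.05 toward the reference cohort's
direction) and correlates the two effect-size vectors (Pearson r, two-sided
p from the t-transform).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .dataio import (
    BetaMatrix,
    beta_to_table,
    load_cohort_inputs,
    write_bed_track,
    write_matrix,
    write_results_tables,
    write_table,
)
from .cell_composition import ReferenceProfiles, compare_group_proportions, estimate_neuronal_proportion
from .dmr import call_dmrs
from .enrichment import (
    annotate_cpg_features,
    chisq_feature_enrichment,
    gwas_proximity,
    permutation_track_enrichment,
    results_to_frame,
    tfbs_enrichment,
)
from .preprocess import apply_detection_mask, filter_probes, quantile_normalize
from .regression import _ols_term, run_cpg_scan
from .synthetic import (
    SimulationConfig,
    generate_annotation_tracks,
    generate_cohort,
    generate_manifest,
)

logger = logging.getLogger("dmrscan")


@dataclass
class ConcordanceReport:
    n_shared: int
    n_replicated: int
    replicated_fraction: float
    pearson_r: float
    pearson_p: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def aod_effect_scan(
    beta_controls: BetaMatrix,
    sheet_controls: pd.DataFrame,
    top_cpgs: pd.DataFrame,
    min_samples: int = 10,
    alpha: float = 0.05,
) -> tuple[dict, pd.DataFrame]:
    """Regress beta on AOD (+ gender, race, array, NP) at top DMR-CpGs.

    ``top_cpgs`` needs columns probe_id and direction.  Returns a summary
    with the per-direction fraction of CpGs significant at ``alpha`` (NaN
    when a direction has no CpGs) plus the per-CpG slope table.
    """
    if (sheet_controls["group"] != "control").any():
        raise ValueError("aod_effect_scan expects control samples only")
    sheet = sheet_controls.set_index("sample_id").loc[beta_controls.sample_ids].reset_index()
    include_np = "np" in sheet.columns and sheet["np"].notna().all()

    cols = [np.ones(len(sheet))]
    labels = ["intercept"]
    for cov in ("gender", "race", "array"):
        values = sheet[cov].astype(str)
        levels = sorted(values.unique())
        for level in levels[1:]:  # treatment coding vs alphabetically first
            cols.append((values == level).to_numpy(float))
            labels.append(f"{cov}[{level}]")
    if include_np:
        cols.append(pd.to_numeric(sheet["np"]).to_numpy(float))
        labels.append("np")
    cols.append(pd.to_numeric(sheet["aod"]).to_numpy(float))
    labels.append("aod")  # tested term, last
    X = np.column_stack(cols)

    V = beta_controls.values.to_numpy(float)
    M = beta_controls.mask.to_numpy(bool)
    idx_of = {p: i for i, p in enumerate(beta_controls.probe_ids)}

    rows = []
    for rec in top_cpgs.itertuples(index=False):
        i = idx_of.get(rec.probe_id)
        if i is None:
            rows.append({"probe_id": rec.probe_id, "direction": rec.direction,
                         "slope": np.nan, "p": np.nan, "note": "absent"})
            continue
        use = M[i]
        if use.sum() < max(min_samples, X.shape[1] + 1):
            rows.append({"probe_id": rec.probe_id, "direction": rec.direction,
                         "slope": np.nan, "p": np.nan, "note": "insufficient_samples"})
            continue
        try:
            coef, se, t, df = _ols_term(V[i, use][:, None], X[use])
        except np.linalg.LinAlgError:
            rows.append({"probe_id": rec.probe_id, "direction": rec.direction,
                         "slope": np.nan, "p": np.nan, "note": "rank_deficient"})
            continue
        p = 2.0 * stats.t.sf(abs(t[0]), df)
        rows.append({"probe_id": rec.probe_id, "direction": rec.direction,
                     "slope": float(coef[0]), "p": float(p), "note": ""})
    table = pd.DataFrame(rows, columns=["probe_id", "direction", "slope", "p", "note"])

    summary = {}
    for d in ("hyper", "hypo"):
        sub = table[(table["direction"] == d) & table["p"].notna()]
        summary[f"{d}_n"] = int(len(sub))
        summary[f"{d}_significant_fraction"] = (
            float((sub["p"] < alpha).mean()) if len(sub) else float("nan")
        )
    return summary, table


def cross_cohort_concordance(
    effects_a: pd.DataFrame, effects_b: pd.DataFrame
) -> ConcordanceReport:
    """Directional replication and effect-size correlation across cohorts.

    ``effects_a`` needs probe_id, coef, p_hyper, p_hypo (the screening
    cohort); ``effects_b`` needs probe_id and coef (the reference cohort).
    A shared CpG replicates when cohort A's coefficient matches cohort B's
    sign and A's one-tailed p toward that sign is < 0.05.
    """
    merged = effects_a.merge(effects_b, on="probe_id", suffixes=("_a", "_b"))
    n_shared = len(merged)
    if n_shared < 3:
        raise ValueError("need >= 3 shared CpGs for concordance")
    b_hyper = merged["coef_b"].to_numpy(float) >= 0
    one_tailed = np.where(
        b_hyper, merged["p_hyper"].to_numpy(float), merged["p_hypo"].to_numpy(float)
    )
    sign_match = (merged["coef_a"].to_numpy(float) >= 0) == b_hyper
    replicated = sign_match & (one_tailed < 0.05)
    n_rep = int(replicated.sum())

    a = merged["coef_a"].to_numpy(float)
    b = merged["coef_b"].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return ConcordanceReport(
            n_shared, n_rep, n_rep / n_shared, float("nan"), float("nan"), degenerate=True
        )
    r, p = stats.pearsonr(a, b)
    return ConcordanceReport(n_shared, n_rep, n_rep / n_shared, float(r), float(p))


@dataclass
class PipelineConfig:
    """Full-run configuration: simulate a cohort or load one from disk."""

    out_dir: str
    seed: int = 0
    simulate: dict | None = None
    manifest_path: str | None = None
    beta_path: str | None = None
    detp_path: str | None = None
    sheet_path: str | None = None
    reference_profiles_path: str | None = None
    window_bp: int = 1000
    fdr: float = 0.01
    min_cpgs: int = 2
    detp_threshold: float = 0.01
    normalize: bool = True
    min_per_group: int = 10
    run_enrichment: bool = True
    n_perm: int = 2000

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> "PipelineConfig":
        if self.simulate is None:
            missing = [
                n for n in ("manifest_path", "beta_path", "sheet_path")
                if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(
                    f"config must request simulation or name inputs; missing {missing}"
                )
        return self


def run_full_pipeline(config: PipelineConfig | str) -> dict:
    """Execute simulate -> preprocess -> scan -> DMR calling -> downstream.

    Writes every intermediate table plus a run manifest into
    ``config.out_dir`` and returns the in-memory results.  Identical config
    and seed give byte-identical output tables.
    """
    if isinstance(config, str):
        config = PipelineConfig.from_yaml(config)
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    stage = "simulate"
    try:
        tracks = None
        truth = None
        if config.simulate is not None:
            sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
            manifest = generate_manifest(sim)
            beta, detp, sheet, truth = generate_cohort(manifest, sim)
            tracks = generate_annotation_tracks(manifest, sim, truth=truth)
            write_table(manifest, os.path.join(out, "manifest.tsv"))
            write_table(sheet, os.path.join(out, "sample_sheet.tsv"))
            write_matrix(beta_to_table(beta), os.path.join(out, "beta.tsv"))
            write_matrix(detp, os.path.join(out, "detection_p.tsv"))
            write_table(truth.planted_dmrs, os.path.join(out, "truth_dmrs.tsv"))
        else:
            manifest, beta, sheet = load_cohort_inputs(
                config.manifest_path, config.beta_path, config.sheet_path,
                detp_path=config.detp_path,
            )
            detp = beta.detection_p

        stage = "preprocess"
        retained, report = filter_probes(manifest)
        write_table(report.to_frame(), os.path.join(out, "filter_report.tsv"))
        beta = beta.subset_probes(retained)
        manifest_f = manifest.set_index("probe_id").loc[retained].reset_index()
        if detp is not None:
            beta = apply_detection_mask(
                beta, detp.loc[retained], threshold=config.detp_threshold
            )
        if config.normalize:
            beta = quantile_normalize(beta)

        stage = "cell_composition"
        np_report = None
        if config.reference_profiles_path is not None:
            refs = ReferenceProfiles.from_table(config.reference_profiles_path)
            np_est = estimate_neuronal_proportion(beta, refs)
            sheet = sheet.copy()
            sheet["np"] = np_est.reindex(sheet["sample_id"]).to_numpy()
        if "np" in sheet.columns and sheet["np"].notna().all():
            np_report = compare_group_proportions(
                pd.Series(sheet["np"].to_numpy(float), index=sheet["sample_id"]),
                pd.Series(sheet["group"].to_numpy(), index=sheet["sample_id"]),
            )
            with open(os.path.join(out, "np_comparison.json"), "w") as fh:
                json.dump(np_report, fh, indent=2, sort_keys=True)

        stage = "cpg_scan"
        cpg_results, skipped = run_cpg_scan(
            beta, manifest_f, sheet, min_per_group=config.min_per_group
        )
        write_table(skipped, os.path.join(out, "skipped_cpgs.tsv"))

        stage = "dmr_calling"
        dmrs = call_dmrs(
            cpg_results, window_bp=config.window_bp, fdr=config.fdr,
            min_cpgs=config.min_cpgs,
        )

        stage = "enrichment"
        enrichments = {}
        gwas_tables = {}
        if config.run_enrichment and tracks is not None and len(dmrs):
            ann = annotate_cpg_features(
                cpg_results[["probe_id", "chromosome", "position"]],
                tracks["genes"], tracks["cpg_islands"],
            )
            dmr_probe_ids = set(
                pid for row in dmrs["probe_ids"] for pid in row.split(",")
            )
            in_dmr = ann["probe_id"].isin(dmr_probe_ids).to_numpy()
            feats = []
            for feature in ("promoter", "gene_body", "intergenic"):
                feats.append(
                    chisq_feature_enrichment(
                        ann.loc[in_dmr, "gene_label"], ann["gene_label"], feature
                    )
                )
            for feature in ("island", "shore", "shelf", "sea"):
                feats.append(
                    chisq_feature_enrichment(
                        ann.loc[in_dmr, "island_label"], ann["island_label"], feature
                    )
                )
            enrichments["features"] = results_to_frame(feats)

            perm = []
            histones = tracks["histone"]
            for mark, track in histones.items():
                perm.append(
                    permutation_track_enrichment(
                        dmrs, track, tracks["chromosome_lengths"],
                        n_perm=config.n_perm, seed=config.seed,
                        n_tracks_tested=len(histones),
                    )
                )
            enrichments["histone_permutation"] = results_to_frame(perm)

            gwas_tables = gwas_proximity(dmrs, tracks["gwas_snps"])
            for window, table in gwas_tables.items():
                write_table(table, os.path.join(out, f"gwas_within_{window}bp.tsv"))

        stage = "downstream"
        aod_summary = None
        if len(dmrs):
            controls = sheet[sheet["group"] == "control"]
            beta_ctrl = beta.subset_samples(controls["sample_id"])
            top = dmrs[["top_cpg_id", "direction"]].rename(
                columns={"top_cpg_id": "probe_id"}
            )
            aod_summary, aod_table = aod_effect_scan(
                beta_ctrl, controls, top, min_samples=config.min_per_group
            )
            write_table(aod_table, os.path.join(out, "aod_scan.tsv"))
            with open(os.path.join(out, "aod_summary.json"), "w") as fh:
                json.dump(aod_summary, fh, indent=2, sort_keys=True, allow_nan=True)

        write_results_tables(out, dmrs=dmrs, cpg_results=cpg_results,
                             enrichments=enrichments)

        run_manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "parameters": {
                k: v for k, v in dataclasses.asdict(config).items()
                if k not in ("out_dir",)
            },
            "n_probes_retained": int(len(retained)),
            "n_cpgs_fitted": int(len(cpg_results)),
            "n_dmrs": int(len(dmrs)),
        }
        with open(os.path.join(out, "run_manifest.json"), "w") as fh:
            json.dump(run_manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "manifest": manifest,
        "beta": beta,
        "sheet": sheet,
        "truth": truth,
        "tracks": tracks,
        "filter_report": report,
        "cpg_results": cpg_results,
        "dmrs": dmrs,
        "np_report": np_report,
        "aod_summary": aod_summary,
        "enrichments": enrichments,
    }
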