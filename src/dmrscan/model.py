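"""Model/results facade over the DMR-calling pipeline.

``SlidingWindowDMR`` is constructed from a cohort (beta matrix, probe
manifest, sample sheet) and holds the analysis parameters; ``fit()`` runs
probe filtering, detection masking, quantile normalization, the per-CpG
covariate-adjusted regression and the direction-aware windowed Fisher
combination, returning a ``DMRResults`` object that carries the per-CpG
estimates, the called DMRs, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataio import BetaMatrix, load_cohort_inputs, write_results_tables
from .dmr import call_dmrs
from .preprocess import apply_detection_mask, filter_probes, quantile_normalize
from .regression import run_cpg_scan
from .synthetic import SimulationConfig, generate_cohort, generate_manifest


class SlidingWindowDMR:
    """Case-control DMR model for 450K-style beta matrices.

    Parameters
    ----------
    beta : BetaMatrix
        Probes x samples methylation fractions with a usability mask.
    manifest : pandas.DataFrame
        Probe manifest (positions, QC flags, cell-type-differential flag).
    sample_sheet : pandas.DataFrame
        Per-sample group, age of death, gender, race, array and optional
        neuronal proportion.
    detection_p : pandas.DataFrame, optional
        Per-cell detection p-values; cells with p > ``detp_threshold`` are
        masked before analysis.
    window_bp, min_cpgs, fdr
        Sliding-window size (base pairs), minimum CpGs per window, and the
        Benjamini-Hochberg FDR cutoff for significant windows.
    """

    def __init__(
        self,
        beta: BetaMatrix,
        manifest: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        detection_p: pd.DataFrame | None = None,
        window_bp: int = 1000,
        min_cpgs: int = 2,
        fdr: float = 0.01,
        detp_threshold: float = 0.01,
        normalize: bool = True,
        min_per_group: int = 10,
    ):
        self.beta = beta
        self.manifest = manifest
        self.sample_sheet = sample_sheet
        self.detection_p = detection_p
        self.window_bp = window_bp
        self.min_cpgs = min_cpgs
        self.fdr = fdr
        self.detp_threshold = detp_threshold
        self.normalize = normalize
        self.min_per_group = min_per_group

    @classmethod
    def from_tables(
        cls, manifest_path: str, beta_path: str, sheet_path: str,
        detp_path: str | None = None, **kwargs
    ) -> "SlidingWindowDMR":
        manifest, beta, sheet = load_cohort_inputs(
            manifest_path, beta_path, sheet_path, detp_path=detp_path
        )
        return cls(beta, manifest, sheet, detection_p=beta.detection_p, **kwargs)

    @classmethod
    def from_simulation(
        cls, config: SimulationConfig | None = None, seed: int | None = None, **kwargs
    ) -> "SlidingWindowDMR":
        """Build the model on a freshly simulated cohort (truth attached)."""
        config = config or SimulationConfig()
        if seed is not None:
            config = config.replace(seed=seed)
        manifest = generate_manifest(config)
        beta, detp, sheet, truth = generate_cohort(manifest, config)
        model = cls(beta, manifest, sheet, detection_p=detp, **kwargs)
        model.truth = truth
        model.sim_config = config
        return model

    def fit(self) -> "DMRResults":
        retained, report = filter_probes(self.manifest)
        beta = self.beta.subset_probes(retained)
        manifest = self.manifest.set_index("probe_id").loc[retained].reset_index()
        if self.detection_p is not None:
            beta = apply_detection_mask(
                beta, self.detection_p.loc[retained], threshold=self.detp_threshold
            )
        if self.normalize:
            beta = quantile_normalize(beta)
        cpg_results, skipped = run_cpg_scan(
            beta, manifest, self.sample_sheet, min_per_group=self.min_per_group
        )
        dmrs = call_dmrs(
            cpg_results, window_bp=self.window_bp, fdr=self.fdr,
            min_cpgs=self.min_cpgs,
        )
        return DMRResults(self, beta, cpg_results, skipped, dmrs, report)


class DMRResults:
    """Fitted DMR analysis: per-CpG estimates, called DMRs, diagnostics."""

    def __init__(self, model, beta, cpg_results, skipped, dmrs, filter_report):
        self.model = model
        self.beta = beta
        self.cpg_results = cpg_results
        self.skipped_cpgs = skipped
        self.dmrs = dmrs
        self.filter_report = filter_report

    @property
    def n_dmrs(self) -> int:
        return len(self.dmrs)

    def summary(self) -> str:
        """Plain-text analysis summary in the spirit of a model fit report."""
        fr = self.filter_report
        d = self.dmrs
        lines = [
            "Sliding-window DMR analysis",
            "=" * 64,
            f"Probes: {fr.n_input} input, {fr.n_retained} retained "
            f"({fr.n_removed_nonautosomal} non-autosomal, "
            f"{fr.n_removed_multimap} multimap, {fr.n_removed_snp} SNP-within-5bp)",
            f"CpGs fitted: {len(self.cpg_results)} "
            f"(skipped: {len(self.skipped_cpgs)})",
            f"Window: {self.model.window_bp} bp, min CpGs {self.model.min_cpgs}, "
            f"FDR {self.model.fdr:g}",
            "-" * 64,
            f"DMRs called: {len(d)}",
        ]
        if len(d):
            n_hyper = int((d["direction"] == "hyper").sum())
            n_hypo = len(d) - n_hyper
            lines += [
                f"  hypermethylated: {n_hyper}   hypomethylated: {n_hypo}",
                f"  mean size: {d['length'].mean():.0f} bp   "
                f"mean CpGs/DMR: {d['n_cpgs'].mean():.2f}",
                f"  DMR-CpGs: {int(d['n_cpgs'].sum())} "
                f"({int(d['n_sig_cpgs'].sum())} independently significant)",
                f"  mean max |delta-beta|: {d['max_abs_coef'].mean():.4f}",
            ]
        return "\n".join(lines)

    def to_tables(self, out_dir: str) -> list[str]:
        return write_results_tables(out_dir, dmrs=self.dmrs, cpg_results=self.cpg_results)

    def plot_manhattan(self, ax=None):
        """-log10 two-sided p per CpG along the genome, DMR CpGs highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        df = self.cpg_results
        offset = 0
        dmr_probes = set(
            pid for row in self.dmrs.get("probe_ids", pd.Series(dtype=str))
            for pid in row.split(",")
        )
        for ci, (chrom, grp) in enumerate(df.groupby("chromosome", sort=True)):
            x = grp["position"].to_numpy() + offset
            y = -np.log10(np.maximum(grp["p_two"].to_numpy(), 1e-300))
            base = "#444444" if ci % 2 == 0 else "#999999"
            in_dmr = grp["probe_id"].isin(dmr_probes).to_numpy()
            ax.scatter(x[~in_dmr], y[~in_dmr], s=3, c=base, linewidths=0)
            ax.scatter(x[in_dmr], y[in_dmr], s=6, c="#c0392b", linewidths=0)
            offset = x.max() + 1
        ax.set_xlabel("genomic position (concatenated chromosomes)")
        ax.set_ylabel(r"$-\log_{10} P$")
        return ax
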