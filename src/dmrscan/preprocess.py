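"""Probe exclusion, detection-p masking, and quantile normalization.

Probe exclusion applies, in a fixed order that makes the removal report
reproducible: non-autosomal probes, then multimapping probes, then probes
with a common SNP within 5 bp of the target CpG.  Per-sample beta values
with detection p-value above 0.01 (strictly) are masked rather than removed.
Quantile normalization maps each sample's observed values through the
across-sample mean quantile curve; with missing data the mapping goes
through interpolated quantile positions, so no imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataio import BetaMatrix

_SEX_CHROMOSOMES = {"chrX", "chrY", "chrM", "X", "Y", "M", "MT"}


@dataclass
class FilterReport:
    n_input: int
    n_removed_nonautosomal: int
    n_removed_multimap: int
    n_removed_snp: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def filter_probes(
    manifest: pd.DataFrame, autosomes: set[str] | None = None
) -> tuple[pd.Index, FilterReport]:
    """Apply the probe exclusion criteria; returns retained ids + a report.

    A probe removed for several reasons is counted once, under the first
    rule applied (autosome -> multimap -> SNP-within-5bp).  Retained probes
    come back sorted by (chromosome, position).
    """
    n_input = len(manifest)
    if autosomes is None:
        chrom_set = set(manifest["chromosome"])
        autosomes = chrom_set - _SEX_CHROMOSOMES
    is_autosomal = manifest["chromosome"].isin(autosomes).to_numpy()
    multimap = manifest["multimap_flag"].to_numpy(bool)
    snp = manifest["snp_within_5bp_flag"].to_numpy(bool)

    removed_nonauto = ~is_autosomal
    removed_multimap = is_autosomal & multimap
    removed_snp = is_autosomal & ~multimap & snp
    keep = is_autosomal & ~multimap & ~snp

    retained = (
        manifest.loc[keep]
        .sort_values(["chromosome", "position"], kind="mergesort")["probe_id"]
    )
    report = FilterReport(
        n_input=n_input,
        n_removed_nonautosomal=int(removed_nonauto.sum()),
        n_removed_multimap=int(removed_multimap.sum()),
        n_removed_snp=int(removed_snp.sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise ValueError("no probes retained after exclusion criteria")
    return pd.Index(retained, name="probe_id"), report


def apply_detection_mask(
    beta: BetaMatrix, detp: pd.DataFrame, threshold: float = 0.01
) -> BetaMatrix:
    """Mask beta entries whose detection p-value exceeds the threshold.

    The comparison is strict (p > threshold is masked; p == threshold is
    retained).  Values are untouched; only the mask changes.
    """
    if detp.shape != beta.values.shape:
        raise ValueError(
            f"detection-p shape {detp.shape} != beta shape {beta.values.shape}"
        )
    detp = detp.reindex(index=beta.values.index, columns=beta.values.columns)
    if detp.isna().any().any():
        raise ValueError("detection-p matrix labels do not match beta matrix")
    new_mask = beta.mask & ~(detp > threshold)
    return BetaMatrix(beta.values.copy(), new_mask)


def quantile_normalize(beta: BetaMatrix) -> BetaMatrix:
    """Quantile-normalize samples to the across-sample mean quantile curve.

    For complete data every sample's sorted values become exactly the mean
    of the per-sample sorted curves.  Masked entries are excluded from both
    the reference curve and the rank computation and come back unchanged
    (still masked).  Ties within a sample receive averaged ranks and hence
    the average of the corresponding reference quantiles.
    """
    V = beta.values.to_numpy(float)
    M = beta.mask.to_numpy(bool)
    n_probes, n_samples = V.shape
    if n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    counts = M.sum(axis=0)
    if (counts == 0).any():
        bad = beta.values.columns[np.where(counts == 0)[0][0]]
        raise ValueError(f"sample {bad!r} has no unmasked values")

    grid = (np.arange(n_probes) + 0.5) / n_probes
    ref = np.zeros(n_probes)
    for j in range(n_samples):
        v = np.sort(V[M[:, j], j])
        k = len(v)
        pos = (np.arange(k) + 0.5) / k
        ref += np.interp(grid, pos, v)
    ref /= n_samples

    out = V.copy()
    for j in range(n_samples):
        rows = np.where(M[:, j])[0]
        v = V[rows, j]
        k = len(v)
        ranks = rankdata(v, method="average")  # 1..k, ties averaged
        q = (ranks - 0.5) / k
        out[rows, j] = np.interp(q, grid, ref)

    return BetaMatrix(
        pd.DataFrame(out, index=beta.values.index, columns=beta.values.columns),
        beta.mask.copy(),
    )
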