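"""Readers, writers and validated in-memory containers for cohort inputs.

All tabular interchange is tab-separated with a mandatory header row.  Point
positions (probe coordinates, SNP positions) are 1-based in tables; interval
tracks are BED, 0-based half-open.  Missing beta values are written as ``NA``;
downstream code consults only the boolean mask, never NaN sentinels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "probe_type",
    "multimap_flag",
    "snp_within_5bp_flag",
    "celltype_differential_flag",
]

SHEET_COLUMNS = ["sample_id", "group", "aod", "gender", "race", "array"]

_FLOAT_FMT = "%.6g"


class CohortValidationError(ValueError):
    """Raised when cohort inputs fail cross-validation."""


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with a usability mask.

    ``values`` is a float DataFrame indexed by probe_id with sample_id
    columns; ``mask`` is a congruent boolean DataFrame where True marks a
    usable measurement.  Masked cells keep whatever value they carried; all
    computation must route through the mask.
    """

    values: pd.DataFrame
    mask: pd.DataFrame = None

    def __post_init__(self):
        if self.mask is None:
            self.mask = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        if self.values.shape != self.mask.shape:
            raise CohortValidationError(
                f"beta values {self.values.shape} and mask {self.mask.shape} differ in shape"
            )
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise CohortValidationError("beta values and mask are differently labelled")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        idx = pd.Index(probe_ids)
        return BetaMatrix(self.values.loc[idx], self.mask.loc[idx])

    def subset_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        cols = pd.Index(sample_ids)
        return BetaMatrix(self.values[cols], self.mask[cols])


@dataclass
class AnnotationTrack:
    """A named collection of genomic intervals, 0-based half-open."""

    name: str
    intervals: pd.DataFrame  # columns: chromosome, start, end, strand, label

    def __post_init__(self):
        df = self.intervals
        for col in ("strand", "label"):
            if col not in df.columns:
                df[col] = "."
        bad = df[df["start"] >= df["end"]]
        if len(bad):
            raise CohortValidationError(
                f"track {self.name!r}: start >= end for {len(bad)} interval(s)"
            )

    def __len__(self) -> int:
        return len(self.intervals)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise CohortValidationError(f"manifest missing columns: {missing}")
    if manifest["probe_id"].duplicated().any():
        dups = manifest.loc[manifest["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise CohortValidationError(f"duplicate probe ids in manifest: {dups}")
    if (manifest["position"] < 1).any():
        raise CohortValidationError("manifest positions must be >= 1 (1-based)")
    return manifest


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise CohortValidationError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        raise CohortValidationError("duplicate sample ids in sheet")
    if (pd.to_numeric(sheet["aod"]) <= 0).any():
        raise CohortValidationError("age of death must be positive")
    bad_groups = set(sheet["group"]) - {"case", "control"}
    if bad_groups:
        raise CohortValidationError(f"unknown group labels: {sorted(bad_groups)}")
    if "np" in sheet.columns:
        np_vals = pd.to_numeric(sheet["np"], errors="coerce")
        ok = np_vals.isna() | ((np_vals >= 0) & (np_vals <= 1))
        if not ok.all():
            raise CohortValidationError("np column values must lie in [0, 1]")
    return sheet


def load_cohort_inputs(
    manifest_path: str,
    beta_path: str,
    sheet_path: str,
    detp_path: str | None = None,
) -> tuple[pd.DataFrame, BetaMatrix, pd.DataFrame]:
    """Read and cross-validate a manifest, beta matrix, and sample sheet.

    The optional detection-p matrix is converted to a mask (p > 0.01 is NOT
    applied here; the raw mask is all-True and masking is a preprocessing
    step).  Dimension or identifier mismatches raise CohortValidationError
    naming the offender.
    """
    manifest = validate_manifest(pd.read_csv(manifest_path, sep="\t"))
    sheet = validate_sample_sheet(pd.read_csv(sheet_path, sep="\t"))

    beta = pd.read_csv(beta_path, sep="\t", index_col=0, na_values=["NA"])
    try:
        beta = beta.astype(float)
    except ValueError as exc:
        raise CohortValidationError(f"non-numeric beta value: {exc}") from exc

    manifest_ids = pd.Index(manifest["probe_id"])
    if not beta.index.equals(manifest_ids):
        extra = beta.index.difference(manifest_ids)
        absent = manifest_ids.difference(beta.index)
        raise CohortValidationError(
            f"beta probes disagree with manifest "
            f"(unknown: {list(extra[:5])}, missing: {list(absent[:5])})"
        )
    sheet_ids = pd.Index(sheet["sample_id"])
    if set(beta.columns) != set(sheet_ids):
        orphans = beta.columns.difference(sheet_ids)
        absent = sheet_ids.difference(beta.columns)
        raise CohortValidationError(
            f"beta samples disagree with sheet "
            f"(orphans: {list(orphans[:5])}, missing: {list(absent[:5])})"
        )
    beta = beta[sheet_ids]

    mask = beta.notna()
    observed = beta.to_numpy(float)
    with np.errstate(invalid="ignore"):
        out_of_range = mask.to_numpy() & ((observed < 0) | (observed > 1))
    if out_of_range.any():
        i, j = np.argwhere(out_of_range)[0]
        raise CohortValidationError(
            f"beta value out of [0,1] at probe {beta.index[i]!r}, sample {beta.columns[j]!r}: "
            f"{observed[i, j]}"
        )

    if detp_path is not None:
        detp = pd.read_csv(detp_path, sep="\t", index_col=0)
        if detp.shape != beta.shape or not detp.index.equals(beta.index):
            raise CohortValidationError("detection-p matrix incongruent with beta matrix")
        detp = detp[sheet_ids]
        bm = BetaMatrix(beta, mask)
        bm.detection_p = detp  # carried along for preprocessing
    else:
        bm = BetaMatrix(beta, mask)
        bm.detection_p = None
    return manifest, bm, sheet


def read_bed_track(path: str, name: str | None = None) -> AnnotationTrack:
    """Parse a BED3+ file into an AnnotationTrack (0-based half-open, as BED).

    Column 4 is kept as ``label``, column 6 as ``strand`` when present.
    """
    name = name or os.path.splitext(os.path.basename(path))[0]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CohortValidationError(
                    f"{path}:{lineno}: BED line has fewer than 3 columns"
                )
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise CohortValidationError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            label = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, strand, label))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "strand", "label"])
    return AnnotationTrack(name=name, intervals=df)


def write_bed_track(track: AnnotationTrack, path: str) -> None:
    df = track.intervals
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.start}\t{row.end}\t{row.label}\t0\t{row.strand}\n"
            )


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a TSV with NA for missing and 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def write_matrix(df: pd.DataFrame, path: str, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=True, na_rep="NA", float_format=float_format)


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def beta_to_table(beta: BetaMatrix) -> pd.DataFrame:
    """Encode a BetaMatrix for writing: masked cells become NA."""
    out = beta.values.copy()
    out = out.where(beta.mask)
    return out


def write_results_tables(
    out_dir: str,
    dmrs: pd.DataFrame | None = None,
    cpg_results: pd.DataFrame | None = None,
    enrichments: dict[str, pd.DataFrame] | None = None,
) -> list[str]:
    """Emit the standard result file set; returns the paths written.

    The DMR table mirrors the headline per-region columns (coordinates,
    length, CpG counts, combined and adjusted p, direction, largest absolute
    effect, top CpG); the DMRs are also written as BED with the direction in
    the name field (start converted to 0-based).
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    if dmrs is not None:
        cols = [
            "chromosome", "start", "end", "length", "n_cpgs", "n_sig_cpgs",
            "combined_p", "q", "direction", "max_abs_coef", "top_cpg_id", "top_cpg_p",
        ]
        table = dmrs[[c for c in cols if c in dmrs.columns]]
        path = os.path.join(out_dir, "dmrs.tsv")
        write_table(table, path)
        written.append(path)
        bed_path = os.path.join(out_dir, "dmrs.bed")
        with open(bed_path, "w") as fh:
            for row in dmrs.itertuples(index=False):
                fh.write(
                    f"{row.chromosome}\t{row.start - 1}\t{row.end}\t{row.direction}\t0\t.\n"
                )
        written.append(bed_path)
    if cpg_results is not None:
        path = os.path.join(out_dir, "cpg_results.tsv")
        write_table(cpg_results, path)
        written.append(path)
    for label, table in (enrichments or {}).items():
        path = os.path.join(out_dir, f"enrichment_{label}.tsv")
        write_table(table, path)
        written.append(path)
    return written
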