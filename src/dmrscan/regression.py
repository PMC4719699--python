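"""Per-CpG multivariate linear model for disease-associated methylation.

Each CpG's beta values are regressed on age of death (AOD), gender, race,
array/batch and — only at CpGs flagged as differentially methylated between
neurons and glia — the neuronal proportion (NP), with the disease indicator
(control = 0, case = 1) entered last:

    beta = intercept + AOD + gender + race + array [+ NP] + disease

The disease coefficient is the covariate-adjusted case-minus-control effect
in beta units.  Hypermethylation means a positive coefficient.  One-sided
p-values toward each direction are derived from the t statistic, so
p_hyper + p_hypo = 1 and p_two = 2 * min(p_hyper, p_hypo).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import BetaMatrix

CPG_RESULT_COLUMNS = [
    "probe_id", "chromosome", "position", "coef", "se", "t", "p_two",
    "p_hyper", "p_hypo", "direction", "n_used", "np_adjusted",
]


@dataclass
class DesignSpec:
    """Covariate plan: ordered covariates and categorical reference levels.

    Categorical covariates use treatment coding against the alphabetically
    first level unless a reference level is supplied.  The disease indicator
    is always the last column.
    """

    covariates: tuple[str, ...] = ("aod", "gender", "race", "array", "np")
    categorical: tuple[str, ...] = ("gender", "race", "array")
    reference_levels: dict = field(default_factory=dict)
    disease_column: str = "group"
    case_label: str = "case"


def build_design_matrix(
    sheet: pd.DataFrame, spec: DesignSpec | None = None, include_np: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Expand the sample sheet into a design matrix with the disease term last.

    Single-level categorical covariates are dropped with a warning; a
    single-level disease column is an error.  Returns (matrix, column labels).
    """
    spec = spec or DesignSpec()
    cols = [np.ones(len(sheet))]
    labels = ["intercept"]
    for cov in spec.covariates:
        if cov == "np" and not include_np:
            continue
        if cov not in sheet.columns:
            if cov == "np":
                raise ValueError("include_np requested but sheet has no 'np' column")
            raise ValueError(f"covariate {cov!r} absent from sample sheet")
        if cov in spec.categorical:
            values = sheet[cov].astype(str)
            levels = sorted(values.unique())
            if len(levels) < 2:
                warnings.warn(
                    f"covariate {cov!r} has a single level; dropped from the design"
                )
                continue
            ref = spec.reference_levels.get(cov, levels[0])
            for level in levels:
                if level == ref:
                    continue
                cols.append((values == level).to_numpy(float))
                labels.append(f"{cov}[{level}]")
        else:
            cols.append(pd.to_numeric(sheet[cov]).to_numpy(float))
            labels.append(cov)
    disease = sheet[spec.disease_column].astype(str)
    if disease.nunique() < 2:
        raise ValueError("disease status has a single level; cannot fit")
    cols.append((disease == spec.case_label).to_numpy(float))
    labels.append("disease")
    return np.column_stack(cols), labels


def fit_single_cpg(
    y: np.ndarray, X: np.ndarray, term: int = -1
) -> tuple[float, float, float]:
    """OLS fit returning (coef, se, p_two) for one design column.

    Rows with masked response must already be removed.  Raises on rank
    deficiency or non-positive residual degrees of freedom; callers doing a
    genome-wide scan catch these and record a skip reason instead.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n - p < 1:
        raise np.linalg.LinAlgError("residual degrees of freedom < 1")
    coef, se, tstat, df = _ols_term(y[:, None], X, term)
    p_two = 2.0 * stats.t.sf(np.abs(tstat[0]), df)
    return float(coef[0]), float(se[0]), float(p_two)


def _ols_term(Y: np.ndarray, X: np.ndarray, term: int = -1):
    """Vectorized OLS of many responses on one design; stats for one term.

    Y is (n_samples, n_responses).  Raises numpy.linalg.LinAlgError when X is
    rank deficient.  Returns (coef, se, t, df) with arrays over responses.
    """
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta_hat = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ beta_hat
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    Rinv = np.linalg.solve(R, np.eye(p))
    xtx_inv_diag = (Rinv**2).sum(axis=1)
    se = np.sqrt(sigma2 * xtx_inv_diag[term])
    coef = beta_hat[term]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, 0.0)
    return coef, se, tstat, df


def one_sided_p(p_two: float, coef_sign: int, direction: str) -> float:
    """Convert a two-sided p-value into a directional one-sided p-value.

    Returns p_two / 2 when the coefficient sign matches the tested direction
    ('hyper' for positive, 'hypo' for negative) and 1 - p_two / 2 otherwise.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError(f"direction must be 'hyper' or 'hypo', got {direction!r}")
    matches = (coef_sign >= 0) == (direction == "hyper")
    return p_two / 2.0 if matches else 1.0 - p_two / 2.0


def run_cpg_scan(
    beta: BetaMatrix,
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    spec: DesignSpec | None = None,
    min_per_group: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the disease model at every probe; NP-adjust flagged probes only.

    Returns (results, skipped): ``results`` has one row per fitted probe in
    coordinate order with signed effect, both one-sided p-values and the
    direction; ``skipped`` records probes dropped for insufficient data or a
    rank-deficient design.  Probes whose manifest row carries the cell-type
    -differential flag are fitted with NP in the model (when the sheet has an
    ``np`` column); all others without.
    """
    spec = spec or DesignSpec()
    manifest = (
        manifest.set_index("probe_id")
        .loc[beta.probe_ids]
        .rename_axis("probe_id")
        .reset_index()
    )
    order = np.lexsort(
        (manifest["position"].to_numpy(), manifest["chromosome"].to_numpy())
    )
    manifest = manifest.iloc[order].reset_index(drop=True)
    beta = beta.subset_probes(manifest["probe_id"])

    sheet = sheet.set_index("sample_id").loc[beta.sample_ids].reset_index()
    have_np = "np" in sheet.columns and sheet["np"].notna().all()
    X_plain, labels_plain = build_design_matrix(sheet, spec, include_np=False)
    if have_np:
        X_np, labels_np = build_design_matrix(sheet, spec, include_np=True)
    else:
        X_np, labels_np = X_plain, labels_plain

    V = beta.values.to_numpy(float)
    M = beta.mask.to_numpy(bool)
    is_case = (sheet[spec.disease_column].astype(str) == spec.case_label).to_numpy()
    ct_flag = manifest["celltype_differential_flag"].to_numpy(bool) & have_np

    n_probes = V.shape[0]
    coef = np.full(n_probes, np.nan)
    se = np.full(n_probes, np.nan)
    tstat = np.full(n_probes, np.nan)
    dfres = np.full(n_probes, -1)
    skip_reason = np.full(n_probes, "", dtype=object)

    complete = M.all(axis=1)
    n_case_all = int(is_case.sum())
    n_ctrl_all = int((~is_case).sum())
    if n_case_all < min_per_group or n_ctrl_all < min_per_group:
        skip_reason[complete] = "insufficient_samples"
        complete = np.zeros_like(complete)
    for use_np in (False, True):
        X = X_np if use_np else X_plain
        sel = complete & (ct_flag == use_np)
        if sel.any():
            try:
                c, s, t, df = _ols_term(V[sel].T, X)
            except np.linalg.LinAlgError:
                skip_reason[sel] = "rank_deficient"
                continue
            coef[sel], se[sel], tstat[sel] = c, s, t
            dfres[sel] = df

    for i in np.where(~complete)[0]:
        rows = M[i]
        n_case = int((rows & is_case).sum())
        n_ctrl = int((rows & ~is_case).sum())
        if n_case < min_per_group or n_ctrl < min_per_group:
            skip_reason[i] = "insufficient_samples"
            continue
        X = X_np if ct_flag[i] else X_plain
        Xs = X[rows]
        if Xs.shape[0] - Xs.shape[1] < 1:
            skip_reason[i] = "insufficient_samples"
            continue
        try:
            c, s, t, df = _ols_term(V[i, rows][:, None], Xs)
        except np.linalg.LinAlgError:
            skip_reason[i] = "rank_deficient"
            continue
        coef[i], se[i], tstat[i], dfres[i] = c[0], s[0], t[0], df

    fitted = dfres > 0
    p_hyper = np.full(n_probes, np.nan)
    p_hypo = np.full(n_probes, np.nan)
    p_two = np.full(n_probes, np.nan)
    ph = stats.t.sf(tstat[fitted], dfres[fitted])
    p_hyper[fitted] = ph
    p_hypo[fitted] = 1.0 - ph
    p_two[fitted] = 2.0 * np.minimum(ph, 1.0 - ph)

    results = pd.DataFrame(
        {
            "probe_id": manifest["probe_id"],
            "chromosome": manifest["chromosome"],
            "position": manifest["position"],
            "coef": coef,
            "se": se,
            "t": tstat,
            "p_two": p_two,
            "p_hyper": p_hyper,
            "p_hypo": p_hypo,
            "direction": np.where(coef >= 0, "hyper", "hypo"),
            "n_used": M.sum(axis=1),
            "np_adjusted": ct_flag,
        }
    )
    skipped = results.loc[~fitted, ["probe_id", "chromosome", "position"]].copy()
    skipped["reason"] = skip_reason[~fitted]
    results = results.loc[fitted].reset_index(drop=True)
    return results, skipped
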