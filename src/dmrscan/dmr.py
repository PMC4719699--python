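"""Direction-aware sliding-window Fisher combination and DMR calling.

A candidate window is anchored at every CpG and contains all CpGs within
``window_bp`` (half-open, [anchor, anchor + window_bp)) on the same
chromosome; candidates with fewer than ``min_cpgs`` members are dropped.
For each window the one-sided regression p-values of ALL member CpGs are
combined with Fisher's method separately toward hypermethylation and toward
hypomethylation; the window's direction is whichever combination is more
significant, so discordant members (one-sided p near 1) penalize a window
rather than being filtered away.  Window p-values are Benjamini-Hochberg
adjusted, windows with q below the FDR cutoff are significant, and
overlapping same-direction significant windows merge into one DMR spanning
its first to last member CpG.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

DMR_COLUMNS = [
    "chromosome", "start", "end", "length", "direction", "combined_p", "q",
    "n_cpgs", "n_sig_cpgs", "max_abs_coef", "top_cpg_id", "top_cpg_p",
    "probe_ids", "n_windows", "overlaps_opposite",
]


def fisher_combine(one_sided_ps) -> tuple[float, float]:
    """Fisher's method: stat = -2 * sum(ln p) ~ chi-square with 2k df.

    Zero p-values are clamped to the smallest positive float with a warning.
    At k = 1 the combined p equals the input p.
    """
    ps = np.asarray(one_sided_ps, dtype=float)
    if ps.size == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (ps == 0).any():
        warnings.warn("p-value of 0 clamped to smallest positive float")
        ps = np.maximum(ps, np.finfo(float).tiny)
    stat = -2.0 * np.log(ps).sum()
    return float(stat), float(chi2.sf(stat, 2 * ps.size))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


def enumerate_windows(
    positions: pd.DataFrame, window_bp: int = 1000, min_cpgs: int = 2
) -> pd.DataFrame:
    """Enumerate candidate windows anchored at each CpG.

    ``positions`` needs columns probe_id, chromosome, position (sorted or
    not; sorting is applied).  Returns one row per qualifying window with
    the anchor probe, the member index range into the coordinate-sorted
    frame, and the member probe ids.
    """
    df = positions.sort_values(["chromosome", "position"], kind="mergesort").reset_index(
        drop=True
    )
    rows = []
    for chrom, grp in df.groupby("chromosome", sort=True):
        pos = grp["position"].to_numpy()
        if len(np.unique(pos)) != len(pos):
            raise ValueError(f"duplicate positions on {chrom}")
        offset = grp.index[0]
        ends = np.searchsorted(pos, pos + window_bp, side="left")
        for i, e in enumerate(ends):
            if e - i < min_cpgs:
                continue
            rows.append(
                {
                    "chromosome": chrom,
                    "anchor_probe_id": grp["probe_id"].iloc[i],
                    "start_idx": offset + i,
                    "end_idx": offset + e,
                    "n_cpgs": e - i,
                    "member_probe_ids": ",".join(grp["probe_id"].iloc[i:e]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "anchor_probe_id", "start_idx", "end_idx", "n_cpgs",
            "member_probe_ids",
        ],
    )


def _window_stats(cpg_results: pd.DataFrame, window_bp: int, min_cpgs: int):
    """Vectorized per-window Fisher statistics in both directions.

    Returns the coordinate-sorted cpg frame plus a window frame with the
    chosen direction and combined p per window.
    """
    df = cpg_results.sort_values(["chromosome", "position"], kind="mergesort").reset_index(
        drop=True
    )
    tiny = np.finfo(float).tiny
    lh_all = np.log(np.maximum(df["p_hyper"].to_numpy(float), tiny))
    ll_all = np.log(np.maximum(df["p_hypo"].to_numpy(float), tiny))

    frames = []
    for chrom, grp in df.groupby("chromosome", sort=True):
        idx = grp.index.to_numpy()
        pos = grp["position"].to_numpy()
        ends_local = np.searchsorted(pos, pos + window_bp, side="left")
        k = ends_local - np.arange(len(pos))
        keep = k >= min_cpgs
        if not keep.any():
            continue
        cum_h = np.concatenate([[0.0], np.cumsum(lh_all[idx])])
        cum_l = np.concatenate([[0.0], np.cumsum(ll_all[idx])])
        i_loc = np.arange(len(pos))[keep]
        e_loc = ends_local[keep]
        kk = k[keep]
        stat_h = -2.0 * (cum_h[e_loc] - cum_h[i_loc])
        stat_l = -2.0 * (cum_l[e_loc] - cum_l[i_loc])
        p_h = chi2.sf(stat_h, 2 * kk)
        p_l = chi2.sf(stat_l, 2 * kk)
        hyper_wins = p_h <= p_l
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "start_idx": idx[0] + i_loc,
                    "end_idx": idx[0] + e_loc,
                    "n_cpgs": kk,
                    "direction": np.where(hyper_wins, "hyper", "hypo"),
                    "fisher_stat": np.where(hyper_wins, stat_h, stat_l),
                    "combined_p": np.where(hyper_wins, p_h, p_l),
                }
            )
        )
    if not frames:
        windows = pd.DataFrame(
            columns=[
                "chromosome", "start_idx", "end_idx", "n_cpgs", "direction",
                "fisher_stat", "combined_p",
            ]
        )
    else:
        windows = pd.concat(frames, ignore_index=True)
    return df, windows


def call_dmrs(
    cpg_results: pd.DataFrame,
    window_bp: int = 1000,
    fdr: float = 0.01,
    min_cpgs: int = 2,
    sig_cpg_p: float = 0.05,
) -> pd.DataFrame:
    """Call DMRs from per-CpG regression results.

    The returned frame has one row per DMR: the span of its member CpGs
    (1-based, inclusive), direction, the combined p and q of its most
    significant constituent window, member counts, the count of members
    independently significant in the DMR direction (one-sided p < sig_cpg_p),
    the largest absolute adjusted effect, and the most significant member
    CpG.  Same-direction significant windows sharing a member CpG merge;
    opposite-direction overlaps stay separate and are flagged.
    """
    df, windows = _window_stats(cpg_results, window_bp, min_cpgs)
    if len(windows) == 0:
        return pd.DataFrame(columns=DMR_COLUMNS)

    windows = windows.copy()
    windows["q"] = bh_adjust(windows["combined_p"].to_numpy())
    sig = windows[windows["q"] < fdr].sort_values(
        ["chromosome", "start_idx", "end_idx"], kind="mergesort"
    )
    if len(sig) == 0:
        return pd.DataFrame(columns=DMR_COLUMNS)

    pos = df["position"].to_numpy()
    coefs = df["coef"].to_numpy(float)
    probe_ids = df["probe_id"].to_numpy()
    p_dir = {
        "hyper": df["p_hyper"].to_numpy(float),
        "hypo": df["p_hypo"].to_numpy(float),
    }

    merged = []  # dicts with mutable span per (chromosome, direction) run
    open_runs: dict[str, dict | None] = {"hyper": None, "hypo": None}
    current_chrom = None
    for win in sig.itertuples(index=False):
        if win.chromosome != current_chrom:
            for d in ("hyper", "hypo"):
                if open_runs[d] is not None:
                    merged.append(open_runs[d])
                open_runs[d] = None
            current_chrom = win.chromosome
        run = open_runs[win.direction]
        if run is not None and win.start_idx < run["end_idx"]:
            run["end_idx"] = max(run["end_idx"], win.end_idx)
            run["n_windows"] += 1
            if win.combined_p < run["combined_p"]:
                run["combined_p"] = win.combined_p
                run["q"] = win.q
        else:
            if run is not None:
                merged.append(run)
            open_runs[win.direction] = {
                "chromosome": win.chromosome,
                "direction": win.direction,
                "start_idx": win.start_idx,
                "end_idx": win.end_idx,
                "combined_p": win.combined_p,
                "q": win.q,
                "n_windows": 1,
            }
    for d in ("hyper", "hypo"):
        if open_runs[d] is not None:
            merged.append(open_runs[d])

    rows = []
    for run in merged:
        i, e = run["start_idx"], run["end_idx"]
        members = np.arange(i, e)
        d = run["direction"]
        ps = p_dir[d][members]
        top_local = int(np.argmin(ps))
        rows.append(
            {
                "chromosome": run["chromosome"],
                "start": int(pos[i]),
                "end": int(pos[e - 1]),
                "length": int(pos[e - 1] - pos[i]),
                "direction": d,
                "combined_p": run["combined_p"],
                "q": run["q"],
                "n_cpgs": int(e - i),
                "n_sig_cpgs": int((ps < sig_cpg_p).sum()),
                "max_abs_coef": float(np.abs(coefs[members]).max()),
                "top_cpg_id": probe_ids[members[top_local]],
                "top_cpg_p": float(ps[top_local]),
                "probe_ids": ",".join(probe_ids[members]),
                "n_windows": run["n_windows"],
                "overlaps_opposite": False,
            }
        )
    dmrs = pd.DataFrame(rows, columns=DMR_COLUMNS).sort_values(
        ["chromosome", "start"], kind="mergesort"
    ).reset_index(drop=True)

    # flag DMRs of opposite direction whose spans overlap
    for chrom, grp in dmrs.groupby("chromosome"):
        g = grp.sort_values("start")
        for a in range(len(g)):
            for b in range(a + 1, len(g)):
                ra, rb = g.iloc[a], g.iloc[b]
                if rb["start"] > ra["end"]:
                    break
                if ra["direction"] != rb["direction"]:
                    dmrs.loc[g.index[a], "overlaps_opposite"] = True
                    dmrs.loc[g.index[b], "overlaps_opposite"] = True
    return dmrs
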