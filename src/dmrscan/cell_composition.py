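"""Two-reference cell-type deconvolution for bulk brain methylation.

Bulk beta values at cell-type-differential CpGs are modelled as a convex
mixture of a neuronal and a glial reference profile:

    beta_bulk = w * beta_neuron + (1 - w) * beta_glia + error

The per-sample neuronal proportion (NP) estimate is the least-squares
minimizer of the residual over shared unmasked reference probes, clipped to
[0, 1].  The closed-form solution is a scalar projection, so the estimate is
exact for noise-free mixtures and invariant to adding probes at which the
two references agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import BetaMatrix


@dataclass
class ReferenceProfiles:
    """Neuron and glia mean beta profiles over a shared probe set."""

    probe_ids: pd.Index
    neuron_mean: np.ndarray
    glia_mean: np.ndarray

    def __post_init__(self):
        self.probe_ids = pd.Index(self.probe_ids)
        self.neuron_mean = np.asarray(self.neuron_mean, dtype=float)
        self.glia_mean = np.asarray(self.glia_mean, dtype=float)
        if not (len(self.probe_ids) == len(self.neuron_mean) == len(self.glia_mean)):
            raise ValueError("reference profiles must share one probe ordering")
        for name, arr in (("neuron", self.neuron_mean), ("glia", self.glia_mean)):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} reference values must lie in [0, 1]")
        if np.allclose(self.neuron_mean, self.glia_mean):
            raise ValueError("reference profiles must differ at >= 1 probe")

    @classmethod
    def from_table(cls, path: str) -> "ReferenceProfiles":
        df = pd.read_csv(path, sep="\t")
        return cls(
            probe_ids=pd.Index(df["probe_id"]),
            neuron_mean=df["neuron_mean"].to_numpy(float),
            glia_mean=df["glia_mean"].to_numpy(float),
        )

    def to_table(self, path: str) -> None:
        pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "neuron_mean": self.neuron_mean,
                "glia_mean": self.glia_mean,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def estimate_neuronal_proportion(
    beta: BetaMatrix, refs: ReferenceProfiles
) -> pd.Series:
    """Estimate per-sample neuronal proportion by constrained least squares.

    For each sample the scalar w minimizing || beta - (w*neuron + (1-w)*glia) ||
    over the shared unmasked reference probes is computed in closed form and
    clipped to [0, 1].  Samples with no usable shared probe raise, naming the
    sample.
    """
    shared = refs.probe_ids.intersection(beta.probe_ids)
    if len(shared) == 0:
        raise ValueError("no reference probes present in the beta matrix")
    ref_pos = refs.probe_ids.get_indexer(shared)
    neuron = refs.neuron_mean[ref_pos]
    glia = refs.glia_mean[ref_pos]
    diff = neuron - glia

    V = beta.values.loc[shared].to_numpy(float)
    M = beta.mask.loc[shared].to_numpy(bool)

    out = np.empty(V.shape[1])
    for j, sample in enumerate(beta.sample_ids):
        use = M[:, j]
        if not use.any():
            raise ValueError(f"sample {sample!r} has no usable reference probes")
        d = diff[use]
        denom = float(d @ d)
        if denom == 0.0:
            raise ValueError(
                f"sample {sample!r}: references identical at all usable probes"
            )
        w = float(d @ (V[use, j] - glia[use])) / denom
        out[j] = min(max(w, 0.0), 1.0)
    return pd.Series(out, index=beta.sample_ids, name="np")


def compare_group_proportions(
    np_values: pd.Series, groups: pd.Series
) -> dict:
    """Welch two-sample t-test of neuronal proportion between groups.

    Returns per-group means plus the t statistic and two-sided p-value.
    """
    groups = groups.reindex(np_values.index) if hasattr(groups, "reindex") else groups
    labels = pd.unique(np.asarray(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    a = np_values[np.asarray(groups) == labels[0]].to_numpy(float)
    b = np_values[np.asarray(groups) == labels[1]].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "means": {str(labels[0]): float(a.mean()), str(labels[1]): float(b.mean())},
        "t": float(t),
        "p": float(p),
        "n": {str(labels[0]): len(a), str(labels[1]): len(b)},
    }
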