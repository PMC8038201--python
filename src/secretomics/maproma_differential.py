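"""Label-free differential selection on aPSM values: DAve/DCI, F screen, Ward.

The two selection indices operate on the averaged spectral counts X and Y of
a protein in two compared conditions:

* DAve (Differential Average)        = (X - Y) / ((X + Y) * 0.5)
* DCI  (Differential Confidence Index) = (X + Y) * (X - Y) / 2

DAve is a bounded symmetric fold-change index in [-2, 2]; |DAve| >= 0.4 is
algebraically the same cut as a 1.5-fold change. DCI weights the difference
by total abundance so that low-count proteins cannot pass on ratio alone.
A protein is selected when both |DAve| >= 0.4 and |DCI| >= 5 (defaults).

The multi-condition screen retains proteins whose one-way fixed-effects
F ratio (model mean square over error mean square across condition groups
of normalized per-run counts) is >= 4.5 with p <= 0.001; retained profiles
feed agglomerative clustering under Ward's criterion with Euclidean
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .psm_matrix import AbundanceMatrix

__all__ = [
    "compute_dave",
    "compute_dci",
    "pairwise_compare",
    "f_ratio_screen",
    "ClusterTree",
    "ward_cluster",
    "write_comparison_tsv",
    "plot_heatmap",
]


def _check_nonneg(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("aPSM values must be non-negative")
    return x, y


def compute_dave(x, y):
    """DAve index, 2(X - Y)/(X + Y); 0 when X = Y = 0. Accepts scalars or
    arrays; result lies in [-2, 2]."""
    x, y = _check_nonneg(x, y)
    s = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, (x - y) / (s * 0.5), 0.0)
    return float(out) if out.ndim == 0 else out


def compute_dci(x, y):
    """DCI index, (X + Y)(X - Y)/2. Accepts scalars or arrays."""
    x, y = _check_nonneg(x, y)
    out = (x + y) * (x - y) / 2.0
    return float(out) if out.ndim == 0 else out


def pairwise_compare(matrix: AbundanceMatrix, cond_a: str, cond_b: str,
                     dave_thr: float = 0.4, dci_thr: float = 5.0,
                     values: str = "apsm") -> pd.DataFrame:
    """DAve/DCI comparison of two conditions over all aligned proteins.

    Returns a DataFrame (accession, x, y, dave, dci, selected, direction).
    ``selected`` requires |DAve| >= dave_thr AND |DCI| >= dci_thr; positive
    indices mean up in ``cond_a`` (equivalently down in ``cond_b``).
    ``values="summed"`` uses per-condition sums of the normalized run counts
    instead of their means (the indices' thresholds then act on totals).
    """
    for cond in (cond_a, cond_b):
        if cond not in matrix.conditions:
            raise KeyError(f"unknown condition {cond!r}")
    if values == "apsm":
        x = matrix.apsm[cond_a].to_numpy()
        y = matrix.apsm[cond_b].to_numpy()
    elif values == "summed":
        x = matrix.runs_of(cond_a).sum(axis=1).to_numpy()
        y = matrix.runs_of(cond_b).sum(axis=1).to_numpy()
    else:
        raise ValueError("values must be 'apsm' or 'summed'")
    dave = compute_dave(x, y)
    dci = compute_dci(x, y)
    selected = (np.abs(dave) >= dave_thr) & (np.abs(dci) >= dci_thr)
    direction = np.where(selected,
                         np.where(dave > 0, f"up_in_{cond_a}", f"up_in_{cond_b}"),
                         "")
    return pd.DataFrame({
        "accession": matrix.accessions, "x": x, "y": y,
        "dave": dave, "dci": dci, "selected": selected,
        "direction": direction,
    }).set_index("accession")


def f_ratio_screen(matrix: AbundanceMatrix, f_thr: float = 4.5,
                   p_thr: float = 0.001) -> pd.DataFrame:
    """Per-protein one-way fixed-effects F across condition groups.

    Uses normalized per-run values; p comes from the F distribution with
    (k - 1, N - k) degrees of freedom. Proteins with zero variance overall
    get F = 0, p = 1. Conditions with fewer than 2 runs make the screen
    untestable and raise.
    """
    conditions = matrix.conditions
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    groups = []
    for cond in conditions:
        block = matrix.runs_of(cond).to_numpy()
        if block.shape[1] < 2:
            raise ValueError(f"condition {cond!r} has < 2 replicate runs")
        groups.append(block)
    k = len(groups)
    n_total = sum(g.shape[1] for g in groups)
    grand = np.hstack(groups)
    grand_mean = grand.mean(axis=1)
    ss_between = sum(g.shape[1] * (g.mean(axis=1) - grand_mean) ** 2
                     for g in groups)
    ss_within = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
                    for g in groups)
    df_b, df_w = k - 1, n_total - k
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(f, df_b, df_w)
    # constant profiles: no model or error variance -> not retained
    degenerate = ~np.isfinite(f)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    retained = (f >= f_thr) & (p <= p_thr)
    return pd.DataFrame({"accession": matrix.accessions, "f_ratio": f,
                         "p_value": p, "retained": retained}).set_index("accession")


@dataclass
class ClusterTree:
    """Agglomerative merge sequence over labelled profiles."""

    linkage_matrix: np.ndarray
    labels: list
    linkage: str = "ward"
    distance: str = "euclidean"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def top_split(self) -> tuple[set, set]:
        """The two main branches (membership below the final merge)."""
        n = len(self.labels)
        members = {i: {i} for i in range(n)}
        for j, (a, b, _, _) in enumerate(self.linkage_matrix):
            members[n + j] = members[int(a)] | members[int(b)]
        a, b = int(self.linkage_matrix[-1, 0]), int(self.linkage_matrix[-1, 1])
        return ({self.labels[i] for i in members[a]},
                {self.labels[i] for i in members[b]})

    def to_newick(self) -> str:
        n = len(self.labels)
        node = {i: self.labels[i] for i in range(n)}
        height = {i: 0.0 for i in range(n)}
        for j, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + j] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + j] = h
        return node[n + len(self.linkage_matrix) - 1] + ";"


def ward_cluster(data: pd.DataFrame, axis: str = "columns") -> ClusterTree:
    """Ward/Euclidean hierarchical clustering of condition profiles (columns,
    default) or proteins (rows). Ties in merge order are resolved by scipy's
    lowest-pair-index convention, fixed for reproducible leaf order."""
    X = data.T.to_numpy(dtype=float) if axis == "columns" else data.to_numpy(dtype=float)
    labels = list(data.columns) if axis == "columns" else list(data.index)
    if X.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    return ClusterTree(linkage_matrix=Z, labels=labels)


def write_comparison_tsv(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    records.to_csv(path, sep="\t", float_format="%.6g")
    return path


def plot_heatmap(data: pd.DataFrame, tree_rows: ClusterTree | None = None,
                 tree_cols: ClusterTree | None = None, path: str | Path = None):
    """Dendrogram-ordered heatmap of a retained-protein submatrix (log scale);
    written to ``path`` when given, otherwise the figure is returned."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ordered = data
    if tree_rows is not None:
        ordered = ordered.loc[tree_rows.leaf_order]
    if tree_cols is not None:
        ordered = ordered[tree_cols.leaf_order]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(np.log1p(ordered.to_numpy(dtype=float)), aspect="auto",
                   cmap="viridis")
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log(1 + aPSM)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return Path(path)
    return fig
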