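"""EV small-RNA cargo statistics from UMI-tagged read records.

Reads are filtered by the library QC rules (adapter present, insert >= 16 nt,
UMI >= 10 nt), collapsed to unique molecules by exact UMI identity per
species and sample, and analysed as a species x sample count matrix:

* RNA-class composition (percentage of unique molecules per class);
* top-N coverage (the fraction of miRNA molecules carried by the N most
  abundant species - the dominant-top-15 statistic);
* differential enrichment between sample groups via a seeded two-sided
  permutation test on group means of log2 RPM, with Benjamini-Hochberg
  correction;
* the stable core: species with the lowest coefficient of variation of RPM
  across donors and preconditioning, stratified by enrichment level, and
  its intersection across gestational stages.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MirnaCountMatrix",
    "qc_filter",
    "umi_collapse",
    "rna_composition",
    "top_n_coverage",
    "differential_enrichment",
    "stable_core",
    "read_reads_tsv",
    "plot_volcano",
]

_MIRNA_PREFIXES = ("miR", "let", "mir")


def species_class(name: str) -> str:
    """RNA class from a species label: miR-*/let-* are miRNA, otherwise the
    prefix before the first dash (rRNA-001 -> rRNA)."""
    if name.startswith(_MIRNA_PREFIXES):
        return "miRNA"
    return name.split("-", 1)[0]


@dataclass
class MirnaCountMatrix:
    """Unique-molecule counts per species (rows) and sample (columns)."""

    counts: pd.DataFrame
    samples: pd.DataFrame | None = None

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def rpm(self) -> pd.DataFrame:
        """Unique molecules per million, per sample (columns sum to 1e6)."""
        lib = self.library_sizes
        return self.counts.div(lib.where(lib > 0), axis=1) * 1e6

    @property
    def classes(self) -> pd.Series:
        return pd.Series({sp: species_class(sp) for sp in self.counts.index},
                         name="class")

    def subset_class(self, rna_class: str = "miRNA") -> "MirnaCountMatrix":
        keep = self.classes[self.classes == rna_class].index
        return replace(self, counts=self.counts.loc[keep])


def qc_filter(reads: pd.DataFrame, min_insert: int = 16, min_umi: int = 10
              ) -> tuple[pd.DataFrame, dict]:
    """Apply the library QC rules; returns kept reads and discard tallies.

    A read is kept iff the adapter was found, the insert is at least
    ``min_insert`` nt and the UMI at least ``min_umi`` nt. Discards are
    tallied by the first failing rule (no_adapter, short_insert, short_umi).
    """
    no_adapter = ~reads["adapter_found"].astype(bool)
    short_insert = ~no_adapter & (reads["insert"].str.len() < min_insert)
    short_umi = (~no_adapter & ~short_insert
                 & (reads["umi"].str.len() < min_umi))
    kept = reads[~(no_adapter | short_insert | short_umi)]
    discards = {"no_adapter": int(no_adapter.sum()),
                "short_insert": int(short_insert.sum()),
                "short_umi": int(short_umi.sum())}
    return kept, discards


def umi_collapse(pools: Mapping[str, pd.DataFrame],
                 samples: pd.DataFrame | None = None) -> MirnaCountMatrix:
    """Collapse reads to unique molecules: the count of a species in a
    sample is the number of distinct UMI strings among its reads."""
    cols = {}
    for sample, reads in pools.items():
        cols[sample] = (reads.groupby("assigned_species")["umi"]
                        .nunique())
    counts = pd.DataFrame(cols).fillna(0).astype(int).sort_index()
    counts = counts[list(pools)]
    return MirnaCountMatrix(counts=counts, samples=samples)


def rna_composition(matrix: MirnaCountMatrix) -> pd.DataFrame:
    """Percentage of unique molecules per RNA class and sample (columns sum
    to 100; an all-zero sample is reported as missing)."""
    by_class = matrix.counts.groupby(matrix.classes).sum()
    totals = by_class.sum(axis=0)
    empty = totals[totals == 0].index
    if len(empty):
        warnings.warn(f"all-zero sample(s): {list(empty)}; composition "
                      "undefined", stacklevel=2)
    return by_class.div(totals.where(totals > 0), axis=1) * 100.0


def top_n_coverage(counts: pd.Series | MirnaCountMatrix, n: int = 15
                   ) -> dict | pd.DataFrame:
    """Fraction of molecules carried by the ``n`` most abundant species.

    For a single sample (Series) returns ``{"coverage", "ranked"}``; for a
    matrix returns a DataFrame with per-sample coverage and the per-sample
    top-n ranked species list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(counts, MirnaCountMatrix):
        rows = []
        for sample in counts.counts.columns:
            res = top_n_coverage(counts.counts[sample], n=n)
            rows.append({"sample": sample, "coverage": res["coverage"],
                         "ranked": res["ranked"]})
        return pd.DataFrame(rows).set_index("sample")
    counts = counts[counts > 0]
    total = counts.sum()
    if len(counts) < n:
        warnings.warn(f"fewer species ({len(counts)}) than n={n}; "
                      "coverage is 1", stacklevel=2)
    ranked = counts.sort_values(ascending=False)
    top = ranked.head(n)
    coverage = float(top.sum() / total) if total > 0 else float("nan")
    return {"coverage": coverage, "ranked": list(top.index)}


def _perm_pvalues(a: np.ndarray, b: np.ndarray, n_perm: int, seed: int,
                  exact_limit: int = 20) -> np.ndarray:
    """Two-sided permutation p-values for the difference of group means,
    row-wise. Exact enumeration when the number of group assignments is at
    most ``exact_limit``, otherwise ``n_perm`` seeded random assignments."""
    na, nb = a.shape[1], b.shape[1]
    data = np.hstack([a, b])
    obs = np.abs(a.mean(axis=1) - b.mean(axis=1))
    idx_all = np.arange(na + nb)
    from math import comb
    eps = 1e-12
    if comb(na + nb, na) <= exact_limit:
        count = np.zeros(a.shape[0])
        total = 0
        for combo in itertools.combinations(idx_all, na):
            sel = np.zeros(na + nb, dtype=bool)
            sel[list(combo)] = True
            d = np.abs(data[:, sel].mean(axis=1) - data[:, ~sel].mean(axis=1))
            count += d >= obs - eps
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = np.ones(a.shape[0])          # the observed assignment
    for _ in range(n_perm):
        perm = rng.permutation(idx_all)
        d = np.abs(data[:, perm[:na]].mean(axis=1)
                   - data[:, perm[na:]].mean(axis=1))
        count += d >= obs - eps
    return count / (n_perm + 1)


def differential_enrichment(matrix: MirnaCountMatrix, group_a: Sequence[str],
                            group_b: Sequence[str], fdr: float = 0.05,
                            pseudocount: float = 0.5, n_perm: int = 10_000,
                            min_mean_count: float = 5.0, seed: int = 0
                            ) -> pd.DataFrame:
    """Per-species differential enrichment between two sample groups.

    log2FC compares group means of RPM (with a pseudocount); the p-value is
    a two-sided permutation test on the difference of group means of
    log2(RPM + pseudocount), exact when at most 20 assignments exist, else
    ``n_perm`` seeded permutations; q is Benjamini-Hochberg. Species below
    ``min_mean_count`` mean unique molecules across the contrast samples
    are excluded (permutation tests have no resolution there). The
    modulated set is {q <= fdr}.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per side of the contrast")
    sub = matrix.counts[group_a + group_b]
    keep = sub.mean(axis=1) >= min_mean_count
    sub = sub[keep]
    lib = matrix.counts[group_a + group_b].sum(axis=0)
    rpm = sub.div(lib, axis=1) * 1e6
    log_rpm = np.log2(rpm + pseudocount)
    a = log_rpm[group_a].to_numpy()
    b = log_rpm[group_b].to_numpy()
    log2fc = np.log2((rpm[group_a].mean(axis=1) + pseudocount)
                     / (rpm[group_b].mean(axis=1) + pseudocount))
    p = _perm_pvalues(a, b, n_perm=n_perm, seed=seed)
    const = (np.ptp(np.hstack([a, b]), axis=1) == 0)
    p = np.where(const, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    out = pd.DataFrame({"species": sub.index, "log2fc": log2fc.to_numpy(),
                        "p": p, "q": q})
    out["modulated"] = out["q"] <= fdr
    return out.set_index("species").sort_values("q")


def stable_core(matrix: MirnaCountMatrix, stage_col: str = "stage",
                n_strata: int = 3, stable_quantile: float = 0.25,
                min_mean_count: float = 1.0) -> dict:
    """Low-variability ("stable") species per gestational stage and their
    shared core.

    Per stage, the coefficient of variation of RPM is computed across all of
    that stage's samples (donors x preconditioning); species are stratified
    into ``n_strata`` enrichment levels (low / dim / high by default) by
    quantiles of mean log10 RPM, and a species is stable when its CV falls
    in the lowest ``stable_quantile`` of its stratum. Returns per-stage
    record tables and the cross-stage shared core.
    """
    if matrix.samples is None:
        raise ValueError("stable_core needs sample metadata on the matrix")
    strata_names = (["low", "dim", "high"] if n_strata == 3
                    else [f"s{i}" for i in range(n_strata)])
    records = {}
    stable_sets = []
    for stage, meta in matrix.samples.groupby(stage_col):
        ids = [s for s in meta["sample"] if s in matrix.counts.columns]
        if len(ids) < 3:
            raise ValueError(f"stage {stage!r} has < 3 samples")
        rpm_all = matrix.rpm[ids]
        mean_count = matrix.counts[ids].mean(axis=1)
        keep = (mean_count >= min_mean_count) & (rpm_all.mean(axis=1) > 0)
        rpm = rpm_all[keep]
        mean = rpm.mean(axis=1)
        cv = rpm.std(axis=1, ddof=1) / mean
        mean_log = np.log10(mean)
        stratum = pd.qcut(mean_log, n_strata, labels=strata_names,
                          duplicates="drop")
        stable_arr = np.zeros(len(rpm), dtype=bool)
        for s in stratum.cat.categories:
            in_s = (stratum == s).to_numpy()
            thr = cv[in_s].quantile(stable_quantile)
            stable_arr[in_s] = (cv[in_s] <= thr).to_numpy()
        stable = pd.Series(stable_arr, index=rpm.index)
        records[stage] = pd.DataFrame({
            "mean_rpm": mean, "mean_log_rpm": mean_log, "cv": cv,
            "stratum": stratum.astype(str), "stable": stable,
        }).rename_axis("species")
        stable_sets.append(set(rpm.index[stable]))
    shared = set.intersection(*stable_sets) if stable_sets else set()
    return {"records": records, "shared_core": shared}


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"insert": str, "umi": str},
                       keep_default_na=False)


def plot_volcano(results: pd.DataFrame, path: str | Path, fdr: float = 0.05):
    """Volcano plot (log2FC vs -log10 p) with modulated species highlighted."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    logp = -np.log10(results["p"].clip(lower=1e-300))
    mod = results["modulated"]
    ax.scatter(results.loc[~mod, "log2fc"], logp[~mod], s=6, c="grey",
               alpha=0.6, label="stable")
    ax.scatter(results.loc[mod, "log2fc"], logp[mod], s=10, c="crimson",
               label=f"q <= {fdr:g}")
    ax.set_xlabel("log2 fold change (RPM)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
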