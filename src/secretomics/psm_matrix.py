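"""Aligned, normalized, averaged spectral-count (aPSM) matrices.

Per-run PSM tables are aligned on the union of identified proteins, each
run is scaled so its total spectral count equals the mean total of the
comparison set, and per-condition aPSM values are the arithmetic mean of
the normalized counts over all runs of that condition. The per-condition
detection *frequency* (number of runs with PSM > 0) drives the overlap
("frequency of at least 2") analyses.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import PsmRunTable

__all__ = [
    "AbundanceMatrix",
    "align_runs",
    "normalize_runs",
    "average_apsm",
    "build_apsm_matrix",
    "frequency_filter",
    "venn_partition",
    "read_psm_runs",
    "write_matrix_tsv",
    "write_venn_json",
]

log = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Aligned run-level counts plus the condition-level aPSM view.

    ``runs``      accession x run_id matrix (zero-filled union of all runs)
    ``run_info``  run metadata indexed by run_id (condition, replicates)
    ``apsm``      accession x condition arithmetic means of the run values
    ``frequency`` accession x condition count of runs with PSM > 0
    """

    runs: pd.DataFrame
    run_info: pd.DataFrame
    apsm: pd.DataFrame
    frequency: pd.DataFrame
    normalized: bool = False
    scaling_factors: dict | None = None

    @property
    def accessions(self) -> list:
        return list(self.apsm.index)

    @property
    def conditions(self) -> list:
        return list(self.apsm.columns)

    def runs_of(self, condition: str) -> pd.DataFrame:
        ids = self.run_info.index[self.run_info["condition"] == condition]
        if len(ids) == 0:
            raise KeyError(f"unknown condition {condition!r}")
        return self.runs[ids]


def _condition_stats(runs_df: pd.DataFrame, run_info: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    conditions = list(dict.fromkeys(run_info["condition"]))
    apsm = {}
    freq = {}
    for cond in conditions:
        ids = run_info.index[run_info["condition"] == cond]
        block = runs_df[ids]
        apsm[cond] = block.mean(axis=1)
        freq[cond] = (block > 0).sum(axis=1).astype(int)
    return pd.DataFrame(apsm), pd.DataFrame(freq)


def align_runs(runs: Sequence[PsmRunTable]) -> AbundanceMatrix:
    """Align per-run protein lists on the union of identified accessions.

    Missing entries are filled with zero; per-condition frequency is the
    number of runs of that condition in which the protein was identified.
    """
    if not runs:
        raise ValueError("need at least one run")
    ids = [r.run_id for r in runs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate run_id(s): {dupes}")
    runs_df = pd.DataFrame({r.run_id: pd.Series(r.counts, dtype=float)
                            for r in runs}).fillna(0.0).sort_index()
    run_info = pd.DataFrame(
        [{"run_id": r.run_id, "condition": r.condition,
          "bio_replicate": r.bio_replicate, "tech_replicate": r.tech_replicate}
         for r in runs]).set_index("run_id")
    apsm, freq = _condition_stats(runs_df, run_info)
    return AbundanceMatrix(runs=runs_df, run_info=run_info, apsm=apsm,
                           frequency=freq, normalized=False)


def normalize_runs(runs: Sequence[PsmRunTable], method: str = "total"
                   ) -> tuple[list[PsmRunTable], dict]:
    """Scale each run so run totals are comparable across the set.

    ``total`` (default): scale each run's counts so its total equals the
    mean total over the comparison set. ``median_ratio``: scale by the
    median ratio of shared proteins to a reference (geometric-mean) profile.
    Returns the rescaled runs and the per-run scaling factors.
    """
    if not runs:
        raise ValueError("need at least one run")
    totals = {r.run_id: r.total for r in runs}
    if any(t <= 0 for t in totals.values()):
        empty = [rid for rid, t in totals.items() if t <= 0]
        raise ValueError(f"run(s) with zero total PSM: {empty}")
    if method == "total":
        target = float(np.mean(list(totals.values())))
        factors = {rid: target / t for rid, t in totals.items()}
    elif method == "median_ratio":
        mat = pd.DataFrame({r.run_id: pd.Series(r.counts, dtype=float)
                            for r in runs}).fillna(0.0)
        logref = np.log(mat.where(mat > 0)).mean(axis=1)
        factors = {}
        for rid in mat.columns:
            col = mat[rid]
            ok = (col > 0) & np.isfinite(logref)
            ratio = np.exp(np.median(np.log(col[ok]) - logref[ok]))
            factors[rid] = 1.0 / ratio
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    out = [replace(r, counts={a: c * factors[r.run_id]
                              for a, c in r.counts.items()})
           for r in runs]
    for rid, f in sorted(factors.items()):
        log.debug("normalize_runs: %s scaled by %.6g", rid, f)
    return out, factors


def average_apsm(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Recompute the condition-level aPSM view from the run-level values
    (arithmetic mean over all runs of each condition)."""
    apsm, freq = _condition_stats(matrix.runs, matrix.run_info)
    return replace(matrix, apsm=apsm, frequency=freq)


def build_apsm_matrix(runs: Sequence[PsmRunTable], normalize: bool = True,
                      method: str = "total") -> AbundanceMatrix:
    """Align -> normalize -> average, the standard aPSM construction."""
    if normalize:
        runs, factors = normalize_runs(runs, method=method)
    else:
        factors = {r.run_id: 1.0 for r in runs}
    matrix = align_runs(list(runs))
    matrix.normalized = normalize
    matrix.scaling_factors = factors
    return matrix


def frequency_filter(matrix: AbundanceMatrix, min_freq: int = 2,
                     collapse_bio: bool = False) -> dict:
    """Per-condition accession sets identified in at least ``min_freq`` runs.

    With ``collapse_bio=True`` the frequency counts biological replicates
    with at least one detection instead of individual runs.
    """
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    out = {}
    for cond in matrix.conditions:
        if collapse_bio:
            ids = matrix.run_info.index[matrix.run_info["condition"] == cond]
            bio = matrix.run_info.loc[ids, "bio_replicate"]
            freq = sum(
                ((matrix.runs[ids[bio == b]] > 0).any(axis=1)).astype(int)
                for b in bio.unique())
        else:
            freq = matrix.frequency[cond]
        out[cond] = set(freq.index[freq >= min_freq])
    return out


def venn_partition(sets: Mapping[str, set]) -> dict:
    """Region counts for 2-4 accession sets plus the all-way shared fraction.

    Region keys name the member sets of the region joined with ``&`` (the
    region contains elements in exactly those sets and no other).
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_partition takes 2 to 4 sets")
    union = set().union(*sets.values())
    regions = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo),
                                  set())
            regions["&".join(combo)] = len(inside - outside)
    core = set.intersection(*sets.values())
    return {
        "regions": regions,
        "union_size": len(union),
        "shared_fraction": (len(core) / len(union)) if union else 0.0,
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_psm_runs(manifest_csv: str | Path) -> list[PsmRunTable]:
    """Load runs from a manifest CSV (run_id, condition, bio_replicate,
    tech_replicate, path) pointing at per-run TSVs (accession, psm)."""
    manifest_csv = Path(manifest_csv)
    man = pd.read_csv(manifest_csv)
    runs = []
    for rec in man.itertuples(index=False):
        df = pd.read_csv(manifest_csv.parent / rec.path, sep="\t")
        runs.append(PsmRunTable(
            run_id=str(rec.run_id), condition=str(rec.condition),
            bio_replicate=int(rec.bio_replicate),
            tech_replicate=int(rec.tech_replicate),
            counts=dict(zip(df["accession"].astype(str), df["psm"]))))
    return runs


def write_matrix_tsv(matrix: AbundanceMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.apsm.rename_axis("accession").to_csv(path, sep="\t",
                                                float_format="%.6g")
    return path


def write_venn_json(venn: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(venn, fh, indent=1, sort_keys=True)
    return path
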