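"""Endpoint-assay calculators: cytokine spots, EV sizing, cell fractions.

Small, well-specified arithmetic behind the remaining quantifications:
background-subtracted cytokine-array spot intensities and between-sample
fold changes (with an "exclusive" class for analytes undetected in the
denominator sample), EV diameter histograms over fixed nm bins with
per-field summaries, nanoparticle-tracking concentration normalization to
particles per 1e6 secreting cells, and percent-positive cell fractions
(senescence, viability) with across-field mean +- sem.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "quantify_spots",
    "fold_change",
    "bin_sizes",
    "nta_normalize",
    "positive_fraction",
    "fields_summary",
]

DEFAULT_SIZE_BINS = np.arange(40.0, 280.0, 30.0)   # 40-250 nm in 30-nm bins


def quantify_spots(table: pd.DataFrame, detection_sds: float = 2.0
                   ) -> pd.DataFrame:
    """Per-analyte mean background-subtracted spot intensity per sample.

    ``table`` is tidy (sample, analyte, intensity, background[, replicate,
    spot]). The mean over replicate spots minus the mean background is
    floored at 0; an analyte is "detected" when its mean spot intensity
    exceeds background mean + ``detection_sds`` background SDs.
    """
    rows = []
    for (sample, analyte), grp in table.groupby(["sample", "analyte"]):
        spots = grp["intensity"].to_numpy(dtype=float)
        bg = grp["background"].to_numpy(dtype=float)
        bg_mean = bg.mean()
        bg_sd = bg.std(ddof=1) if bg.size > 1 else 0.0
        net = max(spots.mean() - bg_mean, 0.0)
        rows.append({"sample": sample, "analyte": analyte,
                     "intensity": net,
                     "detected": bool(spots.mean() > bg_mean
                                      + detection_sds * bg_sd)})
    return pd.DataFrame(rows).set_index(["sample", "analyte"])


def fold_change(a: Sequence[float], b: Sequence[float],
                detection_threshold: float = 0.0) -> dict:
    """Fold change of mean intensity A over B with a Welch t comparison.

    When the denominator sample is undetected (mean at or below
    ``detection_threshold``) the analyte is classed "exclusive" to A and no
    finite ratio is reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mean_a, mean_b = a.mean(), b.mean()
    if mean_b <= detection_threshold:
        return {"ratio": np.inf, "classification": "exclusive",
                "p_value": None}
    ratio = mean_a / mean_b
    if a.size >= 2 and b.size >= 2:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        p = None
    return {"ratio": float(ratio), "classification": "detected", "p_value": p}


def bin_sizes(fields: Sequence[np.ndarray],
              bin_edges: np.ndarray = DEFAULT_SIZE_BINS) -> dict:
    """EV diameter histogram per micrograph field plus pooled summaries.

    Diameters outside the configured bin range go to open underflow and
    overflow bins (flagged). Returns per-field bin counts, per-field means,
    and the pooled mean +- sem, median and range.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(fields) == 0:
        raise ValueError("need at least one field")
    labels = [f"[{bin_edges[i]:g},{bin_edges[i+1]:g})"
              for i in range(len(bin_edges) - 1)]
    counts = {}
    field_means = []
    pooled = []
    under = over = 0
    for i, diam in enumerate(fields):
        diam = np.asarray(diam, dtype=float)
        if diam.size == 0 or np.any(diam <= 0):
            raise ValueError(f"field {i}: diameters must be positive and "
                             "non-empty")
        hist, _ = np.histogram(diam, bins=bin_edges)
        counts[f"field{i + 1}"] = hist
        under += int((diam < bin_edges[0]).sum())
        over += int((diam >= bin_edges[-1]).sum())
        field_means.append(diam.mean())
        pooled.append(diam)
    pooled = np.concatenate(pooled)
    field_means = np.asarray(field_means)
    return {
        "bin_counts": pd.DataFrame(counts, index=labels),
        "underflow": under, "overflow": over,
        "out_of_range_flag": bool(under or over),
        "field_means": field_means,
        "pooled_mean": float(pooled.mean()),
        "pooled_sem": float(pooled.std(ddof=1) / np.sqrt(pooled.size)),
        "mean_of_field_means": float(field_means.mean()),
        "sem_of_field_means": float(field_means.std(ddof=1)
                                    / np.sqrt(field_means.size))
        if field_means.size > 1 else 0.0,
        "median": float(np.median(pooled)),
        "range": (float(pooled.min()), float(pooled.max())),
    }


def nta_normalize(raw_concentration_per_ml: float, dilution_factor: float,
                  volume_ml: float, cell_count: float) -> float:
    """Particles per 1e6 secreting cells from a diluted NTA reading:
    raw * dilution * volume / (cells / 1e6)."""
    if min(raw_concentration_per_ml, dilution_factor, volume_ml) <= 0:
        raise ValueError("concentration, dilution and volume must be positive")
    if cell_count <= 0:
        raise ValueError("cell_count must be positive")
    return (raw_concentration_per_ml * dilution_factor * volume_ml
            / (cell_count / 1e6))


def positive_fraction(positive: int, total: int) -> float:
    """Percentage of positive cells over total cells in a field."""
    if total <= 0:
        raise ValueError("total must be positive")
    if positive < 0 or positive > total:
        raise ValueError("positive must lie in [0, total]")
    return 100.0 * positive / total


def fields_summary(field_counts: Sequence[tuple]) -> dict:
    """Mean +- sem of per-field percent-positive values.

    ``field_counts`` is a sequence of (positive, total) pairs, one per field.
    """
    percents = np.array([positive_fraction(p, t) for p, t in field_counts])
    sem = (percents.std(ddof=1) / np.sqrt(percents.size)
           if percents.size > 1 else 0.0)
    return {"per_field_percent": percents, "mean": float(percents.mean()),
            "sem": float(sem)}
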