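"""Mitochondrial and glycolytic read-outs from raw assay traces.

Oxygen consumption and ATP-synthesis rates are ordinary-least-squares
slopes of the recorded traces (O2 concentration declining in a closed
chamber; luciferin/luciferase luminescence converted to ATP amount through
a linear calibration against standards). Oxidative-phosphorylation
efficiency is the P/O ratio - ATP molecules synthesized per oxygen *atom*
consumed, the convention under which fully coupled mitochondria give about
2.5 with NADH-linked substrates (pyruvate + malate) and about 1.5 with the
FADH2-linked succinate; molecular-O2 rates are converted by the factor 2.
Glucose consumption and lactate release come from A340 endpoint changes of
the NAD(P)H-coupled enzyme assays via Beer-Lambert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .synthetic_data import Trace, RespirationExperiment

__all__ = [
    "CalibrationCurve",
    "CalibrationError",
    "PoResult",
    "fit_rate",
    "calibrate_atp",
    "luminescence_to_atp_nmol",
    "compute_po",
    "analyze_respiration",
    "inhibition_fractions",
    "glycolysis_assays",
]


class CalibrationError(ValueError):
    """Standards unusable for a linear calibration."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float
    response_min: float
    response_max: float

    def invert(self, response: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map responses back to concentrations; the second array flags
        extrapolation beyond the standard response range."""
        response = np.asarray(response, dtype=float)
        conc = (response - self.intercept) / self.slope
        extrapolated = ((response < self.response_min)
                        | (response > self.response_max))
        return conc, extrapolated


@dataclass(frozen=True)
class PoResult:
    """ATP synthesized per oxygen atom consumed."""

    substrate: str
    atp_rate: float      # nmol ATP / min / 1e6 cells
    o_rate: float        # nmol O atoms / min / 1e6 cells
    po: float
    oxygen_unit: str = "O_atoms"


def fit_rate(trace: Trace, skip_s: float = 60.0, window: tuple | None = None,
             consumption: bool = False, per_cells: float = 1e6) -> dict:
    """OLS slope of a trace, per minute, normalized per ``per_cells`` cells.

    The default window drops the first 60 s (mixing/equilibration) and uses
    the rest; ``window=(t0, t1)`` in seconds overrides. ``consumption=True``
    flips the sign so that a declining signal gives a positive rate.
    """
    t = np.asarray(trace.time_s, dtype=float)
    v = np.asarray(trace.value, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
    else:
        mask = t >= skip_s
        if mask.sum() < 3:       # short trace: use it all
            mask = np.ones_like(t, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 points in the fit window")
    res = stats.linregress(t[mask] / 60.0, v[mask])
    slope = -res.slope if consumption else res.slope
    return {
        "rate": slope * per_cells / trace.cell_count,
        "slope_per_min": res.slope,
        "r_squared": float(res.rvalue ** 2),
        "n_points": int(mask.sum()),
        "per_cells": per_cells,
    }


def calibrate_atp(concentrations: np.ndarray, responses: np.ndarray
                  ) -> CalibrationCurve:
    """Linear calibration of luminescence against ATP standards."""
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size < 3:
        raise CalibrationError("need at least 3 standards")
    order = np.argsort(conc)
    if not (np.all(np.diff(resp[order]) > 0)
            or np.all(np.diff(resp[order]) < 0)):
        raise CalibrationError("standard responses are not monotone in "
                               "concentration")
    res = stats.linregress(conc, resp)
    return CalibrationCurve(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        conc_min=float(conc.min()), conc_max=float(conc.max()),
        response_min=float(resp.min()), response_max=float(resp.max()))


def luminescence_to_atp_nmol(lum_trace: Trace, curve: CalibrationCurve,
                             assay_dilution: float,
                             assay_volume_ml: float = 1.0) -> Trace:
    """Convert a luminescence trace to nmol ATP in the reaction.

    The calibration maps counts to molar ATP in the luminometer cuvette;
    the reaction was diluted ``assay_dilution``-fold into a cuvette of
    ``assay_volume_ml``, so nmol = M * volume[L] * 1e9 * dilution.
    """
    conc, extrapolated = curve.invert(lum_trace.value)
    nmol = conc * assay_dilution * (assay_volume_ml * 1e-3) * 1e9
    out = Trace(lum_trace.time_s, nmol, label=lum_trace.label + " (nmol ATP)",
                cell_count=lum_trace.cell_count)
    if extrapolated.any():
        import warnings
        warnings.warn(f"{int(extrapolated.sum())} point(s) outside the "
                      "calibration range (extrapolated)", stacklevel=2)
    return out


def compute_po(atp_rate: float, o2_rate: float,
               oxygen_unit: str = "O2", substrate: str = "") -> PoResult:
    """P/O ratio from an ATP-synthesis rate and an oxygen-consumption rate.

    ``oxygen_unit="O2"`` (molecular oxygen) is converted to O atoms by the
    factor 2; pass ``"O_atoms"`` for a rate already in atoms.
    """
    if atp_rate < 0 or o2_rate < 0:
        raise ValueError("rates must be non-negative")
    if o2_rate == 0:
        raise ValueError("P/O undefined at zero oxygen-consumption rate")
    if oxygen_unit == "O2":
        o_rate = 2.0 * o2_rate
    elif oxygen_unit == "O_atoms":
        o_rate = o2_rate
    else:
        raise ValueError("oxygen_unit must be 'O2' or 'O_atoms'")
    return PoResult(substrate=substrate, atp_rate=atp_rate, o_rate=o_rate,
                    po=atp_rate / o_rate)


def analyze_respiration(exp: RespirationExperiment, skip_s: float = 60.0
                        ) -> dict:
    """Full P/O analysis of a respiration experiment.

    Fits the O2-consumption and calibrated ATP-synthesis rate per replicate
    (nmol/min per 1e6 cells), computes per-replicate P/O (per O atom) and
    the replicate mean +- sd.
    """
    curve = calibrate_atp(exp.standard_conc_m, exp.standard_response)
    results = []
    for o2_tr, lum_tr in zip(exp.o2_traces, exp.lum_traces):
        o2 = fit_rate(o2_tr, skip_s=skip_s, consumption=True)
        atp_tr = luminescence_to_atp_nmol(lum_tr, curve, exp.assay_dilution)
        atp = fit_rate(atp_tr, skip_s=skip_s)
        o2_rate = o2["rate"] * exp.chamber_volume_ml   # nmol O2/min/1e6 cells
        results.append(compute_po(atp["rate"], o2_rate, oxygen_unit="O2",
                                  substrate=exp.substrate))
    po_values = np.array([r.po for r in results])
    return {
        "substrate": exp.substrate,
        "calibration": curve,
        "replicates": results,
        "po_mean": float(po_values.mean()),
        "po_sd": float(po_values.std(ddof=1)) if po_values.size > 1 else 0.0,
        "atp_rate_mean": float(np.mean([r.atp_rate for r in results])),
        "o2_rate_mean": float(np.mean([r.o_rate for r in results]) / 2.0),
    }


def inhibition_fractions(rates: Mapping[str, float], baseline: str | float
                         ) -> dict:
    """Percent inhibition of each condition relative to baseline.

    ``inhibition% = 100 (baseline - inhibited) / baseline``, clamped at 0
    when the inhibited rate exceeds baseline (the raw value is retained).
    ``baseline`` may be a key into ``rates`` or a number.
    """
    if isinstance(baseline, str):
        if baseline not in rates:
            raise ValueError(f"missing baseline condition {baseline!r}")
        base = float(rates[baseline])
        items = {k: v for k, v in rates.items() if k != baseline}
    else:
        base = float(baseline)
        items = dict(rates)
    if base <= 0:
        raise ValueError("baseline rate must be positive")
    out = {}
    for name, rate in items.items():
        raw = 100.0 * (base - rate) / base
        out[name] = {"percent": max(raw, 0.0), "raw_percent": raw}
    return out


def glycolysis_assays(delta_a340_glucose: float, delta_a340_lactate: float,
                      cell_count: float, sample_fraction: float = 0.1,
                      epsilon_mm_cm: float = 6.22, path_cm: float = 1.0
                      ) -> dict:
    """Glucose consumed and lactate released (mM per 1e6 cells) from A340
    endpoint changes of the NAD(P)H-coupled assays, plus the glycolytic
    yield (lactate / glucose; 2 for fully fermentative metabolism).

    ``sample_fraction`` is the dilution of the medium into the cuvette;
    Beer-Lambert with the NAD(P)H extinction coefficient (default
    6.22 mM^-1 cm^-1) converts absorbance to cuvette concentration.
    A negative computed consumption is flagged, not clamped.
    """
    if cell_count <= 0:
        raise ValueError("cell_count must be positive")
    factor = 1.0 / (epsilon_mm_cm * path_cm * sample_fraction)
    per_million = 1e6 / cell_count
    glucose = delta_a340_glucose * factor * per_million
    lactate = delta_a340_lactate * factor * per_million
    return {
        "glucose_consumed_mm_per_1e6": glucose,
        "lactate_released_mm_per_1e6": lactate,
        "yield_lactate_per_glucose": (lactate / glucose) if glucose != 0
        else float("nan"),
        "negative_consumption_flag": glucose < 0 or lactate < 0,
    }
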