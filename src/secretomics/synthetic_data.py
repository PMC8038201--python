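"""Synthetic ground-truth data for every stage of the secretome pipeline.

The generators emulate the three data streams of a fetal vs perinatal
amniotic-fluid stem-cell (hAFS) secretome study:

* spectral-count proteomics — 8 conditions ({fetal, perinatal} x {CM, EV} x
  {normoxia, hypoxia}), 3 biological replicates in technical duplicate,
  i.e. 48 per-run PSM tables, with a configurable fraction of proteins
  spiked at a known fold change;
* UMI-tagged small-RNA sequencing of EV cargo — read pools with a dominant
  top-15 miRNA fraction, a planted low-variability core, condition-modulated
  species, duplicated UMIs and planted QC violations;
* respirometry / luminometry traces for oxygen consumption and ATP
  synthesis with a known ATP:O stoichiometry, plus endpoint assays.

Every generator takes a frozen design dataclass carrying one integer seed;
all randomness flows through a single ``numpy.random.Generator`` derived
from it, so identical designs give byte-identical outputs. Each generator
returns a :class:`SyntheticTruth` describing exactly what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "ProteomeDesign",
    "MirnaDesign",
    "RespirationDesign",
    "SyntheticTruth",
    "PsmRunTable",
    "Trace",
    "RespirationExperiment",
    "STAGES",
    "COMPARTMENTS",
    "OXYGEN",
    "condition_label",
    "generate_psm_runs",
    "generate_mirna_reads",
    "generate_respiration",
    "generate_glycolysis",
    "generate_annotation",
    "generate_spot_tables",
    "generate_ev_diameters",
    "write_psm_runs",
    "write_reads_tsv",
    "write_reads_fastq",
    "write_trace_csv",
    "write_truth_json",
]


class DesignError(ValueError):
    """Invalid field in a synthetic-data design."""


STAGES = ("f", "p")            # fetal (II trimester) / perinatal (III trimester)
COMPARTMENTS = ("CM", "EV")    # conditioned medium / extracellular vesicles
OXYGEN = ("normo", "hypo")     # normoxia / hypoxic preconditioning


def condition_label(stage: str, compartment: str, oxygen: str) -> str:
    """Canonical condition label, e.g. ``f-CM-hypo``."""
    return f"{stage}-{compartment}-{oxygen}"


ALL_CONDITIONS = tuple(
    condition_label(s, c, o) for c in COMPARTMENTS for s in STAGES for o in OXYGEN
)


@dataclass
class SyntheticTruth:
    """Ground-truth labels attached to a generated dataset."""

    differential_proteins: dict = field(default_factory=dict)
    stable_mirnas: tuple = ()
    modulated_mirnas: dict = field(default_factory=dict)
    unique_molecules: dict = field(default_factory=dict)
    true_po: float | None = None
    true_inhibition_fractions: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Proteomics: per-run PSM tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsmRunTable:
    """One LC-MS/MS run: spectral counts per identified protein."""

    run_id: str
    condition: str
    bio_replicate: int
    tech_replicate: int
    counts: dict

    def __post_init__(self):
        if len(set(self.counts)) != len(self.counts):
            raise ValueError(f"duplicate accessions in run {self.run_id}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError(f"negative PSM count in run {self.run_id}")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass(frozen=True)
class ProteomeDesign:
    """Design of the synthetic spectral-count experiment.

    ``baseline_mean`` is the mean PSM count of a detected protein; per-protein
    baselines are spread log-normally (``abundance_sigma``) around it, so the
    default 1000 proteins x mean 20 gives roughly 20,000 PSMs per run.
    ``spike_fraction`` of proteins carry a true ``spike_fold`` change between
    gestational stages in one (compartment, oxygen) cell.
    """

    n_proteins: int = 1000
    conditions: tuple = ALL_CONDITIONS
    n_bio_replicates: int = 3
    n_tech_replicates: int = 2
    baseline_mean: float = 20.0
    abundance_sigma: float = 0.5
    detection_prob: float = 0.98
    abundance_linked_dropout: bool = False
    dispersion: float = 0.02
    spike_fraction: float = 0.10
    spike_fold: float = 2.0
    compartment_sigma: float = 0.4
    compartment_shift: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise DesignError("n_proteins must be >= 1")
        if len(self.conditions) < 2:
            raise DesignError("need at least two conditions")
        if self.n_bio_replicates < 1 or self.n_tech_replicates < 1:
            raise DesignError("replicate counts must be >= 1")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise DesignError("spike_fraction must lie in [0, 1]")
        if self.spike_fold <= 0:
            raise DesignError("spike_fold must be positive")
        if not 0.0 < self.detection_prob <= 1.0:
            raise DesignError("detection_prob must lie in (0, 1]")
        if self.dispersion < 0:
            raise DesignError("dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise DesignError("baseline_mean must be positive")


def _nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0.0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_psm_runs(design: ProteomeDesign) -> tuple[list[PsmRunTable], SyntheticTruth]:
    """Generate one PSM table per (condition, bio replicate, tech replicate).

    Counts are negative-binomial around per-condition protein means; spiked
    proteins have their mean multiplied by ``spike_fold`` in the favoured
    gestational stage of their assigned (compartment, oxygen) cell; Bernoulli
    detection dropout is applied per protein-run.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_proteins
    accessions = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    # per-protein baseline means, log-normal with the design mean preserved
    sig = design.abundance_sigma
    base = design.baseline_mean * rng.lognormal(-0.5 * sig**2, sig, size=n)

    # spike assignment: each spiked protein is up in one gestational stage of
    # one (compartment, oxygen) cell, mirroring the fetal-vs-perinatal contrasts
    n_spike = int(round(design.spike_fraction * n))
    spike_idx = rng.choice(n, size=n_spike, replace=False) if n_spike else np.array([], int)
    cells = [(c, o) for c in COMPARTMENTS for o in OXYGEN
             if any(condition_label(s, c, o) in design.conditions for s in STAGES)]
    # systematic CM-vs-EV profile difference: per-protein log-normal factor
    # (EVs run higher on average), shared by all EV conditions so that
    # within-compartment contrasts are unaffected
    ev_factor = rng.lognormal(design.compartment_shift, design.compartment_sigma,
                              size=n)
    truth = SyntheticTruth()
    cond_means = {
        cond: base * ev_factor if "-EV-" in cond else base.copy()
        for cond in design.conditions
    }
    for j, i in enumerate(spike_idx):
        comp, oxy = cells[int(rng.integers(len(cells)))]
        up_stage = STAGES[int(rng.integers(2))]
        down_stage = STAGES[1 - STAGES.index(up_stage)]
        up = condition_label(up_stage, comp, oxy)
        down = condition_label(down_stage, comp, oxy)
        if up in cond_means:
            cond_means[up][i] *= design.spike_fold
        truth.differential_proteins[str(accessions[i])] = {
            "condition_up": up,
            "condition_down": down,
            "fold": design.spike_fold,
        }

    runs: list[PsmRunTable] = []
    for cond in design.conditions:
        means = cond_means[cond]
        if design.abundance_linked_dropout:
            # calibrated so a protein at baseline_mean is detected at detection_prob
            lam = -np.log1p(-design.detection_prob)
            p_det = 1.0 - np.exp(-lam * means / design.baseline_mean)
        else:
            p_det = np.full(n, design.detection_prob)
        for b in range(1, design.n_bio_replicates + 1):
            for t in range(1, design.n_tech_replicates + 1):
                counts = _nbinom(rng, means, design.dispersion)
                detected = rng.random(n) < p_det
                counts = np.where(detected, counts, 0)
                nz = counts > 0
                runs.append(PsmRunTable(
                    run_id=f"{cond}__b{b}t{t}",
                    condition=cond,
                    bio_replicate=b,
                    tech_replicate=t,
                    counts=dict(zip(accessions[nz].tolist(),
                                    counts[nz].astype(int).tolist())),
                ))
    truth.extras["baseline_means"] = dict(zip(accessions.tolist(), base.tolist()))
    return runs, truth


# ---------------------------------------------------------------------------
# Small RNA: UMI-tagged read pools
# ---------------------------------------------------------------------------

_CLASS_FRACTIONS = {"miRNA": 0.355, "rRNA": 0.36, "tRNA": 0.10, "other": 0.185}


@dataclass(frozen=True)
class MirnaDesign:
    """Design of the synthetic EV small-RNA read pools.

    12 samples by default: 2 gestational stages x 2 preconditioning states x
    3 donors. The ``top_k`` most abundant miRNA species jointly carry
    ``top_mass_fraction`` of miRNA molecules (the dominant-top-15 structure);
    ``n_core`` species just below them are generated with pure sampling noise
    (the low-variability core); ``n_modulated`` mid-abundance species differ
    ``modulated_fold``-fold between gestational stages.
    """

    n_species: int = 1000
    top_k: int = 15
    top_mass_fraction: float = 0.64
    n_core: int = 8
    n_modulated: int = 24
    modulated_fold: float = 4.0
    n_donors: int = 3
    reads_per_sample: int = 50_000
    umi_duplication_rate: float = 1.5
    umi_length: int = 12
    adapter: str = "AGATCGGAAGAGC"
    insert_length: tuple = (18, 24)
    frac_no_adapter: float = 0.05
    frac_short_insert: float = 0.03
    frac_short_umi: float = 0.02
    noise_sigma: float = 0.10
    class_fractions: tuple = tuple(_CLASS_FRACTIONS.items())
    seed: int = 0

    def validate(self) -> None:
        if not self.adapter:
            raise DesignError("adapter must be non-empty")
        if not 0.0 < self.top_mass_fraction < 1.0:
            raise DesignError("top_mass_fraction must lie in (0, 1)")
        if self.top_k > self.n_species:
            raise DesignError("top_k cannot exceed n_species")
        if self.umi_duplication_rate < 1.0:
            raise DesignError("umi_duplication_rate must be >= 1")
        if self.top_k + self.n_core + self.n_modulated > self.n_species:
            raise DesignError("top_k + n_core + n_modulated exceed n_species")
        total_viol = self.frac_no_adapter + self.frac_short_insert + self.frac_short_umi
        if total_viol >= 1.0:
            raise DesignError("planted QC-violation fractions must sum below 1")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return b"".join(_BASES[rng.integers(0, 4, size=length)]).decode()


def _distinct_umis(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """``n`` distinct fixed-length UMI strings (distinct within the batch)."""
    space = 4 ** length
    codes = np.array([], dtype=np.int64)
    while codes.size < n:
        extra = rng.integers(0, space, size=2 * (n - codes.size) + 16)
        codes = np.unique(np.concatenate([codes, extra]))
    codes = rng.permutation(codes)[:n]
    # decode base-4 digits to ACGT
    digits = np.empty((n, length), dtype=np.int64)
    c = codes.copy()
    for pos in range(length - 1, -1, -1):
        digits[:, pos] = c % 4
        c //= 4
    chars = _BASES[digits]
    return chars.view(f"S{length}").ravel().astype(str)


def _mirna_weights(design: MirnaDesign, rng: np.random.Generator) -> np.ndarray:
    """Baseline miRNA abundance weights: geometric top block + Zipf tail."""
    k, n = design.top_k, design.n_species
    top = 0.75 ** np.arange(k)
    top = top / top.sum() * design.top_mass_fraction
    tail = 1.0 / (np.arange(1, n - k + 1) + 10.0) ** 0.9
    tail = tail / tail.sum() * (1.0 - design.top_mass_fraction)
    return np.concatenate([top, tail])


def generate_mirna_reads(design: MirnaDesign) -> tuple[dict, pd.DataFrame, SyntheticTruth]:
    """Generate UMI-tagged small-RNA read pools for all samples.

    Returns ``(pools, samples, truth)`` where ``pools`` maps sample id to a
    DataFrame of read records (read_id, insert, umi, adapter_found,
    assigned_species), ``samples`` is the sample metadata table (stage,
    preconditioning, donor) and ``truth`` records the planted core and
    modulated species plus the expected post-filter unique-molecule counts.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    species = np.array([f"miR-{i:04d}" for i in range(1, design.n_species + 1)])
    core = tuple(species[design.top_k:design.top_k + design.n_core])
    mod_idx = np.arange(design.top_k + design.n_core,
                        design.top_k + design.n_core + design.n_modulated)
    base_w = _mirna_weights(design, rng)

    modulated: dict[str, dict] = {}
    for j, i in enumerate(mod_idx):
        up_stage = STAGES[j % 2]
        modulated[str(species[i])] = {
            "contrast": "stage",
            "up_in": up_stage,
            "fold": design.modulated_fold,
        }

    # fixed per-species insert sequences (a species is one mature sequence)
    ins_len = rng.integers(design.insert_length[0], design.insert_length[1] + 1,
                           size=design.n_species)
    inserts = np.array([_random_seq(rng, int(l)) for l in ins_len])

    class_names, class_fracs = zip(*design.class_fractions)
    class_fracs = np.asarray(class_fracs, float)
    class_fracs = class_fracs / class_fracs.sum()
    other_species = {
        cls: np.array([f"{cls}-{i:03d}" for i in range(1, 21)]) for cls in class_names
        if cls != "miRNA"
    }
    other_inserts = {
        cls: np.array([_random_seq(rng, 22) for _ in arr])
        for cls, arr in other_species.items()
    }

    samples = pd.DataFrame([
        {"sample": f"{s}-EV-{o}-d{d}", "stage": s, "preconditioning": o, "donor": d}
        for s in STAGES for o in OXYGEN for d in range(1, design.n_donors + 1)
    ])

    n_unique_total = int(round(design.reads_per_sample / design.umi_duplication_rate))
    core_mask = np.isin(species, core)
    pools: dict[str, pd.DataFrame] = {}
    truth = SyntheticTruth(stable_mirnas=core, modulated_mirnas=modulated)
    truth.extras["species_order"] = species.tolist()

    for _, row in samples.iterrows():
        w = base_w.copy()
        for sp, info in modulated.items():
            i = int(np.where(species == sp)[0][0])
            if row["stage"] != info["up_in"]:
                w[i] /= info["fold"]
        jitter = np.exp(rng.normal(0.0, design.noise_sigma, size=design.n_species))
        jitter[core_mask] = 1.0   # core species: sampling noise only
        w = w * jitter
        w /= w.sum()

        class_counts = rng.multinomial(n_unique_total, class_fracs)
        per_class_frames = []
        mol_species: list[np.ndarray] = []
        for cls, cnt in zip(class_names, class_counts):
            if cnt == 0:
                continue
            if cls == "miRNA":
                sp_counts = rng.multinomial(cnt, w)
                mol_species.append(np.repeat(species, sp_counts))
                per_class_frames.append(np.repeat(inserts, sp_counts))
            else:
                sub = rng.multinomial(cnt, np.full(len(other_species[cls]),
                                                   1.0 / len(other_species[cls])))
                mol_species.append(np.repeat(other_species[cls], sub))
                per_class_frames.append(np.repeat(other_inserts[cls], sub))
        mol_sp = np.concatenate(mol_species)
        mol_ins = np.concatenate(per_class_frames)
        n_mol = mol_sp.size
        umis = _distinct_umis(rng, n_mol, design.umi_length)

        # PCR duplication: geometric multiplicity with mean umi_duplication_rate
        if design.umi_duplication_rate == 1.0:
            mult = np.ones(n_mol, dtype=int)
        else:
            mult = rng.geometric(1.0 / design.umi_duplication_rate, size=n_mol)
        r_sp = np.repeat(mol_sp, mult)
        r_ins = np.repeat(mol_ins, mult)
        r_umi = np.repeat(umis, mult)
        mol_id = np.repeat(np.arange(n_mol), mult)
        n_reads = r_sp.size

        # planted QC violations, assigned per read
        viol = rng.choice(
            4, size=n_reads,
            p=[1.0 - design.frac_no_adapter - design.frac_short_insert
               - design.frac_short_umi,
               design.frac_no_adapter, design.frac_short_insert,
               design.frac_short_umi])
        adapter_found = viol != 1
        short_ins = np.where(viol == 2)[0]
        short_umi = np.where(viol == 3)[0]
        r_ins = r_ins.astype(object)
        r_umi = r_umi.astype(object)
        for i in short_ins:
            r_ins[i] = r_ins[i][: int(rng.integers(8, 16))]
        for i in short_umi:
            r_umi[i] = r_umi[i][: int(rng.integers(6, 10))]

        pool = pd.DataFrame({
            "read_id": [f"{row['sample']}:r{i:07d}" for i in range(n_reads)],
            "insert": r_ins.astype(str),
            "umi": r_umi.astype(str),
            "adapter_found": adapter_found,
            "assigned_species": r_sp,
        })
        pools[row["sample"]] = pool

        # expected post-filter unique molecules: a molecule survives iff at
        # least one of its reads passes all QC rules
        ok = viol == 0
        surv = np.zeros(n_mol, dtype=bool)
        np.logical_or.at(surv, mol_id, ok)
        surv_sp = pd.Series(mol_sp[surv]).value_counts()
        truth.unique_molecules[row["sample"]] = {str(k): int(v)
                                                 for k, v in surv_sp.items()}

    return pools, samples, truth


# ---------------------------------------------------------------------------
# Bioenergetics: respiration and ATP-synthesis traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trace:
    """A timed assay recording (O2 concentration, luminescence, absorbance)."""

    time_s: np.ndarray
    value: np.ndarray
    label: str = ""
    cell_count: int = 100_000

    def __post_init__(self):
        t = np.asarray(self.time_s, float)
        if t.size < 3:
            raise ValueError("a trace needs at least 3 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("trace times must be strictly increasing")


@dataclass
class RespirationExperiment:
    """Paired O2 / luminescence replicate traces with calibration standards."""

    substrate: str
    o2_traces: list
    lum_traces: list
    standard_conc_m: np.ndarray
    standard_response: np.ndarray
    cell_count: int
    chamber_volume_ml: float
    assay_dilution: float
    inhibited_o2_traces: dict = field(default_factory=dict)
    inhibited_lum_traces: dict = field(default_factory=dict)


_PRESET_ATP_PER_O = {"pm_coupled": 2.5, "succ_coupled": 1.5, "uncoupled": 0.4}
_PRESET_SUBSTRATE = {"pm_coupled": "pyruvate+malate", "succ_coupled": "succinate",
                     "uncoupled": "pyruvate+malate+FCCP"}


@dataclass(frozen=True)
class RespirationDesign:
    """Design of a synthetic coupled/uncoupled respiration experiment.

    ``true_atp_per_o`` defaults to the preset stoichiometry: 2.5 ATP per O
    atom for the NADH-linked substrate (pyruvate + malate), 1.5 for the
    FADH2-linked one (succinate), 0.4 for the uncoupled control. ``o2_rate``
    is in nmol O2/min per 1e5 cells; traces are sampled every ``dt_s``.
    """

    substrate_preset: str = "pm_coupled"
    true_atp_per_o: float | None = None
    o2_rate: float = 1.0
    noise_cv: float = 0.02
    n_timepoints: int = 9
    dt_s: float = 30.0
    n_replicates: int = 4
    cell_count: int = 100_000
    chamber_volume_ml: float = 1.0
    o2_start: float = 200.0
    lum_per_molar: float = 1.0e12
    assay_dilution: float = 200.0
    n_standards: int = 7
    standard_range_m: tuple = (1e-10, 1e-7)
    inhibitors: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if self.substrate_preset not in _PRESET_ATP_PER_O:
            raise DesignError(f"unknown substrate preset {self.substrate_preset!r}")
        if self.o2_rate <= 0:
            raise DesignError("o2_rate must be positive")
        if self.noise_cv < 0:
            raise DesignError("noise_cv must be >= 0")
        if self.n_timepoints < 3:
            raise DesignError("n_timepoints must be >= 3")
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")

    @property
    def atp_per_o(self) -> float:
        if self.true_atp_per_o is not None:
            return self.true_atp_per_o
        return _PRESET_ATP_PER_O[self.substrate_preset]


def _noisy(rng: np.random.Generator, clean: np.ndarray, noise_cv: float) -> np.ndarray:
    """Additive Gaussian noise scaled to the dynamic range of the clean trace."""
    span = float(np.ptp(clean))
    if noise_cv == 0.0 or span == 0.0:
        return clean.copy()
    return clean + rng.normal(0.0, noise_cv * span, size=clean.shape)


def generate_respiration(design: RespirationDesign
                         ) -> tuple[RespirationExperiment, SyntheticTruth]:
    """Generate paired O2-decline and ATP-luminescence traces.

    The O2 trace declines linearly at ``o2_rate`` (nmol O2/min per 1e5 cells);
    the ATP amount grows at ``atp_per_o * 2 * o2_rate`` (two O atoms per O2)
    and is reported as luminescence through a linear calibration whose
    standards span the stated 1e-10 to 1e-7 M range.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    t_s = np.arange(design.n_timepoints) * design.dt_s
    t_min = t_s / 60.0
    atp_per_o = design.atp_per_o
    atp_rate = atp_per_o * 2.0 * design.o2_rate          # nmol ATP/min per 1e5 cells

    conc = np.geomspace(*design.standard_range_m, design.n_standards)
    resp_clean = design.lum_per_molar * conc
    responses = resp_clean * (1.0 + rng.normal(0.0, design.noise_cv, conc.size))

    o2_clean = design.o2_start - design.o2_rate * t_min / design.chamber_volume_ml
    atp_nmol = atp_rate * t_min
    conc_m = atp_nmol * 1e-6 / design.assay_dilution     # diluted into the luminometer
    lum_clean = design.lum_per_molar * conc_m

    o2_traces, lum_traces = [], []
    for r in range(design.n_replicates):
        o2_traces.append(Trace(t_s, _noisy(rng, o2_clean, design.noise_cv),
                               label=f"O2 rep{r + 1}", cell_count=design.cell_count))
        lum_traces.append(Trace(t_s, _noisy(rng, lum_clean, design.noise_cv),
                                label=f"lum rep{r + 1}", cell_count=design.cell_count))

    exp = RespirationExperiment(
        substrate=_PRESET_SUBSTRATE[design.substrate_preset],
        o2_traces=o2_traces, lum_traces=lum_traces,
        standard_conc_m=conc, standard_response=responses,
        cell_count=design.cell_count,
        chamber_volume_ml=design.chamber_volume_ml,
        assay_dilution=design.assay_dilution,
    )
    truth = SyntheticTruth(true_po=atp_per_o)
    truth.extras["o2_rate"] = design.o2_rate
    truth.extras["atp_rate"] = atp_rate

    for name, frac in design.inhibitors:
        truth.true_inhibition_fractions[name] = frac
        o2_i = design.o2_start - design.o2_rate * (1 - frac) * t_min
        lum_i = design.lum_per_molar * (atp_rate * (1 - frac) * t_min
                                        * 1e-6 / design.assay_dilution)
        exp.inhibited_o2_traces[name] = [
            Trace(t_s, _noisy(rng, o2_i, design.noise_cv), label=f"O2 {name} rep{r+1}",
                  cell_count=design.cell_count) for r in range(design.n_replicates)]
        exp.inhibited_lum_traces[name] = [
            Trace(t_s, _noisy(rng, lum_i, design.noise_cv), label=f"lum {name} rep{r+1}",
                  cell_count=design.cell_count) for r in range(design.n_replicates)]
    return exp, truth


def generate_glycolysis(glucose_consumed_mm: float = 2.0,
                        lactate_per_glucose: float = 2.0,
                        cell_count: int = 1_000_000,
                        sample_fraction: float = 0.1,
                        epsilon_mm_cm: float = 6.22,
                        path_cm: float = 1.0,
                        noise_cv: float = 0.0,
                        seed: int = 0) -> tuple[dict, SyntheticTruth]:
    """Endpoint A340 pairs for the glucose/lactate coupled-enzyme assays.

    A fully fermentative sample has ``lactate_per_glucose`` = 2 (glycolytic
    stoichiometry). ``sample_fraction`` is the medium dilution into the cuvette.
    """
    rng = np.random.default_rng(seed)
    lactate_mm = glucose_consumed_mm * lactate_per_glucose
    da_glc = glucose_consumed_mm * sample_fraction * epsilon_mm_cm * path_cm
    da_lac = lactate_mm * sample_fraction * epsilon_mm_cm * path_cm
    if noise_cv:
        da_glc *= 1.0 + rng.normal(0.0, noise_cv)
        da_lac *= 1.0 + rng.normal(0.0, noise_cv)
    data = {
        "delta_a340_glucose": da_glc,
        "delta_a340_lactate": da_lac,
        "sample_fraction": sample_fraction,
        "cell_count": cell_count,
    }
    truth = SyntheticTruth()
    truth.extras.update(glucose_consumed_mm=glucose_consumed_mm,
                        lactate_released_mm=lactate_mm,
                        yield_lactate_per_glucose=lactate_per_glucose)
    return data, truth


# ---------------------------------------------------------------------------
# Annotation / assay fixtures
# ---------------------------------------------------------------------------

def generate_annotation(universe: Sequence[str], n_terms: int = 20,
                        term_size: tuple = (10, 60), planted_term: str | None = None,
                        planted_members: Sequence[str] | None = None,
                        seed: int = 0) -> dict:
    """Random GMT-like annotation over ``universe``, optionally with one
    planted term whose members are supplied by the caller (e.g. oversampled
    into a query to create a truly enriched category)."""
    rng = np.random.default_rng(seed)
    uni = np.asarray(list(universe))
    terms = {}
    for i in range(n_terms):
        k = int(rng.integers(term_size[0], term_size[1] + 1))
        k = min(k, uni.size)
        members = rng.choice(uni, size=k, replace=False)
        terms[f"TERM:{i:04d}"] = {"label": f"process {i}",
                                  "members": set(members.tolist())}
    if planted_term is not None:
        terms[planted_term] = {"label": "planted process",
                               "members": set(planted_members or [])}
    return terms


def generate_spot_tables(analytes: Sequence[str] = ("IGFBP2", "OPN", "PAI-1", "MIF"),
                         folds: Mapping[str, float] | None = None,
                         base_intensity: float = 100.0, n_spots: int = 2,
                         n_replicates: int = 3, background: float = 10.0,
                         noise_cv: float = 0.05, seed: int = 0
                         ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Two-group cytokine-array spot intensities with known fold changes.

    Returns a tidy table (sample, replicate, analyte, spot, intensity,
    background); group ``A`` carries ``folds[analyte]`` times the group ``B``
    intensity (default 1.0 for analytes not listed).
    """
    rng = np.random.default_rng(seed)
    folds = dict(folds or {})
    rows = []
    for grp in ("A", "B"):
        for rep in range(1, n_replicates + 1):
            for analyte in analytes:
                f = folds.get(analyte, 1.0) if grp == "A" else 1.0
                mean = base_intensity * f
                for spot in range(1, n_spots + 1):
                    val = mean * (1.0 + rng.normal(0.0, noise_cv))
                    bg = background * (1.0 + rng.normal(0.0, noise_cv))
                    rows.append({"sample": grp, "replicate": rep,
                                 "analyte": analyte, "spot": spot,
                                 "intensity": max(val, 0.0),
                                 "background": max(bg, 0.0)})
    truth = SyntheticTruth()
    truth.extras["folds"] = {a: folds.get(a, 1.0) for a in analytes}
    return pd.DataFrame(rows), truth


def generate_ev_diameters(mean_nm: float = 100.0, sigma_log: float = 0.35,
                          n_fields: int = 10, per_field: int = 30,
                          seed: int = 0) -> tuple[list[np.ndarray], SyntheticTruth]:
    """Log-normal EV diameters per micrograph field (TEM morphometry shape)."""
    rng = np.random.default_rng(seed)
    mu = np.log(mean_nm) - 0.5 * sigma_log**2
    fields = [rng.lognormal(mu, sigma_log, size=per_field) for _ in range(n_fields)]
    truth = SyntheticTruth()
    truth.extras["mean_nm"] = mean_nm
    return fields, truth


# ---------------------------------------------------------------------------
# Writers (plain-text interchange formats)
# ---------------------------------------------------------------------------

def write_psm_runs(runs: Sequence[PsmRunTable], outdir: str | Path) -> Path:
    """Write one TSV per run (accession, psm) plus a manifest CSV; returns
    the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for run in runs:
        path = outdir / f"{run.run_id}.tsv"
        df = pd.DataFrame(sorted(run.counts.items()), columns=["accession", "psm"])
        df.to_csv(path, sep="\t", index=False)
        manifest.append({"run_id": run.run_id, "condition": run.condition,
                         "bio_replicate": run.bio_replicate,
                         "tech_replicate": run.tech_replicate, "path": path.name})
    mpath = outdir / "manifest.csv"
    pd.DataFrame(manifest).to_csv(mpath, index=False)
    return mpath


def write_reads_tsv(pool: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    pool.to_csv(path, sep="\t", index=False)
    return path


def write_reads_fastq(pool: pd.DataFrame, path: str | Path, adapter: str) -> Path:
    """4-line FASTQ; read layout is insert + UMI + adapter (adapter omitted
    for reads planted without one)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in pool.itertuples(index=False):
            seq = rec.insert + rec.umi + (adapter if rec.adapter_found else "")
            fh.write(f"@{rec.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def write_trace_csv(trace: Trace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s, "value": trace.value}).to_csv(
        path, index=False)
    return path


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, tuple, np.ndarray)):
            return sorted(o) if isinstance(o, set) else list(o)
        raise TypeError(type(o).__name__)

    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True, default=default)
    return path
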