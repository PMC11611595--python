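"""Synthetic FT-ICR-MS and quantitative-chemistry data generator.

Emulates a progressive-drought aeroponic experiment on cotton: two
treatments (control, drought), nine sampling days spanning a baseline day,
an 11-day treatment phase and a recovery phase, five of ten pots sampled
per treatment per day.  The generator emits per-sample [M-H]- peak lists
(true molecules plus 13C isotopologues, uniform noise and blank
contaminants, all under a configurable ppm miscalibration), sampling-blank
spectra, and per-sample quantitative chemistry (TOC, TN, NO3-N, NH4-N,
amino acids), together with the ground truth needed for recovery tests.

Drought enrichment of the N metabolome is injected as a presence-probability
boost for N-containing low-molecular-weight molecules inside the 275-390 and
450-550 amu windows, confined to treatment-phase days (2-11).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formulas import MolecularFormula, ElementBounds, C13_DELTA, classify_elemental
from .peaks import SampleSpectrum

logger = logging.getLogger(__name__)

SAMPLING_DAYS = (0, 2, 4, 7, 9, 11, 14, 16, 18)
TREATMENT_DAYS = (2, 4, 7, 9, 11)
RECOVERY_DAYS = (14, 16, 18)


def phase_of_day(day: int) -> str:
    if day == 0:
        return "baseline"
    if day in TREATMENT_DAYS:
        return "treatment"
    if day in RECOVERY_DAYS:
        return "recovery"
    raise ValueError(f"day {day} is not a sampling day")


def _default_quant_effects() -> dict:
    # drought/control multipliers per analyte and phase, from the measured
    # end-of-phase composition of the emulated experiment
    return {
        "TOC": {"treatment": 84.2 / 79.0, "recovery": 78.5 / 77.5},
        "TON": {"treatment": 34.4 / 20.4, "recovery": 35.8 / 23.4},
        "AA": {"treatment": 8.0, "recovery": 1.0},
    }


def _default_quant_control_means() -> dict:
    # control-phase means/SDs (mg/L) and root dry weight (g)
    return {
        "treatment": {"TOC": (79.0, 4.2), "TON": (20.4, 6.8),
                      "root_dw": {"control": 3.25, "drought": 3.14}},
        "recovery": {"TOC": (77.5, 0.8), "TON": (23.4, 5.2),
                     "root_dw": {"control": 5.0, "drought": 4.6}},
    }


# per-AA control concentration (mg/L); drought-responsive AAs get an extra
# multiplier on top of the phase-level AA effect
_AA_BASELINE = {
    "serine": 0.08, "aspartic_acid": 0.10, "asparagine": 0.06,
    "glutamic_acid": 0.12, "tryptophan": 0.03, "glutamine": 0.08,
    "phenylalanine": 0.04, "lysine": 0.05, "glycine": 0.10, "alanine": 0.09,
}
_AA_DROUGHT_EXTRA = {"serine": 4.3, "aspartic_acid": 2.4, "asparagine": 3.6}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment."""

    n_pots_per_treatment: int = 10
    pots_sampled_per_day: int = 5
    plants_per_pot: int = 3
    days: tuple = SAMPLING_DAYS
    formula_library_size: int = 4000
    n_fraction: float = 0.40
    n_ch2_series: int = 12
    ch2_series_length: int = 12
    n_noise_peaks: int = 330
    drought_lmw_windows: tuple = ((275.0, 390.0), (450.0, 550.0))
    drought_presence_boost: float = 0.25
    base_presence_range: tuple = (0.2, 0.9)
    quant_effects: dict = field(default_factory=_default_quant_effects)
    quant_control_means: dict = field(default_factory=_default_quant_control_means)
    calibration_offset_ppm: float = 0.0
    isotopologue_rate: float = 0.3
    blank_contaminant_count: int = 30
    n_blanks: int = 3
    noise_floor: float = 2.0e4
    rinseate_volume_ml: float = 128.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_fraction", "drought_presence_boost", "isotopologue_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must be a probability in [0, 1]")
        for lo, hi in self.drought_lmw_windows:
            if not (200 <= lo < hi <= 900):
                raise ValueError(f"drought window ({lo}, {hi}) outside [200, 900]")
        if self.formula_library_size < 1:
            raise ValueError("formula_library_size must be >= 1")
        if not 0 < self.pots_sampled_per_day <= self.n_pots_per_treatment:
            raise ValueError("pots_sampled_per_day must be in (0, n_pots_per_treatment]")


@dataclass
class GroundTruth:
    """What the generator actually put into the data."""

    catalog: dict  # molecule id -> MolecularFormula
    theoretical_mz: dict  # molecule id -> [M-H]- m/z
    presence: dict  # sample_id -> set of molecule ids
    boosted_ids: set  # N-containing LMW molecules boosted under drought
    contaminant_mz: np.ndarray
    quant_effects: dict
    clip_warnings: int = 0

    def presence_matrix(self, design: pd.DataFrame) -> pd.DataFrame:
        """Molecules x samples binary matrix from the true presence sets."""
        ids = sorted(self.catalog)
        mat = pd.DataFrame(0, index=ids, columns=design["sample_id"], dtype=int)
        for sid, present in self.presence.items():
            mat.loc[sorted(present), sid] = 1
        return mat


def build_formula_library(config: SimulationConfig,
                          forced: list[MolecularFormula] | None = None) -> dict:
    """Random CHNOSP catalog within the detected compositional space.

    Rejection-samples element counts until each candidate satisfies the
    bounds (C 5-56, N 0-3, S 0-3, P 0-2), plausibility screening, and an
    [M-H]- m/z inside [200, 900].  About ``n_fraction`` of molecules carry
    at least one N.  A configurable number of CH2 homologous series (the
    backbone structure of dissolved organic matter that internal
    calibration relies on) is seeded first and extended member by member.
    """
    rng = np.random.default_rng(config.seed)
    bounds = ElementBounds()
    catalog: dict[str, MolecularFormula] = {}
    seen: set = set()
    forced = list(forced or [])
    n_target = config.formula_library_size

    def _admit(f: MolecularFormula) -> None:
        if f.counts not in seen and len(catalog) < n_target:
            seen.add(f.counts)
            catalog[f"mol{len(catalog):05d}"] = f

    for f in forced:
        _admit(f)
    for _ in range(config.n_ch2_series):
        # CHO-type lignin-like series, the usual internal calibrants
        c = int(rng.integers(10, 18))
        h = int(rng.integers(int(np.ceil(c * 0.8)), 2 * c))
        o = int(rng.integers(2, 8))
        base = MolecularFormula(c, h, 0, o)
        for k in range(config.ch2_series_length):
            member = MolecularFormula(base.c + k, base.h + 2 * k, base.n, base.o)
            if 200.0 <= member.deprotonated_mz <= 900.0 and bounds.is_plausible(member):
                _admit(member)

    attempts = 0
    while len(catalog) < n_target:
        attempts += 1
        if attempts > 200000:
            raise ValueError("unsatisfiable formula-library configuration")
        c = int(rng.integers(5, 57))
        n = int(rng.integers(1, 4)) if rng.random() < config.n_fraction else 0
        o = int(rng.integers(0, min(bounds.o[1], int(c * bounds.oc_max)) + 1))
        s = int(rng.integers(0, 4)) if rng.random() < 0.15 else 0
        p = int(rng.integers(0, 3)) if rng.random() < 0.08 else 0
        h_lo = max(bounds.h[0], int(np.ceil(c * bounds.hc_range[0])))
        h_hi = min(bounds.h[1], int(np.floor(c * bounds.hc_range[1])))
        if h_lo > h_hi:
            continue
        h = int(rng.integers(h_lo, h_hi + 1))
        f = MolecularFormula(c, h, n, o, s, p)
        if not bounds.is_plausible(f):
            continue
        if not 200.0 <= f.deprotonated_mz <= 900.0:
            continue
        _admit(f)
    return catalog


def make_design(config: SimulationConfig) -> pd.DataFrame:
    """Sampling design: per day and treatment, a random subset of pots."""
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for day in config.days:
        for treatment in ("control", "drought"):
            pots = rng.choice(config.n_pots_per_treatment,
                              size=config.pots_sampled_per_day, replace=False)
            for pot in np.sort(pots):
                sid = f"{treatment[:4]}_d{day:02d}_p{pot:02d}"
                rows.append({"sample_id": sid, "treatment": treatment,
                             "day": day, "phase": phase_of_day(day),
                             "pot": int(pot)})
    return pd.DataFrame(rows)


def _in_windows(mass: float, windows) -> bool:
    return any(lo <= mass <= hi for lo, hi in windows)


def simulate_peak_tables(
    config: SimulationConfig,
    catalog: dict | None = None,
    design: pd.DataFrame | None = None,
) -> tuple[dict, list, GroundTruth, pd.DataFrame]:
    """Per-sample spectra, blank spectra, ground truth, and the design table.

    Each molecule present in a sample emits a peak at its theoretical [M-H]-
    m/z scaled by the configured ppm miscalibration; with probability
    ``isotopologue_rate`` a 13C partner follows at +1.003355 with relative
    intensity 1.1% per carbon.  Noise peaks are uniform over [150, 950] with
    low S/N.  Blank contaminants appear both in the blanks and (with high
    probability) in samples.
    """
    rng = np.random.default_rng(config.seed + 2)
    catalog = catalog if catalog is not None else build_formula_library(config)
    design = design if design is not None else make_design(config)
    scale = 1.0 + config.calibration_offset_ppm * 1e-6

    ids = sorted(catalog)
    theo_mz = {i: catalog[i].deprotonated_mz for i in ids}
    base_p = dict(zip(ids, rng.uniform(*config.base_presence_range, size=len(ids))))
    # members of CH2 homologous series are the abundant backbone of the
    # spectrum and must be near-ubiquitous for internal calibration to work
    counts_set = {catalog[i].counts for i in ids}
    for i in ids:
        f = catalog[i]
        if ((f.c - 1, f.h - 2, f.n, f.o, f.s, f.p) in counts_set
                or (f.c + 1, f.h + 2, f.n, f.o, f.s, f.p) in counts_set):
            base_p[i] = float(rng.uniform(0.92, 1.0))
    boosted = {i for i in ids
               if catalog[i].n > 0 and _in_windows(theo_mz[i], config.drought_lmw_windows)}

    contaminant_mz = np.sort(rng.uniform(220.0, 880.0, size=config.blank_contaminant_count))

    samples: dict[str, SampleSpectrum] = {}
    presence: dict[str, set] = {}
    for row in design.itertuples(index=False):
        p = np.array([base_p[i] for i in ids])
        if row.treatment == "drought" and row.phase == "treatment":
            idx = [k for k, i in enumerate(ids) if i in boosted]
            p[idx] = np.minimum(1.0, p[idx] + config.drought_presence_boost)
        present_mask = rng.random(len(ids)) < p
        present = {i for i, m in zip(ids, present_mask) if m}
        presence[row.sample_id] = present

        mzs, intens, snrs = [], [], []
        for i in sorted(present):
            inten = rng.lognormal(mean=np.log(1e6), sigma=1.0)
            mzs.append(theo_mz[i] * scale)
            intens.append(inten)
            snrs.append(inten / config.noise_floor)
            if rng.random() < config.isotopologue_rate:
                iso_inten = inten * 0.011 * catalog[i].c
                mzs.append(theo_mz[i] * scale + C13_DELTA)
                intens.append(iso_inten)
                snrs.append(iso_inten / config.noise_floor)
        # contaminants ride along in most samples
        for cmz in contaminant_mz:
            if rng.random() < 0.9:
                inten = rng.lognormal(mean=np.log(8e5), sigma=0.5)
                mzs.append(cmz * scale)
                intens.append(inten)
                snrs.append(inten / config.noise_floor)
        # electronic/chemical noise: low S/N, anywhere in scan range
        n_noise = config.n_noise_peaks
        noise_mz = rng.uniform(150.0, 950.0, size=n_noise)
        noise_inten = rng.lognormal(mean=np.log(5e4), sigma=0.8, size=n_noise)
        mzs.extend(noise_mz)
        intens.extend(noise_inten)
        snrs.extend(noise_inten / config.noise_floor)

        df = pd.DataFrame({"mz": mzs, "intensity": intens, "snr": snrs})
        samples[row.sample_id] = SampleSpectrum(
            row.sample_id, df,
            {"treatment": row.treatment, "day": row.day, "phase": row.phase},
        )

    blanks = []
    for b in range(config.n_blanks):
        inten = rng.lognormal(mean=np.log(8e5), sigma=0.5, size=contaminant_mz.size)
        df = pd.DataFrame({"mz": contaminant_mz * scale, "intensity": inten,
                           "snr": inten / config.noise_floor})
        blanks.append(SampleSpectrum(f"blank_{b:02d}", df, {"blank": True}))

    truth = GroundTruth(catalog=catalog, theoretical_mz=theo_mz, presence=presence,
                        boosted_ids=boosted, contaminant_mz=contaminant_mz,
                        quant_effects=config.quant_effects)
    return samples, blanks, truth, design


def simulate_quant_tables(config: SimulationConfig,
                          design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample quantitative chemistry at the end-of-phase timepoints.

    Control analytes are drawn around the configured control means; drought
    samples are scaled by the per-analyte, per-phase effect multipliers.
    NO3-N is generated so inorganic N is about 20% of total N; NH4-N is 0
    throughout (none detected).  Negative draws are clipped to 0 and counted.
    """
    rng = np.random.default_rng(config.seed + 3)
    design = design if design is not None else make_design(config)
    quant_days = {max(TREATMENT_DAYS): "treatment", max(config.days): "recovery"}
    rows = []
    clipped = 0
    for row in design.itertuples(index=False):
        if row.day not in quant_days:
            continue
        ph = quant_days[row.day]
        means = config.quant_control_means[ph]
        eff = config.quant_effects

        toc = rng.normal(*means["TOC"])
        ton = rng.normal(*means["TON"])
        if row.treatment == "drought":
            toc *= eff["TOC"][ph]
            ton *= eff["TON"][ph]
        if ton < 0 or toc < 0:
            clipped += int(ton < 0) + int(toc < 0)
            toc, ton = max(toc, 0.0), max(ton, 0.0)
        # inorganic N ~ 20% of TN  =>  NO3-N = TON / 4 (with mild jitter)
        no3 = ton * 0.25 * rng.normal(1.0, 0.05)
        no3 = max(no3, 0.0)
        tn = ton + no3

        aa = {}
        for name, base in _AA_BASELINE.items():
            conc = base * rng.lognormal(0.0, 0.3)
            if row.treatment == "drought":
                conc *= eff["AA"][ph] * _AA_DROUGHT_EXTRA.get(name, 1.0)
            aa[name] = conc

        root_dw = max(rng.normal(means["root_dw"][row.treatment], 0.3), 0.5)
        rows.append({"sample_id": row.sample_id, "treatment": row.treatment,
                     "day": row.day, "phase": ph,
                     "TOC_conc": toc, "TN_conc": tn, "NO3N_conc": no3,
                     "NH4N_conc": 0.0,
                     "rinseate_volume": config.rinseate_volume_ml,
                     "root_dry_weight": root_dw,
                     "plants_per_pot": config.plants_per_pot,
                     **{f"aa_{k}": v for k, v in aa.items()}})
    if clipped:
        logger.warning("quant simulation: %d negative concentrations clipped to 0", clipped)
    return pd.DataFrame(rows)


def write_dataset(config: SimulationConfig, outdir) -> Path:
    """Write the full synthetic dataset as TSV/JSON files under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    samples, blanks, truth, design = simulate_peak_tables(config)
    quant = simulate_quant_tables(config, design)

    for sid, spec in samples.items():
        spec.peaks.to_csv(outdir / "peaks" / f"{sid}.tsv", sep="\t", index=False)
    for spec in blanks:
        spec.peaks.to_csv(outdir / "peaks" / f"{spec.sample_id}.tsv", sep="\t", index=False)
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    quant.to_csv(outdir / "quant.tsv", sep="\t", index=False)

    gt = {
        "catalog": {i: str(f) for i, f in truth.catalog.items()},
        "theoretical_mz": truth.theoretical_mz,
        "presence": {sid: sorted(p) for sid, p in truth.presence.items()},
        "boosted_ids": sorted(truth.boosted_ids),
        "contaminant_mz": truth.contaminant_mz.tolist(),
        "quant_effects": truth.quant_effects,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)
    logger.info("synthetic dataset written to %s (%d samples, %d blanks, "
                "%d catalog molecules)", outdir, len(samples), len(blanks),
                len(truth.catalog))
    return outdir
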