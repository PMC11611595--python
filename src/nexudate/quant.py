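"""Quantitative C and N balance of root exudates.

Total organic nitrogen is derived by subtracting inorganic N (NO3-N and
NH4-N) from total N; concentrations (mg/L) convert to exuded mass (mg) via
the rinseate volume collected per pot (128.8 mL by default), and to
specific exudation (mg per g root dry weight).  Amino-acid N converts each
amino acid's mass concentration to its nitrogen share using a built-in
table of proteinogenic amino-acid formulas and average molar masses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formulas import MolecularFormula, AVG_N

logger = logging.getLogger(__name__)

DEFAULT_RINSEATE_ML = 128.8

# 20 proteinogenic amino acids: neutral molecular formulas
AMINO_ACID_FORMULAS: dict[str, MolecularFormula] = {
    "glycine": MolecularFormula.parse("C2H5NO2"),
    "alanine": MolecularFormula.parse("C3H7NO2"),
    "serine": MolecularFormula.parse("C3H7NO3"),
    "proline": MolecularFormula.parse("C5H9NO2"),
    "valine": MolecularFormula.parse("C5H11NO2"),
    "threonine": MolecularFormula.parse("C4H9NO3"),
    "cysteine": MolecularFormula.parse("C3H7NO2S"),
    "leucine": MolecularFormula.parse("C6H13NO2"),
    "isoleucine": MolecularFormula.parse("C6H13NO2"),
    "asparagine": MolecularFormula.parse("C4H8N2O3"),
    "aspartic_acid": MolecularFormula.parse("C4H7NO4"),
    "glutamine": MolecularFormula.parse("C5H10N2O3"),
    "lysine": MolecularFormula.parse("C6H14N2O2"),
    "glutamic_acid": MolecularFormula.parse("C5H9NO4"),
    "methionine": MolecularFormula.parse("C5H11NO2S"),
    "histidine": MolecularFormula.parse("C6H9N3O2"),
    "phenylalanine": MolecularFormula.parse("C9H11NO2"),
    "arginine": MolecularFormula.parse("C6H14N4O2"),
    "tyrosine": MolecularFormula.parse("C9H11NO3"),
    "tryptophan": MolecularFormula.parse("C11H12N2O2"),
}


class QuantValidationError(ValueError):
    """Raised on invalid quantitative inputs (negative concentrations etc.)."""


def derive_TON(TN: float, NO3N: float, NH4N: float = 0.0) -> tuple[float, bool]:
    """Total organic N (mg/L) = TN - NO3-N - NH4-N.

    Returns ``(TON, flagged)``; a negative balance is reported as missing
    (NaN) with the flag set rather than clamped, so downstream means are
    not silently biased.
    """
    for name, v in (("TN", TN), ("NO3N", NO3N), ("NH4N", NH4N)):
        if v < 0:
            raise QuantValidationError(f"{name} must be >= 0, got {v}")
    ton = TN - NO3N - NH4N
    if ton < 0:
        logger.warning("negative TON (TN=%.3g, inorganic=%.3g); recorded as missing",
                       TN, NO3N + NH4N)
        return float("nan"), True
    return ton, False


def mass_exuded(conc: float, volume_ml: float = DEFAULT_RINSEATE_ML) -> float:
    """Exuded mass (mg) from concentration (mg/L) and rinseate volume (mL)."""
    if conc < 0:
        raise QuantValidationError(f"concentration must be >= 0, got {conc}")
    if volume_ml <= 0:
        raise QuantValidationError(f"volume must be > 0, got {volume_ml}")
    return conc * volume_ml / 1000.0


def specific_exudation(mass_mg: float, root_dw_g: float) -> float:
    """Exuded mass normalized to root dry weight (mg per g DW)."""
    if root_dw_g <= 0:
        raise QuantValidationError(f"root dry weight must be > 0, got {root_dw_g}")
    return mass_mg / root_dw_g


def cn_ratio(
    toc_mass,
    ton_mass,
    aggregation: str = "per_replicate_then_mean",
) -> float:
    """C:N of exudates from per-replicate TOC and TON masses (mg).

    ``per_replicate_then_mean`` averages each replicate's TOC/TON ratio
    (the reported-table behavior); ``ratio_of_means`` divides the mean
    masses instead.  Replicates with zero or missing TON are dropped with
    a warning (flagged missing).
    """
    toc = np.atleast_1d(np.asarray(toc_mass, dtype=float))
    ton = np.atleast_1d(np.asarray(ton_mass, dtype=float))
    if toc.shape != ton.shape:
        raise QuantValidationError("TOC and TON vectors must have equal length")
    valid = ~np.isnan(toc) & ~np.isnan(ton) & (ton > 0)
    if not valid.any():
        logger.warning("C:N undefined: no replicate with TON > 0")
        return float("nan")
    if valid.sum() < valid.size:
        logger.warning("C:N: %d replicates with TON <= 0 or missing dropped",
                       int(valid.size - valid.sum()))
    if aggregation == "per_replicate_then_mean":
        return float(np.mean(toc[valid] / ton[valid]))
    if aggregation == "ratio_of_means":
        return float(np.mean(toc[valid]) / np.mean(ton[valid]))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def amino_acid_nitrogen(profile: dict[str, float],
                        extra_formulas: dict[str, MolecularFormula] | None = None) -> float:
    """Total amino-acid nitrogen (mg N/L) from per-AA concentrations (mg/L).

    Each amino acid contributes conc x (N_count x 14.007 / average molar
    mass).  Unknown names raise with the accepted list.
    """
    table = dict(AMINO_ACID_FORMULAS)
    if extra_formulas:
        table.update(extra_formulas)
    total = 0.0
    for name, conc in profile.items():
        if name not in table:
            raise QuantValidationError(
                f"unknown amino acid {name!r}; accepted: {sorted(table)}")
        if conc < 0:
            raise QuantValidationError(f"{name}: concentration must be >= 0")
        f = table[name]
        total += conc * (f.n * AVG_N / f.average_mass)
    return total


@dataclass
class ExudateBalance:
    """Derived balance for one sample."""

    sample_id: str
    TON_conc: float
    TOC_mass: float
    TON_mass: float
    specific_TOC: float
    specific_TON: float
    AA_N_conc: float
    flagged: bool


def balance_table(quant: pd.DataFrame, per_plant: bool = False) -> pd.DataFrame:
    """Per-sample exudate balance from a quant table.

    Expects columns TOC_conc, TN_conc, NO3N_conc, NH4N_conc,
    rinseate_volume, root_dry_weight, plants_per_pot and aa_* amino-acid
    concentrations.  With ``per_plant=True`` masses are divided by the
    number of plants per pot; the default reports whole-pot masses, which
    is how the rinseate collection is expressed.
    """
    rows = []
    for rec in quant.to_dict("records"):
        ton, flagged = derive_TON(rec["TN_conc"], rec["NO3N_conc"], rec["NH4N_conc"])
        vol = rec.get("rinseate_volume", DEFAULT_RINSEATE_ML)
        divisor = rec.get("plants_per_pot", 3) if per_plant else 1
        toc_mass = mass_exuded(rec["TOC_conc"], vol) / divisor
        ton_mass = (mass_exuded(ton, vol) / divisor) if not np.isnan(ton) else float("nan")
        dw = rec["root_dry_weight"]
        aa = {k[3:]: v for k, v in rec.items() if k.startswith("aa_")}
        rows.append({
            "sample_id": rec["sample_id"],
            "treatment": rec.get("treatment"), "day": rec.get("day"),
            "phase": rec.get("phase"),
            "TON_conc": ton,
            "TOC_mass": toc_mass, "TON_mass": ton_mass,
            "specific_TOC": specific_exudation(toc_mass, dw),
            "specific_TON": (specific_exudation(ton_mass, dw)
                             if not np.isnan(ton_mass) else float("nan")),
            "AA_N_conc": amino_acid_nitrogen(aa),
            "flagged": flagged,
        })
    return pd.DataFrame(rows)


def composition_table(quant: pd.DataFrame) -> pd.DataFrame:
    """Stacked mass-balance composition (mg/L) per treatment and phase.

    Components: TOC, TON, NO3-N and amino-acid N, averaged within each
    treatment x phase cell — the stacked-composition analog of the measured
    rinseate make-up.
    """
    bal = balance_table(quant)
    merged = quant.merge(bal[["sample_id", "TON_conc", "AA_N_conc"]], on="sample_id")
    out = (merged.groupby(["phase", "treatment"])
           [["TOC_conc", "TON_conc", "NO3N_conc", "AA_N_conc"]]
           .mean().reset_index())
    return out
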