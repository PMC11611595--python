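"""Molecular formula arithmetic and CHNOSP formula assignment.

Accurate-mass formula assignment for singly deprotonated ([M-H]-) ions
detected by ultrahigh-resolution mass spectrometry.  Candidate formulas are
enumerated exhaustively within configurable element bounds, screened by
standard chemical-plausibility rules (DBE, H/C, O/C), ranked by absolute
ppm error with a deterministic tie-break, and optionally post-filtered at a
tighter ppm threshold.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

# Monoisotopic atomic masses (amu)
MASS_C = 12.000000
MASS_H = 1.0078250319
MASS_N = 14.0030740052
MASS_O = 15.9949146221
MASS_S = 31.97207069
MASS_P = 30.97376151

# Average atomic masses (amu), for average-molar-mass bookkeeping
AVG_C = 12.011
AVG_H = 1.008
AVG_N = 14.007
AVG_O = 15.999
AVG_S = 32.06
AVG_P = 30.974

# Proton mass; electron mass neglected (< 0.5 ppm at m/z >= 200)
PROTON_MASS = 1.0072765

# Mass difference between 13C and 12C
C13_DELTA = 1.003355

_ELEMENT_ORDER = ("C", "H", "N", "O", "S", "P")
_MONO = dict(zip(_ELEMENT_ORDER, (MASS_C, MASS_H, MASS_N, MASS_O, MASS_S, MASS_P)))
_AVG = dict(zip(_ELEMENT_ORDER, (AVG_C, AVG_H, AVG_N, AVG_O, AVG_S, AVG_P)))

_FORMULA_TOKEN = re.compile(r"([CHNOSP])(\d*)")


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Element counts for a CHNOSP molecule."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"element count {name}={v!r} must be a non-negative integer")
        if self.total_atoms == 0:
            raise ValueError("formula must contain at least one atom")

    @property
    def counts(self) -> tuple[int, int, int, int, int, int]:
        return (self.c, self.h, self.n, self.o, self.s, self.p)

    @property
    def total_atoms(self) -> int:
        return self.c + self.h + self.n + self.o + self.s + self.p

    @property
    def monoisotopic_mass(self) -> float:
        return (
            self.c * MASS_C + self.h * MASS_H + self.n * MASS_N
            + self.o * MASS_O + self.s * MASS_S + self.p * MASS_P
        )

    @property
    def average_mass(self) -> float:
        return (
            self.c * AVG_C + self.h * AVG_H + self.n * AVG_N
            + self.o * AVG_O + self.s * AVG_S + self.p * AVG_P
        )

    @property
    def deprotonated_mz(self) -> float:
        """m/z of the singly deprotonated [M-H]- ion."""
        return self.monoisotopic_mass - PROTON_MASS

    @property
    def dbe(self) -> float:
        """Double-bond equivalents (rings + degrees of unsaturation)."""
        return self.c - self.h / 2 + self.n / 2 + self.p / 2 + 1

    def __str__(self) -> str:
        parts = []
        for sym, count in zip(_ELEMENT_ORDER, self.counts):
            if count == 0:
                continue
            parts.append(sym if count == 1 else f"{sym}{count}")
        return "".join(parts)

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a CHNOSP formula string such as ``C13H21O3N3``."""
        counts = dict.fromkeys(_ELEMENT_ORDER, 0)
        pos = 0
        stripped = text.strip()
        for m in _FORMULA_TOKEN.finditer(stripped):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            counts[m.group(1)] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(stripped) or pos == 0:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(
            c=counts["C"], h=counts["H"], n=counts["N"],
            o=counts["O"], s=counts["S"], p=counts["P"],
        )


def formula_mass(f: MolecularFormula, kind: str = "neutral_monoisotopic") -> float:
    """Mass of a formula: neutral monoisotopic, [M-H]- m/z, or average."""
    if kind == "neutral_monoisotopic":
        return f.monoisotopic_mass
    if kind == "deprotonated_mz":
        return f.deprotonated_mz
    if kind == "average":
        return f.average_mass
    raise ValueError(f"unknown mass kind {kind!r}")


@dataclass(frozen=True)
class ElementBounds:
    """Per-element (min, max) count bounds plus plausibility switches.

    Defaults cover the detected compositional space (C 5-56, N 0-3) with
    standard screening rules: DBE in [0, 40], 0.3 <= H/C <= 2.5, O/C <= 1.2.
    """

    c: tuple[int, int] = (5, 56)
    h: tuple[int, int] = (4, 120)
    n: tuple[int, int] = (0, 3)
    o: tuple[int, int] = (0, 40)
    s: tuple[int, int] = (0, 3)
    p: tuple[int, int] = (0, 2)
    dbe_range: tuple[float, float] = (0.0, 40.0)
    hc_range: tuple[float, float] = (0.3, 2.5)
    oc_max: float = 1.2
    apply_plausibility: bool = True

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    def is_plausible(self, f: MolecularFormula) -> bool:
        if f.c == 0:
            return False
        hc = f.h / f.c
        oc = f.o / f.c
        return (
            self.dbe_range[0] <= f.dbe <= self.dbe_range[1]
            and self.hc_range[0] <= hc <= self.hc_range[1]
            and oc <= self.oc_max
        )


@dataclass(frozen=True)
class FormulaCandidate:
    formula: MolecularFormula
    error_ppm: float
    plausible: bool


@dataclass(frozen=True)
class FormulaAssignment:
    """Result of assigning a formula to one observed [M-H]- m/z."""

    observed_mz: float
    neutral_mass: float
    formula: MolecularFormula | None
    error_ppm: float
    elemental_class: str | None
    assigned: bool


@lru_cache(maxsize=8)
def _candidate_grid(bounds: ElementBounds):
    """Vectorized (c, n, o, s, p) grid with partial masses, cached per bounds."""
    axes = [np.arange(lo, hi + 1) for lo, hi in
            (bounds.c, bounds.n, bounds.o, bounds.s, bounds.p)]
    c, n, o, s, p = (a.ravel() for a in np.meshgrid(*axes, indexing="ij"))
    partial = c * MASS_C + n * MASS_N + o * MASS_O + s * MASS_S + p * MASS_P
    order = np.argsort(partial)
    return c[order], n[order], o[order], s[order], p[order], partial[order]


def _tie_break_key(cand: FormulaCandidate):
    f = cand.formula
    return (abs(cand.error_ppm), f.s + f.p, f.n, f.counts)


def enumerate_candidates(
    neutral_mass: float,
    tol_ppm: float = 1.0,
    bounds: ElementBounds | None = None,
) -> list[FormulaCandidate]:
    """All formulas within ``tol_ppm`` of a neutral monoisotopic mass.

    Exhaustive within the element bounds; plausibility rules are reported as
    flags, never silent drops.  Sorted by |error_ppm| with a deterministic
    tie-break (fewer S+P, then fewer N, then CHNOSP-lexicographic).
    """
    if not (0 < neutral_mass <= 1000):
        raise ValueError(f"neutral mass {neutral_mass} outside (0, 1000]")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    bounds = bounds or ElementBounds()

    c, n, o, s, p, partial = _candidate_grid(bounds)
    tol_mass = neutral_mass * tol_ppm * 1e-6
    h_lo, h_hi = bounds.h

    # only grids whose residual mass can be made of an in-bounds H count
    lo_idx = np.searchsorted(partial, neutral_mass - tol_mass - h_hi * MASS_H)
    hi_idx = np.searchsorted(partial, neutral_mass + tol_mass - h_lo * MASS_H)
    sl = slice(lo_idx, hi_idx)
    residual = neutral_mass - partial[sl]
    h = np.rint(residual / MASS_H).astype(int)
    mass = partial[sl] + h * MASS_H
    ok = (h >= h_lo) & (h <= h_hi) & (np.abs(mass - neutral_mass) <= tol_mass)

    out: list[FormulaCandidate] = []
    for ci, hi_, ni, oi, si, pi, mi in zip(
        c[sl][ok], h[ok], n[sl][ok], o[sl][ok], s[sl][ok], p[sl][ok], mass[ok]
    ):
        f = MolecularFormula(int(ci), int(hi_), int(ni), int(oi), int(si), int(pi))
        err = (neutral_mass - mi) / mi * 1e6
        out.append(FormulaCandidate(f, err, bounds.is_plausible(f)))
    out.sort(key=_tie_break_key)
    return out


def enumerate_candidates_bruteforce(
    neutral_mass: float,
    tol_ppm: float = 1.0,
    bounds: ElementBounds | None = None,
) -> list[FormulaCandidate]:
    """Nested-loop enumeration with no pruning; independent reference path.

    Intended for small bounds only (used to guard the vectorized search).
    """
    bounds = bounds or ElementBounds()
    tol_mass = neutral_mass * tol_ppm * 1e-6
    ranges = [range(lo, hi + 1) for lo, hi in
              (bounds.c, bounds.h, bounds.n, bounds.o, bounds.s, bounds.p)]
    out = []
    for c, h, n, o, s, p in itertools.product(*ranges):
        if c + h + n + o + s + p == 0:
            continue
        f = MolecularFormula(c, h, n, o, s, p)
        m = f.monoisotopic_mass
        if abs(m - neutral_mass) <= tol_mass:
            err = (neutral_mass - m) / m * 1e6
            out.append(FormulaCandidate(f, err, bounds.is_plausible(f)))
    out.sort(key=_tie_break_key)
    return out


def classify_elemental(f: MolecularFormula) -> str:
    """Elemental class of an assigned formula.

    N-free molecules are ``nonN``; N-containing molecules split by the
    presence of S and/or P into CHON, CHON-S, CHON-P, CHON-SP.
    """
    if f.n == 0:
        return "nonN"
    if f.s > 0 and f.p > 0:
        return "CHON-SP"
    if f.s > 0:
        return "CHON-S"
    if f.p > 0:
        return "CHON-P"
    return "CHON"


ELEMENTAL_CLASSES = ("CHON", "CHON-S", "CHON-P", "CHON-SP", "nonN")


def assign_formula(
    observed_mz: float,
    tol_ppm: float = 1.0,
    bounds: ElementBounds | None = None,
    error_filter_ppm: float | None = 0.5,
) -> FormulaAssignment:
    """Assign the best CHNOSP formula to one observed [M-H]- m/z.

    The neutral mass is observed_mz + proton mass; the best candidate is the
    minimum-|error| plausible formula within ``tol_ppm``.  When
    ``error_filter_ppm`` is set, assignments with |error| above it are
    discarded afterwards (tighter post-assignment error filtering).
    """
    neutral = observed_mz + PROTON_MASS
    cands = [c for c in enumerate_candidates(neutral, tol_ppm, bounds) if c.plausible]
    if not cands:
        return FormulaAssignment(observed_mz, neutral, None, np.nan, None, False)
    best = cands[0]
    if error_filter_ppm is not None and abs(best.error_ppm) > error_filter_ppm:
        return FormulaAssignment(observed_mz, neutral, None, np.nan, None, False)
    return FormulaAssignment(
        observed_mz, neutral, best.formula, best.error_ppm,
        classify_elemental(best.formula), True,
    )
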