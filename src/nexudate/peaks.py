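"""Peak-list quality control for direct-injection FT-ICR-MS spectra.

Stages, in pipeline order: ingestion of per-sample peak tables, internal
calibration against CH2 homologous series, S/N and m/z-window filters,
13C-isotopologue removal, blank subtraction, cross-sample alignment with a
prevalence filter, and z-score normalization.  Every stage returns a subset
of its input peaks, so per-stage counts form a monotone QC funnel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .formulas import C13_DELTA

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ("mz", "intensity", "snr")

# Monoisotopic mass of a CH2 group, the spacing of homologous series used
# for internal calibration.
CH2_MASS = 14.015650


class PeakTableError(ValueError):
    """Raised when a peak table cannot be parsed."""


@dataclass
class SampleSpectrum:
    """One sample's peak list (mz ascending) plus design metadata."""

    sample_id: str
    peaks: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.peaks.columns]
        if missing:
            raise PeakTableError(f"{self.sample_id}: missing columns {missing}")
        self.peaks = (
            self.peaks.loc[:, list(PEAK_COLUMNS)]
            .sort_values("mz", kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return self.peaks["mz"].to_numpy()

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks["intensity"].to_numpy()

    def _with_mask(self, mask: np.ndarray) -> "SampleSpectrum":
        return SampleSpectrum(self.sample_id, self.peaks.loc[mask], dict(self.metadata))


def read_peak_table(path, sample_id: str | None = None, sep: str = "\t",
                    metadata: dict | None = None) -> SampleSpectrum:
    """Read a delimited peak table with columns mz, intensity, snr."""
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise PeakTableError(f"{path}: empty file") from exc
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(f"{path}: missing columns {missing}")
    for col in PEAK_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise PeakTableError(f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = coerced
    if df[list(PEAK_COLUMNS)].isna().any().any():
        row = int(df[list(PEAK_COLUMNS)].isna().any(axis=1).idxmax())
        raise PeakTableError(f"{path}: missing value in row {row}")
    if (df["mz"] <= 0).any() or (df["intensity"] < 0).any() or (df["snr"] < 0).any():
        raise PeakTableError(f"{path}: mz must be > 0 and intensity/snr >= 0")
    name = sample_id if sample_id is not None else str(path)
    return SampleSpectrum(name, df, metadata or {})


def filter_snr(spec: SampleSpectrum, threshold: float = 7.0) -> SampleSpectrum:
    """Retain peaks with S/N strictly above the threshold (S/N > 7 default)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return spec._with_mask(spec.peaks["snr"].to_numpy() > threshold)


def filter_mz_window(spec: SampleSpectrum, low: float = 200.0,
                     high: float = 900.0) -> SampleSpectrum:
    """Retain peaks inside the closed m/z window [low, high]."""
    if not low < high:
        raise ValueError("low must be < high")
    mz = spec.mz
    return spec._with_mask((mz >= low) & (mz <= high))


@dataclass(frozen=True)
class CalibrationModel:
    """Linear ppm correction over m/z: ppm(m) = intercept + slope * m."""

    intercept: float
    slope: float
    n_series: int
    warning: bool = False

    def ppm(self, mz: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(mz, dtype=float)


def _find_ch2_series(mz: np.ndarray, spacing: float, match_tol_ppm: float) -> list[np.ndarray]:
    """Greedy ascending chains of peaks spaced by one CH2 unit."""
    used = np.zeros(len(mz), dtype=bool)
    chains = []
    for start in range(len(mz)):
        if used[start]:
            continue
        chain = [start]
        while True:
            target = mz[chain[-1]] + spacing
            tol = target * match_tol_ppm * 1e-6
            j = np.searchsorted(mz, target)
            best, best_d = -1, tol
            for k in (j - 1, j):
                if 0 <= k < len(mz) and not used[k]:
                    d = abs(mz[k] - target)
                    if d <= best_d:
                        best, best_d = k, d
            if best < 0:
                break
            chain.append(best)
        if len(chain) > 1:
            used[chain] = True
            chains.append(np.asarray(chain))
    return chains


def calibrate_internal(
    spec: SampleSpectrum,
    series_spacing: float = CH2_MASS,
    min_series_length: int = 5,
    match_tol_ppm: float = 2.0,
) -> tuple[SampleSpectrum, CalibrationModel]:
    """Internal calibration from CH2 homologous series.

    A uniform (or slowly varying) ppm miscalibration scales the spacing of a
    homologous series away from the exact CH2 mass; each detected series
    therefore yields one ppm-offset estimate, localized at its mean m/z.  A
    linear ppm model over m/z is fit to these estimates (a constant when only
    one series is found) and divided out.  With no series of the minimum
    length, the spectrum is returned unchanged with a warning flag.
    """
    if len(spec) == 0:
        raise ValueError("cannot calibrate an empty spectrum")
    mz = spec.mz
    chains = [c for c in _find_ch2_series(mz, series_spacing, match_tol_ppm)
              if len(c) >= min_series_length]
    if not chains:
        logger.warning("%s: no CH2 series of length >= %d; calibration skipped",
                       spec.sample_id, min_series_length)
        return spec, CalibrationModel(0.0, 0.0, 0, warning=True)

    centers, offsets, weights = [], [], []
    for chain in chains:
        obs = mz[chain]
        k = np.arange(len(chain), dtype=float)
        slope = np.polyfit(k, obs, 1)[0]  # observed spacing
        offsets.append((slope / series_spacing - 1.0) * 1e6)
        centers.append(obs.mean())
        weights.append(float(len(chain)))
    centers, offsets, weights = map(np.asarray, (centers, offsets, weights))

    # chains bridging unrelated peaks give wild offsets; keep chains near the
    # weighted median before fitting
    order = np.argsort(offsets)
    cum = np.cumsum(weights[order])
    med = offsets[order][np.searchsorted(cum, cum[-1] / 2)]
    good = np.abs(offsets - med) <= 0.5
    centers, offsets, weights = centers[good], offsets[good], weights[good]
    n_series = int(good.sum())

    if n_series >= 2 and np.ptp(centers) > 1e-9:
        b, a = np.polyfit(centers, offsets, 1, w=weights)
        model = CalibrationModel(intercept=float(a), slope=float(b), n_series=n_series)
    else:
        model = CalibrationModel(intercept=float(np.average(offsets, weights=weights)),
                                 slope=0.0, n_series=n_series)
    corrected = spec.peaks.copy()
    corrected["mz"] = mz / (1.0 + model.ppm(mz) * 1e-6)
    return SampleSpectrum(spec.sample_id, corrected, dict(spec.metadata)), model


def apply_calibration(spec: SampleSpectrum, model: CalibrationModel) -> SampleSpectrum:
    """Apply an existing ppm-correction model to a spectrum.

    Used for blanks, which carry no homologous series of their own but share
    the instrument session (and hence the miscalibration) of the samples.
    """
    corrected = spec.peaks.copy()
    mz = spec.mz
    corrected["mz"] = mz / (1.0 + model.ppm(mz) * 1e-6)
    return SampleSpectrum(spec.sample_id, corrected, dict(spec.metadata))


def median_calibration(models: list[CalibrationModel]) -> CalibrationModel:
    """Session-level consensus correction from per-sample models."""
    fitted = [m for m in models if not m.warning]
    if not fitted:
        return CalibrationModel(0.0, 0.0, 0, warning=True)
    return CalibrationModel(
        intercept=float(np.median([m.intercept for m in fitted])),
        slope=float(np.median([m.slope for m in fitted])),
        n_series=len(fitted),
    )


def remove_isotopologues(
    spec: SampleSpectrum,
    delta: float = C13_DELTA,
    tol_ppm: float = 1.0,
    ratio_max: float = 0.65,
) -> SampleSpectrum:
    """Drop 13C isotopologue peaks.

    A peak is removed when a retained peak sits one 13C-12C mass difference
    below it (within tolerance) and its intensity is below ``ratio_max``
    times that parent's intensity.  Parents are always retained; scanning
    ascending guarantees a parent is judged before its partner.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    mz, inten = spec.mz, spec.intensity
    keep = np.ones(len(spec), dtype=bool)
    for j in range(len(spec)):
        target = mz[j] - delta
        tol = mz[j] * tol_ppm * 1e-6
        lo = np.searchsorted(mz, target - tol)
        hi = np.searchsorted(mz, target + tol, side="right")
        for i in range(lo, hi):
            if keep[i] and inten[j] < ratio_max * inten[i]:
                keep[j] = False
                break
    return spec._with_mask(keep)


def subtract_blanks(
    samples: list[SampleSpectrum],
    blanks: list[SampleSpectrum],
    tol_ppm: float = 1.0,
) -> list[SampleSpectrum]:
    """Remove sample peaks that match any blank peak within tolerance."""
    blank_mz = np.sort(np.concatenate([b.mz for b in blanks])) if blanks else np.array([])
    if blank_mz.size == 0:
        logger.warning("blank subtraction skipped: no blank peaks provided")
        return list(samples)
    out = []
    for spec in samples:
        mz = spec.mz
        idx = np.searchsorted(blank_mz, mz)
        tol = mz * tol_ppm * 1e-6
        near_lo = np.abs(blank_mz[np.clip(idx - 1, 0, blank_mz.size - 1)] - mz) <= tol
        near_hi = np.abs(blank_mz[np.clip(idx, 0, blank_mz.size - 1)] - mz) <= tol
        out.append(spec._with_mask(~(near_lo | near_hi)))
    return out


@dataclass
class AlignedPeakTable:
    """Consensus m/z bins x samples intensity table from cross-sample alignment."""

    table: pd.DataFrame  # index: consensus m/z; columns: sample ids
    tol_ppm: float
    n_bins_total: int
    n_bins_retained: int

    @property
    def consensus_mz(self) -> np.ndarray:
        return self.table.index.to_numpy()


def align_and_prevalence_filter(
    samples: list[SampleSpectrum],
    tol_ppm: float = 1.0,
    min_samples: int = 2,
) -> AlignedPeakTable:
    """Single-linkage alignment of peaks across samples, then prevalence filter.

    Peaks pooled over samples are chained into bins wherever consecutive
    sorted m/z values lie within ``tol_ppm``; each raw peak lands in exactly
    one bin.  Bins seen in fewer than ``min_samples`` distinct samples are
    dropped.  When one sample contributes several peaks to one bin the most
    intense is kept, ties broken toward lower m/z.
    """
    if len(samples) < 2:
        raise ValueError("alignment requires at least 2 samples")
    frames = []
    for spec in samples:
        df = spec.peaks[["mz", "intensity"]].copy()
        df["sample_id"] = spec.sample_id
        frames.append(df)
    pool = pd.concat(frames, ignore_index=True).sort_values(
        ["mz", "sample_id"], kind="mergesort").reset_index(drop=True)
    if pool.empty:
        empty = pd.DataFrame(index=pd.Index([], name="mz"),
                             columns=[s.sample_id for s in samples], dtype=float)
        return AlignedPeakTable(empty, tol_ppm, 0, 0)

    mz = pool["mz"].to_numpy()
    gap = np.diff(mz)
    new_bin = np.concatenate([[True], gap > mz[:-1] * tol_ppm * 1e-6])
    bin_id = np.cumsum(new_bin) - 1
    pool["bin"] = bin_id

    # within (bin, sample): keep the most intense peak; ties toward lower mz
    pool = pool.sort_values(["bin", "sample_id", "intensity", "mz"],
                            ascending=[True, True, False, True], kind="mergesort")
    dup = pool.duplicated(["bin", "sample_id"])
    if dup.any():
        logger.warning("alignment: %d peaks merged into bins already holding a "
                       "peak from the same sample (tolerance may be too wide)",
                       int(dup.sum()))
    pool = pool[~dup]

    consensus = pool.groupby("bin")["mz"].mean()
    wide = pool.pivot(index="bin", columns="sample_id", values="intensity")
    wide = wide.reindex(columns=[s.sample_id for s in samples])
    wide.index = pd.Index(consensus.loc[wide.index], name="mz")

    n_total = len(wide)
    prevalence = wide.notna().sum(axis=1)
    wide = wide[prevalence >= min_samples]
    return AlignedPeakTable(wide, tol_ppm, n_total, len(wide))


def normalize_intensities(table: AlignedPeakTable, method: str = "zscore") -> AlignedPeakTable:
    """Z-score each feature over the samples where it is present.

    Missing entries stay missing, so downstream presence/absence analysis is
    unaffected.  Zero-variance features normalize to 0 with a warning.
    """
    if method != "zscore":
        raise ValueError(f"unknown normalization method {method!r}")
    values = table.table.to_numpy(dtype=float)
    out = np.full_like(values, np.nan)
    n_constant = 0
    for i, row in enumerate(values):
        present = ~np.isnan(row)
        if present.sum() < 2:
            raise ValueError("normalization requires >= 2 non-missing values per feature")
        sd = row[present].std()
        if sd == 0:
            out[i, present] = 0.0
            n_constant += 1
        else:
            out[i, present] = (row[present] - row[present].mean()) / sd
    if n_constant:
        logger.warning("normalization: %d zero-variance features set to 0", n_constant)
    norm = table.table.copy()
    norm.loc[:, :] = out
    return replace(table, table=norm)
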