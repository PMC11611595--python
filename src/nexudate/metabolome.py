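"""N-centric descriptors of the assigned exudate metabolome.

Works on a binary molecules x samples presence matrix with formula and
design metadata: relative abundance of N-containing molecules and its
drought response ratio, elemental-class proportions, occurrence-weighted
element totals with mass C:N, molecular-weight binning and kernel
densities, Venn partitions between treatments, and selection of molecules
important to the drought response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .formulas import MolecularFormula, ELEMENTAL_CLASSES, classify_elemental, AVG_C, AVG_N

logger = logging.getLogger(__name__)

LMW_RANGE = (200.0, 600.0)
HMW_RANGE = (600.0, 900.0)


@dataclass
class MoleculeMatrix:
    """Binary presence of assigned molecules across samples.

    ``presence``: DataFrame (index molecule ids, columns sample ids) in {0,1}.
    ``molecules``: per-molecule metadata (formula object, mz, elemental class,
    element counts).  ``samples``: per-sample design (treatment, day, phase).
    """

    presence: pd.DataFrame
    molecules: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.presence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence entries must be 0 or 1")
        if not self.presence.index.equals(self.molecules.index):
            raise ValueError("presence rows must match molecule metadata index")
        if list(self.presence.columns) != list(self.samples.index):
            raise ValueError("presence columns must match sample metadata index")
        if "formula" not in self.molecules.columns:
            raise ValueError("molecule metadata must carry a 'formula' column")

    @classmethod
    def build(cls, presence: pd.DataFrame, formulas: dict,
              mz: dict, design: pd.DataFrame) -> "MoleculeMatrix":
        """Assemble from a presence frame, formula/mz maps and a design table."""
        mols = pd.DataFrame(index=presence.index)
        mols["formula"] = [formulas[i] for i in presence.index]
        mols["mz"] = [mz[i] for i in presence.index]
        mols["elemental_class"] = [classify_elemental(f) for f in mols["formula"]]
        for el in ("c", "n"):
            mols[el] = [getattr(f, el) for f in mols["formula"]]
        samp = design.set_index("sample_id").loc[list(presence.columns)]
        return cls(presence.astype(int), mols, samp)

    @property
    def n_containing(self) -> pd.Series:
        return self.molecules["n"] > 0

    def subset_samples(self, mask: pd.Series) -> "MoleculeMatrix":
        cols = self.samples.index[mask]
        return MoleculeMatrix(self.presence[cols], self.molecules,
                              self.samples.loc[cols])


def presence_absence(intensity_table: pd.DataFrame) -> pd.DataFrame:
    """Binary presence from an intensity table: 1 iff intensity > 0 and present."""
    vals = intensity_table.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative intensities are invalid")
    out = pd.DataFrame(((~np.isnan(vals)) & (vals > 0)).astype(int),
                       index=intensity_table.index, columns=intensity_table.columns)
    return out


def relative_abundance(matrix: MoleculeMatrix, sample_id: str) -> float:
    """Percent of a sample's present molecules that contain N."""
    col = matrix.presence[sample_id]
    total = int(col.sum())
    if total == 0:
        logger.warning("%s: no molecules present; RA undefined", sample_id)
        return float("nan")
    n_count = int(col[matrix.n_containing].sum())
    return 100.0 * n_count / total


def relative_abundance_table(matrix: MoleculeMatrix) -> pd.DataFrame:
    """Per-sample RA with treatment/day metadata."""
    rows = [{"sample_id": sid,
             "RA": relative_abundance(matrix, sid),
             "treatment": matrix.samples.loc[sid, "treatment"],
             "day": matrix.samples.loc[sid, "day"],
             "phase": matrix.samples.loc[sid, "phase"]}
            for sid in matrix.presence.columns]
    return pd.DataFrame(rows)


def response_ratio(ra_drought: float, ra_control: float) -> float:
    """Drought response ratio: 100 x (RA_d - RA_c) / RA_d.

    Positive values mean drought-enriched N metabolome.  Undefined (NaN)
    when RA_drought is 0, since the ratio normalizes by the drought RA.
    """
    if np.isnan(ra_drought) or ra_drought == 0:
        logger.warning("response ratio undefined for RA_drought=%s", ra_drought)
        return float("nan")
    return 100.0 * (ra_drought - ra_control) / ra_drought


def response_ratio_series(matrix: MoleculeMatrix) -> pd.DataFrame:
    """Day-level response-ratio time series.

    Per-sample RA values are averaged by day and treatment first, then the
    drought mean is normalized against the control mean for each day.
    """
    ra = relative_abundance_table(matrix)
    day_means = ra.groupby(["day", "treatment"])["RA"].mean().unstack("treatment")
    out = pd.DataFrame({
        "RA_control": day_means["control"],
        "RA_drought": day_means["drought"],
        "response_ratio": [response_ratio(d, c) for d, c in
                           zip(day_means["drought"], day_means["control"])],
    }).reset_index()
    out["phase"] = [matrix.samples.loc[matrix.samples["day"] == d, "phase"].iloc[0]
                    for d in out["day"]]
    return out


def class_proportions(matrix: MoleculeMatrix, sample_id: str) -> pd.Series:
    """Proportion of a sample's present molecules in each elemental class."""
    col = matrix.presence[sample_id]
    total = int(col.sum())
    if total == 0:
        logger.warning("%s: empty sample; class proportions undefined", sample_id)
        return pd.Series(np.nan, index=list(ELEMENTAL_CLASSES))
    counts = matrix.molecules.loc[col == 1, "elemental_class"].value_counts()
    props = counts.reindex(ELEMENTAL_CLASSES, fill_value=0) / total
    return props.astype(float)


def class_proportion_table(matrix: MoleculeMatrix) -> pd.DataFrame:
    """Samples x elemental-class proportion table (rows sum to 1)."""
    rows = {sid: class_proportions(matrix, sid) for sid in matrix.presence.columns}
    return pd.DataFrame(rows).T.loc[list(matrix.presence.columns)]


def mass_cn_ratio(sum_c_atoms: int, sum_n_atoms: int) -> float:
    """Mass-based C:N from summed atom counts, (C x 12.011) / (N x 14.007)."""
    if sum_n_atoms <= 0:
        return float("nan")
    return (sum_c_atoms * AVG_C) / (sum_n_atoms * AVG_N)


def element_totals(matrix: MoleculeMatrix,
                   group_by: tuple = ("phase", "treatment")) -> pd.DataFrame:
    """Occurrence-weighted molecule and element counts with mass C:N.

    A molecule is counted once per sample in which it is present, so group
    totals far exceed distinct-molecule counts.  Mass C:N uses average
    atomic masses (C 12.011, N 14.007).  A grand-total row is appended.
    """
    if matrix.presence.size == 0:
        raise ValueError("empty matrix")
    occ = matrix.presence.T  # samples x molecules
    meta = matrix.samples
    keys = list(group_by)
    rows = []

    def _row(label: dict, block: pd.DataFrame) -> dict:
        counts = block.sum(axis=0)  # per-molecule occurrence counts
        n_mask = matrix.n_containing
        sum_c = int((counts * matrix.molecules["c"]).sum())
        sum_n = int((counts * matrix.molecules["n"]).sum())
        cn = mass_cn_ratio(sum_c, sum_n)
        return {**label,
                "molecules_N": int(counts[n_mask].sum()),
                "molecules_all": int(counts.sum()),
                "atoms_N": sum_n, "atoms_C": sum_c,
                "mass_CN": cn}

    for label_vals, idx in meta.groupby(keys, sort=True).groups.items():
        if not isinstance(label_vals, tuple):
            label_vals = (label_vals,)
        rows.append(_row(dict(zip(keys, label_vals)), occ.loc[idx]))
    rows.append(_row({k: "total" for k in keys}, occ))
    return pd.DataFrame(rows)


def mw_bin(deprotonated_mz: float) -> str:
    """LMW ([200, 600)) or HMW ([600, 900]) bin of a molecular mass."""
    if not LMW_RANGE[0] <= deprotonated_mz <= HMW_RANGE[1]:
        raise ValueError(f"mass {deprotonated_mz} outside [200, 900]")
    return "LMW" if deprotonated_mz < LMW_RANGE[1] else "HMW"


def mw_density(matrix: MoleculeMatrix,
               group_by: tuple = ("phase", "treatment"),
               grid: np.ndarray | None = None) -> pd.DataFrame:
    """Occurrence-weighted Gaussian kernel density of N-molecule masses.

    One density per group (Silverman bandwidth), evaluated on a shared mass
    grid; each N-containing molecule is weighted by the number of group
    samples where it is present.  Groups with fewer than 2 distinct masses
    are skipped as missing.
    """
    if grid is None:
        grid = np.linspace(200.0, 900.0, 701)
    n_mask = matrix.n_containing
    masses = matrix.molecules.loc[n_mask, "mz"].to_numpy(dtype=float)
    frames = []
    for label_vals, idx in matrix.samples.groupby(list(group_by), sort=True).groups.items():
        if not isinstance(label_vals, tuple):
            label_vals = (label_vals,)
        weights = matrix.presence.loc[n_mask, idx].sum(axis=1).to_numpy(dtype=float)
        sel = weights > 0
        if np.unique(masses[sel]).size < 2:
            logger.warning("mw_density: group %s has < 2 masses; skipped", label_vals)
            continue
        kde = gaussian_kde(masses[sel], bw_method="silverman", weights=weights[sel])
        frames.append(pd.DataFrame({
            **dict(zip(group_by, [[v] * len(grid) for v in label_vals])),
            "mass": grid, "density": kde(grid)}))
    if not frames:
        return pd.DataFrame(columns=[*group_by, "mass", "density"])
    return pd.concat(frames, ignore_index=True)


def venn_partition(matrix: MoleculeMatrix, phase: str,
                   factor: str = "treatment",
                   n_only: bool = True) -> dict[str, set]:
    """Unique/shared molecule-id partition between two factor levels in a phase."""
    sub = matrix.subset_samples(matrix.samples["phase"] == phase)
    levels = sorted(sub.samples[factor].unique())
    if len(levels) != 2:
        raise ValueError(f"venn partition needs exactly 2 levels of {factor!r} "
                         f"in phase {phase!r}, found {levels}")
    if n_only:
        sub = MoleculeMatrix(sub.presence.loc[sub.n_containing],
                             sub.molecules.loc[sub.n_containing], sub.samples)
    sets = {}
    for lv in levels:
        cols = sub.samples.index[sub.samples[factor] == lv]
        sets[lv] = set(sub.presence.index[sub.presence[cols].sum(axis=1) > 0])
    a, b = levels
    return {f"unique_{a}": sets[a] - sets[b],
            f"unique_{b}": sets[b] - sets[a],
            "shared": sets[a] & sets[b]}


def select_important(matrix: MoleculeMatrix, unique_set: set,
                     phase: str = "treatment", treatment: str = "drought",
                     min_days: int = 3, min_occurrence: int = 5) -> list:
    """Molecules important to the drought response.

    From a unique set, keep molecules present on at least ``min_days``
    distinct days of the phase and detected in at least ``min_occurrence``
    samples overall within that phase and treatment.
    """
    unknown = unique_set - set(matrix.presence.index)
    if unknown:
        raise ValueError(f"unique_set ids not in matrix: {sorted(unknown)[:5]}")
    meta = matrix.samples
    cols = meta.index[(meta["phase"] == phase) & (meta["treatment"] == treatment)]
    selected = []
    for mol in sorted(unique_set):
        row = matrix.presence.loc[mol, cols]
        present_cols = row[row == 1].index
        days = meta.loc[present_cols, "day"].nunique()
        occurrences = int(row.sum())
        if days >= min_days and occurrences >= min_occurrence:
            selected.append(mol)
    return selected


def important_molecule_table(matrix: MoleculeMatrix, selected: list,
                             phase: str = "treatment",
                             treatment: str = "drought") -> pd.DataFrame:
    """Report table for selected molecules: mass, formula, days, occurrence."""
    meta = matrix.samples
    cols = meta.index[(meta["phase"] == phase) & (meta["treatment"] == treatment)]
    rows = []
    for mol in selected:
        row = matrix.presence.loc[mol, cols]
        present_cols = row[row == 1].index
        rows.append({"mass_amu": round(float(matrix.molecules.loc[mol, "mz"]), 2),
                     "formula": str(matrix.molecules.loc[mol, "formula"]),
                     "days_present": int(meta.loc[present_cols, "day"].nunique()),
                     "occurrence": int(row.sum())})
    return pd.DataFrame(rows).sort_values("mass_amu").reset_index(drop=True) \
        if rows else pd.DataFrame(columns=["mass_amu", "formula", "days_present", "occurrence"])


def kegg_map(molecules: pd.DataFrame, annotator=None) -> pd.DataFrame:
    """Pathway-database mapping hook.

    N-containing exudate molecules have no database matches in this
    workflow; without an external annotator the stub returns an empty
    match table with the expected columns.
    """
    if annotator is not None:
        return annotator(molecules)
    return pd.DataFrame(columns=["molecule_id", "pathway", "match"])
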