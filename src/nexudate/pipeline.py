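"""End-to-end orchestration: QC -> formula assignment -> N metabolome -> stats.

A declarative YAML config names the input tables and every stage parameter;
each stage writes TSV/JSON artifacts into the output directory and logs its
counts, building a QC funnel (peaks detected -> after QC -> assigned ->
N-containing).  All randomness flows from one seed in the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import peaks as pk
from . import formulas as fm
from . import metabolome as mb
from . import quant as qt
from . import stats as st
from .simulate import SimulationConfig, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    dataset_dir: str = "dataset"
    output_dir: str = "results"
    snr_threshold: float = 7.0
    mz_low: float = 200.0
    mz_high: float = 900.0
    calibrate: bool = True
    min_series_length: int = 5
    iso_tol_ppm: float = 1.0
    iso_ratio_max: float = 0.65
    blank_tol_ppm: float = 1.0
    align_tol_ppm: float = 1.0
    min_samples: int = 2
    assign_tol_ppm: float = 1.0
    error_filter_ppm: float = 0.5
    n_perm: int = 999
    n_boot: int = 10000
    min_days: int = 3
    min_occurrence: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class FunnelReport:
    """Per-stage peak/molecule counts; must be non-increasing."""

    counts: dict = field(default_factory=dict)

    def record(self, stage: str, count: int) -> None:
        prior = list(self.counts.values())
        if prior and count > prior[-1]:
            raise ValueError(f"funnel violated at {stage}: {count} > {prior[-1]}")
        self.counts[stage] = int(count)
        logger.info("funnel: %-42s %d", stage, count)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


def _load_dataset(config: PipelineConfig):
    root = Path(config.dataset_dir)
    design = pd.read_csv(root / "design.tsv", sep="\t")
    samples, blanks = [], []
    meta = design.set_index("sample_id")
    for path in sorted((root / "peaks").glob("*.tsv")):
        sid = path.stem
        if sid.startswith("blank"):
            blanks.append(pk.read_peak_table(path, sample_id=sid))
        else:
            md = meta.loc[sid].to_dict() if sid in meta.index else {}
            samples.append(pk.read_peak_table(path, sample_id=sid, metadata=md))
    quant_path = root / "quant.tsv"
    quant = pd.read_csv(quant_path, sep="\t") if quant_path.exists() else None
    return samples, blanks, design, quant


def run_qc(samples, blanks, config: PipelineConfig, funnel: FunnelReport
           ) -> pk.AlignedPeakTable:
    """Calibration, filters, isotopologue removal, blank subtraction, alignment."""
    funnel.record("peaks detected", sum(len(s) for s in samples))
    processed, models = [], []
    for spec in samples:
        try:
            if config.calibrate:
                spec, model = pk.calibrate_internal(
                    spec, min_series_length=config.min_series_length)
                models.append(model)
            spec = pk.filter_snr(spec, config.snr_threshold)
            spec = pk.filter_mz_window(spec, config.mz_low, config.mz_high)
            spec = pk.remove_isotopologues(
                spec, tol_ppm=config.iso_tol_ppm, ratio_max=config.iso_ratio_max)
            processed.append(spec)
        except Exception as exc:  # noqa: BLE001 - annotate failing sample
            raise PipelineError("qc", f"sample {spec.sample_id}: {exc}") from exc
    # blanks share the instrument session: correct them with the consensus
    # model (they carry no homologous series of their own)
    if config.calibrate and models:
        session = pk.median_calibration(models)
        blanks = [pk.apply_calibration(b, session) for b in blanks]
    processed = pk.subtract_blanks(processed, blanks, config.blank_tol_ppm)
    funnel.record("peaks after QC including blank removal",
                  sum(len(s) for s in processed))
    aligned = pk.align_and_prevalence_filter(
        processed, config.align_tol_ppm, config.min_samples)
    funnel.record("aligned bins in >= 2 samples", aligned.n_bins_retained)
    return aligned


def run_assignment(aligned: pk.AlignedPeakTable, config: PipelineConfig,
                   funnel: FunnelReport) -> pd.DataFrame:
    """Per-bin CHNOSP formula assignment; returns the assignment table."""
    rows = []
    for mz in aligned.consensus_mz:
        a = fm.assign_formula(mz, config.assign_tol_ppm,
                              error_filter_ppm=config.error_filter_ppm)
        rows.append({"mz": mz, "neutral_mass": a.neutral_mass,
                     "formula": str(a.formula) if a.assigned else "",
                     "error_ppm": a.error_ppm,
                     "elemental_class": a.elemental_class or "",
                     "assigned": a.assigned})
    table = pd.DataFrame(rows)
    funnel.record("molecules assigned molecular formula", int(table["assigned"].sum()))
    n_count = int(((table["elemental_class"] != "nonN")
                   & (table["elemental_class"] != "")).sum())
    funnel.record("assigned molecules containing N", n_count)
    return table


def build_matrix(aligned: pk.AlignedPeakTable, assignments: pd.DataFrame,
                 design: pd.DataFrame) -> mb.MoleculeMatrix:
    """Presence matrix over assigned bins only."""
    assigned = assignments[assignments["assigned"]].reset_index(drop=True)
    ids = [f"bin{i:05d}" for i in range(len(assigned))]
    inten = aligned.table.loc[assigned["mz"].to_numpy()]
    inten.index = ids
    presence = mb.presence_absence(inten.fillna(0.0))
    formulas = {i: fm.MolecularFormula.parse(f)
                for i, f in zip(ids, assigned["formula"])}
    mz = dict(zip(ids, assigned["mz"]))
    design = design[design["sample_id"].isin(presence.columns)]
    presence = presence[list(design["sample_id"])]
    return mb.MoleculeMatrix.build(presence, formulas, mz, design)


def run_metabolome(matrix: mb.MoleculeMatrix, config: PipelineConfig, outdir: Path) -> dict:
    """N-metabolome descriptors; writes the descriptor tables."""
    ra = mb.relative_abundance_table(matrix)
    rr = mb.response_ratio_series(matrix)
    props = mb.class_proportion_table(matrix)
    totals = mb.element_totals(matrix)
    density = mb.mw_density(matrix)
    venn = mb.venn_partition(matrix, "treatment")
    selected = mb.select_important(
        matrix, venn["unique_drought"],
        min_days=config.min_days, min_occurrence=config.min_occurrence)
    important = mb.important_molecule_table(matrix, selected)

    ra.to_csv(outdir / "relative_abundance.tsv", sep="\t", index=False)
    rr.to_csv(outdir / "response_ratio.tsv", sep="\t", index=False)
    props.to_csv(outdir / "class_proportions.tsv", sep="\t")
    totals.to_csv(outdir / "element_totals.tsv", sep="\t", index=False)
    density.to_csv(outdir / "mw_density.tsv", sep="\t", index=False)
    important.to_csv(outdir / "important_molecules.tsv", sep="\t", index=False)
    with open(outdir / "venn.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in venn.items()}, fh, indent=1)
    return {"ra": ra, "response_ratio": rr, "proportions": props,
            "totals": totals, "venn": venn, "important": important}


def run_stats(matrix: mb.MoleculeMatrix, props: pd.DataFrame,
              quant: pd.DataFrame | None, config: PipelineConfig,
              outdir: Path) -> dict:
    """PERMANOVA per phase, PCA of class proportions, quant tests, KS of masses."""
    out: dict = {}

    # per-phase PERMANOVA of the N metabolome (binary Bray-Curtis)
    permanova_frames = []
    for phase, terms in (("baseline", ("treatment",)),
                         ("treatment", ("treatment", "day", "treatment:day")),
                         ("recovery", ("treatment", "day", "treatment:day"))):
        sub = matrix.subset_samples(matrix.samples["phase"] == phase)
        nsub = mb.MoleculeMatrix(sub.presence.loc[sub.n_containing],
                                 sub.molecules.loc[sub.n_containing], sub.samples)
        terms_use = terms if nsub.samples["day"].nunique() > 1 else ("treatment",)
        dist = st.bray_curtis_binary(nsub.presence)
        try:
            res = st.permanova(dist, nsub.samples.reset_index(), terms=terms_use,
                               n_perm=config.n_perm, seed=config.seed)
        except ValueError as exc:
            logger.warning("PERMANOVA skipped for phase %s: %s", phase, exc)
            continue
        res.insert(0, "phase", phase)
        permanova_frames.append(res)
    out["permanova"] = (pd.concat(permanova_frames, ignore_index=True)
                        if permanova_frames else
                        pd.DataFrame(columns=["phase", "term", "df", "SS",
                                              "R2", "F", "p_value"]))
    out["permanova"].to_csv(outdir / "permanova.tsv", sep="\t", index=False)

    # PCA of elemental-class proportions with treatment/phase supplementary
    pca = st.pca_squared_cosines(props, matrix.samples[["treatment", "phase"]])
    pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    pca.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
    pca.squared_cosines.to_csv(outdir / "pca_squared_cosines.tsv", sep="\t")
    out["pca"] = pca

    # KS of N-containing molecular masses between treatments, per phase
    ks_rows = []
    n_mask = matrix.n_containing
    masses = matrix.molecules.loc[n_mask, "mz"]
    for phase in ("baseline", "treatment", "recovery"):
        cols = matrix.samples.index[matrix.samples["phase"] == phase]
        vals = {}
        for trt in ("control", "drought"):
            tc = [c for c in cols if matrix.samples.loc[c, "treatment"] == trt]
            occ = matrix.presence.loc[n_mask, tc].sum(axis=1)
            vals[trt] = np.repeat(masses[occ > 0].to_numpy(), occ[occ > 0])
        if min(len(vals["control"]), len(vals["drought"])) == 0:
            continue
        res = st.ks_two_sample(vals["control"], vals["drought"], mode="asymptotic")
        ks_rows.append({"phase": phase, "D": res.statistic, "p_value": res.p_value})
    out["ks"] = pd.DataFrame(ks_rows)
    out["ks"].to_csv(outdir / "ks_masses.tsv", sep="\t", index=False)

    # quantitative bootstrap tests with BH adjustment per timepoint
    if quant is not None and not quant.empty:
        bal = qt.balance_table(quant)
        rows = []
        for phase in bal["phase"].dropna().unique():
            sub = bal[bal["phase"] == phase]
            pvals, keys = [], []
            for analyte in ("TOC_mass", "TON_mass", "specific_TON", "AA_N_conc"):
                x = sub.loc[sub["treatment"] == "drought", analyte].dropna()
                y = sub.loc[sub["treatment"] == "control", analyte].dropna()
                if len(x) < 2 or len(y) < 2:
                    continue
                res = st.bootstrap_t_test(x, y, n_boot=config.n_boot, seed=config.seed)
                pvals.append(res.p_value)
                keys.append({"phase": phase, "analyte": analyte,
                             "statistic": res.statistic, "p_value": res.p_value})
            for rec, adj in zip(keys, st.bh_adjust(pvals)):
                rec["p_adjusted"] = adj
                rows.append(rec)
        out["quant_tests"] = pd.DataFrame(rows)
        out["quant_tests"].to_csv(outdir / "quant_tests.tsv", sep="\t", index=False)
        bal.to_csv(outdir / "exudate_balance.tsv", sep="\t", index=False)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns in-memory results and writes artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_used.yaml")
    funnel = FunnelReport()

    samples, blanks, design, quant = _load_dataset(config)
    aligned = run_qc(samples, blanks, config, funnel)
    aligned.table.to_csv(outdir / "aligned_peaks.tsv", sep="\t")
    assignments = run_assignment(aligned, config, funnel)
    assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    matrix = build_matrix(aligned, assignments, design)
    met = run_metabolome(matrix, config, outdir)
    stats_out = run_stats(matrix, met["proportions"], quant, config, outdir)

    with open(outdir / "funnel.json", "w") as fh:
        json.dump(funnel.counts, fh, indent=1)
    logger.info("pipeline complete: %s", outdir)
    return {"funnel": funnel, "aligned": aligned, "assignments": assignments,
            "matrix": matrix, **met, **stats_out}


def simulate_dataset(sim_config: SimulationConfig, dataset_dir) -> Path:
    """Thin validated wrapper over the synthetic-data writer."""
    return write_dataset(sim_config, dataset_dir)
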