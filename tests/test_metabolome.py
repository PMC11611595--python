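"""N-metabolome descriptors on presence/absence matrices."""

import math

import numpy as np
import pandas as pd
import pytest

from nexudate import MoleculeMatrix, SimulationConfig, simulate_peak_tables
from nexudate.metabolome import (
    class_proportion_table,
    class_proportions,
    element_totals,
    important_molecule_table,
    kegg_map,
    mass_cn_ratio,
    mw_bin,
    mw_density,
    presence_absence,
    relative_abundance,
    relative_abundance_table,
    response_ratio,
    response_ratio_series,
    select_important,
    venn_partition,
)
from conftest import toy_matrix


# ----------------------------------------------------------- presence/absence

def test_presence_absence_thresholds():
    df = pd.DataFrame({"s1": [523.1, 0.0, np.nan]}, index=["a", "b", "c"])
    out = presence_absence(df)
    assert list(out["s1"]) == [1, 0, 0]
    # idempotence
    pd.testing.assert_frame_equal(presence_absence(out.astype(float)), out)
    with pytest.raises(ValueError):
        presence_absence(pd.DataFrame({"s1": [-1.0]}))


# ------------------------------------------------------------------------ RA

def test_relative_abundance_fraction(matrix):
    # s3: present m1 (N), m2 (N), m4 (N), m5 (nonN), m6 (N) -> 4/5
    assert relative_abundance(matrix, "s3") == pytest.approx(80.0)
    # abstract-level proportion: 1,616 N of 3,985 rounds to 41%
    assert round(100 * 1616 / 3985) == 41


def test_relative_abundance_bounds(matrix):
    ra = relative_abundance_table(matrix)["RA"]
    assert ((ra >= 0) & (ra <= 100)).all()


def test_response_ratio_cases():
    assert response_ratio(40.0, 40.0) == 0.0
    assert response_ratio(40.0, 30.0) == pytest.approx(25.0)
    assert math.isnan(response_ratio(0.0, 30.0))
    assert response_ratio(50.0, 80.0) < 0


def test_response_ratio_always_below_100(rng):
    for _ in range(200):
        d, c = rng.uniform(0.1, 100, size=2)
        assert response_ratio(d, c) < 100


def test_day_level_series(matrix):
    rr = response_ratio_series(matrix)
    assert list(rr["day"]) == [0, 2, 4, 14]
    # day 0: control RA from s0 {m1,m3,m5}=1/3, drought s1 {m1,m5,m6}=2/3
    # day 0: control s0 {m1, m3, m5} has 2 N-containing of 3; drought s1
    # {m1, m5, m6} likewise 2 of 3
    d0 = rr.set_index("day").loc[0]
    assert d0["RA_control"] == pytest.approx(200 / 3)
    assert d0["RA_drought"] == pytest.approx(200 / 3)
    assert d0["response_ratio"] == pytest.approx(0.0)


def test_boost_recovery_day11_exceeds_day0():
    """Injected treatment-phase enrichment shows up in the day-level series."""
    wins = 0
    n_runs = 30
    for seed in range(n_runs):
        cfg = SimulationConfig(seed=seed, formula_library_size=1000,
                               n_noise_peaks=0, drought_presence_boost=0.25)
        _, _, truth, design = simulate_peak_tables(cfg)
        mm = MoleculeMatrix.build(truth.presence_matrix(design),
                                  dict(truth.catalog), dict(truth.theoretical_mz),
                                  design)
        rr = response_ratio_series(mm).set_index("day")["response_ratio"]
        wins += rr[11] > rr[0]
    assert wins >= 0.95 * n_runs


# -------------------------------------------------------------------- classes

def test_class_proportions_partition(matrix):
    for sid in matrix.presence.columns:
        props = class_proportions(matrix, sid)
        assert props.sum() == pytest.approx(1.0, abs=1e-12)
        # reconstruction: proportions x total give integral counts
        total = int(matrix.presence[sid].sum())
        counts = props * total
        assert np.allclose(counts, np.round(counts), atol=1e-9)


def test_class_proportion_single_molecule():
    m = toy_matrix()
    sub = MoleculeMatrix(m.presence.loc[["m1"]], m.molecules.loc[["m1"]], m.samples)
    props = class_proportions(sub, "s0")
    assert props["CHON"] == 1.0 and props.drop("CHON").sum() == 0.0


# ------------------------------------------------------------- element totals

def test_mass_cn_ratio_single_molecule():
    assert mass_cn_ratio(10, 1) == pytest.approx(8.57, abs=0.01)
    assert math.isnan(mass_cn_ratio(10, 0))


def test_element_totals_additivity(matrix):
    totals = element_totals(matrix, group_by=("treatment",))
    by_group = totals[totals["treatment"] != "total"]
    grand = totals[totals["treatment"] == "total"].iloc[0]
    for col in ("molecules_N", "molecules_all", "atoms_N", "atoms_C"):
        assert by_group[col].sum() == grand[col]


def test_element_totals_occurrence_weighting(matrix):
    totals = element_totals(matrix).set_index(["phase", "treatment"])
    # baseline control = sample s0 with m1, m3, m5 present
    row = totals.loc[("baseline", "control")]
    assert row["molecules_all"] == 3
    assert row["atoms_C"] == 13 + 18 + 10
    assert row["atoms_N"] == 3 + 1


# ------------------------------------------------------------------- MW bins

def test_mw_bin_boundaries():
    assert mw_bin(599.99) == "LMW"
    assert mw_bin(600.0) == "HMW"
    assert mw_bin(266.15) == "LMW"
    assert mw_bin(900.0) == "HMW"
    with pytest.raises(ValueError):
        mw_bin(150.0)


def test_mw_density_normalized(matrix):
    # wide grid: with few masses the Silverman bandwidth is broad and the
    # Gaussian tails extend well beyond the detection window
    grid = np.linspace(-1000, 2100, 3101)
    dens = mw_density(matrix, group_by=("treatment",), grid=grid)
    for _, block in dens.groupby("treatment"):
        integral = np.trapezoid(block["density"], block["mass"])
        assert integral == pytest.approx(1.0, abs=1e-3)


def test_mw_density_detects_window_enrichment():
    cfg = SimulationConfig(seed=13, formula_library_size=200, n_noise_peaks=0,
                           drought_presence_boost=0.35)
    _, _, truth, design = simulate_peak_tables(cfg)
    mm = MoleculeMatrix.build(truth.presence_matrix(design),
                              dict(truth.catalog), dict(truth.theoretical_mz), design)
    treat = mm.subset_samples(mm.samples["phase"] == "treatment")
    grid = np.linspace(200, 900, 701)
    dens = mw_density(treat, group_by=("treatment",), grid=grid)
    in_win = ((grid >= 275) & (grid <= 390)) | ((grid >= 450) & (grid <= 550))
    mass_in = {trt: np.trapezoid(block["density"].to_numpy()[in_win], grid[in_win])
               for trt, block in dens.groupby("treatment")}
    assert mass_in["drought"] > mass_in["control"]


# ---------------------------------------------------------------------- Venn

def test_venn_partition_oracle(rng):
    m = toy_matrix()
    parts = venn_partition(m, "treatment")
    # brute-force set algebra over treatment-phase samples
    cols_d = [s for s in ("s3", "s5")]
    cols_c = [s for s in ("s2", "s4")]
    n_ids = m.presence.index[m.n_containing]
    seen_d = {i for i in n_ids if m.presence.loc[i, cols_d].any()}
    seen_c = {i for i in n_ids if m.presence.loc[i, cols_c].any()}
    assert parts["unique_drought"] == seen_d - seen_c
    assert parts["unique_control"] == seen_c - seen_d
    assert parts["shared"] == seen_d & seen_c
    # conservation
    union = parts["unique_drought"] | parts["unique_control"] | parts["shared"]
    assert len(union) == sum(len(v) for v in parts.values())


def test_venn_partition_degenerate_cases(matrix):
    identical = matrix.presence.copy()
    identical.loc[:, :] = 1
    m2 = MoleculeMatrix(identical, matrix.molecules, matrix.samples)
    parts = venn_partition(m2, "treatment", n_only=False)
    assert not parts["unique_drought"] and not parts["unique_control"]
    assert len(parts["shared"]) == 6


def test_venn_requires_two_levels(matrix):
    sub = matrix.subset_samples(matrix.samples["treatment"] == "control")
    with pytest.raises(ValueError):
        venn_partition(sub, "treatment")


# ---------------------------------------------------------- important molecules

def _selection_matrix(day_pattern):
    """One molecule present in drought treatment samples per day_pattern."""
    days = [2, 2, 4, 4, 7, 7, 9, 9, 11, 11]
    design = pd.DataFrame({
        "sample_id": [f"d{i}" for i in range(10)],
        "treatment": ["drought"] * 10,
        "day": days,
        "phase": ["treatment"] * 10,
    })
    from nexudate import MolecularFormula
    presence = pd.DataFrame([day_pattern], index=["m"],
                            columns=design["sample_id"])
    return MoleculeMatrix.build(
        presence, {"m": MolecularFormula.parse("C13H21O3N3")},
        {"m": 266.151}, design)


@pytest.mark.parametrize("pattern, expected", [
    ([1, 1, 1, 1, 1, 1, 1, 1, 1, 0], True),   # 5 days, 9 occurrences
    ([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], False),  # 2 days, 4 occurrences
    ([1, 1, 1, 1, 1, 1, 0, 0, 0, 0], True),   # 3 days, 6 occurrences
    ([1, 0, 1, 0, 1, 0, 1, 0, 0, 0], False),  # 4 days but 4 occurrences
])
def test_select_important_rules(pattern, expected):
    mm = _selection_matrix(pattern)
    selected = select_important(mm, {"m"})
    assert (selected == ["m"]) is expected


def test_important_molecule_table_layout():
    mm = _selection_matrix([1, 1, 1, 1, 1, 1, 1, 1, 1, 0])
    table = important_molecule_table(mm, ["m"])
    row = table.iloc[0]
    assert row["mass_amu"] == 266.15
    assert row["days_present"] == 5 and row["occurrence"] == 9


def test_kegg_stub_returns_no_matches(matrix):
    out = kegg_map(matrix.molecules)
    assert out.empty
    assert list(out.columns) == ["molecule_id", "pathway", "match"]
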