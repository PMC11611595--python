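import numpy as np
import pandas as pd
import pytest

from nexudate import MoleculeMatrix, MolecularFormula


def toy_matrix() -> MoleculeMatrix:
    """Hand-built 6-molecule x 8-sample presence matrix covering all classes."""
    formulas = {
        "m1": MolecularFormula.parse("C13H21O3N3"),   # CHON, LMW
        "m2": MolecularFormula.parse("C15H34O2N2S2"),  # CHON-S
        "m3": MolecularFormula.parse("C18H32O3NP"),    # CHON-P
        "m4": MolecularFormula.parse("C20H30O3N2SP"),  # CHON-SP
        "m5": MolecularFormula.parse("C10H12O5"),      # nonN
        "m6": MolecularFormula.parse("C40H60O8N2"),    # CHON, HMW
    }
    mz = {k: f.deprotonated_mz for k, f in formulas.items()}
    design = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(8)],
        "treatment": ["control", "drought"] * 4,
        "day": [0, 0, 2, 2, 4, 4, 14, 14],
        "phase": ["baseline"] * 2 + ["treatment"] * 4 + ["recovery"] * 2,
    })
    presence = pd.DataFrame(
        [[1, 1, 1, 1, 1, 1, 1, 1],   # m1 everywhere
         [0, 0, 0, 1, 0, 1, 0, 0],   # m2 drought treatment only
         [1, 0, 1, 0, 1, 0, 1, 0],   # m3 control only
         [0, 0, 1, 1, 0, 1, 0, 0],   # m4
         [1, 1, 1, 1, 1, 1, 1, 1],   # m5 everywhere
         [0, 1, 0, 1, 1, 1, 1, 1]],  # m6
        index=list(formulas), columns=design["sample_id"])
    return MoleculeMatrix.build(presence, formulas, mz, design)


@pytest.fixture
def matrix():
    return toy_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
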