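import math

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from glycogu.calibration import CalibrationCurve, LadderTable
from glycogu.io import ProteinRecord
from glycogu.retention import CoefficientTable


@pytest.fixture
def exact_curve():
    """A noiseless logarithmic calibration: rt = 2 + 3*ln(GU)."""
    return CalibrationCurve(
        intercept_a=2.0,
        slope_b=3.0,
        fit_rmse=0.0,
        n_rungs=14,
        source_runs=("synthetic",),
        rt_range=(2.0 + 3.0 * math.log(2), 2.0 + 3.0 * math.log(15)),
    )


@pytest.fixture
def exact_ladder():
    """Noiseless dextran ladder on the rt = 2 + 3*ln(GU) law, GU 2..15."""
    return LadderTable(
        run_label="exact",
        rungs=tuple((g, 2.0 + 3.0 * math.log(g)) for g in range(2, 16)),
    )


@pytest.fixture
def uniform_table():
    """Coefficient table: every residue 0.1 GU, intercept 1.0 GU,
    glycation +0.35 GU."""
    return CoefficientTable(
        residue_gu={r: 0.1 for r in "ACDEFGHIKLMNPQRSTVWY"},
        term_gu={"intercept": 1.0},
        modification_gu={"glycation": 0.35},
    )


@pytest.fixture
def toy_protein():
    return ProteinRecord(id="toy", sequence="MKAR")
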