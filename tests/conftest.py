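import numpy as np
import pytest

from thermoquant.io_formats import MeltCurveSet, _empty_annotations
from thermoquant.synthetic import (LigandSeriesScenario, MstScenario,
                                   gen_ligand_series, gen_mst_traces,
                                   two_state_plate_scenario, gen_dsf_plate)


@pytest.fixture(scope="session")
def small_plate():
    """12 two-state wells, 0.5% noise, with the scenario truth attached."""
    scenario = two_state_plate_scenario(n_wells=12, seed=11)
    return scenario, gen_dsf_plate(scenario)


@pytest.fixture(scope="session")
def ligand_series():
    """16-concentration coupled folding-binding titration (Kd = 2 uM)."""
    scenario = LigandSeriesScenario(seed=21)
    return scenario, gen_ligand_series(scenario)


@pytest.fixture(scope="session")
def mst_traces():
    """16-capillary MST trace set (Kd = 1 uM, 25 nM protein)."""
    scenario = MstScenario(seed=31)
    return scenario, gen_mst_traces(scenario)


def make_melt_set(seed: int, n_wells: int = 3, n_temps: int = 40) -> MeltCurveSet:
    """Random (but valid) melt set for round-trip tests."""
    rng = np.random.default_rng(seed)
    t = 290.0 + np.cumsum(rng.uniform(0.2, 1.5, n_temps))
    signals = rng.normal(1000.0, 200.0, (n_wells, n_temps))
    wells = [f"W{i}" for i in range(n_wells)]
    ann = _empty_annotations(wells)
    ann["condition"] = [f"cond{i}" for i in range(n_wells)]
    ann["ligand_conc_M"] = rng.uniform(0, 1e-4, n_wells)
    ann["replicate"] = ["r1"] * n_wells
    return MeltCurveSet(t, signals, wells, ann)
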