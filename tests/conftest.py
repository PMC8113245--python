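import numpy as np
import pytest

import tandemgpc as tg


@pytest.fixture(scope="session")
def fluor():
    return tg.load_preset("gpcv2-fluor")


@pytest.fixture(scope="session")
def attp():
    return tg.load_preset("attp-gpcv2-crispr")


@pytest.fixture(scope="session")
def crispr():
    return tg.load_preset("gpcv2-crispr")


@pytest.fixture(scope="session")
def fluor_schedule(fluor):
    """48 h windows with 12 h gaps: GIB[0,48], ABA[60,108], GIB[120,168]."""
    return tg.LigandSchedule.alternating(fluor.design.ligand_order(),
                                         stage_hours=48.0, gap_hours=12.0)


@pytest.fixture(scope="session")
def calib_params():
    """Calibration used for the headline cascade runs: 98.5% per-window
    completion (0.087/h over 48 h) and 5e-4/h leak."""
    return tg.KineticParams(excision_hazard=0.087, leak_hazard=5e-4)


@pytest.fixture(scope="session")
def cascade_run(fluor, fluor_schedule, calib_params):
    """The 10,000-cell full-schedule reference run shared across tests."""
    return tg.simulate_population(
        fluor.design, calib_params, fluor.pk, fluor.copy_model,
        fluor_schedule, n=10_000, seed=1)


def make_two_gpc_design(seed=7):
    """Small synthetic two-unit design used by several oracle tests."""
    return tg.random_design(seed, n_stages=2, version="v2")
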