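"""Shared fixtures: the baseline dialysis scenario and its expensive runs.

Session-scoped so that the seven modality simulations, the displacer
calibrations and the month-long schedules are computed once and shared by
the unit and acceptance tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from pbutkin import (
    NumericsConfig,
    PatientParams,
    Prescription,
    calibrate_displacer,
    initialize_patient,
    simulate_schedule,
    simulate_session,
)
from pbutkin.binding import SoluteDefinition, calibrate_binding
from pbutkin.circuit import DialyzerSpec, TubeSpec
from pbutkin.pharmacology import IBUPROFEN, TRYPTOPHAN

ALBUMIN_PL = 600e-6

TOXIN_DEFS = [
    SoluteDefinition("IS", 100e-6, 0.07, 213.21, generation_rate=0.02477),
    SoluteDefinition("pCS", 150e-6, 0.05, 188.20, generation_rate=0.02557),
]


@pytest.fixture(scope="session")
def solutes():
    return calibrate_binding(TOXIN_DEFS, ALBUMIN_PL)


@pytest.fixture(scope="session")
def params():
    return PatientParams()


@pytest.fixture(scope="session")
def patient(params, solutes):
    return initialize_patient(params, solutes)


@pytest.fixture(scope="session")
def dialyzer():
    return DialyzerSpec()


@pytest.fixture(scope="session")
def tube():
    return TubeSpec()


@pytest.fixture(scope="session")
def numerics():
    return NumericsConfig()


@pytest.fixture(scope="session")
def trp_drug(params, solutes, dialyzer, tube, numerics):
    """Tryptophan with self-consistently calibrated free elimination rate."""
    return calibrate_displacer(TRYPTOPHAN, params, solutes,
                               dialyzer=dialyzer, tube=tube, numerics=numerics)


@pytest.fixture(scope="session")
def ibu_drug(params, solutes, dialyzer, tube, numerics):
    return calibrate_displacer(IBUPROFEN, params, solutes,
                               dialyzer=dialyzer, tube=tube, numerics=numerics)


def _prescriptions(trp_drug, ibu_drug):
    return {
        "hd": Prescription(modality="hd"),
        "hdf_pre20": Prescription(modality="hdf_pre", replacement_volume=20.0),
        "hdf_post20": Prescription(modality="hdf_post", replacement_volume=20.0),
        "hdf_pre60": Prescription(modality="hdf_pre", replacement_volume=60.0),
        "adsorption": Prescription(modality="hd_adsorption"),
        "tryptophan": Prescription(modality="hd_displacer", drug=trp_drug),
        "ibuprofen": Prescription(modality="hd_displacer", drug=ibu_drug),
    }


@pytest.fixture(scope="session")
def modality_results(patient, params, solutes, dialyzer, tube, numerics,
                     trp_drug, ibu_drug):
    """Session results for all seven standard modalities."""
    out = {}
    for name, rx in _prescriptions(trp_drug, ibu_drug).items():
        out[name] = simulate_session(patient.copy(), rx, params, solutes,
                                     dialyzer, tube, numerics)
    return out


@pytest.fixture(scope="session")
def month_results(patient, params, solutes, dialyzer, tube, numerics, trp_drug):
    """One-month (28-day, thrice-weekly) HD and tryptophan-HD schedules."""
    out = {}
    for name, rx in {
        "hd": Prescription(modality="hd"),
        "tryptophan": Prescription(modality="hd_displacer", drug=trp_drug),
    }.items():
        out[name] = simulate_schedule(patient.copy(), rx, params, solutes,
                                      dialyzer=dialyzer, tube=tube,
                                      numerics=numerics)
    return out
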