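"""Shared fixtures: a synthetic recording generated by the model itself and
the linear system assembled from it (expensive; built once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from ionrep import (ConductanceRepertoireModel, ForcingProgram, Waveform,
                    build_linear_system, species_list, table2_repertoire)
from ionrep.synthetic import NoiseConfig, generate_waveforms


def pulse_train_injection(duration_ms: float = 6000.0,
                          amplitude: float = 0.9) -> Waveform:
    """Current pulses that evoke electrical activity in the generator."""
    t = np.arange(0.0, duration_ms, 1.0)
    i = np.where((t % 3000.0) < 300.0, amplitude, 0.0) * (t > 800.0)
    return Waveform(t, i, "pA")


@pytest.fixture(scope="session")
def synthetic_recording():
    """(v, ca, injected, kappa_true): a model-generated V/Ca pair."""
    inj = pulse_train_injection()
    kappa = table2_repertoire()
    v, ca, _ = generate_waveforms(kappa, ForcingProgram(injected=inj),
                                  duration_ms=6000.0, seed=3,
                                  noise=NoiseConfig())
    return v, ca, inj, kappa


@pytest.fixture(scope="session")
def linear_system(synthetic_recording):
    v, ca, inj, kappa = synthetic_recording
    specs = species_list(kappa.species)
    return build_linear_system(specs, v, ca, injected=inj)


@pytest.fixture(scope="session")
def fitted_results(synthetic_recording):
    v, ca, inj, kappa = synthetic_recording
    model = ConductanceRepertoireModel(v, ca, species=kappa.species,
                                       injected=inj)
    return model.fit()
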