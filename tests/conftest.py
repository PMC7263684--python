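"""Shared fixtures: noiseless flies, standard stimuli, small screens."""

import numpy as np
import pytest

from flyssvep import FlyParams, GenotypeEffect, StimulusSpec, Trace


@pytest.fixture
def spec12():
    """Standard 12 Hz, 1 s, 1 kHz stimulus at full contrast."""
    return StimulusSpec(f1=12.0, mean_level=0.5, contrast=1.0, duration=1.0, sample_rate=1000.0)


@pytest.fixture
def quiet_fly():
    return FlyParams(r_max_P=10.0, c50=0.3, hill_n=2.0, g_L=0.05, noise_sd=0.0)


@pytest.fixture
def null_effect():
    return GenotypeEffect(label="control")


def make_two_harmonic_trace(a1, a2, spec, phase1=0.0, phase2=0.0):
    """Noiseless two-harmonic trace with known amplitudes (test oracle input)."""
    t = spec.times()
    v = a1 * np.sin(2 * np.pi * spec.f1 * t + phase1) + a2 * np.sin(
        4 * np.pi * spec.f1 * t + phase2
    )
    return Trace(voltage_uv=v, spec=spec)


@pytest.fixture
def two_harmonic_trace(spec12):
    return make_two_harmonic_trace(5.0, 2.0, spec12)
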