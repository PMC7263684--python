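"""Contrast-flicker stimuli about a fixed mean light level.

The screen presents sinusoidal luminance flicker at a fixed mean level while
the Michelson contrast of the flicker is stepped across a series (10% to 100%
in the standard design). Because the mean is held constant, any change in the
response with contrast reflects the contrast response proper, not a change in
adaptation state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusSpec",
    "ContrastSeries",
    "make_contrast_series",
    "synthesize_stimulus",
]

#: Default stimulus fundamental (Hz). The pipeline is frequency-agnostic;
#: every downstream stage reads f1 from the StimulusSpec it is given.
DEFAULT_F1 = 12.0


@dataclass(frozen=True)
class StimulusSpec:
    """One flicker stimulus: L(t) = mean_level * (1 + contrast * sin(2*pi*f1*t)).

    Parameters
    ----------
    f1 : float
        Fundamental flicker frequency in Hz.
    mean_level : float
        Mean luminance, normalized to [0, 1].
    contrast : float
        Michelson contrast fraction in [0, 1].
    duration : float
        Epoch duration in seconds. ``f1 * duration`` must be a whole number
        of cycles so harmonic bins land exactly on the FFT grid.
    sample_rate : float
        Sampling rate in Hz; must exceed 4*f1 so the second harmonic is
        resolved.
    """

    f1: float = DEFAULT_F1
    mean_level: float = 0.5
    contrast: float = 1.0
    duration: float = 1.0
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError(f"contrast must be in [0, 1], got {self.contrast}")
        if self.mean_level * (1.0 + self.contrast) > 1.0 + 1e-12:
            raise ValueError(
                "stimulus would clip: mean_level*(1+contrast) = "
                f"{self.mean_level * (1.0 + self.contrast):g} > 1"
            )
        n_cycles = self.f1 * self.duration
        if abs(n_cycles - round(n_cycles)) > 1e-9:
            raise ValueError(
                f"f1*duration must be an integer number of cycles, got {n_cycles}"
            )
        if self.sample_rate <= 4.0 * self.f1:
            raise ValueError(
                f"sample_rate {self.sample_rate} must exceed 4*f1 = {4 * self.f1}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def times(self) -> np.ndarray:
        """Sample times in seconds (endpoint excluded)."""
        return np.arange(self.n_samples) / self.sample_rate

    def replace(self, **kwargs) -> "StimulusSpec":
        d = asdict(self)
        d.update(kwargs)
        return StimulusSpec(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "StimulusSpec":
        d = json.loads(s)
        extra = set(d) - {"f1", "mean_level", "contrast", "duration", "sample_rate"}
        if extra:
            raise ValueError(f"unknown StimulusSpec fields: {sorted(extra)}")
        return cls(**d)


@dataclass(frozen=True)
class ContrastSeries:
    """Strictly increasing series of Michelson contrast fractions."""

    contrasts: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.contrasts, dtype=float)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("contrasts must be a nonempty 1-D sequence")
        if np.any(c < 0.0) or np.any(c > 1.0):
            raise ValueError("all contrasts must lie in [0, 1]")
        if np.any(np.diff(c) <= 0.0):
            raise ValueError("contrasts must be strictly increasing")
        object.__setattr__(self, "contrasts", tuple(float(x) for x in c))

    def __len__(self) -> int:
        return len(self.contrasts)

    def __iter__(self):
        return iter(self.contrasts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.contrasts, dtype=float)


def make_contrast_series(n: int = 9, c_min: float = 0.10, c_max: float = 1.00) -> ContrastSeries:
    """Equally spaced contrast series including both endpoints.

    Defaults match the screen design: 9 contrasts from 10% to 100%.
    """
    if n < 2:
        raise ValueError(f"need at least 2 contrasts, got n={n}")
    if not (0.0 <= c_min < c_max <= 1.0):
        raise ValueError(f"require 0 <= c_min < c_max <= 1, got [{c_min}, {c_max}]")
    return ContrastSeries(tuple(np.linspace(c_min, c_max, n)))


def synthesize_stimulus(spec: StimulusSpec) -> np.ndarray:
    """Sampled luminance waveform L(t) = mean_level*(1 + contrast*sin(2*pi*f1*t)).

    The sample mean equals ``mean_level`` (the flicker is a whole number of
    cycles, so the sine averages to zero) and the Michelson contrast
    (max-min)/(max+min) equals ``spec.contrast``.
    """
    t = spec.times()
    return spec.mean_level * (1.0 + spec.contrast * np.sin(2.0 * np.pi * spec.f1 * t))


def stimulus_to_csv(spec: StimulusSpec, path) -> None:
    """Export a synthesized waveform as two-column CSV (time_s, luminance)."""
    import pandas as pd

    t = spec.times()
    pd.DataFrame({"time_s": t, "luminance": synthesize_stimulus(spec)}).to_csv(
        path, index=False, float_format="%.9g"
    )
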