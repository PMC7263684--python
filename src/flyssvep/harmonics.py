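"""Harmonic decomposition of voltage traces.

Each epoch is Fourier-transformed (rectangular window — the stimulus epochs
are cut to a whole number of cycles, so there is no leakage) and the
response is read off at the stimulus fundamental (1F1, photoreceptor
component) and at twice it (2F1, lamina-neuron component).  Repeats are
averaged on amplitude spectra by default (incoherent averaging, robust to
phase drift between presentations); a coherent complex-mean mode is
available.  Higher harmonics are not analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .synthetic import Trace

__all__ = [
    "AmplitudeSpectrum",
    "HarmonicMeasure",
    "amplitude_spectrum",
    "average_repeats",
    "extract_harmonics",
]

#: Bins averaged on each side of a harmonic when estimating its noise floor.
NOISE_FLOOR_K = 5


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided amplitude spectrum of an epoch (or average of epochs).

    ``amps[i]`` is the peak amplitude (uV) attributable to frequency
    ``freqs[i]``: a pure sinusoid of peak amplitude A contributes A to its
    bin, and the DC bin carries the signal mean.  ``complex_amps`` retains
    the scaled complex FFT coefficients so that coherent (phase-preserving)
    averaging remains possible; it is None after incoherent averaging.
    """

    freqs: np.ndarray
    amps: np.ndarray
    duration: float
    n_averaged: int = 1
    complex_amps: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.freqs.shape != self.amps.shape:
            raise ValueError("freqs and amps must have the same shape")
        if np.any(self.amps < 0):
            raise ValueError("amplitudes must be nonnegative")

    @property
    def df(self) -> float:
        """Frequency resolution in Hz (1/duration)."""
        return 1.0 / self.duration

    def bin_index(self, f: float) -> int:
        """Index of the exact bin at frequency f; raises if f is off-grid."""
        idx = f * self.duration
        if abs(idx - round(idx)) > 1e-6:
            raise ValueError(
                f"{f} Hz is not on the spectral grid (resolution {self.df:g} Hz); "
                "epochs must contain an integral number of stimulus cycles"
            )
        i = int(round(idx))
        if not (0 <= i < self.freqs.size):
            raise ValueError(f"{f} Hz outside the spectrum (Nyquist exceeded)")
        return i


@dataclass(frozen=True)
class HarmonicMeasure:
    """1F1/2F1 amplitudes with local noise floors and SNRs.

    The noise floor of a harmonic is the mean amplitude of the
    ``NOISE_FLOOR_K`` nearest bins on each side, excluding DC and every bin
    at an integer multiple of f1.  SNR = amplitude / noise floor; when the
    floor is exactly zero the SNR is reported as 0 for a zero amplitude and
    inf otherwise.
    """

    a_1F1: float
    a_2F1: float
    noise_1F1: float
    noise_2F1: float
    snr_1F1: float
    snr_2F1: float
    n_averaged: int = 1


def amplitude_spectrum(trace: Trace) -> AmplitudeSpectrum:
    """One-sided amplitude spectrum of a single epoch.

    Scaling: bin amplitude = 2|X_k|/N for 0 < k < N/2, |X_k|/N at DC and
    (for even N) at Nyquist, so a pure sinusoid of peak amplitude A yields
    exactly A in its bin.
    """
    v = np.asarray(trace.voltage_uv, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("trace must be a 1-D array with at least 2 samples")
    if not np.all(np.isfinite(v)):
        raise ValueError("trace contains non-finite samples")
    n = v.size
    coeffs = np.fft.rfft(v) / n
    scale = np.full(coeffs.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    complex_amps = coeffs * scale
    freqs = np.fft.rfftfreq(n, d=1.0 / trace.spec.sample_rate)
    return AmplitudeSpectrum(
        freqs=freqs,
        amps=np.abs(complex_amps),
        duration=trace.spec.duration,
        n_averaged=1,
        complex_amps=complex_amps,
    )


def average_repeats(
    spectra: Sequence[AmplitudeSpectrum], *, mode: str = "incoherent"
) -> AmplitudeSpectrum:
    """Average repeat presentations of the same stimulus.

    ``incoherent`` (default) takes the bin-wise arithmetic mean of the
    amplitude spectra.  ``coherent`` averages the complex coefficients first
    and takes the magnitude of the mean, which rewards phase-locked repeats
    but cancels responses whose phase drifts.
    """
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.freqs.shape != ref.freqs.shape or not np.allclose(
            s.freqs, ref.freqs, rtol=0, atol=1e-9
        ):
            raise ValueError("spectra have mismatched frequency grids")
    n_total = sum(s.n_averaged for s in spectra)
    if mode == "incoherent":
        amps = np.mean([s.amps for s in spectra], axis=0)
        return AmplitudeSpectrum(
            freqs=ref.freqs, amps=amps, duration=ref.duration, n_averaged=n_total
        )
    if mode == "coherent":
        if any(s.complex_amps is None for s in spectra):
            raise ValueError("coherent averaging requires complex spectra")
        cmean = np.mean([s.complex_amps for s in spectra], axis=0)
        return AmplitudeSpectrum(
            freqs=ref.freqs,
            amps=np.abs(cmean),
            duration=ref.duration,
            n_averaged=n_total,
            complex_amps=cmean,
        )
    raise ValueError(f"unknown averaging mode {mode!r}")


def _noise_floor(spectrum: AmplitudeSpectrum, harmonic_bin: int, f1_bin: int, k: int) -> float:
    """Mean amplitude of the k nearest eligible bins on each side.

    Eligible bins exclude DC and every integer multiple of the fundamental
    (so neighbouring response components never inflate the floor estimate).
    """
    n = spectrum.amps.size
    picked: List[int] = []
    for step in (-1, +1):
        found = 0
        i = harmonic_bin + step
        while 0 < i < n and found < k:
            if i % f1_bin != 0:  # skips DC (i=0 excluded by loop) and all harmonics
                picked.append(i)
                found += 1
            i += step
    if not picked:
        return 0.0
    return float(np.mean(spectrum.amps[picked]))


def _snr(amp: float, floor: float) -> float:
    if floor > 0:
        return amp / floor
    return float("inf") if amp > 0 else 0.0


def extract_harmonics(
    spectrum: AmplitudeSpectrum, f1: float, *, k: int = NOISE_FLOOR_K
) -> HarmonicMeasure:
    """Read the 1F1 and 2F1 responses off the exact spectral bins.

    Raises if f1 or 2*f1 does not fall exactly on the frequency grid — a
    silent nearest-bin fallback would hide an epoch-length mistake.
    """
    if k < 1:
        raise ValueError(f"noise-floor width k must be >= 1, got {k}")
    b1 = spectrum.bin_index(f1)
    b2 = spectrum.bin_index(2.0 * f1)
    if b1 == 0:
        raise ValueError("f1 maps to the DC bin; epoch too short")
    a1 = float(spectrum.amps[b1])
    a2 = float(spectrum.amps[b2])
    n1 = _noise_floor(spectrum, b1, b1, k)
    n2 = _noise_floor(spectrum, b2, b1, k)
    return HarmonicMeasure(
        a_1F1=a1,
        a_2F1=a2,
        noise_1F1=n1,
        noise_2F1=n2,
        snr_1F1=_snr(a1, n1),
        snr_2F1=_snr(a2, n2),
        n_averaged=spectrum.n_averaged,
    )
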