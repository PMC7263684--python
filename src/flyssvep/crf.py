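"""Per-fly contrast-response functions (CRFs) and best responses.

For each fly and each harmonic, the repeat-averaged amplitude is plotted
against stimulus contrast; the fly's "best response" is the maximum of that
empirical CRF.  No curve is fitted first — the screen statistic operates on
the raw maximum, taken independently for the 1F1 and 2F1 components (they
need not peak at the same contrast).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .harmonics import HarmonicMeasure

__all__ = [
    "ContrastResponseFunction",
    "FlyResult",
    "build_crf",
    "best_response",
    "fly_result",
]

HARMONICS = ("1F1", "2F1")


@dataclass(frozen=True)
class ContrastResponseFunction:
    """Amplitude (uV) per contrast for one fly and one harmonic."""

    contrasts: Tuple[float, ...]
    amps: Tuple[float, ...]
    harmonic: str
    fly_id: str = "fly0"
    genotype_label: str = "control"
    rab_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.harmonic not in HARMONICS:
            raise ValueError(f"harmonic must be one of {HARMONICS}")
        if len(self.amps) != len(self.contrasts):
            raise ValueError("amps and contrasts must have equal length")
        if len(self.contrasts) == 0:
            raise ValueError("CRF must be nonempty")
        if any(a < 0 for a in self.amps):
            raise ValueError("amplitudes must be nonnegative")
        if any(b <= a for a, b in zip(self.contrasts, self.contrasts[1:])):
            raise ValueError("contrasts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.contrasts)


@dataclass(frozen=True)
class FlyResult:
    """A fly's two CRFs and its best (maximum) response per harmonic."""

    best_1F1: float
    best_2F1: float
    crf_1F1: ContrastResponseFunction
    crf_2F1: ContrastResponseFunction


def build_crf(
    measures: Sequence[Tuple[float, HarmonicMeasure]],
    harmonic: str,
    *,
    fly_id: str = "fly0",
    genotype_label: str = "control",
    rab_id: Optional[str] = None,
    min_snr: Optional[float] = None,
) -> ContrastResponseFunction:
    """Assemble a CRF from (contrast, HarmonicMeasure) pairs.

    Input order is irrelevant — the CRF is sorted by ascending contrast.
    Duplicate or missing contrasts are an error: the screen design presents
    each contrast exactly once per repeat block.  ``min_snr`` optionally
    zeroes out amplitudes whose SNR falls below the threshold (off by
    default; the screen applies no exclusion rule).
    """
    if harmonic not in HARMONICS:
        raise ValueError(f"harmonic must be one of {HARMONICS}")
    if len(measures) == 0:
        raise ValueError("no measures supplied")
    contrasts = [c for c, _ in measures]
    if len(set(contrasts)) != len(contrasts):
        raise ValueError("duplicate contrast in measures")
    order = np.argsort(contrasts)
    amps = []
    for i in order:
        m = measures[i][1]
        amp = m.a_1F1 if harmonic == "1F1" else m.a_2F1
        snr = m.snr_1F1 if harmonic == "1F1" else m.snr_2F1
        if min_snr is not None and snr < min_snr:
            amp = 0.0
        amps.append(amp)
    return ContrastResponseFunction(
        contrasts=tuple(contrasts[i] for i in order),
        amps=tuple(amps),
        harmonic=harmonic,
        fly_id=fly_id,
        genotype_label=genotype_label,
        rab_id=rab_id,
    )


def best_response(crf: ContrastResponseFunction) -> float:
    """Maximum amplitude over the CRF.

    Ties go to the lowest contrast achieving the maximum (np.argmax's
    first-occurrence rule on the contrast-sorted amplitudes).
    """
    amps = np.asarray(crf.amps)
    return float(amps[int(np.argmax(amps))])


def fly_result(
    crf_1f1: ContrastResponseFunction, crf_2f1: ContrastResponseFunction
) -> FlyResult:
    """Bundle a fly's two CRFs with their best responses."""
    if crf_1f1.fly_id != crf_2f1.fly_id:
        raise ValueError("CRFs belong to different flies")
    return FlyResult(
        best_1F1=best_response(crf_1f1),
        best_2F1=best_response(crf_2f1),
        crf_1F1=crf_1f1,
        crf_2F1=crf_2f1,
    )
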