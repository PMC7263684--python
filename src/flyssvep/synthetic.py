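"""Synthetic SSVEP trace generator with known ground truth.

The generator mirrors the two-stage structure the analysis assumes.  The
photoreceptor layer responds at the stimulus fundamental with a saturating
Naka-Rushton contrast dependence,

    A1(c) = r_max_P * c**n / (c**n + c50**n),

and the lamina stage is modeled as a static quadratic nonlinearity, so its
output is a pure second harmonic with amplitude

    A2(c) = g_L * A1(c)**2.

Genotype acts multiplicatively on each stage (``gain_P``, ``gain_L``), with
extra ``synergy_P`` / ``synergy_L`` multipliers that engage only when both
the Rab and the G2019S kinase are expressed — the generative analogue of the
epistatic interaction the screen is designed to detect.  Fly-to-fly spread is
lognormal (amplitudes stay positive) and recording noise is additive white
Gaussian on the voltage trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stimulus import ContrastSeries, StimulusSpec, make_contrast_series

__all__ = [
    "FlyParams",
    "GenotypeEffect",
    "ScreenDesign",
    "Trace",
    "ARMS",
    "deterministic_amplitudes",
    "simulate_trace",
    "sample_fly_params",
    "simulate_screen",
    "make_screen_effects",
    "synthetic_annotation_table",
]

#: The four genotype arms of the screen.  ``control`` is the driver-only
#: TH/+ cross, ``g2019s_only`` the THG2 recombinant, ``rab_only`` TH>Rab,
#: and ``both`` the THG2>Rab co-expression arm.
ARMS = ("control", "rab_only", "g2019s_only", "both")

#: Fly Rabs with mammalian orthologs, as screened.
DEFAULT_RAB_IDS = (
    "Rab1", "Rab2", "Rab3", "Rab4", "Rab5", "Rab6", "Rab7", "Rab8", "Rab9",
    "Rab10", "Rab11", "Rab14", "Rab18", "Rab19", "Rab21", "Rab23", "Rab26",
    "Rab27", "Rab30", "Rab32", "Rab35", "Rab39", "Rab40",
)


@dataclass(frozen=True)
class FlyParams:
    """Generative parameters of one fly.

    ``r_max_P`` (uV) is the photoreceptor saturation amplitude, ``c50`` the
    semi-saturation contrast, ``hill_n`` the Naka-Rushton exponent, ``g_L``
    (uV per uV^2) the lamina quadratic gain, ``phase1``/``phase2`` (rad) the
    harmonic phases, and ``noise_sd`` (uV) the additive noise level.
    """

    r_max_P: float = 10.0
    c50: float = 0.3
    hill_n: float = 2.0
    g_L: float = 0.05
    phase1: float = 0.0
    phase2: float = 0.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.r_max_P < 0:
            raise ValueError("r_max_P must be >= 0")
        if not (0.0 < self.c50 <= 1.0):
            raise ValueError("c50 must be in (0, 1]")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")
        if self.g_L < 0:
            raise ValueError("g_L must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GenotypeEffect:
    """Multiplicative genotype effect on the two response stages.

    ``synergy_P`` and ``synergy_L`` apply only when ``label == "both"``:
    they encode the extra response present when the Rab and G2019S are
    co-expressed, over and above the product of their solo effects.
    """

    label: str
    rab_id: Optional[str] = None
    gain_P: float = 1.0
    gain_L: float = 1.0
    synergy_P: float = 1.0
    synergy_L: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in ARMS:
            raise ValueError(f"label must be one of {ARMS}, got {self.label!r}")
        for name in ("gain_P", "gain_L", "synergy_P", "synergy_L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ScreenDesign:
    """Size and stimulus layout of a simulated screen.

    Defaults follow the screen protocol: each fly is presented 5 times with
    a set of 9 flickering stimuli spanning 10-100% contrast.
    """

    rab_ids: Tuple[str, ...] = DEFAULT_RAB_IDS
    n_flies_per_arm: int = 10
    contrast_series: ContrastSeries = field(default_factory=make_contrast_series)
    n_repeats: int = 5
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.n_flies_per_arm < 1:
            raise ValueError("n_flies_per_arm must be >= 1")


@dataclass(frozen=True)
class Trace:
    """A sampled voltage response plus its acquisition metadata."""

    voltage_uv: np.ndarray
    spec: StimulusSpec
    fly_id: str = "fly0"
    genotype_label: str = "control"
    rab_id: Optional[str] = None
    repeat: int = 0

    def times(self) -> np.ndarray:
        return self.spec.times()


def deterministic_amplitudes(
    fly: FlyParams, effect: GenotypeEffect, contrast: float
) -> Tuple[float, float]:
    """Noise-free harmonic amplitudes (A1, A2) in uV at the given contrast.

    A1 follows the Naka-Rushton contrast response scaled by the genotype's
    photoreceptor gain; A2 is the lamina quadratic output scaled by the
    lamina gain.  Synergy multipliers engage only on the co-expression arm.
    """
    if not (0.0 <= contrast <= 1.0):
        raise ValueError(f"contrast must be in [0, 1], got {contrast}")
    both = effect.label == "both"
    gp = effect.gain_P * (effect.synergy_P if both else 1.0)
    gl = effect.gain_L * (effect.synergy_L if both else 1.0)
    if contrast == 0.0:
        return 0.0, 0.0
    cn = contrast ** fly.hill_n
    a1 = gp * fly.r_max_P * cn / (cn + fly.c50 ** fly.hill_n)
    a2 = gl * fly.g_L * a1 * a1
    return a1, a2


def simulate_trace(
    fly: FlyParams,
    effect: GenotypeEffect,
    spec: StimulusSpec,
    rng: np.random.Generator,
    *,
    fly_id: str = "fly0",
    repeat: int = 0,
) -> Trace:
    """One voltage epoch: two harmonics at f1 and 2*f1 plus Gaussian noise.

    V(t) = A1 sin(2 pi f1 t + phase1) + A2 sin(4 pi f1 t + phase2) + N(0, noise_sd).
    """
    a1, a2 = deterministic_amplitudes(fly, effect, spec.contrast)
    t = spec.times()
    v = a1 * np.sin(2.0 * np.pi * spec.f1 * t + fly.phase1)
    v += a2 * np.sin(4.0 * np.pi * spec.f1 * t + fly.phase2)
    if fly.noise_sd > 0:
        v = v + rng.normal(0.0, fly.noise_sd, size=t.size)
    return Trace(
        voltage_uv=v,
        spec=spec,
        fly_id=fly_id,
        genotype_label=effect.label,
        rab_id=effect.rab_id,
        repeat=repeat,
    )


# Parameters jittered lognormally across flies; phases are carried over
# unchanged (they are circular, not positive-scale quantities).
_LOGNORMAL_FIELDS = ("r_max_P", "c50", "hill_n", "g_L", "noise_sd")


def sample_fly_params(
    population_means: FlyParams, cv: float, rng: np.random.Generator
) -> FlyParams:
    """Draw one fly's parameters lognormally around the population means.

    Each positive parameter X is drawn with E[X] equal to its population
    mean and coefficient of variation ``cv`` (sigma^2 = ln(1+cv^2),
    mu = ln(mean) - sigma^2/2).  ``cv = 0`` returns the means exactly.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return population_means
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    drawn = {}
    for name in _LOGNORMAL_FIELDS:
        mean = getattr(population_means, name)
        if mean == 0.0:
            drawn[name] = 0.0
        else:
            mu = np.log(mean) - 0.5 * sigma2
            drawn[name] = float(rng.lognormal(mu, sigma))
    # c50 must stay in (0, 1]; a lognormal draw can exceed 1 for means near 1
    drawn["c50"] = min(drawn["c50"], 1.0)
    return replace(population_means, **drawn)


def make_screen_effects(
    rab_ids: Sequence[str],
    *,
    synergy_L: Optional[Mapping[str, float]] = None,
    synergy_P: Optional[Mapping[str, float]] = None,
    solo_gain_P: Optional[Mapping[str, float]] = None,
    solo_gain_L: Optional[Mapping[str, float]] = None,
) -> Dict[str, Dict[str, GenotypeEffect]]:
    """Build the per-Rab, per-arm effect table for :func:`simulate_screen`.

    All multipliers default to 1 (the null screen).  ``synergy_*`` maps set
    the co-expression-only multipliers of selected Rabs; ``solo_gain_*``
    maps elevate a Rab's effect on its own (applied on both the rab_only
    and both arms, as a solo effect carries over under co-expression).
    """
    synergy_L = dict(synergy_L or {})
    synergy_P = dict(synergy_P or {})
    solo_gain_P = dict(solo_gain_P or {})
    solo_gain_L = dict(solo_gain_L or {})
    effects: Dict[str, Dict[str, GenotypeEffect]] = {}
    for rab in rab_ids:
        gp = solo_gain_P.get(rab, 1.0)
        gl = solo_gain_L.get(rab, 1.0)
        effects[rab] = {
            "control": GenotypeEffect(label="control", rab_id=None),
            "g2019s_only": GenotypeEffect(label="g2019s_only", rab_id=None),
            "rab_only": GenotypeEffect(
                label="rab_only", rab_id=rab, gain_P=gp, gain_L=gl
            ),
            "both": GenotypeEffect(
                label="both",
                rab_id=rab,
                gain_P=gp,
                gain_L=gl,
                synergy_P=synergy_P.get(rab, 1.0),
                synergy_L=synergy_L.get(rab, 1.0),
            ),
        }
    return effects


def _fly_rng(seed: int, arm: str, rab: Optional[str], fly_index: int) -> np.random.Generator:
    """Deterministic per-fly RNG: one global seed fans out via SeedSequence keyed
    by (arm, rab, fly), so partial re-runs reproduce the same flies."""
    import zlib

    arm_key = ARMS.index(arm)
    rab_key = 0 if rab is None else 1 + zlib.crc32(rab.encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), arm_key, rab_key, int(fly_index)])
    )


def simulate_screen(
    design: ScreenDesign,
    effects: Mapping[str, Mapping[str, GenotypeEffect]],
    *,
    population: FlyParams = FlyParams(),
    cv: float = 0.3,
    cv_by_arm: Optional[Mapping[str, float]] = None,
) -> Tuple[List[Trace], pd.DataFrame]:
    """Simulate the whole screen; return all traces plus a ground-truth table.

    The control (TH/+) and G2019S-only (THG2) arms do not depend on the Rab
    and are simulated once for the whole screen; the rab_only and both arms
    are simulated per Rab.  Each fly sees every contrast ``n_repeats`` times.

    ``cv_by_arm`` optionally overrides the fly-to-fly coefficient of
    variation for particular arms (off by default).

    The ground-truth table holds, per (rab_id, genotype_label), the
    population-level A1/A2 at full contrast and the multipliers used.
    """
    for rab in design.rab_ids:
        if rab not in effects:
            raise ValueError(f"missing effect table for {rab!r}")
        missing = [a for a in ARMS if a not in effects[rab]]
        if missing:
            raise ValueError(f"Rab {rab!r} missing arms: {missing}")

    cv_by_arm = dict(cv_by_arm or {})
    traces: List[Trace] = []
    truth_rows = []

    def run_arm(arm: str, rab: Optional[str], effect: GenotypeEffect) -> None:
        arm_cv = cv_by_arm.get(arm, cv)
        tag = rab if rab is not None else "shared"
        for i in range(design.n_flies_per_arm):
            rng = _fly_rng(design.seed, arm, rab, i)
            fly = sample_fly_params(population, arm_cv, rng)
            fly_id = f"{tag}_{arm}_{i}"
            for contrast in design.contrast_series:
                spec = design.stimulus.replace(contrast=contrast)
                for rep in range(design.n_repeats):
                    traces.append(
                        simulate_trace(
                            fly, effect, spec, rng, fly_id=fly_id, repeat=rep
                        )
                    )
        a1, a2 = deterministic_amplitudes(population, effect, 1.0)
        truth_rows.append(
            {
                "rab_id": tag,
                "genotype_label": arm,
                "true_A1_uv": a1,
                "true_A2_uv": a2,
                "gain_P": effect.gain_P,
                "gain_L": effect.gain_L,
                "synergy_P": effect.synergy_P,
                "synergy_L": effect.synergy_L,
            }
        )

    first_rab = design.rab_ids[0]
    run_arm("control", None, effects[first_rab]["control"])
    run_arm("g2019s_only", None, effects[first_rab]["g2019s_only"])
    for rab in design.rab_ids:
        run_arm("rab_only", rab, effects[rab]["rab_only"])
        run_arm("both", rab, effects[rab]["both"])

    return traces, pd.DataFrame(truth_rows)


def synthetic_annotation_table(rab_ids: Iterable[str] = DEFAULT_RAB_IDS) -> pd.DataFrame:
    """A synthetic Rab annotation table for exercising the enrichment machinery.

    Columns mirror the overlays a screen would test (Parkinson's linkage,
    phylogenetic group, active-site residue, in-vitro phosphorylation,
    organelle).  The in-vitro phosphorylation column follows the published
    biochemical substrate list where a fly homolog exists (Rabs 3, 5, 8, 10,
    35) and Rab40's His active-site residue; the remaining assignments are
    synthetic placeholders, not curated biology.
    """
    rab_ids = list(rab_ids)
    in_vitro = {"Rab3", "Rab5", "Rab8", "Rab10", "Rab35"}
    pd_linked = {"Rab10", "Rab29", "Rab39", "Rab7", "Rab35"}
    rows = []
    for i, rab in enumerate(rab_ids):
        rows.append(
            {
                "rab_id": rab,
                "pd_linked": rab in pd_linked,
                "phylo_group": f"group{i % 4}",
                "active_site_residue": "His" if rab == "Rab40" else ("Thr" if i % 2 else "Ser"),
                "in_vitro_phospho": rab in in_vitro,
                "organelle": ["endosome", "Golgi", "lysosome", "mitochondria"][i % 4],
            }
        )
    return pd.DataFrame(rows)
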