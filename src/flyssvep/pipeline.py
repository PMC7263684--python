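"""Dataset I/O, configuration and the four-stage analysis pipeline.

Stages mirror the experiment's workflow:

  simulate -> extract -> crf -> screen

``simulate`` produces a synthetic trace dataset (or one is read from disk);
``extract`` turns each fly's epochs into repeat-averaged 1F1/2F1 amplitudes;
``crf`` builds per-fly contrast-response functions and best responses;
``screen`` aggregates by genotype and computes the synergy spectrum,
enrichment, signaling regression with outliers, and ANOVA/Dunnett tables.
One global seed drives every stochastic stage through an explicit
seed-derivation scheme, so identical config + seed reproduces outputs
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .stimulus import ContrastSeries, StimulusSpec, make_contrast_series
from .synthetic import (
    ARMS,
    DEFAULT_RAB_IDS,
    FlyParams,
    GenotypeEffect,
    ScreenDesign,
    Trace,
    make_screen_effects,
    simulate_screen,
)
from .harmonics import NOISE_FLOOR_K, amplitude_spectrum, average_repeats, extract_harmonics
from .crf import build_crf, best_response
from .screen_stats import (
    DUNNETT_DRAWS,
    OUTLIER_THRESHOLD,
    GenotypeSummary,
    anova_dunnett,
    detect_outliers,
    enrichment_test,
    fit_spectrum,
    signaling_points,
    summarize_genotype,
    synergy_xy,
)

__all__ = [
    "PipelineConfig",
    "read_trace_dataset",
    "write_trace_dataset",
    "harmonic_table",
    "fly_results_table",
    "screen_tables",
    "run_pipeline",
]

log = logging.getLogger("flyssvep")

FLOAT_FMT = "%.9g"

TRACE_COLUMNS = [
    "fly_id",
    "genotype_label",
    "rab_id",
    "contrast",
    "repeat",
    "time_s",
    "voltage_uv",
]


def _setup_logging(verbose: bool = False) -> None:
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        log.addHandler(h)
    log.setLevel(logging.DEBUG if verbose else logging.INFO)


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs with their documented defaults.

    Stimulus: 12 Hz sinusoidal flicker about mean level 0.5, 1 s epochs at
    1 kHz.  Design: 9 contrasts from 10% to 100%, 5 repeats, 10 flies per
    arm across the 23 mammalian-ortholog Rabs.  Analysis: incoherent repeat
    averaging, 5-bin noise floors, no SNR gate, unweighted spectrum fit,
    outlier threshold 3, 1e5 Dunnett draws.
    """

    # stimulus
    f1: float = 12.0
    mean_level: float = 0.5
    duration: float = 1.0
    sample_rate: float = 1000.0
    # contrast series
    n_contrasts: int = 9
    c_min: float = 0.10
    c_max: float = 1.00
    # screen design
    rab_ids: Tuple[str, ...] = DEFAULT_RAB_IDS
    n_flies_per_arm: int = 10
    n_repeats: int = 5
    cv: float = 0.3
    # genotype effect maps (rab -> multiplier); empty = null screen
    synergy_L: Dict[str, float] = field(default_factory=dict)
    synergy_P: Dict[str, float] = field(default_factory=dict)
    solo_gain_P: Dict[str, float] = field(default_factory=dict)
    solo_gain_L: Dict[str, float] = field(default_factory=dict)
    # harmonic analysis
    avg_mode: str = "incoherent"
    noise_floor_k: int = NOISE_FLOOR_K
    # CRF
    min_snr: Optional[float] = None
    # screen statistics
    weighted_fit: bool = False
    outlier_threshold: float = OUTLIER_THRESHOLD
    dunnett_draws: int = DUNNETT_DRAWS
    # global
    seed: int = 0
    out_dir: str = "flyssvep_out"

    def stimulus_spec(self, contrast: float = 1.0) -> StimulusSpec:
        return StimulusSpec(
            f1=self.f1,
            mean_level=self.mean_level,
            contrast=contrast,
            duration=self.duration,
            sample_rate=self.sample_rate,
        )

    def contrast_series(self) -> ContrastSeries:
        return make_contrast_series(self.n_contrasts, self.c_min, self.c_max)

    def design(self) -> ScreenDesign:
        return ScreenDesign(
            rab_ids=tuple(self.rab_ids),
            n_flies_per_arm=self.n_flies_per_arm,
            contrast_series=self.contrast_series(),
            n_repeats=self.n_repeats,
            stimulus=self.stimulus_spec(),
            seed=self.seed,
        )

    def effects(self) -> Dict[str, Dict[str, GenotypeEffect]]:
        return make_screen_effects(
            self.rab_ids,
            synergy_L=self.synergy_L,
            synergy_P=self.synergy_P,
            solo_gain_P=self.solo_gain_P,
            solo_gain_L=self.solo_gain_L,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["rab_ids"] = list(d["rab_ids"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "PipelineConfig":
        d = json.loads(s)
        if "rab_ids" in d:
            d["rab_ids"] = tuple(d["rab_ids"])
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config fields: {sorted(extra)}")
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def recovery_screen_config(seed: int = 0, *, out_dir: str = "flyssvep_out") -> PipelineConfig:
    """Reference 23-Rab screen with known synergistic and solo-acting Rabs.

    The scenario used for end-to-end parameter-recovery checks:

    * ``Rab10`` — lamina-only synergy (synergy_L = 8): its lamina response
      under co-expression is 8x what its photoreceptor signal predicts, so
      it should be the unique signaling-regression outlier.
    * ``Rab14``, ``Rab27`` — photoreceptor-driven synergy (synergy_P =
      sqrt(6), sqrt(5)), whose lamina folds of 6 and 5 arise naturally
      through the quadratic lamina stage; they stay on the
      photoreceptor-to-lamina signaling relation.
    * ``Rab3``, ``Rab32``, ``Rab1`` — strong solo effects (elevated
      photoreceptor and lamina gains) with a mild response ceiling under
      co-expression (synergy_P slightly below 1), giving the spectrum its
      inverse relationship.
    * the remaining 17 Rabs are null.

    Fly-to-fly coefficient of variation is 0.15 (moderate); recording noise
    is the 0.5 uV default.  The expected read-out: the three synergy Rabs
    carry the three largest positive lamina-spectrum residuals, the fitted
    spectrum slope is negative, and Rab10 is the only outlier flag.
    """
    return PipelineConfig(
        synergy_L={"Rab10": 8.0},
        synergy_P={
            "Rab14": 6.0**0.5,
            "Rab27": 5.0**0.5,
            "Rab3": 0.80,
            "Rab32": 0.85,
            "Rab1": 0.90,
        },
        solo_gain_P={"Rab3": 1.8, "Rab32": 1.6, "Rab1": 1.5},
        solo_gain_L={"Rab3": 2.0, "Rab32": 1.8, "Rab1": 1.6},
        cv=0.15,
        seed=seed,
        out_dir=out_dir,
    )


# ---------------------------------------------------------------------------
# trace dataset I/O


def write_trace_dataset(traces: Sequence[Trace], out_dir, manifest: dict) -> None:
    """Write a long-format trace CSV plus a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for tr in traces:
        t = tr.times()
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": tr.fly_id,
                    "genotype_label": tr.genotype_label,
                    "rab_id": tr.rab_id if tr.rab_id is not None else "",
                    "contrast": tr.spec.contrast,
                    "repeat": tr.repeat,
                    "time_s": t,
                    "voltage_uv": tr.voltage_uv,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(out / "traces.csv", index=False, float_format=FLOAT_FMT)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


class TraceDatasetError(ValueError):
    """Schema violation in a trace dataset, with offending row numbers."""


def read_trace_dataset(path) -> Tuple[List[Trace], dict]:
    """Read a long-format trace dataset directory back into Trace objects.

    ``path`` must contain ``traces.csv`` and ``manifest.json``.  The
    manifest's stimulus spec supplies f1/mean level/duration/sample rate;
    contrast comes from each trace's rows.  Schema violations raise
    :class:`TraceDatasetError` naming the column and row numbers.
    """
    p = Path(path)
    csv_path, man_path = p / "traces.csv", p / "manifest.json"
    if not man_path.exists():
        raise TraceDatasetError(f"manifest.json not found in {p}")
    manifest = json.loads(man_path.read_text())
    if not csv_path.exists():
        raise TraceDatasetError(f"traces.csv not found in {p}")
    df = pd.read_csv(csv_path, dtype={"rab_id": str}, keep_default_na=False)
    if df.empty:
        raise TraceDatasetError("empty trace dataset")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceDatasetError(f"missing columns: {missing}")
    for col in ("contrast", "time_s", "voltage_uv"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise TraceDatasetError(
                f"non-numeric values in column {col!r} at rows {bad[:10]}"
            )
        df[col] = vals

    spec_d = manifest["stimulus"]
    traces: List[Trace] = []
    for (fly, label, rab, contrast, rep), grp in df.groupby(
        ["fly_id", "genotype_label", "rab_id", "contrast", "repeat"], sort=True
    ):
        grp = grp.sort_values("time_s")
        dt = np.diff(grp["time_s"].to_numpy())
        if dt.size and (np.ptp(dt) > 1e-9 or dt[0] <= 0):
            raise TraceDatasetError(
                f"non-uniform sampling for fly {fly!r} contrast {contrast}"
            )
        spec = StimulusSpec(
            f1=spec_d["f1"],
            mean_level=spec_d["mean_level"],
            contrast=float(contrast),
            duration=spec_d["duration"],
            sample_rate=spec_d["sample_rate"],
        )
        traces.append(
            Trace(
                voltage_uv=grp["voltage_uv"].to_numpy(),
                spec=spec,
                fly_id=str(fly),
                genotype_label=str(label),
                rab_id=str(rab) if rab != "" else None,
                repeat=int(rep),
            )
        )
    return traces, manifest


# ---------------------------------------------------------------------------
# stage 2: harmonic extraction


def harmonic_table(
    traces: Sequence[Trace],
    *,
    mode: str = "incoherent",
    k: int = NOISE_FLOOR_K,
) -> pd.DataFrame:
    """Repeat-averaged harmonic amplitudes per (fly, contrast).

    Repeats of the same (fly, contrast) are averaged (incoherently by
    default) before the 1F1/2F1 bins are read off.
    """
    groups: Dict[tuple, List[Trace]] = {}
    for tr in traces:
        key = (tr.fly_id, tr.genotype_label, tr.rab_id, tr.spec.contrast)
        groups.setdefault(key, []).append(tr)
    rows = []
    for (fly, label, rab, contrast), grp in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][3])
    ):
        spectra = [amplitude_spectrum(tr) for tr in grp]
        avg = average_repeats(spectra, mode=mode)
        m = extract_harmonics(avg, grp[0].spec.f1, k=k)
        rows.append(
            {
                "fly_id": fly,
                "genotype_label": label,
                "rab_id": rab if rab is not None else "",
                "contrast": contrast,
                "a_1F1": m.a_1F1,
                "a_2F1": m.a_2F1,
                "noise_1F1": m.noise_1F1,
                "noise_2F1": m.noise_2F1,
                "snr_1F1": m.snr_1F1,
                "snr_2F1": m.snr_2F1,
                "n_averaged": m.n_averaged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 3: CRFs and best responses


def fly_results_table(
    harmonics_df: pd.DataFrame, *, min_snr: Optional[float] = None
) -> pd.DataFrame:
    """Best 1F1/2F1 response per fly from the harmonic table."""
    from .harmonics import HarmonicMeasure

    rows = []
    for (fly, label, rab), grp in harmonics_df.groupby(
        ["fly_id", "genotype_label", "rab_id"], sort=True
    ):
        measures = [
            (
                r.contrast,
                HarmonicMeasure(
                    a_1F1=r.a_1F1,
                    a_2F1=r.a_2F1,
                    noise_1F1=r.noise_1F1,
                    noise_2F1=r.noise_2F1,
                    snr_1F1=r.snr_1F1,
                    snr_2F1=r.snr_2F1,
                    n_averaged=int(r.n_averaged),
                ),
            )
            for r in grp.itertuples()
        ]
        bests = {}
        for h in ("1F1", "2F1"):
            crf = build_crf(
                measures,
                h,
                fly_id=str(fly),
                genotype_label=str(label),
                rab_id=str(rab) or None,
                min_snr=min_snr,
            )
            bests[h] = best_response(crf)
        rows.append(
            {
                "fly_id": fly,
                "genotype_label": label,
                "rab_id": rab,
                "best_1F1": bests["1F1"],
                "best_2F1": bests["2F1"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 4: screen statistics


def _arm_summaries(fly_df: pd.DataFrame) -> Dict[Tuple[str, str, str], GenotypeSummary]:
    """GenotypeSummary per (rab_id, genotype_label, harmonic).

    Shared arms (control, g2019s_only) are keyed with rab_id = ''.
    """
    out = {}
    for (rab, label), grp in fly_df.groupby(["rab_id", "genotype_label"], sort=True):
        for h, col in (("1F1", "best_1F1"), ("2F1", "best_2F1")):
            out[(str(rab), str(label), h)] = summarize_genotype(
                grp[col].to_numpy(),
                harmonic=h,
                genotype_label=str(label),
                rab_id=str(rab) or None,
            )
    return out


def screen_tables(
    fly_df: pd.DataFrame,
    *,
    annotations: Optional[pd.DataFrame] = None,
    weighted_fit: bool = False,
    outlier_threshold: float = OUTLIER_THRESHOLD,
    dunnett_draws: int = DUNNETT_DRAWS,
    seed: int = 0,
    control_label: str = "control",
) -> Dict[str, object]:
    """All screen-level outputs from a fly-results table.

    Returns a dict with keys ``summaries`` (DataFrame), ``synergy``
    (DataFrame), ``spectrum_fits`` (harmonic -> SpectrumFit), ``enrichment``
    (DataFrame, empty without annotations), ``signaling`` (DataFrame with
    outlier flags), ``outliers`` (harmonic-independent OutlierReport) and
    ``anova`` (DataFrame of ANOVA + Dunnett rows per harmonic).
    """
    summaries = _arm_summaries(fly_df)
    rabs = sorted(
        {r for r, l, _ in summaries if l in ("rab_only", "both") and r},
    )

    sum_rows = [
        {
            "rab_id": s.rab_id or "",
            "genotype_label": s.genotype_label,
            "harmonic": s.harmonic,
            "n": s.n,
            "mean": s.mean,
            "se": s.se,
            "median": s.median,
            "iqr": s.iqr,
        }
        for s in summaries.values()
    ]
    summaries_df = pd.DataFrame(sum_rows).sort_values(
        ["harmonic", "rab_id", "genotype_label"], ignore_index=True
    )

    # synergy spectrum per harmonic
    syn_points = {h: [] for h in ("1F1", "2F1")}
    for h in ("1F1", "2F1"):
        ctrl = summaries[("", control_label, h)]
        for rab in rabs:
            syn_points[h].append(
                synergy_xy(ctrl, summaries[(rab, "rab_only", h)], summaries[(rab, "both", h)])
            )
    synergy_df = pd.DataFrame(
        [
            {
                "rab_id": p.rab_id,
                "harmonic": h,
                "X": p.X,
                "Y": p.Y,
                "se_X": p.se_X,
                "se_Y": p.se_Y,
            }
            for h in ("1F1", "2F1")
            for p in syn_points[h]
        ]
    )

    spectrum_fits = {}
    enrich_rows = []
    if len(rabs) >= 3:
        for h in ("1F1", "2F1"):
            fit = fit_spectrum(syn_points[h], weighted=weighted_fit)
            spectrum_fits[h] = fit
            synergy_df.loc[synergy_df["harmonic"] == h, "residual"] = fit.residuals
            synergy_df.loc[synergy_df["harmonic"] == h, "above_line"] = fit.above_line
            if annotations is not None:
                ann = annotations.set_index("rab_id")
                for col in ann.columns:
                    vals = ann[col]
                    if vals.dtype != bool and set(vals.unique()) - {True, False, 0, 1}:
                        continue  # enrichment needs a boolean column
                    res = enrichment_test(fit, vals.astype(bool).to_dict())
                    enrich_rows.append(
                        {
                            "harmonic": h,
                            "annotation": col,
                            "n11": res.table[0, 0],
                            "n10": res.table[0, 1],
                            "n01": res.table[1, 0],
                            "n00": res.table[1, 1],
                            "odds_ratio": res.odds_ratio,
                            "p_two_sided": res.p_two_sided,
                        }
                    )
    enrichment_df = pd.DataFrame(
        enrich_rows,
        columns=[
            "harmonic", "annotation", "n11", "n10", "n01", "n00",
            "odds_ratio", "p_two_sided",
        ],
    )

    # signaling regression + outliers
    sig_summaries = {
        rab: {
            (l, h): summaries[(rab, l, h)]
            for l in ("rab_only", "both")
            for h in ("1F1", "2F1")
        }
        for rab in rabs
    }
    signaling_df = pd.DataFrame()
    outlier_report = None
    if len(rabs) >= 4:
        pts = signaling_points(sig_summaries)
        outlier_report = detect_outliers(pts, threshold=outlier_threshold)
        signaling_df = pd.DataFrame(
            {
                "rab_id": outlier_report.rab_ids,
                "x_photoreceptor": [p.x_photoreceptor for p in pts],
                "y_lamina": [p.y_lamina for p in pts],
                "predicted_y": outlier_report.predicted,
                "ratio": outlier_report.ratio,
                "studentized": outlier_report.studentized,
                "flagged": outlier_report.flagged,
            }
        )

    # ANOVA + Dunnett per harmonic across all genotype arms
    anova_rows = []
    for h, col in (("1F1", "best_1F1"), ("2F1", "best_2F1")):
        groups = {}
        for (rab, label), grp in fly_df.groupby(["rab_id", "genotype_label"], sort=True):
            name = label if not rab else f"{label}:{rab}"
            if len(grp) >= 2:
                groups[name] = grp[col].to_numpy()
        if control_label not in groups or len(groups) < 2:
            continue
        res = anova_dunnett(
            groups, control_label, n_draws=dunnett_draws, seed=seed + (0 if h == "1F1" else 1)
        )
        anova_rows.append(
            {
                "harmonic": h,
                "comparison": "(ANOVA)",
                "statistic": res.f,
                "df1": res.df_between,
                "df2": res.df_within,
                "p": res.p,
            }
        )
        for lab, (diff, t, p_adj) in sorted(res.comparisons.items()):
            anova_rows.append(
                {
                    "harmonic": h,
                    "comparison": lab,
                    "statistic": t,
                    "df1": np.nan,
                    "df2": res.df_within,
                    "p": p_adj,
                    "mean_diff": diff,
                }
            )
    anova_df = pd.DataFrame(anova_rows)

    return {
        "summaries": summaries_df,
        "synergy": synergy_df,
        "spectrum_fits": spectrum_fits,
        "enrichment": enrichment_df,
        "signaling": signaling_df,
        "outliers": outlier_report,
        "anova": anova_df,
    }


# ---------------------------------------------------------------------------
# one-shot runner


def run_pipeline(
    config: PipelineConfig,
    *,
    annotations: Optional[pd.DataFrame] = None,
    write_traces: bool = False,
) -> Dict[str, object]:
    """Run simulate -> extract -> crf -> screen and write all outputs.

    Outputs (CSV/JSON, 9 significant digits) land in ``config.out_dir``
    along with a machine-readable run manifest; a run log goes to stderr.
    Identical config + seed yields byte-identical numeric outputs.
    """
    _setup_logging()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        log.info("stage %s: %d Rabs, %d flies/arm", stage, len(config.rab_ids), config.n_flies_per_arm)
        traces, truth = simulate_screen(
            config.design(), config.effects(), cv=config.cv
        )
        truth.to_csv(out / "ground_truth.csv", index=False, float_format=FLOAT_FMT)
        if write_traces:
            write_trace_dataset(
                traces,
                out / "traces",
                {
                    "stimulus": dataclasses.asdict(config.stimulus_spec()),
                    "seed": config.seed,
                    "design": {
                        "rab_ids": list(config.rab_ids),
                        "n_flies_per_arm": config.n_flies_per_arm,
                        "n_repeats": config.n_repeats,
                    },
                },
            )

        stage = "extract"
        log.info("stage %s: %d traces", stage, len(traces))
        hdf = harmonic_table(traces, mode=config.avg_mode, k=config.noise_floor_k)
        hdf.to_csv(out / "harmonics.csv", index=False, float_format=FLOAT_FMT)

        stage = "crf"
        fdf = fly_results_table(hdf, min_snr=config.min_snr)
        fdf.to_csv(out / "fly_results.csv", index=False, float_format=FLOAT_FMT)

        stage = "screen"
        log.info("stage %s: %d flies", stage, len(fdf))
        tables = screen_tables(
            fdf,
            annotations=annotations,
            weighted_fit=config.weighted_fit,
            outlier_threshold=config.outlier_threshold,
            dunnett_draws=config.dunnett_draws,
            seed=config.seed,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    tables["summaries"].to_csv(out / "summaries.csv", index=False, float_format=FLOAT_FMT)
    tables["synergy"].to_csv(out / "synergy_points.csv", index=False, float_format=FLOAT_FMT)
    fits = {
        h: {
            "slope": f.slope,
            "intercept": f.intercept,
            "r_squared": f.r_squared,
            "rab_ids": list(f.rab_ids),
            "residuals": [float(r) for r in f.residuals],
        }
        for h, f in tables["spectrum_fits"].items()
    }
    (out / "spectrum_fit.json").write_text(json.dumps(fits, indent=2, sort_keys=True))
    tables["enrichment"].to_csv(out / "enrichment.csv", index=False, float_format=FLOAT_FMT)
    tables["signaling"].to_csv(out / "signaling.csv", index=False, float_format=FLOAT_FMT)
    tables["anova"].to_csv(out / "anova_dunnett.csv", index=False, float_format=FLOAT_FMT)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(config.to_json()),
        "versions": {
            "flyssvep": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: outputs in %s", out)
    tables["fly_results"] = fdf
    tables["harmonics"] = hdf
    tables["ground_truth"] = truth
    return tables
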