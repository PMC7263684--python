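"""Screen-level statistics: synergy spectrum, enrichment, signaling regression.

The screen quantifies the interaction between each Rab and the G2019S kinase
through two differences of genotype means (best responses, uV):

    X = mean(TH > Rab)   - mean(TH/+)        (effect of the Rab alone)
    Y = mean(THG2 > Rab) - mean(TH > Rab)    (extra effect of adding G2019S)

so X + Y is the total departure of the co-expression arm from control.  A
Rab with large Y at small X synergizes with the kinase; a Rab with large X
and small Y acts on its own.  Plotting Y against X across Rabs and fitting
an ordinary least-squares line yields the "spectrum": Rabs above the line
respond to G2019S more than their solo effect predicts.  Annotation
enrichment above/below the line is tested with Fisher's exact test; the
photoreceptor-to-lamina signaling relation is an OLS regression of the
G2019S-induced 2F1 increase on the 1F1 increase, with leave-one-out
studentized-residual outlier detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "GenotypeSummary",
    "SynergyPoint",
    "SpectrumFit",
    "EnrichmentResult",
    "SignalingPoint",
    "OutlierReport",
    "AnovaDunnettResult",
    "summarize_genotype",
    "fold_change",
    "synergy_xy",
    "fit_spectrum",
    "fisher_exact_2x2",
    "enrichment_test",
    "signaling_points",
    "detect_outliers",
    "anova_dunnett",
]

#: Default studentized-residual threshold for flagging a signaling outlier.
OUTLIER_THRESHOLD = 3.0

#: Default Monte-Carlo sample size for the Dunnett adjustment.
DUNNETT_DRAWS = 100_000


# ---------------------------------------------------------------------------
# aggregation


@dataclass(frozen=True)
class GenotypeSummary:
    """Location and spread of best responses within one genotype arm."""

    n: int
    mean: float
    se: float
    median: float
    iqr: float
    harmonic: str = "1F1"
    genotype_label: str = "control"
    rab_id: Optional[str] = None


def summarize_genotype(
    bests: Sequence[float],
    *,
    harmonic: str = "1F1",
    genotype_label: str = "control",
    rab_id: Optional[str] = None,
) -> GenotypeSummary:
    """Mean +/- SE and median +/- IQR of a genotype's best responses.

    SE uses the sample standard deviation (n-1 denominator); quartiles use
    linear interpolation.  A single observation gets SE = 0 by convention.
    """
    x = np.asarray(bests, dtype=float)
    if x.size == 0:
        raise ValueError("empty list of best responses")
    mean = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    return GenotypeSummary(
        n=int(x.size),
        mean=mean,
        se=se,
        median=float(med),
        iqr=float(q3 - q1),
        harmonic=harmonic,
        genotype_label=genotype_label,
        rab_id=rab_id,
    )


def fold_change(arm: GenotypeSummary, reference: GenotypeSummary) -> float:
    """Ratio of mean responses, arm over reference."""
    if reference.mean <= 0:
        raise ZeroDivisionError(
            f"reference mean must be > 0 for a fold change, got {reference.mean}"
        )
    return arm.mean / reference.mean


# ---------------------------------------------------------------------------
# synergy spectrum


@dataclass(frozen=True)
class SynergyPoint:
    """Per-Rab (X, Y) coordinates of the synergy spectrum with SEs."""

    rab_id: str
    X: float
    Y: float
    se_X: float
    se_Y: float
    harmonic: str


def synergy_xy(
    control: GenotypeSummary,
    rab_only: GenotypeSummary,
    both: GenotypeSummary,
) -> SynergyPoint:
    """X = mean(rab_only) - mean(control); Y = mean(both) - mean(rab_only).

    SEs combine in quadrature (the arms are independent fly cohorts).
    X + Y = mean(both) - mean(control) by construction.
    """
    if not (control.harmonic == rab_only.harmonic == both.harmonic):
        raise ValueError(
            "harmonic mismatch: "
            f"{control.harmonic}, {rab_only.harmonic}, {both.harmonic}"
        )
    return SynergyPoint(
        rab_id=rab_only.rab_id if rab_only.rab_id is not None else "?",
        X=rab_only.mean - control.mean,
        Y=both.mean - rab_only.mean,
        se_X=float(np.hypot(rab_only.se, control.se)),
        se_Y=float(np.hypot(both.se, rab_only.se)),
        harmonic=control.harmonic,
    )


@dataclass(frozen=True)
class SpectrumFit:
    """OLS fit of Y on X across Rabs, with per-Rab residual classification."""

    slope: float
    intercept: float
    r_squared: float
    rab_ids: Tuple[str, ...]
    residuals: np.ndarray
    above_line: np.ndarray
    harmonic: str

    def residual_of(self, rab_id: str) -> float:
        return float(self.residuals[self.rab_ids.index(rab_id)])


def _ols(x: np.ndarray, y: np.ndarray, w: Optional[np.ndarray] = None):
    """(Weighted) least-squares line fit; returns slope, intercept, fitted."""
    X = np.column_stack([x, np.ones_like(x)])
    if w is not None:
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[0]), float(beta[1]), X @ beta


def fit_spectrum(
    points: Sequence[SynergyPoint], *, weighted: bool = False
) -> SpectrumFit:
    """Fit the synergy spectrum line Y = slope*X + intercept across Rabs.

    Unweighted OLS by default; ``weighted=True`` weights each Rab by
    1/se_Y^2 (Rabs with se_Y = 0 are given the largest finite weight
    present).  Residual sign classifies each Rab as above/below the line.
    """
    if len(points) < 3:
        raise ValueError(f"need at least 3 points to fit, got {len(points)}")
    harmonics = {p.harmonic for p in points}
    if len(harmonics) != 1:
        raise ValueError(f"points mix harmonics: {sorted(harmonics)}")
    x = np.array([p.X for p in points], dtype=float)
    y = np.array([p.Y for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in X: spectrum fit is degenerate")
    w = None
    if weighted:
        se = np.array([p.se_Y for p in points], dtype=float)
        w = np.zeros_like(se)
        pos = se > 0
        if not pos.any():
            w = None
        else:
            w[pos] = 1.0 / se[pos] ** 2
            w[~pos] = w[pos].max()
    slope, intercept, fitted = _ols(x, y, w)
    resid = y - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SpectrumFit(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        rab_ids=tuple(p.rab_id for p in points),
        residuals=resid,
        above_line=resid > 0,
        harmonic=points[0].harmonic,
    )


# ---------------------------------------------------------------------------
# enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher's exact test of an annotation against above/below the line.

    ``table`` rows are annotation True/False, columns above/below the line.
    """

    table: np.ndarray
    p_two_sided: float
    odds_ratio: float


def fisher_exact_2x2(table: np.ndarray) -> Tuple[float, float]:
    """Two-sided Fisher exact p (probability-mass rule) and odds ratio ad/bc.

    The two-sided p sums the probabilities of all tables with the observed
    margins that are no more probable than the observed one.  Degenerate
    tables (any margin zero) return p = 1.  Odds-ratio conventions:
    ad/bc with bc = 0 and ad > 0 giving inf, ad = 0 giving 0, and 0/0 nan.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    ad, bc = a * d, b * c
    if ad == 0 and bc == 0:
        odds = float("nan")
    elif bc == 0:
        odds = float("inf")
    else:
        odds = ad / bc
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0, odds
    p = float(sps.fisher_exact(t, alternative="two-sided")[1])
    return min(p, 1.0), odds


def enrichment_test(
    fit: SpectrumFit, annotation: Mapping[str, bool]
) -> EnrichmentResult:
    """Test whether annotated Rabs preferentially sit above the spectrum line."""
    missing = [r for r in fit.rab_ids if r not in annotation]
    if missing:
        raise ValueError(f"annotation missing for Rabs: {missing}")
    ann = np.array([bool(annotation[r]) for r in fit.rab_ids])
    above = fit.above_line
    table = np.array(
        [
            [int(np.sum(ann & above)), int(np.sum(ann & ~above))],
            [int(np.sum(~ann & above)), int(np.sum(~ann & ~above))],
        ]
    )
    p, odds = fisher_exact_2x2(table)
    return EnrichmentResult(table=table, p_two_sided=p, odds_ratio=odds)


# ---------------------------------------------------------------------------
# signaling regression and outliers


@dataclass(frozen=True)
class SignalingPoint:
    """G2019S-induced increase in lamina (2F1) vs photoreceptor (1F1) signal."""

    rab_id: str
    x_photoreceptor: float
    y_lamina: float
    age_group: str = "day1"


def signaling_points(
    summaries: Mapping[str, Mapping[Tuple[str, str], GenotypeSummary]],
    *,
    age_group: str = "day1",
) -> List[SignalingPoint]:
    """Build the signaling scatter from per-Rab arm summaries.

    ``summaries[rab][(label, harmonic)]`` must hold the rab_only and both
    arms for both harmonics.  Each point is the G2019S-induced increase:
    x = mean(both, 1F1) - mean(rab_only, 1F1) and likewise for y with 2F1.
    """
    pts = []
    for rab in summaries:
        s = summaries[rab]
        needed = [(l, h) for l in ("rab_only", "both") for h in ("1F1", "2F1")]
        missing = [k for k in needed if k not in s]
        if missing:
            raise ValueError(f"Rab {rab!r} missing arm summaries: {missing}")
        pts.append(
            SignalingPoint(
                rab_id=rab,
                x_photoreceptor=s[("both", "1F1")].mean - s[("rab_only", "1F1")].mean,
                y_lamina=s[("both", "2F1")].mean - s[("rab_only", "2F1")].mean,
                age_group=age_group,
            )
        )
    return pts


@dataclass(frozen=True)
class OutlierReport:
    """Leave-one-out outlier diagnostics for the signaling regression.

    ``ratio`` is observed_y / predicted_y from the leave-one-out line (the
    "how many times the expected value" statistic); ``studentized`` is the
    externally studentized residual; ``flagged`` marks |studentized| >=
    threshold.  Points whose leave-one-out fit is degenerate are left
    unflagged and listed in ``warnings``.
    """

    rab_ids: Tuple[str, ...]
    studentized: np.ndarray
    ratio: np.ndarray
    predicted: np.ndarray
    flagged: np.ndarray
    threshold: float
    warnings: Tuple[str, ...] = ()

    def flagged_rabs(self) -> List[str]:
        return [r for r, f in zip(self.rab_ids, self.flagged) if f]


def detect_outliers(
    points: Sequence[SignalingPoint], *, threshold: float = OUTLIER_THRESHOLD
) -> OutlierReport:
    """Flag signaling points far from the line fitted to the other points.

    For each point i an OLS line is fitted to the remaining points; the
    externally studentized residual is (y_i - yhat_i) / (s * sqrt(1 + h_i))
    with s the residual standard error and h_i the leverage of x_i under
    the leave-one-out fit.  A perfect leave-one-out line (s = 0) with a
    nonzero residual studentizes to +/- inf and is always flagged.
    """
    if len(points) < 4:
        raise ValueError(f"need at least 4 points, got {len(points)}")
    x = np.array([p.x_photoreceptor for p in points], dtype=float)
    y = np.array([p.y_lamina for p in points], dtype=float)
    n = x.size
    studentized = np.zeros(n)
    ratio = np.full(n, np.nan)
    predicted = np.full(n, np.nan)
    warns: List[str] = []
    for i in range(n):
        keep = np.arange(n) != i
        xi, yi = x[keep], y[keep]
        if np.ptp(xi) == 0:
            warns.append(
                f"{points[i].rab_id}: leave-one-out fit degenerate (no X spread)"
            )
            continue
        slope, intercept, fitted = _ols(xi, yi)
        yhat = slope * x[i] + intercept
        predicted[i] = yhat
        if yhat != 0:
            ratio[i] = y[i] / yhat
        resid = yi - fitted
        dof = xi.size - 2
        s2 = float(np.sum(resid**2) / dof) if dof > 0 else 0.0
        xbar = xi.mean()
        sxx = float(np.sum((xi - xbar) ** 2))
        leverage = 1.0 / xi.size + (x[i] - xbar) ** 2 / sxx
        se_pred = np.sqrt(s2 * (1.0 + leverage))
        e = y[i] - yhat
        if se_pred > 0:
            studentized[i] = e / se_pred
        else:
            studentized[i] = 0.0 if e == 0 else np.copysign(np.inf, e)
    flagged = np.abs(studentized) >= threshold
    return OutlierReport(
        rab_ids=tuple(p.rab_id for p in points),
        studentized=studentized,
        ratio=ratio,
        predicted=predicted,
        flagged=flagged,
        threshold=threshold,
        warnings=tuple(warns),
    )


# ---------------------------------------------------------------------------
# ANOVA with Dunnett many-to-one comparisons


@dataclass(frozen=True)
class AnovaDunnettResult:
    """One-way ANOVA plus Dunnett-adjusted comparisons vs the control group.

    ``comparisons`` maps each non-control label to (mean difference from
    control, t statistic, family-wise adjusted two-sided p).
    """

    f: float
    df_between: int
    df_within: int
    p: float
    control_label: str
    comparisons: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)


def anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    *,
    n_draws: int = DUNNETT_DRAWS,
    seed: int = 0,
) -> AnovaDunnettResult:
    """One-way ANOVA and Dunnett many-to-one tests against a shared control.

    The Dunnett adjustment is computed by seeded Monte-Carlo sampling of the
    joint null: group means are drawn as independent normals with variance
    1/n_g, the pooled variance as chi2(df)/df, and each comparison's
    adjusted p is the probability that the maximum |T| across comparisons
    exceeds the observed |t|.  With a single comparison this reduces to the
    two-sample pooled t-test.
    """
    if control_label not in groups:
        raise ValueError(f"control label {control_label!r} not among groups")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2, got {v.size}")

    k = len(arrays)
    n_total = sum(v.size for v in arrays.values())
    df_b, df_w = k - 1, n_total - k
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in arrays.values())
    if ss_within == 0:
        raise ZeroDivisionError("zero within-group variance everywhere")
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p_anova = float(sps.f.sf(f_stat, df_b, df_w))

    s2 = ss_within / df_w
    ctrl = arrays[control_label]
    others = [lab for lab in arrays if lab != control_label]
    t_obs = {}
    for lab in others:
        g = arrays[lab]
        diff = g.mean() - ctrl.mean()
        t_obs[lab] = (diff, diff / np.sqrt(s2 * (1.0 / g.size + 1.0 / ctrl.size)))

    # Monte-Carlo null of max |T| over the correlated comparisons
    rng = np.random.default_rng(seed)
    m = len(others)
    z0 = rng.normal(0.0, 1.0 / np.sqrt(ctrl.size), size=n_draws)
    zi = rng.normal(0.0, 1.0, size=(n_draws, m)) / np.sqrt(
        [arrays[lab].size for lab in others]
    )
    u = rng.chisquare(df_w, size=n_draws) / df_w
    denom = np.sqrt(u)[:, None] * np.sqrt(
        [1.0 / arrays[lab].size + 1.0 / ctrl.size for lab in others]
    )
    t_null = (zi - z0[:, None]) / denom
    max_abs = np.max(np.abs(t_null), axis=1)

    comparisons = {}
    for lab in others:
        diff, t = t_obs[lab]
        p_adj = float(np.mean(max_abs >= abs(t)))
        comparisons[lab] = (float(diff), float(t), p_adj)

    return AnovaDunnettResult(
        f=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p=p_anova,
        control_label=control_label,
        comparisons=comparisons,
    )
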