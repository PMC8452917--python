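"""Agreement and diagnostic-accuracy statistics for paired FFR data.

Implements the validation suite typically reported for non-invasive FFR
against the invasive reference: Pearson correlation, Bland-Altman bias with
95% limits of agreement, 2x2 diagnostic metrics at the 0.80 ischemia
threshold, and reproducibility indices (intraclass correlation and
coefficient of variation) for repeated measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedFFR:
    """One vessel's paired invasive and simulated FFR at a given phase."""

    vessel_id: str
    phase: str  # pre | post
    ffr_invasive: float
    ffr_sim: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference (bias), SD of differences, and limits of agreement;
    carries the plotting payload (pair means vs differences)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class DiagnosticMetrics:
    """2x2 contingency counts with the derived percentages (0-100 scale,
    full precision; round only for presentation)."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


@dataclass(frozen=True)
class ReproResult:
    """Reproducibility of repeated measurements."""

    icc: float
    icc_ci: tuple[float, float]
    cov_percent: float
    cov_ci: tuple[float, float]
    bland_altman: BlandAltmanResult


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(
    x: Sequence[float], y: Sequence[float], k: float = LOA_MULTIPLIER
) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements: differences d = x - y,
    bias = mean(d), LoA = bias +/- k * SD(d) (sample SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise InsufficientDataError("Bland-Altman needs n >= 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd,
        loa_low=bias - k * sd, loa_high=bias + k * sd,
        means=(x + y) / 2.0, diffs=d,
    )


def diagnostic_metrics(
    predicted_positive: Sequence[bool], truth_positive: Sequence[bool]
) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV, and raw accuracy (percent).

    Raises :class:`DegenerateDataError` when a metric's denominator is empty
    (e.g. no truth positives leaves sensitivity undefined).
    """
    pred = np.asarray(predicted_positive, dtype=bool)
    truth = np.asarray(truth_positive, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    if pred.size == 0:
        raise InsufficientDataError("need at least one observation")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    for name, denom in (("sensitivity", tp + fn), ("specificity", tn + fp),
                        ("PPV", tp + fp), ("NPV", tn + fn)):
        if denom == 0:
            raise DegenerateDataError(f"{name} undefined: empty denominator")
    return DiagnosticMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        ppv=100.0 * tp / (tp + fp),
        npv=100.0 * tn / (tn + fn),
        accuracy=100.0 * (tp + tn) / pred.size,
    )


def intraclass_correlation(a: np.ndarray, b: np.ndarray) -> tuple[float, tuple[float, float]]:
    """ICC (two-way model, absolute agreement, single measurement) with 95% CI.

    Computed with pingouin's ANOVA-based estimator (the ICC2 / ICC(A,1) row,
    whose point estimate is identical under the random- and mixed-effects
    readings of the two-way model).
    """
    import pingouin as pg

    n = a.size
    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "score": np.concatenate([a, b]),
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        table = pg.intraclass_corr(df, targets="target", raters="rater",
                                   ratings="score")
    mask = table["Type"].isin(["ICC2", "ICC(A,1)"])
    row = table[mask].iloc[0]
    icc = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = row[ci_col]
    if not np.isfinite(icc):  # zero between- and within-variance corner
        icc, lo, hi = 1.0, 1.0, 1.0
    return icc, (float(lo), float(min(hi, 1.0)))


def reproducibility_stats(
    measurements_a: Sequence[float],
    measurements_b: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
    k: float = LOA_MULTIPLIER,
) -> ReproResult:
    """Reproducibility of two measurement passes over the same cases.

    COV = SD of paired differences / grand mean of all measurements * 100,
    with a seeded percentile-bootstrap 95% CI over case resampling.  The
    Bland-Altman differences are second pass minus first.
    """
    a = np.asarray(measurements_a, dtype=float)
    b = np.asarray(measurements_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise InsufficientDataError("reproducibility needs n >= 3 pairs")
    ba = bland_altman(b, a, k=k)
    grand = float(np.mean(np.concatenate([a, b])))
    cov = 100.0 * float(np.std(a - b, ddof=1)) / grand
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = a.size
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sd = float(np.std(a[idx] - b[idx], ddof=1))
        gm = float(np.mean(np.concatenate([a[idx], b[idx]])))
        boots[i] = 100.0 * sd / gm
    cov_ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    icc, icc_ci = intraclass_correlation(a, b)
    return ReproResult(icc=icc, icc_ci=icc_ci, cov_percent=cov,
                       cov_ci=cov_ci, bland_altman=ba)


def paired_frame(pairs: Sequence[PairedFFR]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pairs])


def agreement_report(
    df: pd.DataFrame,
    threshold: float = 0.80,
    difference: str = "invasive_minus_sim",
) -> dict:
    """Full agreement report for a paired-FFR table (columns vessel_id,
    phase, ffr_invasive, ffr_sim), per phase and pooled.

    ``difference`` selects the Bland-Altman sign convention; the default
    reports invasive minus simulated.
    """
    out = {}
    phases = list(dict.fromkeys(df["phase"])) + ["all"]
    for phase in phases:
        sub = df if phase == "all" else df[df["phase"] == phase]
        if len(sub) < 3:
            continue
        inv = sub["ffr_invasive"].to_numpy()
        sim = sub["ffr_sim"].to_numpy()
        x, y = (inv, sim) if difference == "invasive_minus_sim" else (sim, inv)
        entry = {"n": int(len(sub)),
                 "mean_invasive": float(np.mean(inv)),
                 "mean_sim": float(np.mean(sim))}
        try:
            r, p = pearson_r(inv, sim)
            entry["pearson_r"], entry["pearson_p"] = r, p
        except DegenerateDataError:
            entry["pearson_r"] = entry["pearson_p"] = float("nan")
        ba = bland_altman(x, y)
        entry["bias"] = ba.bias
        entry["loa"] = [ba.loa_low, ba.loa_high]
        try:
            dm = diagnostic_metrics(sim <= threshold, inv <= threshold)
            entry["diagnostics"] = {
                "tp": dm.tp, "fp": dm.fp, "fn": dm.fn, "tn": dm.tn,
                "sensitivity": dm.sensitivity, "specificity": dm.specificity,
                "ppv": dm.ppv, "npv": dm.npv, "accuracy": dm.accuracy,
            }
        except DegenerateDataError as exc:
            entry["diagnostics"] = {"undefined": str(exc)}
        out[phase] = entry
    return out
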