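"""QMSP quantitation and diagnostic-panel evaluation statistics.

Covers standard-curve quantitation of Ct values, normalization to the
beta-actin loading control, dichotomization at zero, any-marker panel
combination, sensitivity/specificity with exact (Clopper-Pearson) binomial
confidence intervals, two-sided Fisher exact tests, Cohen's kappa with a
large-sample CI, percent agreement, paired Spearman correlation, and
2^-ddCt relative expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAX_QMSP_CYCLES = 38.0


class InvalidSampleError(ValueError):
    """Loading control failed to amplify: the sample is invalid, not negative."""


@dataclass
class StandardCurve:
    """Fitted line Ct = slope * log10(quantity) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    points: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class DiagnosticSummary:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    se_ci: tuple[float, float]
    sp_ci: tuple[float, float]
    fisher_p: float


@dataclass
class ConcordanceSummary:
    a: int  # both positive
    b: int  # rater/assay B positive only (e.g. saliva only)
    c: int  # rater/assay A positive only (e.g. tissue only)
    d: int  # both negative
    kappa: Optional[float]
    kappa_ci: Optional[tuple[float, float]]
    percent_agreement: float
    spearman_rho: Optional[float] = None
    spearman_p: Optional[float] = None


# ---------------------------------------------------------------------------
# Standard-curve quantitation
# ---------------------------------------------------------------------------

def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Ct against log10 input quantity.

    points: (log10 quantity, Ct) pairs; needs >= 2 distinct quantities.
    A non-negative slope is physically implausible and logged as a warning.
    """
    pts = [(float(x), float(y)) for x, y in points]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.unique(xs).size < 2:
        raise ValueError("standard curve needs >= 2 distinct log-quantity points")
    res = stats.linregress(xs, ys)
    if res.slope >= 0:
        logger.warning("standard curve slope %.3f is non-negative", res.slope)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        points=pts,
    )


def quantify(
    ct: Optional[float], curve: StandardCurve, max_cycles: float = MAX_QMSP_CYCLES
) -> float:
    """Interpolate input quantity from a Ct value via the standard curve.

    Undetermined Ct (None/NaN) or Ct beyond max_cycles is censored to 0 to
    eliminate false-positive signal.
    """
    if ct is None or (isinstance(ct, float) and math.isnan(ct)) or ct > max_cycles:
        return 0.0
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def relative_level(q_target: float, q_actin: float) -> float:
    """Methylation level as 100 * target / beta-actin."""
    if q_actin <= 0:
        raise InvalidSampleError(
            "beta-actin did not amplify: insufficient DNA, sample invalid"
        )
    if q_target < 0:
        raise ValueError("target quantity must be nonnegative")
    return 100.0 * q_target / q_actin


def dichotomize(level: float) -> bool:
    """Methylated iff any signal was detected (level strictly > 0)."""
    if level < 0:
        raise ValueError("relative level must be nonnegative")
    return level > 0


def panel_combine(calls: Sequence[bool]) -> bool:
    """Any-marker rule: panel positive iff any individual marker is positive."""
    if len(calls) == 0:
        raise ValueError("panel_combine requires at least one call")
    return any(bool(c) for c in calls)


# ---------------------------------------------------------------------------
# Exact binomial machinery
# ---------------------------------------------------------------------------

def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (inverse incomplete beta)."""
    if not (0 <= x <= n) or n < 1:
        raise ValueError("require 0 <= x <= n with n >= 1")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood method.

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (relative
    tolerance 1e-7). All-zero table gives p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def sensitivity_specificity(
    calls: Sequence[bool], disease_labels: Sequence[bool], level: float = 0.95
) -> DiagnosticSummary:
    """Diagnostic 2x2 from per-patient binary calls and disease labels.

    Sensitivity = test-positive among diseased, specificity = test-negative
    among non-diseased, each with an exact binomial CI; Fisher p compares
    positivity between the two groups.
    """
    calls = np.asarray(calls, dtype=bool)
    disease = np.asarray(disease_labels, dtype=bool)
    if calls.shape != disease.shape:
        raise ValueError("calls and disease labels differ in length")
    n_dis = int(disease.sum())
    n_ctl = int((~disease).sum())
    if n_dis == 0 or n_ctl == 0:
        raise ValueError("need at least one diseased and one control subject")
    tp = int((calls & disease).sum())
    fn = n_dis - tp
    fp = int((calls & ~disease).sum())
    tn = n_ctl - fp
    se = tp / n_dis
    sp = tn / n_ctl
    return DiagnosticSummary(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=se, specificity=sp,
        se_ci=clopper_pearson(tp, n_dis, level),
        sp_ci=clopper_pearson(tn, n_ctl, level),
        fisher_p=fisher_exact_2x2(tp, fn, fp, tn),
    )


# ---------------------------------------------------------------------------
# Agreement / concordance
# ---------------------------------------------------------------------------

def cohen_kappa(
    a: int, b: int, c: int, d: int, level: float = 0.95
) -> tuple[Optional[float], Optional[tuple[float, float]]]:
    """Cohen's kappa on a paired 2x2 with a large-sample (Fleiss) CI.

    Returns (None, None) when expected agreement p_e = 1 (kappa undefined).
    """
    n = a + b + c + d
    if n < 1:
        raise ValueError("need at least one paired observation")
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if p_e == 1.0:
        logger.warning("kappa undefined: expected agreement is 1")
        return None, None
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    z = stats.norm.ppf(0.5 + level / 2)
    return kappa, (kappa - z * se, kappa + z * se)


def percent_agreement(a: int, b: int, c: int, d: int) -> float:
    """100 * (a + d) / N."""
    n = a + b + c + d
    if n < 1:
        raise ValueError("need at least one paired observation")
    return 100.0 * (a + d) / n


def reconstruct_paired_table(
    n: int, pos_a: int, pos_b: int, agreement_percent: float
) -> tuple[int, int, int, int]:
    """Recover the unique integer paired 2x2 from marginals + agreement.

    a+b = pos_a, a+c = pos_b, a+d = round(n * agreement / 100). Raises when no
    consistent nonnegative integer solution exists.
    """
    if not (0 <= pos_a <= n and 0 <= pos_b <= n):
        raise ValueError("positive counts must lie in [0, n]")
    agree = round(n * agreement_percent / 100.0)
    bc = n - agree
    twice_a = pos_a + pos_b - bc
    if twice_a < 0 or twice_a % 2 != 0:
        raise ValueError("inputs admit no integer 2x2 reconstruction")
    a = twice_a // 2
    b = pos_a - a
    c = pos_b - a
    d = agree - a
    cells = (a, b, c, d)
    if any(v < 0 for v in cells):
        raise ValueError("inputs admit no nonnegative 2x2 reconstruction")
    return cells


def paired_spearman(
    levels_a: Sequence[float], levels_b: Sequence[float]
) -> tuple[float, float]:
    """Spearman correlation between paired continuous levels (e.g. tissue vs
    saliva relative methylation per patient)."""
    x = np.asarray(levels_a, dtype=float)
    y = np.asarray(levels_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined on a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def concordance_summary(
    calls_a: Sequence[bool],
    calls_b: Sequence[bool],
    levels_a: Optional[Sequence[float]] = None,
    levels_b: Optional[Sequence[float]] = None,
) -> ConcordanceSummary:
    """Paired agreement between two assays on the same patients.

    Convention: a = both positive, b = only assay B positive, c = only assay A
    positive, d = both negative.
    """
    x = np.asarray(calls_a, dtype=bool)
    y = np.asarray(calls_b, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("paired call vectors differ in length")
    a = int((x & y).sum())
    b = int((~x & y).sum())
    c = int((x & ~y).sum())
    d = int((~x & ~y).sum())
    kappa, kci = cohen_kappa(a, b, c, d)
    rho = p = None
    if levels_a is not None and levels_b is not None:
        try:
            rho, p = paired_spearman(levels_a, levels_b)
        except ValueError as exc:
            logger.warning("paired Spearman unavailable: %s", exc)
    return ConcordanceSummary(
        a=a, b=b, c=c, d=d,
        kappa=kappa, kappa_ci=kci,
        percent_agreement=percent_agreement(a, b, c, d),
        spearman_rho=rho, spearman_p=p,
    )


# ---------------------------------------------------------------------------
# qRT-PCR relative expression
# ---------------------------------------------------------------------------

def ddct_expression(
    ct_gene_sample: float,
    ct_ref_sample: Union[float, Sequence[float]],
    ct_gene_calibrator: float,
    ct_ref_calibrator: Union[float, Sequence[float]],
) -> float:
    """Fold change by 2^-ddCt; multiple reference genes enter as the
    arithmetic mean of their Ct values."""
    ref_s = float(np.mean(np.atleast_1d(np.asarray(ct_ref_sample, dtype=float))))
    ref_c = float(np.mean(np.atleast_1d(np.asarray(ct_ref_calibrator, dtype=float))))
    for v in (ct_gene_sample, ref_s, ct_gene_calibrator, ref_c):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_gene_sample - ref_s) - (ct_gene_calibrator - ref_c)
    return float(2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# QMSP table evaluation pipeline
# ---------------------------------------------------------------------------

def quantify_qmsp(
    qmsp: "pd.DataFrame | object",
    curve: StandardCurve,
    max_cycles: float = MAX_QMSP_CYCLES,
) -> pd.DataFrame:
    """Compute relative levels and binary calls for a long-format QMSP table.

    Accepts a QmspTable or its DataFrame. Rows whose beta-actin control fails
    get call = NA (excluded from downstream denominators). Pre-supplied
    quantity columns take precedence over Ct interpolation.
    """
    df = getattr(qmsp, "table", qmsp).copy()
    qt = df["quantity_target"] if "quantity_target" in df else pd.Series(np.nan, index=df.index)
    qa = df["quantity_actin"] if "quantity_actin" in df else pd.Series(np.nan, index=df.index)
    levels, calls = [], []
    for i, row in df.iterrows():
        q_t = qt.loc[i]
        q_a = qa.loc[i]
        if pd.isna(q_t):
            q_t = quantify(row["ct_target"], curve, max_cycles)
        if pd.isna(q_a):
            q_a = quantify(row["ct_actin"], curve, max_cycles)
        try:
            lvl = relative_level(q_t, q_a)
        except InvalidSampleError:
            levels.append(np.nan)
            calls.append(pd.NA)
            continue
        levels.append(lvl)
        calls.append(dichotomize(lvl))
    df["relative_level"] = levels
    df["call"] = pd.array(calls, dtype="boolean")
    return df
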