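"""Heterogeneity diagnostics: Cochran's Q, I-squared, per-variant Q
contributions, outlier removal with refit, and leave-one-out analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mrkit.estimators import MREstimate, RatioEstimate, gx_heterogeneity, ivw, wald_ratios
from mrkit.sumstats import HarmonisedSet

Z95 = 1.96


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    p: float
    i2: float
    i2_ci_low: float | None = None
    i2_ci_high: float | None = None


@dataclass(frozen=True)
class QContribution:
    variant_id: str
    q_j: float
    exceeds_nominal: bool
    exceeds_bonferroni: bool


@dataclass
class OutlierReport:
    thresholds: tuple[float, float]  # (nominal, bonferroni) chi2_1 quantiles
    flagged: list[str]
    refit: MREstimate
    refit_het: HeterogeneityResult
    contributions: list[QContribution]


@dataclass
class LooResult:
    rows: list[tuple[str, MREstimate]]
    max_influence_id: str


@dataclass(frozen=True)
class GxHeterogeneity:
    q_gx: float
    i2_gx: float
    simex_recommended: bool


def _i2_confidence_interval(q: float, k: int) -> tuple[float, float]:
    """Test-based CI for I2 via ln H (Higgins-Thompson).

    H = sqrt(Q/(k-1)) clamped at 1.  se(ln H) uses the Q > k branch
    0.5*(ln Q - ln(k-1))/(sqrt(2Q) - sqrt(2k-3)) and otherwise the small-Q
    approximation sqrt(1/(2(k-2)) * (1 - 1/(3(k-2)^2))); requires k >= 3.
    """
    df = k - 1
    h = max(1.0, np.sqrt(q / df))
    if q > k:
        se_ln_h = 0.5 * (np.log(q) - np.log(df)) / (np.sqrt(2 * q) - np.sqrt(2 * k - 3))
    else:
        se_ln_h = np.sqrt(1.0 / (2 * (k - 2)) * (1.0 - 1.0 / (3 * (k - 2) ** 2)))
    ln_h = np.log(h)
    h_lo = max(1.0, np.exp(ln_h - Z95 * se_ln_h))
    h_hi = max(1.0, np.exp(ln_h + Z95 * se_ln_h))
    to_i2 = lambda hh: float(max(0.0, min(1.0 - 1e-12, (hh**2 - 1.0) / hh**2)))
    return to_i2(h_lo), to_i2(h_hi)


def cochran_q(
    ratios: Sequence[RatioEstimate], pooled: MREstimate
) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios about their IVW-FE pooled value.

    Q = sum w_j (ratio_j - pooled)^2 on k-1 df; I2 = max(0, (Q - df)/Q).
    A test-based I2 CI is reported for k >= 3 (None for k = 2).
    """
    k = len(ratios)
    if k < 2:
        raise ValueError("heterogeneity needs at least 2 ratios")
    b = np.array([r.ratio for r in ratios])
    w = np.array([r.weight for r in ratios])
    q = float(np.sum(w * (b - pooled.beta) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df)) if q > 0 else 1.0
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    if k >= 3:
        lo, hi = _i2_confidence_interval(q, k)
    else:
        lo = hi = None
    return HeterogeneityResult(Q=q, df=df, p=p, i2=i2, i2_ci_low=lo, i2_ci_high=hi)


def q_thresholds(k: int, alpha: float = 0.05) -> tuple[float, float]:
    """(nominal, Bonferroni) upper chi2_1 quantiles for Q contributions."""
    return (
        float(stats.chi2.ppf(1 - alpha, df=1)),
        float(stats.chi2.ppf(1 - alpha / k, df=1)),
    )


def q_contributions(
    ratios: Sequence[RatioEstimate],
    pooled: MREstimate,
    alpha: float = 0.05,
) -> list[QContribution]:
    """Per-variant contributions q_j = w_j (ratio_j - pooled)^2, flagged
    against nominal (alpha) and Bonferroni (alpha/k) chi2_1 quantiles.
    Contributions sum to Q exactly."""
    k = len(ratios)
    nominal, bonferroni = q_thresholds(k, alpha)
    out = []
    for r in ratios:
        q_j = float(r.weight * (r.ratio - pooled.beta) ** 2)
        out.append(
            QContribution(
                variant_id=r.variant_id,
                q_j=q_j,
                exceeds_nominal=q_j > nominal,
                exceeds_bonferroni=q_j > bonferroni,
            )
        )
    return out


def remove_outliers_refit(
    hset: HarmonisedSet,
    alpha: float = 0.05,
    iterative: bool = False,
    second_order: bool = False,
) -> OutlierReport:
    """Flag Bonferroni-exceeding Q contributors and refit IVW-FE without them.

    The default is a single pass; ``iterative`` repeats flagging on the
    refitted set until no further variant exceeds the (recomputed)
    Bonferroni threshold.
    """
    if hset.k < 3:
        raise ValueError("outlier analysis needs at least 3 pairs")
    ratios, _ = wald_ratios(hset, second_order=second_order)
    pooled = ivw(ratios, mode="FE")
    contributions = q_contributions(ratios, pooled, alpha)
    thresholds = q_thresholds(len(ratios), alpha)
    flagged = [c.variant_id for c in contributions if c.exceeds_bonferroni]

    current = [r for r in ratios if r.variant_id not in set(flagged)]
    if iterative:
        while True:
            if len(current) < 3:
                break
            pooled_i = ivw(current, mode="FE")
            extra = [
                c.variant_id
                for c in q_contributions(current, pooled_i, alpha)
                if c.exceeds_bonferroni
            ]
            if not extra:
                break
            flagged.extend(extra)
            current = [r for r in current if r.variant_id not in set(extra)]

    if len(current) < 2:
        raise ValueError("outlier removal left fewer than 2 instruments")
    refit = ivw(current, mode="FE")
    refit_het = cochran_q(current, refit)
    return OutlierReport(
        thresholds=thresholds,
        flagged=flagged,
        refit=refit,
        refit_het=refit_het,
        contributions=contributions,
    )


def leave_one_out(ratios: Sequence[RatioEstimate]) -> LooResult:
    """IVW-FE refits each omitting one SNP; flags the most influential one."""
    k = len(ratios)
    if k < 3:
        raise ValueError("leave-one-out needs at least 3 ratios")
    full = ivw(ratios, mode="FE")
    rows: list[tuple[str, MREstimate]] = []
    best_id, best_shift = ratios[0].variant_id, -1.0
    for i, r in enumerate(ratios):
        sub = list(ratios[:i]) + list(ratios[i + 1 :])
        est = ivw(sub, mode="FE")
        rows.append((r.variant_id, est))
        shift = abs(est.beta - full.beta)
        if shift > best_shift:
            best_id, best_shift = r.variant_id, shift
    return LooResult(rows=rows, max_influence_id=best_id)


def i2_gx(hset: HarmonisedSet) -> GxHeterogeneity:
    """Relative measurement error of the exposure effects (NOME violation).

    Computed on pairs oriented so all exposure effects are non-negative, as
    in the Egger fit.  Values below 0.9 recommend SIMEX correction.
    """
    if hset.k < 2:
        raise ValueError("i2_gx needs at least 2 pairs")
    gx = np.abs(hset.gx())
    q, i2 = gx_heterogeneity(gx, hset.gx_se())
    return GxHeterogeneity(q_gx=q, i2_gx=i2, simex_recommended=i2 < 0.9)


# ---------------------------------------------------------------------------
# TSV emission (plot-ready tables)


def heterogeneity_frame(het: HeterogeneityResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "Q": het.Q,
                "df": het.df,
                "p": het.p,
                "i2": het.i2,
                "i2_ci_low": het.i2_ci_low,
                "i2_ci_high": het.i2_ci_high,
            }
        ]
    )


def contributions_frame(
    contributions: Sequence[QContribution], thresholds: tuple[float, float]
) -> pd.DataFrame:
    nominal, bonferroni = thresholds
    return pd.DataFrame(
        [
            {
                "variant_id": c.variant_id,
                "q_j": c.q_j,
                "nominal_threshold": nominal,
                "bonferroni_threshold": bonferroni,
                "flagged": c.exceeds_bonferroni,
            }
            for c in contributions
        ]
    )


def loo_frame(loo: LooResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "left_out_id": vid,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.p,
            }
            for vid, est in loo.rows
        ]
    )
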