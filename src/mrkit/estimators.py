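"""Per-SNP Wald ratios and pooled causal-effect estimators.

All estimators work on the log-odds scale; :func:`to_odds_scale` converts a
pooled estimate to an odds ratio with its 95% CI.  Bootstrap-based standard
errors (weighted median / weighted mode) are driven by a single seeded
generator and are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from mrkit.sumstats import HarmonisedSet

Z95 = 1.96  # fixed 95% multiplier used throughout

DEFAULT_BOOTSTRAP_B = 1000
DEFAULT_SIMEX_LAMBDAS = (0.0, 0.5, 1.0, 1.5, 2.0)
SIMEX_I2GX_THRESHOLD = 0.9


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio (outcome effect over exposure effect)."""

    variant_id: str
    ratio: float
    se: float
    weight: float  # 1 / se**2

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("ratio se must be positive")


@dataclass(frozen=True)
class MREstimate:
    """Pooled causal effect on the log-odds scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    df_note: str = "normal"


@dataclass(frozen=True)
class OddsScaleResult:
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    p: float


@dataclass
class EggerResult:
    """MR-Egger slope + intercept, optionally SIMEX-corrected."""

    slope: MREstimate
    intercept_beta: float
    intercept_se: float
    intercept_p: float
    i2_gx: float
    simex_applied: bool = False
    simex_lambda_grid: tuple[float, ...] = ()
    simex_B: int = 0


def _as_arrays(ratios: Sequence[RatioEstimate]):
    b = np.array([r.ratio for r in ratios], dtype=float)
    se = np.array([r.se for r in ratios], dtype=float)
    w = np.array([r.weight for r in ratios], dtype=float)
    return b, se, w


def _normal_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wald_ratios(
    hset: HarmonisedSet, second_order: bool = False
) -> tuple[list[RatioEstimate], list[tuple[str, str]]]:
    """Per-SNP Wald ratios gy/gx with delta-method standard errors.

    The default (first-order) SE is gy_se/|gx|, which makes IVW pooling
    equivalent to weighted regression through the origin.  ``second_order``
    adds the exposure-uncertainty term gy^2 * gx_se^2 / gx^4 under the
    square root.  Pairs with gx exactly zero are excluded with reason
    ``zero_gx`` (second return value).
    """
    ratios: list[RatioEstimate] = []
    excluded: list[tuple[str, str]] = []
    for p in hset.pairs:
        if p.gx_beta == 0:
            excluded.append((p.variant_id, "zero_gx"))
            continue
        ratio = p.gy_beta / p.gx_beta
        var = p.gy_se**2 / p.gx_beta**2
        if second_order:
            var += p.gy_beta**2 * p.gx_se**2 / p.gx_beta**4
        se = float(np.sqrt(var))
        ratios.append(
            RatioEstimate(
                variant_id=p.variant_id, ratio=float(ratio), se=se, weight=1.0 / se**2
            )
        )
    return ratios, excluded


def ivw(ratios: Sequence[RatioEstimate], mode: str = "FE") -> MREstimate:
    """Inverse-variance-weighted pooling of Wald ratios.

    mode="FE": fixed effect, se = (sum w)^(-1/2).
    mode="RE": multiplicative overdispersion; the FE se is scaled by
        max(1, sqrt(Q/(k-1))).
    mode="RE-ADD": additive DerSimonian-Laird random effects.
    """
    if len(ratios) < 2:
        raise ValueError("IVW needs at least 2 ratios")
    b, se, w = _as_arrays(ratios)
    k = len(b)
    beta = float(np.sum(w * b) / np.sum(w))
    se_fe = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - beta) ** 2))

    if mode == "FE":
        method, pooled_se, note = "IVW-FE", se_fe, "normal"
    elif mode == "RE":
        scale = max(1.0, float(np.sqrt(q / (k - 1))))
        method, pooled_se, note = "IVW-RE", se_fe * scale, "normal; multiplicative overdispersion"
    elif mode == "RE-ADD":
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (se**2 + tau2)
        beta = float(np.sum(w_star * b) / np.sum(w_star))
        method, pooled_se, note = (
            "IVW-RE",
            float(1.0 / np.sqrt(np.sum(w_star))),
            "normal; DerSimonian-Laird additive",
        )
    else:
        raise ValueError(f"unknown IVW mode: {mode!r}")

    return MREstimate(
        method=method,
        beta=beta,
        se=pooled_se,
        ci_low=beta - Z95 * pooled_se,
        ci_high=beta + Z95 * pooled_se,
        p=_normal_p(beta / pooled_se),
        n_snps=k,
        df_note=note,
    )


def _interp_weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b, kind="stable")
    b, w = b[order], w[order]
    w = w / w.sum()
    pos = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, pos, b))


def _bootstrap_se(
    estimate_fn, b: np.ndarray, se: np.ndarray, w: np.ndarray, B: int, rng
) -> float:
    draws = b[None, :] + se[None, :] * rng.standard_normal((B, len(b)))
    ests = np.array([estimate_fn(draws[i], w) for i in range(B)])
    return float(np.std(ests, ddof=1))


def weighted_median(
    ratios: Sequence[RatioEstimate],
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = 0,
) -> MREstimate:
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    Ratios are sorted; the estimate interpolates the weighted empirical
    quantile function to position 0.5 (an order statistic hit exactly at 0.5
    is returned as is).  The SE is the standard deviation of the estimate
    over B draws ratio_j* ~ Normal(ratio_j, se_j) with fixed weights.
    """
    if len(ratios) < 3:
        raise ValueError("weighted median needs at least 3 ratios")
    if B < 100:
        raise ValueError("B must be >= 100")
    b, se, w = _as_arrays(ratios)
    beta = _interp_weighted_median(b, w)
    rng = np.random.default_rng(seed)
    boot_se = _bootstrap_se(lambda x, ww: _interp_weighted_median(x, ww), b, se, w, B, rng)
    return MREstimate(
        method="WMe",
        beta=beta,
        se=boot_se,
        ci_low=beta - Z95 * boot_se,
        ci_high=beta + Z95 * boot_se,
        p=_normal_p(beta / boot_se) if boot_se > 0 else 1.0,
        n_snps=len(b),
        df_note="normal; bootstrap SE",
    )


def _mode_bandwidth(b: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: 0.9 * min(sd, IQR/1.34) * k^(-1/5), scaled
    by phi.  Falls back to the non-zero candidate when sd or IQR degenerates."""
    k = len(b)
    sd = float(np.std(b, ddof=1))
    iqr = float(np.subtract(*np.percentile(b, [75, 25])))
    candidates = [c for c in (sd, iqr / 1.34) if c > 0]
    if not candidates:
        return 0.0
    return phi * 0.9 * min(candidates) * k ** (-1 / 5)


def _mode_estimate(
    b: np.ndarray, w: np.ndarray, phi: float, grid_points: int = 512
) -> float:
    h = _mode_bandwidth(b, phi)
    if h <= 0:
        return float(b[0])
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, grid_points)
    wn = w / w.sum()
    dens = (wn[:, None] * np.exp(-0.5 * ((grid[None, :] - b[:, None]) / h) ** 2)).sum(
        axis=0
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    ratios: Sequence[RatioEstimate],
    phi: float = 1.0,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = 0,
    grid_points: int = 512,
) -> MREstimate:
    """Weighted mode-based estimate: argmax of the weight-weighted normal
    kernel density of the ratios, bootstrap SE as in the weighted median."""
    if len(ratios) < 3:
        raise ValueError("weighted mode needs at least 3 ratios")
    if phi <= 0:
        raise ValueError("phi must be positive")
    b, se, w = _as_arrays(ratios)
    beta = _mode_estimate(b, w, phi, grid_points)
    rng = np.random.default_rng(seed)
    boot_se = _bootstrap_se(
        lambda x, ww: _mode_estimate(x, ww, phi, grid_points), b, se, w, B, rng
    )
    return MREstimate(
        method="WMo",
        beta=beta,
        se=boot_se,
        ci_low=beta - Z95 * boot_se,
        ci_high=beta + Z95 * boot_se,
        p=_normal_p(beta / boot_se) if boot_se > 0 else 1.0,
        n_snps=len(b),
        df_note="normal; bootstrap SE",
    )


# ---------------------------------------------------------------------------
# MR-Egger and SIMEX


def _oriented(hset: HarmonisedSet):
    """Orient every pair so the exposure effect is non-negative."""
    gx, gy = hset.gx(), hset.gy()
    sign = np.where(gx < 0, -1.0, 1.0)
    return gx * sign, hset.gx_se(), gy * sign, hset.gy_se()


def gx_heterogeneity(gx: np.ndarray, gx_se: np.ndarray) -> tuple[float, float]:
    """Q and I2 of the (oriented) exposure effects weighted by 1/gx_se^2.

    The I2 here (often written I2_GX) measures relative measurement error in
    the exposure effects; low values signal regression dilution of the Egger
    slope.
    """
    w = 1.0 / np.maximum(gx_se, 1e-12) ** 2  # zero SE = no measurement error
    mean = np.sum(w * gx) / np.sum(w)
    q = float(np.sum(w * (gx - mean) ** 2))
    k = len(gx)
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return q, i2


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted least squares of y on [1, x].

    Returns (intercept, slope, var_intercept, var_slope, rss_w); vectorised
    over a leading batch axis of x/y.
    """
    sw = np.sum(w, axis=-1)
    sx = np.sum(w * x, axis=-1)
    sy = np.sum(w * y, axis=-1)
    sxx = np.sum(w * x * x, axis=-1)
    sxy = np.sum(w * x * y, axis=-1)
    syy = np.sum(w * y * y, axis=-1)
    det = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det
    rss = syy - slope * sxy - intercept * sy
    return intercept, slope, sxx / det, sw / det, np.maximum(rss, 0.0)


def mr_egger(hset: HarmonisedSet, overdispersion: bool = True, t_dist: bool = True) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure effects with an
    unconstrained intercept (the average directional pleiotropic effect).

    Pairs are oriented so all exposure effects are non-negative.  SEs carry
    a multiplicative overdispersion factor max(1, sqrt(RSS_w/(k-2))) and
    p-values use a t reference with k-2 df (normal optional).
    """
    if hset.k < 3:
        raise ValueError("MR-Egger needs at least 3 pairs")
    gx, gx_se, gy, gy_se = _oriented(hset)
    k = hset.k
    w = 1.0 / gy_se**2
    intercept, slope, vi, vs, rss = _wls_line(gx, gy, w)
    scale2 = max(1.0, rss / (k - 2)) if overdispersion else 1.0
    slope_se = float(np.sqrt(vs * scale2))
    int_se = float(np.sqrt(vi * scale2))

    if t_dist:
        pfun = lambda z: float(min(1.0, 2.0 * stats.t.sf(abs(z), df=k - 2)))
        note = f"t({k - 2})"
    else:
        pfun = _normal_p
        note = "normal"

    q_gx, i2_gx_val = gx_heterogeneity(gx, gx_se)
    slope_est = MREstimate(
        method="Egger",
        beta=float(slope),
        se=slope_se,
        ci_low=float(slope) - Z95 * slope_se,
        ci_high=float(slope) + Z95 * slope_se,
        p=pfun(slope / slope_se) if slope_se > 0 else 1.0,
        n_snps=k,
        df_note=note,
    )
    return EggerResult(
        slope=slope_est,
        intercept_beta=float(intercept),
        intercept_se=int_se,
        intercept_p=pfun(intercept / int_se) if int_se > 0 else 1.0,
        i2_gx=i2_gx_val,
    )


def quadratic_extrapolate(lambdas: Sequence[float], values: Sequence[float]) -> float:
    """Fit a quadratic in lambda and evaluate it at lambda = -1 (the SIMEX
    no-measurement-error limit)."""
    coef = np.polyfit(np.asarray(lambdas, dtype=float), np.asarray(values, dtype=float), deg=2)
    return float(np.polyval(coef, -1.0))


def egger_simex(
    hset: HarmonisedSet,
    lambda_grid: Sequence[float] = DEFAULT_SIMEX_LAMBDAS,
    B: int = 200,
    seed: int = 0,
) -> EggerResult:
    """SIMEX dilution correction for the MR-Egger slope.

    For each lambda, the exposure effects are perturbed with extra noise of
    variance lambda * gx_se^2 (B replicates) and the Egger fit is averaged;
    a quadratic in lambda is then extrapolated to lambda = -1, the
    no-measurement-error limit.  The SE extrapolates the per-lambda mean
    model variance the same way (falling back to the naive model SE when the
    extrapolated variance is not positive).
    """
    if hset.k < 3:
        raise ValueError("SIMEX needs at least 3 pairs")
    if B < 1:
        raise ValueError("B must be positive")
    naive = mr_egger(hset)
    gx, gx_se, gy, gy_se = _oriented(hset)
    if np.all(gx_se == 0):
        return naive  # no measurement error to simulate

    k = hset.k
    w = 1.0 / gy_se**2
    rng = np.random.default_rng(seed)
    lams = np.asarray(lambda_grid, dtype=float)

    mean_slopes, mean_ints, mean_vars_s, mean_vars_i = [], [], [], []
    for lam in lams:
        if lam == 0:
            gx_b = gx[None, :]
        else:
            z = rng.standard_normal((B, k))
            gx_b = gx[None, :] + np.sqrt(lam) * gx_se[None, :] * z
        intercept, slope, vi, vs, rss = _wls_line(gx_b, gy[None, :], w[None, :])
        scale2 = np.maximum(1.0, rss / (k - 2))
        mean_slopes.append(float(np.mean(slope)))
        mean_ints.append(float(np.mean(intercept)))
        mean_vars_s.append(float(np.mean(vs * scale2)))
        mean_vars_i.append(float(np.mean(vi * scale2)))

    slope_x = quadratic_extrapolate(lams, mean_slopes)
    int_x = quadratic_extrapolate(lams, mean_ints)
    var_s = quadratic_extrapolate(lams, mean_vars_s)
    var_i = quadratic_extrapolate(lams, mean_vars_i)
    slope_se = float(np.sqrt(var_s)) if var_s > 0 else naive.slope.se
    int_se = float(np.sqrt(var_i)) if var_i > 0 else naive.intercept_se

    pfun = lambda z: float(min(1.0, 2.0 * stats.t.sf(abs(z), df=k - 2)))
    slope_est = MREstimate(
        method="Egger-SIMEX",
        beta=slope_x,
        se=slope_se,
        ci_low=slope_x - Z95 * slope_se,
        ci_high=slope_x + Z95 * slope_se,
        p=pfun(slope_x / slope_se) if slope_se > 0 else 1.0,
        n_snps=k,
        df_note=f"t({k - 2}); SIMEX extrapolated",
    )
    return EggerResult(
        slope=slope_est,
        intercept_beta=int_x,
        intercept_se=int_se,
        intercept_p=pfun(int_x / int_se) if int_se > 0 else 1.0,
        i2_gx=naive.i2_gx,
        simex_applied=True,
        simex_lambda_grid=tuple(float(x) for x in lams),
        simex_B=B,
    )


# ---------------------------------------------------------------------------
# reporting helpers


def to_odds_scale(est: MREstimate) -> OddsScaleResult:
    """Exponentiate a pooled log-odds estimate to the odds-ratio scale."""
    return OddsScaleResult(
        odds_ratio=float(np.exp(est.beta)),
        or_ci_low=float(np.exp(est.beta - Z95 * est.se)),
        or_ci_high=float(np.exp(est.beta + Z95 * est.se)),
        p=est.p,
    )


def p_from_or_ci(odds_ratio: float, ci_low: float, ci_high: float) -> float:
    """Two-sided normal p implied by an odds ratio and its 95% CI.

    beta = ln(OR); se = (ln(upper) - ln(lower)) / (2 * 1.96).  Useful as a
    consistency check on reported results.
    """
    beta = np.log(odds_ratio)
    se = (np.log(ci_high) - np.log(ci_low)) / (2 * Z95)
    return _normal_p(beta / se)


def or_from_ci(ci_low: float, ci_high: float) -> float:
    """Point estimate implied by a symmetric Wald interval on the log scale:
    the geometric mean of the CI bounds."""
    return float(np.sqrt(ci_low * ci_high))
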