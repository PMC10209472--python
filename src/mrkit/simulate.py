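"""Seeded synthetic two-sample GWAS summary statistics with known truth.

Statistics are generated directly on the (beta, se) scale — the object the
analysis consumes — for a configurable number of instruments, causal slope
and pleiotropy scenario.  One root seed drives everything; replicate streams
in :func:`recovery_experiment` are spawned from it with
``numpy.random.SeedSequence.spawn`` so replicates are independent and the
whole experiment is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mrkit import diagnostics, estimators
from mrkit.sumstats import GwasTable, HarmonisedSet, SumStatRecord, harmonise

SCENARIOS = ("none", "balanced", "directional", "correlated")

#: non-palindromic allele pairs cycled over variants
_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))

METHOD_LABELS = ("IVW-FE", "IVW-RE", "WMe", "WMo", "Egger", "Egger-SIMEX")


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic two-sample dataset.

    True instrument effects are |Normal(0, gamma_sd^2)| + gamma_floor; the
    default SE ranges put per-SNP F statistics roughly in the 10-100 range.
    ``pleiotropy`` picks the distribution of the direct effects alpha_j:
    none (0), balanced (Normal(0, tau^2)), directional (Normal(mu_alpha,
    tau^2)) or correlated (rho * gamma_j + Normal(0, tau^2), violating
    InSIDE).  ``n_outliers`` plants that many extra-large direct effects of
    size ``outlier_alpha`` on randomly chosen variants;
    ``outlier_se_scale`` additionally inflates those variants' outcome SEs,
    which keeps their IVW weight small so the planted heterogeneity shows up
    in their own Q contribution rather than dragging the pooled estimate.
    """

    k: int = 19
    beta_true: float = 0.0
    gamma_sd: float = 0.15
    gamma_floor: float = 0.05
    se_x_range: tuple[float, float] = (0.02, 0.05)
    se_y_range: tuple[float, float] = (0.05, 0.15)
    pleiotropy: str = "none"
    tau: float = 0.0
    mu_alpha: float = 0.0
    rho: float = 0.0
    n_outliers: int = 0
    outlier_alpha: float = 0.0
    outlier_se_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.pleiotropy not in SCENARIOS:
            raise ValueError(
                f"unknown pleiotropy scenario {self.pleiotropy!r}; "
                f"expected one of {SCENARIOS}"
            )
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        for rng_ in (self.se_x_range, self.se_y_range):
            if not (0 < rng_[0] <= rng_[1]):
                raise ValueError("se ranges must be positive and ordered")
        if not 0 <= self.n_outliers <= self.k:
            raise ValueError("n_outliers must be in [0, k]")
        if self.outlier_se_scale <= 0:
            raise ValueError("outlier_se_scale must be positive")


@dataclass
class SimTruth:
    """Generating parameters behind one simulated dataset."""

    beta_true: float
    gamma: np.ndarray
    alpha: np.ndarray
    outlier_ids: list[str] = field(default_factory=list)


@dataclass
class MethodRecovery:
    bias: float
    rmse: float
    ci_coverage: float
    rejection_rate: float


@dataclass
class RecoveryReport:
    per_method: dict[str, MethodRecovery]
    q_rejection_rate: float
    replicates: int
    egger_intercept_mean: float | None = None
    outlier_sensitivity: float | None = None
    outlier_specificity: float | None = None


def _draw(cfg: SimConfig, rng: np.random.Generator):
    gamma = np.abs(rng.normal(0.0, cfg.gamma_sd, cfg.k)) + cfg.gamma_floor
    se_x = rng.uniform(*cfg.se_x_range, cfg.k)
    se_y = rng.uniform(*cfg.se_y_range, cfg.k)

    # scenario "none" draws with zero scale so the rng stream is identical
    # across scenarios (tau=0 balanced degenerates to none bit-exactly)
    if cfg.pleiotropy == "none":
        alpha = rng.normal(0.0, 0.0, cfg.k)
    elif cfg.pleiotropy == "balanced":
        alpha = rng.normal(0.0, cfg.tau, cfg.k)
    elif cfg.pleiotropy == "directional":
        alpha = rng.normal(cfg.mu_alpha, cfg.tau, cfg.k)
    else:  # correlated, InSIDE-violating
        alpha = cfg.rho * gamma + rng.normal(0.0, cfg.tau, cfg.k)

    outlier_idx = np.array([], dtype=int)
    if cfg.n_outliers:
        outlier_idx = rng.choice(cfg.k, size=cfg.n_outliers, replace=False)
        alpha = alpha.copy()
        alpha[outlier_idx] += cfg.outlier_alpha
        if cfg.outlier_se_scale != 1.0:
            se_y = se_y.copy()
            se_y[outlier_idx] *= cfg.outlier_se_scale

    gx_hat = gamma + rng.normal(0.0, 1.0, cfg.k) * se_x
    big_gamma = cfg.beta_true * gamma + alpha
    gy_hat = big_gamma + rng.normal(0.0, 1.0, cfg.k) * se_y
    eaf = rng.uniform(0.1, 0.9, cfg.k)
    return gamma, alpha, se_x, se_y, gx_hat, gy_hat, eaf, outlier_idx


def _pnorm2(z: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return np.clip(2.0 * norm.sf(np.abs(z)), 5e-324, 1.0)


def _simulate(cfg: SimConfig, rng: np.random.Generator):
    gamma, alpha, se_x, se_y, gx_hat, gy_hat, eaf, outlier_idx = _draw(cfg, rng)
    ids = [f"rs{100001 + i}" for i in range(cfg.k)]
    p_x = _pnorm2(gx_hat / se_x)
    p_y = _pnorm2(gy_hat / se_y)

    exp_records, out_records = [], []
    for i, vid in enumerate(ids):
        ea, oa = _ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]
        exp_records.append(
            SumStatRecord(vid, ea, oa, float(gx_hat[i]), float(se_x[i]),
                          eaf=float(eaf[i]), pval=float(p_x[i]))
        )
        out_records.append(
            SumStatRecord(vid, ea, oa, float(gy_hat[i]), float(se_y[i]),
                          eaf=float(eaf[i]), pval=float(p_y[i]))
        )
    truth = SimTruth(
        beta_true=cfg.beta_true,
        gamma=gamma,
        alpha=alpha,
        outlier_ids=[ids[i] for i in sorted(outlier_idx)],
    )
    exposure = GwasTable(exp_records, trait_label="sim_exposure")
    outcome = GwasTable(out_records, trait_label="sim_outcome")
    return exposure, outcome, truth


def simulate_two_sample(cfg: SimConfig) -> tuple[GwasTable, GwasTable, SimTruth]:
    """Generate one exposure table, one outcome table and the truth behind
    them.  Exposure and outcome noise are independent (two-sample design);
    identical config + seed gives bit-identical output."""
    rng = np.random.default_rng(cfg.seed)
    return _simulate(cfg, rng)


def truth_frame(truth: SimTruth, ids: Sequence[str]):
    import pandas as pd

    return pd.DataFrame(
        {
            "variant_id": list(ids),
            "gamma": truth.gamma,
            "alpha": truth.alpha,
            "is_outlier": [vid in set(truth.outlier_ids) for vid in ids],
            "beta_true": truth.beta_true,
        }
    )


def _fit_method(
    method: str,
    hset: HarmonisedSet,
    ratios,
    bootstrap_b: int,
    seed: int,
) -> estimators.MREstimate:
    if method == "IVW-FE":
        return estimators.ivw(ratios, mode="FE")
    if method == "IVW-RE":
        return estimators.ivw(ratios, mode="RE")
    if method == "WMe":
        return estimators.weighted_median(ratios, B=bootstrap_b, seed=seed)
    if method == "WMo":
        return estimators.weighted_mode(ratios, B=bootstrap_b, seed=seed)
    if method == "Egger":
        return estimators.mr_egger(hset).slope
    if method == "Egger-SIMEX":
        return estimators.egger_simex(hset, B=max(100, bootstrap_b // 2), seed=seed).slope
    raise ValueError(f"unknown method label {method!r}; expected one of {METHOD_LABELS}")


def recovery_experiment(
    cfg: SimConfig,
    replicates: int,
    methods: Sequence[str] = ("IVW-FE",),
    alpha: float = 0.05,
    bootstrap_b: int = 200,
) -> RecoveryReport:
    """Repeatedly simulate, run the estimator/diagnostic stack, aggregate.

    Per method: mean bias, RMSE, 95% CI coverage of the true slope and
    rejection rate at ``alpha``.  Also reports the Q-test rejection rate,
    the mean Egger intercept when Egger runs, and outlier-flagging
    sensitivity/specificity when outliers are planted.
    """
    if replicates < 100:
        raise ValueError("replicates must be >= 100")
    for m in methods:
        if m not in METHOD_LABELS:
            raise ValueError(f"unknown method label {m!r}")

    children = np.random.SeedSequence(cfg.seed).spawn(replicates)
    errors: dict[str, list[float]] = {m: [] for m in methods}
    covered: dict[str, list[bool]] = {m: [] for m in methods}
    rejected: dict[str, list[bool]] = {m: [] for m in methods}
    q_rejects: list[bool] = []
    intercepts: list[float] = []
    sens: list[float] = []
    spec: list[float] = []

    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        exposure, outcome, truth = _simulate(cfg, rng)
        hset = harmonise(exposure, outcome)
        ratios, _ = estimators.wald_ratios(hset)
        pooled = estimators.ivw(ratios, mode="FE")
        het = diagnostics.cochran_q(ratios, pooled)
        q_rejects.append(het.p < alpha)

        boot_seed = int(child.generate_state(1)[0])
        for m in methods:
            est = _fit_method(m, hset, ratios, bootstrap_b, boot_seed)
            errors[m].append(est.beta - truth.beta_true)
            covered[m].append(est.ci_low <= truth.beta_true <= est.ci_high)
            rejected[m].append(est.p < alpha)
        if "Egger" in methods or "Egger-SIMEX" in methods:
            intercepts.append(estimators.mr_egger(hset).intercept_beta)

        if cfg.n_outliers:
            report = diagnostics.remove_outliers_refit(hset, alpha=alpha)
            planted = set(truth.outlier_ids)
            flagged = set(report.flagged)
            others = set(hset.ids()) - planted
            sens.append(len(flagged & planted) / len(planted))
            spec.append(len(others - flagged) / len(others) if others else 1.0)

    per_method = {}
    for m in methods:
        err = np.asarray(errors[m])
        per_method[m] = MethodRecovery(
            bias=float(err.mean()),
            rmse=float(np.sqrt(np.mean(err**2))),
            ci_coverage=float(np.mean(covered[m])),
            rejection_rate=float(np.mean(rejected[m])),
        )
    return RecoveryReport(
        per_method=per_method,
        q_rejection_rate=float(np.mean(q_rejects)),
        replicates=replicates,
        egger_intercept_mean=float(np.mean(intercepts)) if intercepts else None,
        outlier_sensitivity=float(np.mean(sens)) if sens else None,
        outlier_specificity=float(np.mean(spec)) if spec else None,
    )
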