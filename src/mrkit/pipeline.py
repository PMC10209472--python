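"""Orchestration of one or both MR directions plus file reporting.

``run_direction`` performs, in order: instrument selection by exposure
p-value, proxy substitution, harmonisation, strength screening, Wald
ratios, IVW-FE pooling and heterogeneity assessment; when heterogeneity is
significant (or robust methods are forced) it adds per-variant Q
contributions, outlier removal with refit and the robust estimators, and it
always runs leave-one-out.  ``run_bidirectional`` does this twice with trait
roles swapped.  All outputs are plain TSV plus one JSON summary, bit-stable
for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from mrkit import diagnostics, estimators, sumstats
from mrkit.diagnostics import (
    HeterogeneityResult,
    LooResult,
    OutlierReport,
    QContribution,
)
from mrkit.estimators import EggerResult, MREstimate
from mrkit.sumstats import GwasTable, HarmonisedPair, HarmonisedSet, InstrumentStrength

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("IVW-FE", "IVW-RE", "WMe", "WMo", "Egger")

_CHRPOS_RE = re.compile(r"^(?:chr)?(\w+)[:_](\d+)")


@dataclass
class RunConfig:
    """Configuration for one MR direction."""

    exposure_path: str
    outcome_path: str
    proxy_path: str | None = None
    annotation_path: str | None = None
    direction: str = "X->Y"
    r2_threshold: float = 0.8
    instrument_p_threshold: float = 5e-8
    palindrome_window: tuple[float, float] = sumstats.DEFAULT_PALINDROME_WINDOW
    methods: tuple[str, ...] = DEFAULT_METHODS
    robust_mode: str = "auto"  # auto | always | never
    alpha: float = 0.05
    bootstrap_b: int = 1000
    seed: int = 0
    out_dir: str | None = None
    min_instrument_distance: int = 500_000
    exposure_column_map: dict | None = None
    outcome_column_map: dict | None = None

    def __post_init__(self):
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")
        if not (0 < self.instrument_p_threshold <= 1):
            raise ValueError("instrument_p_threshold must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.robust_mode not in ("auto", "always", "never"):
            raise ValueError("robust_mode must be auto, always or never")


@dataclass
class DirectionReport:
    """Everything computed for one MR direction."""

    direction: str
    n_instruments_initial: int
    n_after_harmonisation: int
    strength: InstrumentStrength
    estimates: list[MREstimate]
    heterogeneity: HeterogeneityResult
    loo: LooResult
    exclusions: list[tuple[str, str, str]]  # (variant_id, stage, reason)
    outliers: OutlierReport | None = None
    egger: EggerResult | None = None
    harmonised: HarmonisedSet | None = None
    annotations: dict[str, str] = field(default_factory=dict)


@dataclass
class BidirectionalReport:
    forward: DirectionReport | None
    reverse: DirectionReport | None
    provenance: dict[str, Any]
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def partial(self) -> bool:
        return bool(self.errors)


# ---------------------------------------------------------------------------
# single direction


def _warn_close_instruments(table: GwasTable, min_distance: int) -> None:
    """Warn when two instruments sit close on the same chromosome (ids of
    the chr:pos form only; independence is an input contract)."""
    positions: dict[str, list[tuple[int, str]]] = {}
    for rec in table.records:
        m = _CHRPOS_RE.match(rec.variant_id)
        if m:
            positions.setdefault(m.group(1), []).append((int(m.group(2)), rec.variant_id))
    for chrom, items in positions.items():
        items.sort()
        for (pos_a, id_a), (pos_b, id_b) in zip(items, items[1:]):
            if pos_b - pos_a < min_distance:
                logger.warning(
                    "instruments %s and %s are %d bp apart on chr%s; "
                    "check LD independence",
                    id_a, id_b, pos_b - pos_a, chrom,
                )


def run_direction(cfg: RunConfig) -> DirectionReport:
    """Run the full single-direction analysis described in the module doc."""
    exposure = sumstats.read_sumstats(
        cfg.exposure_path, column_map=cfg.exposure_column_map, trait_label="exposure"
    )
    outcome = sumstats.read_sumstats(
        cfg.outcome_path, column_map=cfg.outcome_column_map, trait_label="outcome"
    )
    exclusions: list[tuple[str, str, str]] = []

    # instrument selection on the exposure p-value
    selected = [
        r
        for r in exposure.records
        if r.pval is not None and r.pval < cfg.instrument_p_threshold
    ]
    if not selected:
        raise ValueError(
            "no instruments pass the exposure p-value threshold "
            f"{cfg.instrument_p_threshold:g}"
        )
    instruments = GwasTable(selected, trait_label=exposure.trait_label)
    n_initial = len(instruments)
    logger.info("%s: %d instruments selected", cfg.direction, n_initial)
    _warn_close_instruments(instruments, cfg.min_instrument_distance)

    # proxy substitution, then harmonisation
    proxied_ids: set[str] = set()
    if cfg.proxy_path:
        proxies = sumstats.read_proxies(cfg.proxy_path)
        result = sumstats.substitute_proxies(
            instruments, outcome, proxies, r2_threshold=cfg.r2_threshold
        )
        outcome = result.outcome
        proxied_ids = set(result.substituted)
        for pid, reason in result.rejected:
            logger.info("proxy %s: %s", pid, reason)

    hset = sumstats.harmonise(
        instruments, outcome, palindrome_window=cfg.palindrome_window,
        proxied_ids=proxied_ids,
    )
    exclusions.extend((vid, "harmonise", reason) for vid, reason in hset.exclusions)
    logger.info(
        "%s: %d pairs after harmonisation (%d excluded)",
        cfg.direction, hset.k, len(hset.exclusions),
    )
    if hset.k < 2:
        raise ValueError(
            f"fewer than 2 usable instruments after harmonisation; "
            f"exclusions: {hset.exclusions}"
        )

    strength = sumstats.instrument_f_stats(hset)
    ratios, ratio_excluded = estimators.wald_ratios(hset)
    exclusions.extend((vid, "wald_ratio", reason) for vid, reason in ratio_excluded)

    main = estimators.ivw(ratios, mode="FE")
    het = diagnostics.cochran_q(ratios, main)
    estimates = [main]

    run_robust = cfg.robust_mode == "always" or (
        cfg.robust_mode == "auto" and het.p < cfg.alpha
    )
    outliers: OutlierReport | None = None
    egger: EggerResult | None = None
    if run_robust and hset.k >= 3:
        try:
            outliers = diagnostics.remove_outliers_refit(hset, alpha=cfg.alpha)
        except ValueError as exc:
            # degenerate (nearly every SNP flagged): report without a refit
            logger.warning("outlier refit skipped: %s", exc)
            outliers = None
        for method in cfg.methods:
            if method == "IVW-FE":
                continue
            if method == "IVW-RE":
                estimates.append(estimators.ivw(ratios, mode="RE"))
            elif method == "WMe":
                estimates.append(
                    estimators.weighted_median(ratios, B=cfg.bootstrap_b, seed=cfg.seed)
                )
            elif method == "WMo":
                estimates.append(
                    estimators.weighted_mode(ratios, B=cfg.bootstrap_b, seed=cfg.seed)
                )
            elif method == "Egger":
                egger = estimators.mr_egger(hset)
                gxh = diagnostics.i2_gx(hset)
                if gxh.simex_recommended:
                    egger = estimators.egger_simex(hset, seed=cfg.seed)
                estimates.append(egger.slope)
            else:
                raise ValueError(f"unknown method in config: {method!r}")

    loo = diagnostics.leave_one_out(ratios) if hset.k >= 3 else LooResult(
        rows=[], max_influence_id=""
    )

    annotations: dict[str, str] = {}
    if cfg.annotation_path:
        ann = pd.read_csv(cfg.annotation_path, sep="\t", dtype=str)
        ids = set(hset.ids())
        for _, row in ann.iterrows():
            if str(row.iloc[0]) in ids:
                annotations[str(row.iloc[0])] = str(row.iloc[1])

    report = DirectionReport(
        direction=cfg.direction,
        n_instruments_initial=n_initial,
        n_after_harmonisation=hset.k,
        strength=strength,
        estimates=estimates,
        heterogeneity=het,
        loo=loo,
        exclusions=exclusions,
        outliers=outliers,
        egger=egger,
        harmonised=hset,
        annotations=annotations,
    )
    if cfg.out_dir:
        write_direction_tables(report, Path(cfg.out_dir))
    return report


def run_bidirectional(
    forward_cfg: RunConfig, reverse_cfg: RunConfig
) -> BidirectionalReport:
    """Two independent ``run_direction`` calls with trait roles swapped.

    One direction may fail without blocking the other; the failure message
    is recorded and the report flagged partial.
    """
    reports: dict[str, DirectionReport | None] = {}
    errors: dict[str, str] = {}
    for key, cfg in (("forward", forward_cfg), ("reverse", reverse_cfg)):
        try:
            reports[key] = run_direction(cfg)
        except (ValueError, OSError, sumstats.ConfigError) as exc:
            logger.error("%s direction failed: %s", key, exc)
            reports[key] = None
            errors[key] = str(exc)

    from mrkit import __version__

    provenance = {
        "version": __version__,
        "forward_config": _config_dict(forward_cfg),
        "reverse_config": _config_dict(reverse_cfg),
    }
    return BidirectionalReport(
        forward=reports["forward"],
        reverse=reports["reverse"],
        provenance=provenance,
        errors=errors,
    )


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["palindrome_window"] = list(cfg.palindrome_window)
    d["methods"] = list(cfg.methods)
    return d


# ---------------------------------------------------------------------------
# table / JSON emission


def _format_or(value: float) -> str:
    # near-null odds ratios need the third decimal to be informative
    return f"{value:.3f}" if abs(value - 1.0) < 0.05 else f"{value:.2f}"


def estimates_frame(report: DirectionReport) -> pd.DataFrame:
    rows = []
    for est in report.estimates:
        orr = estimators.to_odds_scale(est)
        rows.append(
            {
                "direction": report.direction,
                "method": est.method,
                "n_snps": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.p,
                "or": orr.odds_ratio,
                "or_ci_low": orr.or_ci_low,
                "or_ci_high": orr.or_ci_high,
            }
        )
        if report.outliers is not None and est.method == "IVW-FE":
            refit = report.outliers.refit
            orr2 = estimators.to_odds_scale(refit)
            rows.append(
                {
                    "direction": report.direction,
                    "method": "IVW-FE (outliers removed)",
                    "n_snps": refit.n_snps,
                    "beta": refit.beta,
                    "se": refit.se,
                    "ci_low": refit.ci_low,
                    "ci_high": refit.ci_high,
                    "p": refit.p,
                    "or": orr2.odds_ratio,
                    "or_ci_low": orr2.or_ci_low,
                    "or_ci_high": orr2.or_ci_high,
                }
            )
    return pd.DataFrame(rows)


def write_direction_tables(report: DirectionReport, out_dir: Path) -> list[Path]:
    """Write per-direction TSVs; file names are prefixed with a slug of the
    direction label."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slug = re.sub(r"\W+", "_", report.direction).strip("_").lower()
    written: list[Path] = []

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / f"{slug}_{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)

    _write("estimates", estimates_frame(report))
    _write("heterogeneity", diagnostics.heterogeneity_frame(report.heterogeneity))
    if report.outliers is not None:
        _write(
            "q_contributions",
            diagnostics.contributions_frame(
                report.outliers.contributions, report.outliers.thresholds
            ),
        )
    if report.loo.rows:
        _write("leave_one_out", diagnostics.loo_frame(report.loo))
    _write(
        "exclusions",
        pd.DataFrame(report.exclusions, columns=["variant_id", "stage", "reason"]),
    )
    return written


def write_report(report: BidirectionalReport, out_dir) -> list[Path]:
    """Write all per-direction tables plus a single JSON summary.

    Output is bit-stable given identical inputs and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    headline = []
    for direction in (report.forward, report.reverse):
        if direction is None:
            continue
        written.extend(write_direction_tables(direction, out_dir))
        main = direction.estimates[0]
        orr = estimators.to_odds_scale(main)
        headline.append(
            {
                "direction": direction.direction,
                "or": _format_or(orr.odds_ratio),
                "or_ci_low": _format_or(orr.or_ci_low),
                "or_ci_high": _format_or(orr.or_ci_high),
                "p": round(orr.p, 4),
            }
        )

    summary = report_to_dict(report)
    summary["headline"] = headline
    path = out_dir / "summary.json"
    path.write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    written.append(path)
    return written


# ---------------------------------------------------------------------------
# JSON (de)serialisation; round-trips to an equal in-memory report


def _est_dict(est: MREstimate) -> dict:
    return dataclasses.asdict(est)


def _est_from(d: dict) -> MREstimate:
    return MREstimate(**d)


def _direction_to_dict(rep: DirectionReport) -> dict:
    return {
        "direction": rep.direction,
        "n_instruments_initial": rep.n_instruments_initial,
        "n_after_harmonisation": rep.n_after_harmonisation,
        "strength": {
            "per_snp_f": [[vid, f] for vid, f in rep.strength.per_snp_f],
            "f_min": rep.strength.f_min,
            "f_max": rep.strength.f_max,
            "weak": list(rep.strength.weak),
        },
        "estimates": [_est_dict(e) for e in rep.estimates],
        "heterogeneity": dataclasses.asdict(rep.heterogeneity),
        "loo": {
            "rows": [[vid, _est_dict(e)] for vid, e in rep.loo.rows],
            "max_influence_id": rep.loo.max_influence_id,
        },
        "exclusions": [list(e) for e in rep.exclusions],
        "outliers": None
        if rep.outliers is None
        else {
            "thresholds": list(rep.outliers.thresholds),
            "flagged": list(rep.outliers.flagged),
            "refit": _est_dict(rep.outliers.refit),
            "refit_het": dataclasses.asdict(rep.outliers.refit_het),
            "contributions": [dataclasses.asdict(c) for c in rep.outliers.contributions],
        },
        "egger": None
        if rep.egger is None
        else {
            "slope": _est_dict(rep.egger.slope),
            "intercept_beta": rep.egger.intercept_beta,
            "intercept_se": rep.egger.intercept_se,
            "intercept_p": rep.egger.intercept_p,
            "i2_gx": rep.egger.i2_gx,
            "simex_applied": rep.egger.simex_applied,
            "simex_lambda_grid": list(rep.egger.simex_lambda_grid),
            "simex_B": rep.egger.simex_B,
        },
        "harmonised": None
        if rep.harmonised is None
        else {
            "pairs": [
                {
                    "variant_id": p.variant_id,
                    "gx_beta": p.gx_beta,
                    "gx_se": p.gx_se,
                    "gy_beta": p.gy_beta,
                    "gy_se": p.gy_se,
                    "flags": sorted(p.flags),
                }
                for p in rep.harmonised.pairs
            ],
            "exclusions": [list(e) for e in rep.harmonised.exclusions],
        },
        "annotations": dict(rep.annotations),
    }


def _direction_from_dict(d: dict) -> DirectionReport:
    outliers = None
    if d["outliers"] is not None:
        o = d["outliers"]
        outliers = OutlierReport(
            thresholds=tuple(o["thresholds"]),
            flagged=list(o["flagged"]),
            refit=_est_from(o["refit"]),
            refit_het=HeterogeneityResult(**o["refit_het"]),
            contributions=[QContribution(**c) for c in o["contributions"]],
        )
    egger = None
    if d["egger"] is not None:
        e = d["egger"]
        egger = EggerResult(
            slope=_est_from(e["slope"]),
            intercept_beta=e["intercept_beta"],
            intercept_se=e["intercept_se"],
            intercept_p=e["intercept_p"],
            i2_gx=e["i2_gx"],
            simex_applied=e["simex_applied"],
            simex_lambda_grid=tuple(e["simex_lambda_grid"]),
            simex_B=e["simex_B"],
        )
    harmonised = None
    if d["harmonised"] is not None:
        h = d["harmonised"]
        harmonised = HarmonisedSet(
            pairs=[
                HarmonisedPair(
                    variant_id=p["variant_id"],
                    gx_beta=p["gx_beta"],
                    gx_se=p["gx_se"],
                    gy_beta=p["gy_beta"],
                    gy_se=p["gy_se"],
                    flags=frozenset(p["flags"]),
                )
                for p in h["pairs"]
            ],
            exclusions=[tuple(e) for e in h["exclusions"]],
        )
    return DirectionReport(
        direction=d["direction"],
        n_instruments_initial=d["n_instruments_initial"],
        n_after_harmonisation=d["n_after_harmonisation"],
        strength=InstrumentStrength(
            per_snp_f=[(vid, f) for vid, f in d["strength"]["per_snp_f"]],
            f_min=d["strength"]["f_min"],
            f_max=d["strength"]["f_max"],
            weak=list(d["strength"]["weak"]),
        ),
        estimates=[_est_from(e) for e in d["estimates"]],
        heterogeneity=HeterogeneityResult(**d["heterogeneity"]),
        loo=LooResult(
            rows=[(vid, _est_from(e)) for vid, e in d["loo"]["rows"]],
            max_influence_id=d["loo"]["max_influence_id"],
        ),
        exclusions=[tuple(e) for e in d["exclusions"]],
        outliers=outliers,
        egger=egger,
        harmonised=harmonised,
        annotations=dict(d["annotations"]),
    )


def report_to_dict(report: BidirectionalReport) -> dict:
    return {
        "forward": None if report.forward is None else _direction_to_dict(report.forward),
        "reverse": None if report.reverse is None else _direction_to_dict(report.reverse),
        "provenance": report.provenance,
        "errors": dict(report.errors),
    }


def report_from_dict(d: dict) -> BidirectionalReport:
    return BidirectionalReport(
        forward=None if d["forward"] is None else _direction_from_dict(d["forward"]),
        reverse=None if d["reverse"] is None else _direction_from_dict(d["reverse"]),
        provenance=d["provenance"],
        errors=dict(d.get("errors", {})),
    )
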