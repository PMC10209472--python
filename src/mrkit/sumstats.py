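"""GWAS summary statistics: reading, validation, harmonisation, screening.

The central objects are :class:`GwasTable` (per-variant summary statistics
for one trait) and :class:`HarmonisedSet` (allele-aligned exposure/outcome
pairs plus an exclusion log).  Every exposure variant entering
:func:`harmonise` ends up either in the pairs or in the exclusion log, never
both and never lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names of the summary-statistics TSV dialect
CANONICAL_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
)

REQUIRED_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se")

#: common aliases recognised when no explicit column_map is given (lower-case)
DEFAULT_ALIASES: Mapping[str, str] = {
    "variant_id": "variant_id",
    "snp": "variant_id",
    "rsid": "variant_id",
    "markername": "variant_id",
    "effect_allele": "effect_allele",
    "ea": "effect_allele",
    "a1": "effect_allele",
    "other_allele": "other_allele",
    "oa": "other_allele",
    "a2": "other_allele",
    "eaf": "eaf",
    "af": "eaf",
    "freq": "eaf",
    "effect_allele_frequency": "eaf",
    "beta": "beta",
    "b": "beta",
    "se": "se",
    "stderr": "se",
    "standard_error": "se",
    "pval": "pval",
    "p": "pval",
    "pvalue": "pval",
    "p_value": "pval",
}

DEFAULT_PALINDROME_WINDOW = (0.42, 0.58)
DEFAULT_R2_THRESHOLD = 0.8
WEAK_F_THRESHOLD = 10.0


class ConfigError(ValueError):
    """Raised for invalid configuration, e.g. a missing required column."""


@dataclass(frozen=True)
class SumStatRecord:
    """One variant's association with one trait (log-odds scale)."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pval: float | None = None

    def invalid_reason(self) -> str | None:
        """Return a short reason string if any invariant fails, else None."""
        if not self.variant_id:
            return "empty_variant_id"
        if self.effect_allele not in VALID_ALLELES:
            return "invalid_effect_allele"
        if self.other_allele not in VALID_ALLELES:
            return "invalid_other_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not np.isfinite(self.beta):
            return "non_finite_beta"
        if not np.isfinite(self.se) or self.se <= 0:
            return "non_positive_se"
        if self.eaf is not None and not (0 < self.eaf < 1):
            return "eaf_out_of_range"
        if self.pval is not None and not (0 < self.pval <= 1):
            return "pval_out_of_range"
        return None

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, where strand cannot be inferred."""
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class GwasTable:
    """Validated summary statistics for one trait.

    ``rejected`` records rows dropped at read time as (variant_id, reason);
    it does not take part in equality comparisons.
    """

    records: list[SumStatRecord]
    trait_label: str = ""
    rejected: list[tuple[str, str]] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({v for v in ids if ids.count(v) > 1})
            raise ValueError(f"duplicate variant ids in table: {dupes}")
        self._index = {r.variant_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, variant_id: str) -> SumStatRecord:
        return self._index[variant_id]

    def ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf if r.eaf is not None else np.nan,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval if r.pval is not None else np.nan,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass(frozen=True)
class ProxyRecord:
    """An LD proxy for a target variant missing from the outcome table.

    ``allele_map`` gives the correspondence from proxy alleles to target
    alleles; at minimum it must map the proxy effect allele.
    """

    target_id: str
    proxy_id: str
    r_squared: float
    allele_map: Mapping[str, str]


@dataclass(frozen=True)
class HarmonisedPair:
    """Allele-aligned exposure (gx) / outcome (gy) effects for one variant."""

    variant_id: str
    gx_beta: float
    gx_se: float
    gy_beta: float
    gy_se: float
    flags: frozenset[str] = frozenset()


@dataclass
class HarmonisedSet:
    """Harmonised pairs plus an exclusion log (variant_id, reason)."""

    pairs: list[HarmonisedPair]
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.pairs)

    def gx(self) -> np.ndarray:
        return np.array([p.gx_beta for p in self.pairs], dtype=float)

    def gx_se(self) -> np.ndarray:
        return np.array([p.gx_se for p in self.pairs], dtype=float)

    def gy(self) -> np.ndarray:
        return np.array([p.gy_beta for p in self.pairs], dtype=float)

    def gy_se(self) -> np.ndarray:
        return np.array([p.gy_se for p in self.pairs], dtype=float)

    def ids(self) -> list[str]:
        return [p.variant_id for p in self.pairs]

    def subset(self, keep_ids: Iterable[str]) -> "HarmonisedSet":
        keep = set(keep_ids)
        return HarmonisedSet(
            pairs=[p for p in self.pairs if p.variant_id in keep],
            exclusions=list(self.exclusions),
        )


@dataclass
class InstrumentStrength:
    """Per-SNP approximate F-statistics with range and weak-instrument list."""

    per_snp_f: list[tuple[str, float]]
    f_min: float
    f_max: float
    weak: list[str]


@dataclass
class ProxyResult:
    """Outcome table with proxies substituted in, plus bookkeeping."""

    outcome: GwasTable
    substituted: dict[str, str]  # target_id -> proxy_id used
    rejected: list[tuple[str, str]]  # (proxy_id or target_id, reason)


# ---------------------------------------------------------------------------
# reading / writing


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical column names to actual file columns.

    ``column_map`` maps canonical names to file column names; without it,
    case-insensitive aliases from DEFAULT_ALIASES are recognised.
    """
    resolved: dict[str, str] = {}
    if column_map:
        for canonical, actual in column_map.items():
            if canonical not in CANONICAL_COLUMNS:
                raise ConfigError(f"unknown canonical column name: {canonical!r}")
            if actual not in header:
                raise ConfigError(f"mapped column not in file: {actual!r}")
            resolved[canonical] = actual
    # fill remaining slots from aliases
    for col in header:
        canonical = DEFAULT_ALIASES.get(col.lower())
        if canonical and canonical not in resolved:
            resolved[canonical] = col
    for canonical in REQUIRED_COLUMNS:
        if canonical not in resolved:
            raise ConfigError(f"missing required column: {canonical!r}")
    return resolved


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
) -> GwasTable:
    """Read a tab-separated summary-statistics file into a GwasTable.

    Rows failing record invariants (non-positive SE, invalid alleles, out of
    range eaf/pval, duplicate ids) are dropped and logged on
    ``GwasTable.rejected`` with a per-row reason.  A missing required column
    raises :class:`ConfigError` naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    resolved = _resolve_columns(list(df.columns), column_map)

    records: list[SumStatRecord] = []
    rejected: list[tuple[str, str]] = []
    seen: set[str] = set()

    def _float(row, canonical) -> float | None:
        if canonical not in resolved:
            return None
        raw = row[resolved[canonical]]
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
            return None
        try:
            return float(raw)
        except (TypeError, ValueError):
            return float("nan")

    for _, row in df.iterrows():
        vid = str(row[resolved["variant_id"]]).strip()
        beta = _float(row, "beta")
        se = _float(row, "se")
        rec = SumStatRecord(
            variant_id=vid,
            effect_allele=str(row[resolved["effect_allele"]]).strip().upper(),
            other_allele=str(row[resolved["other_allele"]]).strip().upper(),
            beta=beta if beta is not None else float("nan"),
            se=se if se is not None else float("nan"),
            eaf=_float(row, "eaf"),
            pval=_float(row, "pval"),
        )
        reason = rec.invalid_reason()
        if reason is not None:
            rejected.append((vid, reason))
            continue
        if vid in seen:
            rejected.append((vid, "duplicate_id"))
            continue
        seen.add(vid)
        records.append(rec)

    table = GwasTable(records=records, trait_label=trait_label)
    table.rejected = rejected
    if rejected:
        logger.warning(
            "%s: rejected %d of %d rows", trait_label or path, len(rejected), len(df)
        )
    return table


def write_sumstats(table: GwasTable, path) -> None:
    """Write a GwasTable in the canonical TSV dialect (round-trips exactly)."""
    table.to_frame().to_csv(path, sep="\t", index=False, na_rep="")


def read_proxies(path) -> list[ProxyRecord]:
    """Read a proxy-map TSV: target_id, proxy_id, r2, proxy_effect_allele,
    target_effect_allele."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"target_id", "proxy_id", "r2", "proxy_effect_allele", "target_effect_allele"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"proxy map missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ProxyRecord(
                target_id=str(row["target_id"]),
                proxy_id=str(row["proxy_id"]),
                r_squared=float(row["r2"]),
                allele_map={
                    str(row["proxy_effect_allele"]).upper(): str(
                        row["target_effect_allele"]
                    ).upper()
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# proxy substitution (runs before harmonisation)


def substitute_proxies(
    exposure: GwasTable,
    outcome: GwasTable,
    proxies: Sequence[ProxyRecord],
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> ProxyResult:
    """Fill outcome-table gaps with LD proxies.

    For each accepted proxy (r-squared at or above ``r2_threshold``), the
    proxy's outcome record is relabelled to the target id with alleles
    translated via the allele map.  Rejections are logged, never fatal.
    """
    new_records = list(outcome.records)
    index = {r.variant_id: i for i, r in enumerate(new_records)}
    substituted: dict[str, str] = {}
    rejected: list[tuple[str, str]] = []

    for proxy in proxies:
        if proxy.target_id in outcome:
            rejected.append((proxy.target_id, "target_already_present"))
            continue
        if proxy.target_id not in exposure:
            rejected.append((proxy.target_id, "target_not_in_exposure"))
            continue
        if proxy.r_squared < r2_threshold:
            rejected.append((proxy.proxy_id, "r2_below_threshold"))
            continue
        if proxy.proxy_id not in outcome:
            rejected.append((proxy.proxy_id, "proxy_missing_in_outcome"))
            continue
        if proxy.target_id in substituted:
            rejected.append((proxy.proxy_id, "target_already_proxied"))
            continue

        prox_rec = outcome.get(proxy.proxy_id)
        exp_rec = exposure.get(proxy.target_id)
        translated = _translate_proxy(prox_rec, exp_rec, proxy)
        if translated is None:
            rejected.append((proxy.proxy_id, "allele_map_mismatch"))
            continue
        new_records.append(translated)
        index[translated.variant_id] = len(new_records) - 1
        substituted[proxy.target_id] = proxy.proxy_id

    table = GwasTable(records=new_records, trait_label=outcome.trait_label)
    table.rejected = list(outcome.rejected)
    return ProxyResult(outcome=table, substituted=substituted, rejected=rejected)


def _translate_proxy(
    prox_rec: SumStatRecord, exp_rec: SumStatRecord, proxy: ProxyRecord
) -> SumStatRecord | None:
    """Relabel a proxy outcome record to the target variant's alleles.

    Returns None when the allele map is inconsistent with the observed
    proxy/target alleles.
    """
    mapped = {p: t for p, t in proxy.allele_map.items()}
    # which target allele does the proxy record's effect allele stand for?
    if prox_rec.effect_allele in mapped:
        target_effect = mapped[prox_rec.effect_allele]
    elif prox_rec.other_allele in mapped:
        # the mapped proxy allele is the record's other allele; the effect
        # allele then corresponds to the *other* target allele
        mapped_target = mapped[prox_rec.other_allele]
        if mapped_target == exp_rec.effect_allele:
            target_effect = exp_rec.other_allele
        elif mapped_target == exp_rec.other_allele:
            target_effect = exp_rec.effect_allele
        else:
            return None
    else:
        return None

    if target_effect == exp_rec.effect_allele:
        target_other = exp_rec.other_allele
    elif target_effect == exp_rec.other_allele:
        target_other = exp_rec.effect_allele
    else:
        return None

    return replace(
        prox_rec,
        variant_id=proxy.target_id,
        effect_allele=target_effect,
        other_allele=target_other,
    )


# ---------------------------------------------------------------------------
# harmonisation


def harmonise(
    exposure: GwasTable,
    outcome: GwasTable,
    palindrome_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW,
    proxied_ids: frozenset[str] | set[str] = frozenset(),
) -> HarmonisedSet:
    """Align outcome effects to the exposure effect allele, variant by variant.

    Rules
    -----
    * identical allele pair: keep as is;
    * swapped alleles (directly or on the opposite strand): negate the
      outcome beta, flag ``sign_flipped``;
    * palindromic (A/T, C/G) variants: resolved by comparing effect-allele
      frequencies on both sides; dropped as ``palindromic_ambiguous`` when
      either eaf is missing or both fall inside ``palindrome_window``;
    * anything else: dropped as ``allele_mismatch``;
    * exposure variants absent from the outcome: ``missing_in_outcome``.

    The exposure variant list is partitioned exactly between ``pairs`` and
    ``exclusions``.
    """
    lo, hi = palindrome_window
    pairs: list[HarmonisedPair] = []
    exclusions: list[tuple[str, str]] = []

    for exp in exposure.records:
        vid = exp.variant_id
        if vid not in outcome:
            exclusions.append((vid, "missing_in_outcome"))
            continue
        out = outcome.get(vid)
        flags: set[str] = set()
        if vid in proxied_ids:
            flags.add("proxy_used")

        gy_beta = out.beta
        out_eaf = out.eaf

        if exp.is_palindromic:
            if not out.is_palindromic or {out.effect_allele, out.other_allele} != {
                exp.effect_allele,
                exp.other_allele,
            }:
                exclusions.append((vid, "allele_mismatch"))
                continue
            if exp.eaf is None or out_eaf is None:
                exclusions.append((vid, "palindromic_ambiguous"))
                continue
            # align allele labels first (A/T vs T/A listing)
            if out.effect_allele != exp.effect_allele:
                gy_beta = -gy_beta
                out_eaf = 1.0 - out_eaf
            if lo <= exp.eaf <= hi and lo <= out_eaf <= hi:
                exclusions.append((vid, "palindromic_ambiguous"))
                continue
            # opposite minor/major side means the strands disagree
            if (exp.eaf < 0.5) != (out_eaf < 0.5):
                gy_beta = -gy_beta
                flags.add("palindromic_aligned")
        else:
            out_alleles = (out.effect_allele, out.other_allele)
            exp_alleles = (exp.effect_allele, exp.other_allele)
            comp_alleles = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])
            if out_alleles == exp_alleles or comp_alleles == exp_alleles:
                pass  # already aligned
            elif out_alleles == exp_alleles[::-1] or comp_alleles == exp_alleles[::-1]:
                gy_beta = -gy_beta
                flags.add("sign_flipped")
            else:
                exclusions.append((vid, "allele_mismatch"))
                continue

        pairs.append(
            HarmonisedPair(
                variant_id=vid,
                gx_beta=exp.beta,
                gx_se=exp.se,
                gy_beta=gy_beta,
                gy_se=out.se,
                flags=frozenset(flags),
            )
        )

    return HarmonisedSet(pairs=pairs, exclusions=exclusions)


# ---------------------------------------------------------------------------
# instrument strength


def instrument_f_stats(hset: HarmonisedSet) -> InstrumentStrength:
    """Per-SNP approximate F-statistic, (gx_beta / gx_se)^2.

    Variants with F at or below 10 are listed as weak (a warning, not an
    exclusion).
    """
    if hset.k == 0:
        raise ValueError("cannot compute instrument strength on an empty set")
    per_snp = [
        (p.variant_id, float((p.gx_beta / p.gx_se) ** 2)) for p in hset.pairs
    ]
    fs = [f for _, f in per_snp]
    weak = [vid for vid, f in per_snp if f <= WEAK_F_THRESHOLD]
    if weak:
        logger.warning("%d weak instrument(s) with F <= 10: %s", len(weak), weak)
    return InstrumentStrength(
        per_snp_f=per_snp, f_min=min(fs), f_max=max(fs), weak=weak
    )


def write_exclusion_log(entries: Sequence[tuple[str, str, str]], path) -> None:
    """Write (variant_id, stage, reason) rows as TSV."""
    pd.DataFrame(entries, columns=["variant_id", "stage", "reason"]).to_csv(
        path, sep="\t", index=False
    )
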