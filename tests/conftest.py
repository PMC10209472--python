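import numpy as np
import pytest

from mrkit.estimators import RatioEstimate
from mrkit.sumstats import GwasTable, HarmonisedPair, HarmonisedSet, SumStatRecord


def ratio(variant_id, value, se):
    return RatioEstimate(variant_id=variant_id, ratio=value, se=se, weight=1.0 / se**2)


def make_ratios(values, ses):
    return [ratio(f"rs{i}", v, s) for i, (v, s) in enumerate(zip(values, ses))]


def make_hset(gx, gy, gx_se=None, gy_se=None):
    k = len(gx)
    gx_se = gx_se if gx_se is not None else [0.02] * k
    gy_se = gy_se if gy_se is not None else [0.05] * k
    pairs = [
        HarmonisedPair(
            variant_id=f"rs{i}",
            gx_beta=float(gx[i]),
            gx_se=float(gx_se[i]),
            gy_beta=float(gy[i]),
            gy_se=float(gy_se[i]),
        )
        for i in range(k)
    ]
    return HarmonisedSet(pairs=pairs)


def random_hset(rng, k=12, beta=0.5):
    gx = rng.uniform(0.05, 0.4, k)
    gx_se = rng.uniform(0.01, 0.03, k)
    gy_se = rng.uniform(0.02, 0.1, k)
    gy = beta * gx + rng.normal(0, 1, k) * gy_se
    return make_hset(gx, gy, gx_se, gy_se)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def simple_table(rows, trait_label="trait"):
    """rows: (vid, ea, oa, beta, se[, eaf[, pval]])"""
    records = []
    for row in rows:
        vid, ea, oa, beta, se = row[:5]
        eaf = row[5] if len(row) > 5 else None
        pval = row[6] if len(row) > 6 else None
        records.append(
            SumStatRecord(
                variant_id=vid, effect_allele=ea, other_allele=oa,
                beta=beta, se=se, eaf=eaf, pval=pval,
            )
        )
    return GwasTable(records=records, trait_label=trait_label)
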