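import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrkit.harmonize import HarmonizedInstrument, HarmonizedSet
from mrkit.summary_io import SummaryRecord, SummaryTable

settings.register_profile(
    "det", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


def make_record(variant_id="rs1", chrom="1", effect_allele="A", other_allele="G",
                eaf=0.3, beta=0.05, se=0.01, pval=1e-9, n=100_000) -> SummaryRecord:
    return SummaryRecord(variant_id, chrom, effect_allele, other_allele,
                         eaf, beta, se, pval, n)


def make_table(rows, trait_name="trait", trait_type="continuous", unit="SD") -> SummaryTable:
    """rows: list of dicts overriding make_record defaults."""
    return SummaryTable(trait_name, trait_type, unit,
                        [make_record(**row) for row in rows])


def make_hset(beta_exp, beta_out, se_out, se_exp=None,
              exposure="exp", outcome="out") -> HarmonizedSet:
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.broadcast_to(np.asarray(se_out, dtype=float), beta_exp.shape)
    if se_exp is None:
        se_exp = np.full_like(beta_exp, 1e-4)
    se_exp = np.broadcast_to(np.asarray(se_exp, dtype=float), beta_exp.shape)
    instruments = [
        HarmonizedInstrument(f"rs{i + 1}", bx, sx, by, sy, 0.3, 0.3)
        for i, (bx, sx, by, sy) in enumerate(zip(beta_exp, se_exp, beta_out, se_out))
    ]
    return HarmonizedSet(exposure, outcome, instruments=instruments)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
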