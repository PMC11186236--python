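import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from scipy.stats import norm

from targetmr.sumstats import HarmonizedPair, SumStatsTable

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_table(records: list[dict], trait_id: str = "trait",
               trait_type: str = "quantitative") -> SumStatsTable:
    """Build a SumStatsTable from partial record dicts with sane defaults."""
    rows = []
    for i, rec in enumerate(records):
        row = {"variant_id": f"rs{i + 1}", "chrom": "1", "pos": 1000 + i,
               "effect_allele": "A", "other_allele": "C", "eaf": 0.3,
               "beta": 0.1, "se": 0.05, "n": 10_000.0,
               "ncase": np.nan, "nctrl": np.nan}
        row.update(rec)
        row.setdefault("pval", 2 * float(norm.sf(abs(row["beta"] / row["se"]))))
        rows.append(row)
    df = pd.DataFrame(rows)[["variant_id", "chrom", "pos", "effect_allele",
                             "other_allele", "eaf", "beta", "se", "pval", "n",
                             "ncase", "nctrl"]]
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return SumStatsTable(trait_id, trait_type, df)


def make_pair(bx: float, sx: float, by: float, sy: float, vid: str = "rs1",
              n_exp: float = 10_000.0, n_out: float = 100_000.0,
              pos: int = 1000) -> HarmonizedPair:
    return HarmonizedPair(vid, "1", pos, "A", "C", bx, sx, 0.5, n_exp, 0.3,
                          by, sy, 0.5, n_out, 0.3, "kept")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
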