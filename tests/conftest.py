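import numpy as np
import pandas as pd
import pytest

from wheatscan.core.variants import VariantTable


def make_table(records, samples, dp=None, ad=None):
    """Build a VariantTable from (chrom, pos, ref, alt, genotypes) tuples.

    ``dp`` may be a scalar, per-record list, or full matrix; ``ad`` an
    optional (ad_ref, ad_alt) matrix pair.
    """
    sites = pd.DataFrame(
        [(r[0], r[1], r[2], r[3]) for r in records],
        columns=["chrom", "pos", "ref", "alt"],
    )
    gt = np.array([r[4] for r in records], dtype=np.int8).reshape(len(records), len(samples))
    dpm = None
    if dp is not None:
        dpm = np.asarray(dp)
        if dpm.ndim == 0:
            dpm = np.full(gt.shape, int(dpm))
        elif dpm.ndim == 1:
            dpm = np.repeat(dpm[:, None], len(samples), axis=1)
    adr = ada = None
    if ad is not None:
        adr, ada = np.asarray(ad[0]), np.asarray(ad[1])
    return VariantTable(sites, gt, list(samples), dp=dpm, ad_ref=adr, ad_alt=ada)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
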