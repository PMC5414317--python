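import numpy as np
import pandas as pd
import pytest

from rdnakit.iocore import SITE_COLUMNS, FilterConfig, SiteCountTable
from rdnakit import simpop


def make_site_table(rows, sample="s1", source="DNA"):
    """Rows of (position, allele, fwd, rev) -> SiteCountTable."""
    df = pd.DataFrame(
        [(sample, source, p, a, f, r) for p, a, f, r in rows], columns=SITE_COLUMNS
    )
    return SiteCountTable(df)


@pytest.fixture
def cfg():
    return FilterConfig()


@pytest.fixture
def two_founders():
    return simpop.make_founder_panel(2, n_variants_per_haplotype=2, copy_number=200, seed=11)


@pytest.fixture
def small_gmap():
    return simpop.GenomeMap.regular(n_chromosomes=5, n_markers=40)
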