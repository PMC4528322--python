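import numpy as np
import pandas as pd
import pytest

from psge.counts import COUNT_COLUMNS
from psge.genotypes import FAMILY_LINEAGES


def make_counts(cells, sample_group="larvae"):
    """Build a validated-schema counts frame from compact cell tuples.

    Each cell is (transcript, chrom, pos, family, replicate, maternal_count,
    paternal_count); lineage columns follow the family design identity.
    """
    rows = []
    for tid, chrom, pos, fam, rep, m, p in cells:
        mat_lin, pat_lin = FAMILY_LINEAGES[fam]
        rows.append((tid, chrom, pos, fam, rep, sample_group, "maternal", mat_lin, m))
        rows.append((tid, chrom, pos, fam, rep, sample_group, "paternal", pat_lin, p))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


@pytest.fixture
def balanced_counts():
    """2 families x 2 replicates x 2 SNPs for one transcript (16 rows)."""
    cells = []
    for fam in ("AE", "EA"):
        for rep in (f"{fam}_larvae_1", f"{fam}_larvae_2"):
            for pos in (100, 200):
                cells.append(("tx1", "chr1", pos, fam, rep, 30, 20))
    return make_counts(cells)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
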