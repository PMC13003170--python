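import numpy as np
import pandas as pd
import pytest

from recombml.genome import ChromRecord, GenomeLayout, build_bins
from recombml.recmap import COSet


@pytest.fixture(scope="session")
def toy_layout() -> GenomeLayout:
    """Two homoeolog pairs plus an unpaired chromosome, ~10 Mbp total."""
    return GenomeLayout(
        (
            ChromRecord("A01", 3_000_000, "A", 1_200_000, 1),
            ChromRecord("A02", 2_100_000, "A", 900_000, 2),
            ChromRecord("C01", 3_500_000, "C", 1_700_000, 1),
            ChromRecord("C02", 2_500_000, "C", 1_000_000, 2),
        )
    )


@pytest.fixture(scope="session")
def toy_grid(toy_layout):
    return build_bins(toy_layout, 300_000)


def make_coset(records, meioses=None) -> COSet:
    """records: (chrom, start, end, individual[, population])."""
    rows = []
    for rec in records:
        chrom, start, end, ind = rec[:4]
        pop = rec[4] if len(rec) > 4 else "Pop1"
        rows.append((chrom, start, end, ind, pop, 2))
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "individual", "population", "generation"]
    )
    if meioses is None:
        meioses = {
            pop: 2 * frame.loc[frame["population"] == pop, "individual"].nunique()
            for pop in frame["population"].unique()
        }
    return COSet(frame=frame, meioses=meioses)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
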