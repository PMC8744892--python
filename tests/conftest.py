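import numpy as np
import pandas as pd
import pytest

from ernascope.synthetic import SimConfig, simulate_experiment


def random_peaks(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=500):
    """Random BED6 frame for oracle comparisons."""
    starts = rng.integers(0, max_pos, n)
    lengths = rng.integers(1, max_len, n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(list(chroms), n),
            "start": starts,
            "end": starts + lengths,
            "name": [f"p{i}" for i in range(n)],
            "score": 0.0,
            "strand": ".",
        }
    )


def brute_overlap(a_row, b_row) -> int:
    if a_row["chrom"] != b_row["chrom"]:
        return 0
    return max(0, min(a_row["end"], b_row["end"]) - max(a_row["start"], b_row["start"]))


def brute_shared_names(a: pd.DataFrame, b: pd.DataFrame, min_bp: int) -> set:
    """Names of rows in a overlapping any row in b by >= min_bp (O(n^2))."""
    b_recs = list(b[["chrom", "start", "end"]].itertuples(index=False, name=None))
    out = set()
    for name, chrom, s, e in zip(a["name"], a["chrom"], a["start"], a["end"]):
        for bc, bs, be in b_recs:
            if bc == chrom and min(e, be) - max(s, bs) >= min_bp:
                out.add(name)
                break
    return out


@pytest.fixture(scope="session")
def default_experiment():
    """One seeded default-condition experiment shared across tests."""
    return simulate_experiment(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
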