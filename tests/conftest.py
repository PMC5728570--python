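import numpy as np
import pandas as pd
import pytest

from panelpop import SimConfig, simulate_panel
from panelpop.matrix import GenotypeMatrix


def make_gm(calls, chrom="1", start=10, step=10, names=None, ref="A", alt="C"):
    """Build a GenotypeMatrix from a plain list-of-rows of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_sites = calls.shape
    if isinstance(chrom, str):
        chroms = [chrom] * n_sites
    else:
        chroms = list(chrom)
    pos = []
    counter = {}
    for c in chroms:
        counter[c] = counter.get(c, 0) + 1
        pos.append(start + (counter[c] - 1) * step)
    sites = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt})
    names = names or [f"ind{i}" for i in range(n_ind)]
    return GenotypeMatrix(calls, sites, names)


@pytest.fixture(scope="session")
def default_panel():
    """The default synthetic panel: 3 groups x 44 lines, 10 x 1000 sites."""
    return simulate_panel(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_truth(default_panel):
    return default_panel[2]
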