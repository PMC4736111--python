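import numpy as np
import pandas as pd
import pytest

from ldscape.popdata import HaplotypeSet, MarkerMap


def make_map(chroms, positions, ids=None):
    n = len(positions)
    return MarkerMap(
        pd.DataFrame(
            {
                "snp_id": ids if ids is not None else [f"s{i}" for i in range(n)],
                "chrom": [str(c) for c in chroms],
                "pos_bp": positions,
                "allele1": ["A"] * n,
                "allele2": ["G"] * n,
            }
        )
    )


def make_haps(matrix, chroms=None, positions=None, label="P"):
    """HaplotypeSet from a raw 0/1 matrix (rows = gametes)."""
    H = np.asarray(matrix, dtype=np.uint8)
    m = H.shape[1]
    if chroms is None:
        chroms = ["1"] * m
    if positions is None:
        positions = [100_000 * (i + 1) for i in range(m)]
    ids = [f"ind{i}" for i in range(H.shape[0] // 2)]
    return HaplotypeSet(H, ids, make_map(chroms, positions), label)


@pytest.fixture
def rng():
    return np.random.default_rng(20160201)


def random_polymorphic_haps(rng, n_gametes, n_markers, **kw):
    """Random phased matrix guaranteed polymorphic at every marker."""
    n_gametes = int(n_gametes) + int(n_gametes) % 2  # gametes come in pairs
    while True:
        H = (rng.random((n_gametes, n_markers)) < rng.uniform(0.1, 0.9, n_markers)).astype(np.uint8)
        p = H.mean(axis=0)
        if np.all((p > 0) & (p < 1)):
            return make_haps(H, **kw)
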