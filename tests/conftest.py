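import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from trioweave.trio import TrioPanel


def make_panel(father, mother, child, pos=None, chrom=None):
    """Build a small TrioPanel from (families x snps) dosage lists."""
    father = np.asarray(father, dtype=np.int8)
    if father.ndim == 1:
        father = father[:, None]
    mother = np.asarray(mother, dtype=np.int8)
    if mother.ndim == 1:
        mother = mother[:, None]
    child = np.asarray(child, dtype=np.int8)
    if child.ndim == 1:
        child = child[:, None]
    n_fam, n_snp = father.shape
    return TrioPanel(
        family_ids=[f"F{i}" for i in range(n_fam)],
        snp_ids=[f"snp{j}" for j in range(n_snp)],
        chrom=chrom if chrom is not None else ["chr1"] * n_snp,
        pos=pos if pos is not None else list(range(0, 1000 * n_snp, 1000)),
        father=father,
        mother=mother,
        child=child,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
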