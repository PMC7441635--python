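import numpy as np
import pytest

from xkin.pedigree import prepare_pedigree


@pytest.fixture
def trio():
    """Base sire and dam with one son and one daughter."""
    return prepare_pedigree(
        [("s", "0", "0", "M"), ("d", "0", "0", "F"),
         ("son", "s", "d", "M"), ("dau", "s", "d", "F")]
    )


@pytest.fixture
def table1_pedigree():
    """All the canonical relationship classes on one pedigree.

    Base parents s1, s2 (sires) and d1, d2, d3 (dams); offspring chosen so
    that every sib class with known, distinct non-shared parents exists.
    """
    return prepare_pedigree(
        [
            ("s1", "0", "0", "M"), ("s2", "0", "0", "M"),
            ("d1", "0", "0", "F"), ("d2", "0", "0", "F"), ("d3", "0", "0", "F"),
            # full sibs of every sex pair (s1 x d1)
            ("fsM1", "s1", "d1", "M"), ("fsM2", "s1", "d1", "M"),
            ("fsF1", "s1", "d1", "F"), ("fsF2", "s1", "d1", "F"),
            # paternal half-sibs: s1 with d2 against the d1 full sibs
            ("phM", "s1", "d2", "M"), ("phF", "s1", "d2", "F"),
            # maternal half-sibs: d3 with both sires
            ("mhM1", "s1", "d3", "M"), ("mhM2", "s2", "d3", "M"),
            ("mhF1", "s1", "d3", "F"), ("mhF2", "s2", "d3", "F"),
        ]
    )


def random_pedigree(seed, n=20):
    """A random valid pedigree built sequentially (parents drawn or unknown)."""
    rng = np.random.default_rng(seed)
    records = []
    males, females = [], []
    for i in range(n):
        sex = "M" if rng.random() < 0.5 or not males else "F"
        if i < 4:
            sex = "M" if i % 2 == 0 else "F"
        sire = rng.choice(males) if males and rng.random() < 0.8 else "0"
        dam = rng.choice(females) if females and rng.random() < 0.8 else "0"
        name = f"i{i}"
        records.append((name, sire, dam, sex))
        (males if sex == "M" else females).append(name)
    return prepare_pedigree(records)
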