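import numpy as np
import pytest

from straitpop import LocusAlignment, PopulationMap

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_alignment(rng, n, length, alphabet=BASES, name="locus"):
    mat = rng.choice(list(alphabet), size=(n, length))
    return LocusAlignment.from_pairs(
        name, [(f"s{i}", "".join(row)) for i, row in enumerate(mat)]
    )


@pytest.fixture
def small_alignment():
    return LocusAlignment.from_pairs(
        "toy", [("a", "AAAA"), ("b", "AAAT"), ("c", "AATT")]
    )


@pytest.fixture
def three_group_pmap():
    """3 groups x 2 populations x 3 samples."""
    records = []
    for g, lat, lon in (("HS", 34.0, 134.0), ("C", 26.5, 118.0), ("TI", 23.8, 121.0)):
        for p in (1, 2):
            for k in range(3):
                records.append(
                    (f"{g}{p}_{k}", f"{g}{p}", g, lat + 0.1 * p, lon + 0.1 * p)
                )
    return PopulationMap.from_records(records)


def grouped_alignment(rng, pmap, length=60, divergence=0.15):
    """Random alignment whose samples follow pmap, with group-private variation."""
    groups = pmap.groups()
    anc = rng.choice(list(BASES), size=length)
    seqs = {}
    for g in groups:
        base = anc.copy()
        nmut = rng.binomial(length, divergence)
        cols = rng.choice(length, size=nmut, replace=False)
        for c in cols:
            base[c] = rng.choice([b for b in BASES if b != base[c]])
        for sid in pmap.samples_in(g):
            s = base.copy()
            for c in rng.choice(length, size=rng.poisson(1.0), replace=False):
                s[c] = rng.choice([b for b in BASES if b != s[c]])
            seqs[sid] = "".join(s)
    return LocusAlignment.from_pairs("grouped", [(sid, seqs[sid]) for sid in pmap.sample_ids])
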