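import numpy as np
import pandas as pd
import pytest

from aneuhic.restriction import RestrictionMap


def make_rmap(length: int, cuts, name: str = "chrT") -> RestrictionMap:
    """Restriction map with explicit cut positions (bypasses motif scan)."""
    cuts = np.asarray(sorted(cuts), dtype=np.int64)
    bounds = np.concatenate(([0], cuts, [length]))
    frags = np.column_stack((bounds[:-1], bounds[1:]))
    return RestrictionMap(name, length, frags, cuts, motif="AAGCTT", cut_offset=1)


def make_pairs(rows) -> pd.DataFrame:
    """Pair table from (chrom1,pos1,strand1,mapped1,chrom2,pos2,strand2,mapped2) rows."""
    return pd.DataFrame(
        rows,
        columns=["chrom1", "pos1", "strand1", "mapped1", "chrom2", "pos2", "strand2", "mapped2"],
    )


@pytest.fixture
def toy_rmap():
    """Three fragments [0,1000), [1000,2500), [2500,4000) on a 4-kb chromosome."""
    return make_rmap(4000, [1000, 2500])


@pytest.fixture
def planted_genome():
    """60-kb toy genome with HindIII sites planted every ~2 kb on average."""
    from aneuhic.simulate import generate_genome

    seq, truth = generate_genome(60_000, gc=0.45, motif="AAGCTT", mean_fragment=2000, seed=11)
    return seq, truth
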