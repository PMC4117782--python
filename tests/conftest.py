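import numpy as np
import pytest

from loopcall4c.counts import FragmentCounts
from loopcall4c.restriction import FragmentLibrary, RestrictionFragment


@pytest.fixture
def toy_library() -> FragmentLibrary:
    """10 fragments over two chromosomes (8 on chr1, 2 on chr2)."""
    frags = []
    bounds = [0, 1000, 2500, 4000, 5000, 7000, 8000, 9500, 10000]
    for i in range(len(bounds) - 1):
        frags.append(
            RestrictionFragment("chr1", bounds[i], bounds[i + 1], f"chr1_frag{i:05d}")
        )
    frags.append(RestrictionFragment("chr2", 0, 3000, "chr2_frag00000"))
    frags.append(RestrictionFragment("chr2", 3000, 5000, "chr2_frag00001"))
    return FragmentLibrary(frags, {"chr1": 10000, "chr2": 5000})


@pytest.fixture
def toy_counts(toy_library) -> FragmentCounts:
    rng = np.random.default_rng(42)
    counts = {
        fid: int(c)
        for fid, c in zip(
            toy_library.fragment_ids, rng.poisson(20, size=len(toy_library))
        )
    }
    return FragmentCounts(library=toy_library, counts=counts, replicate_id="rep1")
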