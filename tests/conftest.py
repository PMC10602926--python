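import numpy as np
import pytest

from lretools import RnaSequence, ScoringModel
from lretools.scan import Hairpin


@pytest.fixture
def model():
    return ScoringModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))


def oracle_hairpins(seq: RnaSequence, model: ScoringModel):
    """Exhaustive O(n^3) reference enumerator.

    Tests every (start, stem_len) combination for valid pairing and keeps,
    per loop position, the longest valid stem capped at max_stem.  Kept
    deliberately brute-force and independent of the incremental scanner.
    """
    s = seq.seq
    n = len(s)
    best = {}
    for start in range(n):
        for k in range(model.min_stem, model.max_stem + 1):
            if start + 2 * k + 3 > n:
                break
            loop_start = start + k
            ok = True
            for d in range(1, k + 1):
                p5 = s[loop_start - d]
                p3 = s[loop_start + 2 + d]
                if not model.allowed_pair(p5, p3, closing=(d == 1)):
                    ok = False
                    break
            if ok and k > best.get(loop_start, 0):
                best[loop_start] = k
    out = []
    for loop_start in sorted(best):
        k = best[loop_start]
        pairs = tuple(
            (s[loop_start - d], s[loop_start + 2 + d]) for d in range(k, 0, -1)
        )
        out.append(
            Hairpin(
                seq_id=seq.id,
                stem5_start=loop_start - k,
                stem_len=k,
                loop_start=loop_start,
                loop=s[loop_start : loop_start + 3],
                pairs=pairs,
            )
        )
    out.sort(key=lambda h: h.stem5_start)
    return out
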