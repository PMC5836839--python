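"""Shared fixtures: small hand-constructed hairpins with known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from mirfoot import HairpinRecord, MatureAnnotation, parse_dot_bracket

# toy T1: clean 20-bp stem, 8-nt loop, 2-nt 3' tail; canonical duplex
T1_STRUCTURE = "(" * 20 + "." * 8 + ")" * 20 + ".."


def make_record(structure, matures=(), hairpin_id="hsa-toy", sequence=None):
    pairing = parse_dot_bracket(structure)
    if sequence is None:
        sequence = "".join(
            "G" if p > i + 1 else ("C" if p else "A")
            for i, p in enumerate(pairing)
        )
    return HairpinRecord(
        id=hairpin_id,
        species=hairpin_id.split("-")[0],
        sequence=sequence,
        pairing=pairing,
        matures=tuple(MatureAnnotation(arm, s, e) for arm, s, e in matures),
    )


@pytest.fixture
def t1():
    """50-nt hairpin, matures [1,22] / [29,50]: canonical (+2,+2) overhangs."""
    return make_record(
        T1_STRUCTURE,
        matures=[("five_prime", 1, 22), ("three_prime", 29, 50)],
        hairpin_id="hsa-t1",
    )


@pytest.fixture
def t2():
    """30-nt hairpin with an internal loop; matures [1,12] / [19,30]."""
    return make_record(
        "((((((..((((....))))..))))))..",
        matures=[("five_prime", 1, 12), ("three_prime", 19, 30)],
        hairpin_id="hsa-t2",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20180209)


def random_mature_spans(rng, n, min_len=8):
    """Two disjoint random intervals inside [1, n], left one first."""
    if n < 2 * min_len + 2:
        raise ValueError("hairpin too short")
    mid = n // 2
    s5 = int(rng.integers(1, mid - min_len))
    e5 = int(rng.integers(s5 + min_len - 1, mid))
    s3 = int(rng.integers(mid + 1, n - min_len + 1))
    e3 = int(rng.integers(s3 + min_len - 1, n)) if s3 + min_len - 1 < n else n
    return (s5, e5), (s3, e3)
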