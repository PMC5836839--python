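"""End-to-loop distances and unpaired-nucleotide-frequency (UNF) profiles.

The loop-counting rule: Dicer cleaves precisely 2 nt from an upstream loop.
Its structural footprint is the signed distance from a mature miRNA end to
the nearest single-stranded nucleotide on the same strand: positive values
count nucleotides between the end and a single-stranded region outside the
miRNA, negative values count nucleotides that would have to be trimmed off
the miRNA to reach a loop inside it, and 0 means the end sits exactly at
the boundary of a single-stranded region.  Ends whose terminal nucleotide
is itself unpaired are excluded (the distance is undefined there).

The UNF at an aligned mature position is the fraction of hairpins whose
nucleotide at that position is single-stranded; it is compared against
per-position nucleotide substitution rates with a rank correlation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ingest import FIVE_PRIME, THREE_PRIME, HairpinRecord, MatureAnnotation
from .overhang_stats import CorrelationResult, rank_correlation

logger = logging.getLogger(__name__)

END_KINDS = ("5p_start", "5p_end", "3p_start", "3p_end")

#: functional position groups along the mature miRNA (1-based from its 5' end)
SEED_POSITIONS = range(2, 9)
ADDITIONAL_SITE_POSITIONS = range(13, 17)
TRANSITION_POSITIONS = (9, 17, 18, 19)


@dataclass(frozen=True)
class EndDistance:
    """Signed distance from one mature end to the nearest unpaired nucleotide.

    ``d`` is None when undefined (terminal nucleotide unpaired, or no
    single-stranded neighbour within the hairpin); ``reason`` says why.
    ``tie`` records that the inside and outside candidates had equal
    magnitude and the outside one was returned.
    """

    hairpin_id: str
    end_kind: str
    d: int | None
    reason: str | None = None
    tie: bool = False


def _end_position(mature: MatureAnnotation, end_kind: str) -> tuple[int, int]:
    """Terminal position and the backbone direction pointing outside the mature."""
    if end_kind.endswith("_start"):
        return mature.start, -1
    return mature.end, +1


def end_to_loop_distance(
    record: HairpinRecord, mature: MatureAnnotation, end_kind: str
) -> EndDistance:
    """Distance from one end of ``mature`` to the nearest unpaired nucleotide.

    Scans along the backbone from the terminal position ``t``: outward, the
    first unpaired position ``u`` outside the mature gives
    ``d_out = |u - t| - 1``; inward, the first unpaired position within the
    mature gives ``d_in = -|u - t|``.  The value of smaller magnitude is
    returned; on ties the outside (non-negative) value wins, because the
    loop-counting rule concerns loops upstream of the cleavage site.
    """
    if end_kind not in END_KINDS:
        raise ValueError(f"unknown end kind {end_kind!r}")
    t, dir_out = _end_position(mature, end_kind)
    if not record.is_paired(t):
        return EndDistance(record.id, end_kind, None, reason="terminal nucleotide unpaired")

    d_out: int | None = None
    pos = t + dir_out
    while 1 <= pos <= record.length:
        if not record.is_paired(pos):
            d_out = abs(pos - t) - 1
            break
        pos += dir_out

    d_in: int | None = None
    pos = t - dir_out
    while mature.start <= pos <= mature.end:
        if not record.is_paired(pos):
            d_in = -abs(pos - t)
            break
        pos -= dir_out

    if d_out is None and d_in is None:
        return EndDistance(record.id, end_kind, None, reason="no single-stranded neighbour")
    if d_in is None:
        return EndDistance(record.id, end_kind, d_out)
    if d_out is None:
        return EndDistance(record.id, end_kind, d_in)
    if abs(d_out) < abs(d_in):
        return EndDistance(record.id, end_kind, d_out)
    if abs(d_in) < abs(d_out):
        return EndDistance(record.id, end_kind, d_in)
    return EndDistance(record.id, end_kind, d_out, tie=True)


def end_distances_for_dataset(
    records: Iterable[HairpinRecord],
    end_kinds: Sequence[str] = END_KINDS,
) -> list[EndDistance]:
    """All defined and undefined end distances over a dataset."""
    out: list[EndDistance] = []
    for rec in records:
        for kind in end_kinds:
            arm = FIVE_PRIME if kind.startswith("5p") else THREE_PRIME
            m = rec.mature(arm)
            if m is None:
                continue
            out.append(end_to_loop_distance(rec, m, kind))
    return out


def distance_histogram(distances: Iterable[EndDistance]) -> Counter:
    """Histogram over the defined distances only."""
    return Counter(d.d for d in distances if d.d is not None)


# ---------------------------------------------------------------------------
# UNF profiles
# ---------------------------------------------------------------------------

@dataclass
class UNFProfile:
    """Per-position unpaired-nucleotide frequency with denominators.

    Positions are 1-based from the mature's 5' end; negative positions are
    the upstream flank (position -1 abuts position 1 directly, there is no
    position 0).  ``denominator[p]`` counts the hairpins that actually
    possess position ``p`` — flank positions falling outside a hairpin and
    positions beyond a record's own mature length do not enter its
    denominator.
    """

    arm: str
    frequency: dict[int, float]
    denominator: dict[int, int]
    unpaired: dict[int, int]

    def positions(self) -> list[int]:
        return sorted(self.frequency)

    def to_frame(self) -> pd.DataFrame:
        pos = self.positions()
        return pd.DataFrame(
            {
                "position": pos,
                "unf": [self.frequency[p] for p in pos],
                "unpaired": [self.unpaired[p] for p in pos],
                "denominator": [self.denominator[p] for p in pos],
            }
        )


def _hairpin_position(mature: MatureAnnotation, p: int) -> int:
    # profile position -> hairpin coordinate; no position 0 exists
    return mature.start + p - 1 if p >= 1 else mature.start + p


def unf_profile(
    records: Iterable[HairpinRecord], arm: str, flank_width: int = 10
) -> UNFProfile:
    """Unpaired-nucleotide frequency across matures of one arm.

    Covers positions ``-flank_width .. -1`` (upstream flank) and ``1 ..``
    the longest mature in the dataset.  Each record contributes to a
    position's denominator only if the mapped hairpin coordinate exists and,
    for positions inside the mature, the record's mature is long enough.
    """
    contributing = [
        (rec, m) for rec in records if (m := rec.mature(arm)) is not None
    ]
    if not contributing:
        raise ValueError(f"no records with a {arm} mature")
    max_len = max(len(m) for _, m in contributing)
    positions = list(range(-flank_width, 0)) + list(range(1, max_len + 1))
    unpaired: Counter = Counter()
    denom: Counter = Counter()
    for rec, m in contributing:
        mlen = len(m)
        for p in positions:
            if p >= 1 and p > mlen:
                continue
            h = _hairpin_position(m, p)
            if not 1 <= h <= rec.length:
                continue
            denom[p] += 1
            if not rec.is_paired(h):
                unpaired[p] += 1
    frequency = {p: unpaired[p] / denom[p] for p in denom}
    return UNFProfile(
        arm=arm,
        frequency=frequency,
        denominator=dict(denom),
        unpaired={p: unpaired[p] for p in denom},
    )


def correlate_unf_substitution(
    profile: UNFProfile,
    rates: Mapping[int, float],
    method: str = "asymptotic",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Rank-correlate a UNF profile with per-position substitution rates.

    Only positions present in both tables enter; at least three shared
    positions are required.  Returns the correlation result and the paired
    points actually used.
    """
    shared = sorted(set(profile.frequency) & set(rates))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared positions; need at least 3")
    unf = [profile.frequency[p] for p in shared]
    rate = [rates[p] for p in shared]
    result = rank_correlation(
        unf, rate, method=method, n_permutations=n_permutations, seed=seed
    )
    points = pd.DataFrame({"position": shared, "unf": unf, "rate": rate})
    return result, points
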