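"""Duplex identification and signed overhang lengths at both processing sites.

The miRNA duplex is the region where the two annotated matures pair across
the hairpin stem.  Its basal closing pair faces the hairpin base (the
Drosha cleavage site for canonical miRNAs, the splice sites for mirtrons)
and its apical closing pair faces the terminal loop (the Dicer site).

Overhangs are measured as the number of excess nucleotides one strand
extends beyond the closing pair of the duplex, regardless of whether those
nucleotides are paired or single-stranded.  Positive values are 3'
overhangs (the canonical RNase III product has +2 at both sites); negative
values are atypical 5' overhangs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .ingest import (
    FIVE_PRIME,
    THREE_PRIME,
    HairpinRecord,
    MatureAnnotation,
    StructureError,
)

BEYOND_CLOSING_PAIR = "beyond_closing_pair"
HANGING_END = "hanging_end"

#: overhang magnitude above which a structure is flagged as suspect
#: (mispredicted terminal loops produce artefactual long overhangs)
SUSPECT_THRESHOLD = 15


class DuplexError(ValueError):
    """Raised when no miRNA duplex can be identified in a hairpin."""


@dataclass(frozen=True)
class TerminalLoop:
    """Unpaired interval enclosed by the innermost base pair of a stem."""

    start: int
    end: int

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Duplex:
    five_p: MatureAnnotation
    three_p: MatureAnnotation
    basal_pair: tuple[int, int]
    apical_pair: tuple[int, int]


@dataclass(frozen=True)
class OverhangPair:
    """Signed basal (Drosha/splice-side) and apical (Dicer-side) overhangs."""

    hairpin_id: str
    basal: int
    apical: int
    variant: str = BEYOND_CLOSING_PAIR
    suspect: bool = False


def _hairpin_loops(record: HairpinRecord) -> list[tuple[int, int]]:
    """All hairpin loops: unpaired intervals [i+1, j-1] under a pair (i, j)
    with no pair strictly inside."""
    loops = []
    for i in range(1, record.length + 1):
        j = record.partner(i)
        if j > i + 1 and all(not record.is_paired(k) for k in range(i + 1, j)):
            loops.append((i + 1, j - 1))
    return loops


def _interval_distance(loop: tuple[int, int], mature: MatureAnnotation) -> int:
    ls, le = loop
    if le < mature.start:
        return mature.start - le
    if ls > mature.end:
        return ls - mature.end
    return 0


def _stem_depth(record: HairpinRecord, loop: tuple[int, int]) -> int:
    ls, le = loop
    return sum(
        1 for i in range(1, record.length + 1)
        if record.partner(i) > i and i < ls and record.partner(i) > le
    )


def find_terminal_loop(record: HairpinRecord) -> TerminalLoop:
    """Locate the terminal loop of the stem carrying the mature annotations.

    For a single-stem structure this is the unique innermost unpaired
    interval.  With several stems the loop nearest to the matures is chosen;
    without matures, the loop under the deepest stem (leftmost on ties).

    Raises
    ------
    StructureError
        If the hairpin has no base pairs or no enclosed unpaired interval.
    """
    if all(p == 0 for p in record.pairing):
        raise StructureError(f"{record.id}: no stem")
    loops = _hairpin_loops(record)
    if not loops:
        raise StructureError(f"{record.id}: no terminal loop (zero-size loops only)")
    if record.matures:
        best = min(
            loops,
            key=lambda lp: (min(_interval_distance(lp, m) for m in record.matures), lp[0]),
        )
    else:
        best = min(loops, key=lambda lp: (-_stem_depth(record, lp), lp[0]))
    return TerminalLoop(*best)


def identify_duplex(record: HairpinRecord) -> Duplex:
    """Find the closing pairs of the miRNA duplex.

    The basal pair is ``(a, partner(a))`` with ``a`` the smallest 5'-mature
    position paired into the 3' mature; the apical pair uses the largest
    such position.  Restricting the search to pairs joining the two mature
    intervals keeps multi-stem structures unambiguous.

    Raises
    ------
    DuplexError
        With fewer than two matures ("duplex undefined") or when no base
        pair joins the two matures ("no duplex closing pair").
    """
    m5 = record.mature(FIVE_PRIME)
    m3 = record.mature(THREE_PRIME)
    if m5 is None or m3 is None:
        raise DuplexError(f"{record.id}: duplex undefined (fewer than two matures)")
    joining = [
        p for p in m5.positions()
        if record.is_paired(p) and m3.start <= record.partner(p) <= m3.end
    ]
    if not joining:
        raise DuplexError(f"{record.id}: no duplex closing pair")
    a, c = min(joining), max(joining)
    return Duplex(
        five_p=m5,
        three_p=m3,
        basal_pair=(a, record.partner(a)),
        apical_pair=(c, record.partner(c)),
    )


def compute_overhangs(
    record: HairpinRecord,
    variant: str = BEYOND_CLOSING_PAIR,
    suspect_threshold: int = SUSPECT_THRESHOLD,
) -> OverhangPair:
    """Signed overhang lengths at the basal and apical duplex boundaries.

    With mature intervals ``[s5,e5]`` and ``[s3,e3]`` and duplex boundary
    positions ``a,b`` (basal) and ``c,d`` (apical)::

        basal  = (e3 - b) - (a - s5)
        apical = (e5 - c) - (d - s3)

    ``beyond_closing_pair`` takes ``a,b,c,d`` from the duplex closing pairs
    (nucleotides are counted regardless of their own pairing state).  The
    ``hanging_end`` robustness variant instead uses the outermost/innermost
    mature positions that are paired to *anything*, so only truly
    single-stranded hanging ends count; the two variants agree whenever the
    terminal mature nucleotides are paired to the partner mature.

    Overhang magnitudes above ``suspect_threshold`` are flagged as suspect
    structures but still reported.
    """
    duplex = identify_duplex(record)
    m5, m3 = duplex.five_p, duplex.three_p
    if variant == BEYOND_CLOSING_PAIR:
        a, b = duplex.basal_pair
        c, d = duplex.apical_pair
    elif variant == HANGING_END:
        paired5 = [p for p in m5.positions() if record.is_paired(p)]
        paired3 = [p for p in m3.positions() if record.is_paired(p)]
        a, c = min(paired5), max(paired5)
        d, b = min(paired3), max(paired3)
    else:
        raise ValueError(f"unknown overhang variant {variant!r}")
    basal = (m3.end - b) - (a - m5.start)
    apical = (m5.end - c) - (d - m3.start)
    return OverhangPair(
        hairpin_id=record.id,
        basal=basal,
        apical=apical,
        variant=variant,
        suspect=max(abs(basal), abs(apical)) > suspect_threshold,
    )


def overhangs_for_dataset(
    records: Iterable[HairpinRecord],
    variant: str = BEYOND_CLOSING_PAIR,
    suspect_threshold: int = SUSPECT_THRESHOLD,
) -> tuple[list[OverhangPair], list[tuple[str, str]]]:
    """Compute overhangs for every record with a duplex; collect failures."""
    pairs: list[OverhangPair] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            pairs.append(compute_overhangs(rec, variant, suspect_threshold))
        except (DuplexError, StructureError) as exc:
            failures.append((rec.id, str(exc)))
    return pairs, failures
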