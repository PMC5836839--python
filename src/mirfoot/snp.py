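"""Region-wise SNP densities and per-sequence SNP occurrence.

Each hairpin is partitioned into disjoint functional regions: the seed
(mature positions 2-8, both arms), the rest of the mature miRNA, the rest
of the pre-miRNA, and upstream/downstream flanks of configurable width.
SNP density is N_snp * 1000 / L per kilobase, pooled over a dataset per
region class.  SNP occurrence per sequence is the mean SNP count per
pre-miRNA in the four disease x mirtron groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .ingest import HairpinRecord, SnpRecord

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

REGION_SEED = "seed"
REGION_MATURE = "mature_excl_seed"
REGION_PREMIRNA = "premirna_excl_mature"
REGION_FLANK_UP = "flank_upstream"
REGION_FLANK_DOWN = "flank_downstream"
REGION_FLANK_POOLED = "flank_pooled"

HAIRPIN_REGIONS = (REGION_SEED, REGION_MATURE, REGION_PREMIRNA)
FLANK_REGIONS = (REGION_FLANK_UP, REGION_FLANK_DOWN)

#: seed = mature positions 2-8 (1-based from the mature 5' end)
SEED_SPAN = (2, 8)

DEFAULT_FLANK_WIDTH = 200


def _subtract(intervals: Sequence[Interval], holes: Sequence[Interval]) -> list[Interval]:
    """Interval-set difference on 1-based inclusive intervals."""
    out = list(intervals)
    for hs, he in holes:
        nxt: list[Interval] = []
        for s, e in out:
            if he < s or hs > e:
                nxt.append((s, e))
                continue
            if s < hs:
                nxt.append((s, hs - 1))
            if he < e:
                nxt.append((he + 1, e))
        out = nxt
    return [iv for iv in out if iv[0] <= iv[1]]


def _total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s + 1 for s, e in intervals)


@dataclass
class RegionPartition:
    """Disjoint functional regions of one hairpin (plus its flanks).

    ``regions`` maps region label to a tuple of 1-based inclusive intervals.
    Flank coordinates extend the hairpin axis: upstream positions are <= 0,
    downstream positions exceed the hairpin length.
    """

    hairpin_id: str
    hairpin_length: int
    regions: dict[str, tuple[Interval, ...]]
    flank_width: int

    def region_of(self, position: int) -> str | None:
        for label, intervals in self.regions.items():
            for s, e in intervals:
                if s <= position <= e:
                    return label
        return None


def partition_regions(
    record: HairpinRecord, flank_width: int = DEFAULT_FLANK_WIDTH
) -> RegionPartition:
    """Partition a hairpin into seed / mature / pre-miRNA / flank regions.

    Requires at least one annotated mature (the seed is defined per mature).
    Seeds shorter than 7 nt are clipped to the mature's end.  With
    ``flank_width=0`` the flank regions are empty.
    """
    if not record.matures:
        raise ValueError(f"{record.id}: no matures; regions undefined")
    if flank_width < 0:
        raise ValueError("flank_width must be >= 0")
    n = record.length
    seeds: list[Interval] = []
    mature_ivs: list[Interval] = []
    for m in record.matures:
        mature_ivs.append((m.start, m.end))
        seed_start = m.start + SEED_SPAN[0] - 1
        seed_end = min(m.start + SEED_SPAN[1] - 1, m.end)
        if seed_start <= seed_end:
            seeds.append((seed_start, seed_end))
    mature_excl_seed = _subtract(mature_ivs, seeds)
    premirna = _subtract([(1, n)], mature_ivs)
    regions: dict[str, tuple[Interval, ...]] = {
        REGION_SEED: tuple(seeds),
        REGION_MATURE: tuple(mature_excl_seed),
        REGION_PREMIRNA: tuple(premirna),
        REGION_FLANK_UP: ((1 - flank_width, 0),) if flank_width else (),
        REGION_FLANK_DOWN: ((n + 1, n + flank_width),) if flank_width else (),
    }
    return RegionPartition(record.id, n, regions, flank_width)


@dataclass(frozen=True)
class RegionDensity:
    """Pooled SNP density of one region class: N_snp * 1000 / L per kb."""

    region: str
    n_snp: int
    length: int
    density: float
    flag_filter: str = "all"


def snp_density(
    snps: Iterable[SnpRecord],
    partitions: Iterable[RegionPartition] | Mapping[str, RegionPartition],
    flag_filter: str = "all",
    pool_flanks: bool = True,
) -> list[RegionDensity]:
    """Pooled per-region SNP densities over a dataset.

    ``flag_filter`` is ``all`` or ``common_only``.  Counts and lengths are
    pooled over all partitions per region class before dividing, so density
    is additive under any split of a region into sub-intervals.  Flank
    densities are reported separately per flank and, with ``pool_flanks``,
    additionally pooled.  Regions with zero pooled length are skipped with
    a warning; SNPs on unknown hairpins or outside every region are dropped
    with a warning.
    """
    if flag_filter not in ("all", "common_only"):
        raise ValueError(f"unknown flag filter {flag_filter!r}")
    if not isinstance(partitions, Mapping):
        partitions = {p.hairpin_id: p for p in partitions}

    region_labels = list(HAIRPIN_REGIONS + FLANK_REGIONS)
    lengths = {
        label: sum(_total_length(p.regions[label]) for p in partitions.values())
        for label in region_labels
    }
    counts = {label: 0 for label in region_labels}
    n_dropped = 0
    for snp in snps:
        if flag_filter == "common_only" and snp.flag != "common":
            continue
        part = partitions.get(snp.hairpin_id)
        if part is None:
            n_dropped += 1
            continue
        label = part.region_of(snp.position)
        if label is None:
            n_dropped += 1
            continue
        counts[label] += 1
    if n_dropped:
        logger.warning("%d SNPs on unknown hairpins or outside all regions dropped", n_dropped)

    out: list[RegionDensity] = []
    for label in region_labels:
        if lengths[label] == 0:
            logger.warning("region %s has zero pooled length; skipped", label)
            continue
        out.append(
            RegionDensity(
                label, counts[label], lengths[label],
                counts[label] * 1000.0 / lengths[label], flag_filter,
            )
        )
    if pool_flanks:
        fl_len = lengths[REGION_FLANK_UP] + lengths[REGION_FLANK_DOWN]
        if fl_len > 0:
            fl_n = counts[REGION_FLANK_UP] + counts[REGION_FLANK_DOWN]
            out.append(
                RegionDensity(REGION_FLANK_POOLED, fl_n, fl_len,
                              fl_n * 1000.0 / fl_len, flag_filter)
            )
    return out


@dataclass(frozen=True)
class GroupOccurrence:
    """Mean SNPs per pre-miRNA in one disease x mirtron group."""

    disease: bool
    mirtron: bool
    mean: float | None
    n_hairpins: int


def snp_occurrence_by_disease(
    snps: Iterable[SnpRecord],
    records: Iterable[HairpinRecord],
    disease_ids: Iterable[str],
    flag_filter: str = "all",
) -> list[GroupOccurrence]:
    """Mean SNP count per pre-miRNA, stratified by disease and mirtron status.

    Only SNPs within the pre-miRNA span [1, length] count; hairpins with no
    SNPs contribute zeros.  Mirtron status comes from the ``mirtron`` record
    tag.  Empty groups are reported with an undefined (None) mean.
    """
    disease_ids = set(disease_ids)
    records = list(records)
    per_hairpin = {r.id: 0 for r in records}
    lengths = {r.id: r.length for r in records}
    for snp in snps:
        if flag_filter == "common_only" and snp.flag != "common":
            continue
        if snp.hairpin_id in per_hairpin and 1 <= snp.position <= lengths[snp.hairpin_id]:
            per_hairpin[snp.hairpin_id] += 1

    out: list[GroupOccurrence] = []
    for disease in (True, False):
        for mirtron in (True, False):
            members = [
                r.id for r in records
                if (r.id in disease_ids) == disease
                and ("mirtron" in r.tags) == mirtron
            ]
            if members:
                mean = sum(per_hairpin[i] for i in members) / len(members)
            else:
                mean = None
            out.append(GroupOccurrence(disease, mirtron, mean, len(members)))
    return out
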