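"""Reading, validating and partitioning pre-miRNA hairpins and auxiliary tables.

The central container is :class:`HairpinRecord`: one pre-miRNA hairpin with its
sequence, a nested base-pairing table, and up to two annotated mature miRNAs.
All coordinates are 1-based, inclusive, and hairpin-relative throughout the
package; conversion to other conventions is a file-boundary concern.

Input dialects (all plain text):

* sequences: FASTA (``U``/``T`` and case are normalized to uppercase RNA);
* structures: either per-record ``id<TAB>dot-bracket`` lines or Vienna-style
  ``>id`` / sequence / dot-bracket triples;
* matures: TSV with columns ``hairpin_id, mature_id, start, end``;
* SNPs: TSV with columns ``hairpin_id, position, maf, flag``;
* branchpoints: TSV with columns ``intron_id, bp_offset_from_3ss`` and
  optional ``hairpin_id, bp_hairpin_position``;
* substitution rates: TSV with columns ``position, rate``;
* id lists: one identifier per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


class StructureError(ValueError):
    """Raised for malformed dot-bracket strings or inconsistent pairing tables."""


# ---------------------------------------------------------------------------
# dot-bracket parsing
# ---------------------------------------------------------------------------

def parse_dot_bracket(db: str) -> tuple[int, ...]:
    """Parse a dot-bracket string into a 1-based pairing table.

    Returns a tuple ``partner`` of the same length as ``db`` where
    ``partner[i-1]`` is the 1-based partner of position ``i``, or 0 if
    position ``i`` is unpaired.  The result is a nested involution by
    construction of bracket matching.

    Raises
    ------
    StructureError
        If ``db`` contains characters other than ``(``, ``)``, ``.`` or the
        brackets are unbalanced; the message names the offending position.
    """
    partner = [0] * len(db)
    stack: list[int] = []
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            opener = stack.pop()
            partner[opener - 1] = pos
            partner[pos - 1] = opener
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise StructureError(
            f"unbalanced at end: '(' at position {stack[-1]} never closed"
        )
    return tuple(partner)


def pairing_to_dot_bracket(pairing: Sequence[int]) -> str:
    """Render a pairing table back into dot-bracket notation."""
    chars = []
    for i, j in enumerate(pairing, start=1):
        if j == 0:
            chars.append(".")
        elif j > i:
            chars.append("(")
        else:
            chars.append(")")
    return "".join(chars)


def _validate_pairing(pairing: Sequence[int]) -> None:
    """Check that a pairing table is a nested involution (no pseudoknots)."""
    n = len(pairing)
    for i, j in enumerate(pairing, start=1):
        if j == 0:
            continue
        if not 1 <= j <= n:
            raise StructureError(f"partner of position {i} out of range: {j}")
        if j == i:
            raise StructureError(f"position {i} paired to itself")
        if pairing[j - 1] != i:
            raise StructureError(f"pairing not an involution at positions {i},{j}")
    # nestedness: a stack scan over opening pairs
    stack: list[int] = []
    for i, j in enumerate(pairing, start=1):
        if j > i:
            if stack and j > stack[-1]:
                raise StructureError(
                    f"pseudoknot: pair ({i},{j}) crosses pair closing at {stack[-1]}"
                )
            stack.append(j)
        elif 0 < j < i:
            if not stack or stack[-1] != i:
                raise StructureError(f"pseudoknot detected at position {i}")
            stack.pop()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class MatureAnnotation:
    """One mature miRNA within its hairpin, 1-based inclusive coordinates."""

    arm: str  # FIVE_PRIME or THREE_PRIME
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.start > self.end:
            raise ValueError(f"mature start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class HairpinRecord:
    """One pre-miRNA hairpin: sequence, pairing table, mature annotations.

    ``pairing[i-1]`` gives the 1-based partner of position ``i`` (0 =
    unpaired).  Invariants (checked on construction): pairing is a nested
    involution of the same length as the sequence; matures lie within the
    hairpin and do not overlap; when two matures are annotated the 5' one
    precedes the 3' one.
    """

    id: str
    species: str
    sequence: str
    pairing: tuple[int, ...]
    matures: tuple[MatureAnnotation, ...] = ()
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.pairing):
            raise StructureError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"pairing length {len(self.pairing)}"
            )
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-canonical nucleotide {sorted(bad)}")
        _validate_pairing(self.pairing)
        if len(self.matures) > 2:
            raise ValueError(f"{self.id}: more than two matures")
        n = len(self.sequence)
        for m in self.matures:
            if m.start < 1 or m.end > n:
                raise ValueError(f"{self.id}: mature [{m.start},{m.end}] outside [1,{n}]")
        if len(self.matures) == 2:
            a, b = sorted(self.matures, key=lambda m: m.start)
            if a.end >= b.start:
                raise ValueError(f"{self.id}: matures overlap")
            if a.arm != FIVE_PRIME or b.arm != THREE_PRIME:
                raise ValueError(f"{self.id}: arm labels inconsistent with order")

    # -- convenience accessors ------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.sequence)

    def partner(self, i: int) -> int:
        """1-based partner of position ``i`` (0 if unpaired)."""
        return self.pairing[i - 1]

    def is_paired(self, i: int) -> bool:
        return self.pairing[i - 1] != 0

    def dot_bracket(self) -> str:
        return pairing_to_dot_bracket(self.pairing)

    def mature(self, arm: str) -> MatureAnnotation | None:
        for m in self.matures:
            if m.arm == arm:
                return m
        return None

    def with_tags(self, *tags: str) -> "HairpinRecord":
        return replace(self, tags=self.tags | frozenset(tags))


def assign_arms(
    intervals: Sequence[tuple[int, int]], hairpin_length: int
) -> tuple[MatureAnnotation, ...]:
    """Label raw mature intervals as 5'- or 3'-arm.

    With two matures the left one is the 5' arm.  With a single mature the
    arm is decided by which side of the hairpin midpoint its own midpoint
    falls on (5' if left of the midpoint).
    """
    if not intervals:
        return ()
    ivs = sorted(intervals)
    if len(ivs) == 1:
        s, e = ivs[0]
        arm = FIVE_PRIME if (s + e) / 2 <= (hairpin_length + 1) / 2 else THREE_PRIME
        return (MatureAnnotation(arm, s, e),)
    if len(ivs) == 2:
        (s1, e1), (s2, e2) = ivs
        return (
            MatureAnnotation(FIVE_PRIME, s1, e1),
            MatureAnnotation(THREE_PRIME, s2, e2),
        )
    raise ValueError("more than two matures")


# ---------------------------------------------------------------------------
# loading hairpins
# ---------------------------------------------------------------------------

def normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def species_of(hairpin_id: str) -> str:
    """Organism prefix of a miRBase-style identifier (``hsa-mir-21`` -> ``hsa``)."""
    return hairpin_id.split("-", 1)[0].lower()


@dataclass
class LoadResult:
    records: list[HairpinRecord]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def ids(self) -> set[str]:
        return {r.id for r in self.records}


def read_structures(path: str | Path) -> dict[str, str]:
    """Read a structure file: TSV (``id<TAB>dot-bracket``) or Vienna blocks."""
    path = Path(path)
    text = path.read_text()
    structures: dict[str, str] = {}
    if text.lstrip().startswith(">"):
        current: str | None = None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
            elif current is not None and set(line) <= set("().") and line:
                structures[current] = line
        return structures
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            logger.warning("%s:%d: malformed structure line skipped", path, lineno)
            continue
        structures[parts[0]] = parts[1].strip()
    return structures


def read_matures(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read the mature TSV into ``hairpin_id -> [(start, end), ...]``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"hairpin_id", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"mature table {path} lacks columns {required}")
    out: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.hairpin_id), []).append((int(row.start), int(row.end)))
    return out


def load_hairpins(
    fasta: str | Path,
    structures: str | Path,
    matures: str | Path | None = None,
) -> LoadResult:
    """Assemble :class:`HairpinRecord` objects from the three input files.

    Applies the study exclusions: records containing characters outside
    {A,C,G,U} after normalization, and records with more than two annotated
    matures, are dropped with a reason.  Records whose structure is missing
    or whose structure length mismatches the sequence are likewise rejected
    rather than fatal.
    """
    struct_map = read_structures(structures)
    mature_map = read_matures(matures) if matures is not None else {}

    result = LoadResult(records=[])
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        hid = rec.id
        seen.add(hid)
        seq = normalize_rna(str(rec.seq))
        if set(seq) - RNA_ALPHABET:
            result.excluded.append((hid, "non-canonical nucleotide"))
            continue
        db = struct_map.get(hid)
        if db is None:
            result.excluded.append((hid, "missing structure"))
            continue
        if len(db) != len(seq):
            result.excluded.append((hid, "structure length mismatch"))
            continue
        try:
            pairing = parse_dot_bracket(db)
        except StructureError as exc:
            result.excluded.append((hid, f"structure parse error: {exc}"))
            continue
        raw_matures = mature_map.get(hid, [])
        if len(raw_matures) > 2:
            result.excluded.append((hid, "more than two matures"))
            continue
        try:
            ann = assign_arms(raw_matures, len(seq))
            record = HairpinRecord(
                id=hid, species=species_of(hid), sequence=seq,
                pairing=pairing, matures=ann,
            )
        except (ValueError, StructureError) as exc:
            result.excluded.append((hid, str(exc)))
            continue
        result.records.append(record)

    orphans = set(mature_map) - seen
    if orphans:
        logger.warning("%d mature annotations reference unknown hairpins", len(orphans))
    return result


def write_hairpins(
    records: Iterable[HairpinRecord],
    fasta: str | Path,
    structures: str | Path,
    matures: str | Path,
) -> None:
    """Serialize records into the exact dialects :func:`load_hairpins` reads."""
    records = list(records)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(fasta), "fasta")
    with open(structures, "w") as fh:
        for r in records:
            fh.write(f"{r.id}\t{r.dot_bracket()}\n")
    rows = []
    for r in records:
        for m in r.matures:
            suffix = "5p" if m.arm == FIVE_PRIME else "3p"
            rows.append((r.id, f"{r.id}-{suffix}", m.start, m.end))
    pd.DataFrame(rows, columns=["hairpin_id", "mature_id", "start", "end"]).to_csv(
        matures, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# dataset partition
# ---------------------------------------------------------------------------

@dataclass
class DatasetPartition:
    """The four study datasets plus bookkeeping of unmatched mirtron ids."""

    all_animal: list[HairpinRecord]
    animal_minus_hs_mm: list[HairpinRecord]
    hs_mm_non_mirtrons: list[HairpinRecord]
    hs_mm_mirtrons: list[HairpinRecord]
    orphan_mirtron_ids: list[str] = field(default_factory=list)

    def sizes(self) -> tuple[int, int, int, int]:
        return (
            len(self.all_animal),
            len(self.animal_minus_hs_mm),
            len(self.hs_mm_non_mirtrons),
            len(self.hs_mm_mirtrons),
        )


def partition_datasets(
    hairpins: Iterable[HairpinRecord],
    mirtron_ids: Iterable[str],
    human_mouse_prefixes: Sequence[str] = ("hsa", "mmu"),
) -> DatasetPartition:
    """Split hairpins into the four study sets by species and mirtron status.

    Human+mouse records go to the mirtron or non-mirtron set according to
    membership in ``mirtron_ids``; every other species lands in the
    animal-minus-human/mouse set.  Mirtron ids that match no hairpin are
    recorded as orphans, not fatal.  Records gain ``mirtron``/``non-mirtron``
    tags in the returned partition.
    """
    mirtron_ids = set(mirtron_ids)
    hs_mm = set(p.lower() for p in human_mouse_prefixes)
    all_animal: list[HairpinRecord] = []
    other: list[HairpinRecord] = []
    non_mirtrons: list[HairpinRecord] = []
    mirtrons: list[HairpinRecord] = []
    seen_ids: set[str] = set()
    for rec in hairpins:
        seen_ids.add(rec.id)
        if rec.species in hs_mm:
            if rec.id in mirtron_ids:
                rec = rec.with_tags("mirtron")
                mirtrons.append(rec)
            else:
                rec = rec.with_tags("non-mirtron")
                non_mirtrons.append(rec)
        else:
            other.append(rec)
        all_animal.append(rec)
    orphans = sorted(mirtron_ids - seen_ids)
    if orphans:
        logger.warning("%d mirtron ids match no loaded hairpin", len(orphans))
    return DatasetPartition(all_animal, other, non_mirtrons, mirtrons, orphans)


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """One SNP in hairpin-relative coordinates.

    Positions <= 0 or > hairpin length denote flank SNPs.  ``flag`` is
    ``common`` (minor allele frequency > 0.01) or ``rare``.
    """

    hairpin_id: str
    position: int
    flag: str
    maf: float | None = None


@dataclass(frozen=True)
class BranchpointRecord:
    """A branchpoint: offset upstream of the intron's 3' splice site.

    ``offset_3ss`` counts from the intron's last nucleotide (offset 0).
    ``bp_position`` is the optional 1-based coordinate within the linked
    hairpin.
    """

    intron_id: str
    offset_3ss: int
    hairpin_id: str | None = None
    bp_position: int | None = None


@dataclass
class AuxTables:
    """Bundle of the auxiliary inputs: SNPs, branchpoints, rates, id lists."""

    snps: list[SnpRecord] = field(default_factory=list)
    branchpoints: list[BranchpointRecord] = field(default_factory=list)
    substitution_rates: dict[int, float] = field(default_factory=dict)
    mirtron_ids: set[str] = field(default_factory=set)
    robust_ids: set[str] = field(default_factory=set)
    disease_ids: set[str] = field(default_factory=set)

    def orphan_ids(self, hairpin_ids: set[str]) -> set[str]:
        """Ids referenced by SNP/branchpoint rows that match no loaded hairpin."""
        referenced = {s.hairpin_id for s in self.snps}
        referenced |= {b.hairpin_id for b in self.branchpoints if b.hairpin_id}
        return referenced - hairpin_ids


COMMON_MAF_THRESHOLD = 0.01


def _load_snps(path: str | Path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    records: list[SnpRecord] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        try:
            maf = float(row.maf) if "maf" in df.columns and pd.notna(row.maf) else None
            flag = getattr(row, "flag", None)
            if flag is None or pd.isna(flag):
                if maf is None:
                    raise ValueError("neither flag nor maf")
                flag = "common" if maf > COMMON_MAF_THRESHOLD else "rare"
            flag = str(flag).lower()
            if flag not in ("common", "rare"):
                raise ValueError(f"bad flag {flag!r}")
            records.append(
                SnpRecord(str(row.hairpin_id), int(row.position), flag, maf)
            )
        except (ValueError, TypeError):
            n_bad += 1
    if n_bad:
        logger.warning("%s: %d malformed SNP rows skipped", path, n_bad)
    return records


def _load_branchpoints(path: str | Path) -> list[BranchpointRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    records: list[BranchpointRecord] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        try:
            hid = getattr(row, "hairpin_id", None)
            hid = None if hid is None or pd.isna(hid) else str(hid)
            bp_pos = getattr(row, "bp_hairpin_position", None)
            bp_pos = None if bp_pos is None or pd.isna(bp_pos) else int(bp_pos)
            offset = int(row.bp_offset_from_3ss)
            if offset < 0:
                raise ValueError("negative offset")
            records.append(BranchpointRecord(str(row.intron_id), offset, hid, bp_pos))
        except (ValueError, TypeError):
            n_bad += 1
    if n_bad:
        logger.warning("%s: %d malformed branchpoint rows skipped", path, n_bad)
    return records


def _load_rates(path: str | Path) -> dict[int, float]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {int(p): float(r) for p, r in zip(df["position"], df["rate"])}


def _load_idlist(path: str | Path) -> set[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = [ln for ln in lines if ln and not ln.startswith("#")]
    unique = set(ids)
    if len(unique) < len(ids):
        logger.info("%s: %d duplicate ids collapsed", path, len(ids) - len(unique))
    return unique


def load_aux_tables(kind: str, path: str | Path):
    """Load one auxiliary table of the given ``kind``.

    ``kind`` is one of ``snp``, ``branchpoint``, ``rates``, ``idlist``;
    anything else is a usage error.  Malformed rows are logged and skipped.
    """
    loaders = {
        "snp": _load_snps,
        "branchpoint": _load_branchpoints,
        "rates": _load_rates,
        "idlist": _load_idlist,
    }
    if kind not in loaders:
        raise ValueError(f"unknown aux table kind {kind!r}; expected one of {sorted(loaders)}")
    return loaders[kind](path)
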