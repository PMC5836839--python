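"""Synthetic hairpin cohorts with designed structural statistics.

Every analysis stage in this package is verified against generated data in
which the ground truth is known by construction: hairpins whose duplex
overhangs are planted exactly, SNP tables placed at designed per-region
rates, and branchpoint tables drawn from designed offset distributions.
The generator emits the same plain-text dialects the ingest module reads,
so the full pipeline round-trips without any external database.

Construction of one hairpin: an unpaired 5' tail, a stem of Watson-Crick
pairs optionally interrupted by internal loops, a terminal loop, the
mirrored 3' strand, and an unpaired 3' tail.  Matures are placed so that
the basal/apical overhang formulas return exactly the designed values:
positive overhangs extend the strand beyond the duplex closing pair into
the adjacent tail or loop, negative ones pull the partner strand's start
across it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import (
    FIVE_PRIME,
    THREE_PRIME,
    BranchpointRecord,
    HairpinRecord,
    MatureAnnotation,
    SnpRecord,
    species_of,
    write_hairpins,
)
from .snp import (
    DEFAULT_FLANK_WIDTH,
    FLANK_REGIONS,
    HAIRPIN_REGIONS,
    REGION_FLANK_DOWN,
    REGION_FLANK_UP,
    RegionPartition,
    partition_regions,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_BASES = np.array(list("ACGU"))


class UnrealizableSpec(ValueError):
    """Raised when a hairpin spec cannot satisfy its own overhang design."""


# ---------------------------------------------------------------------------
# single hairpin
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinSpec:
    """Design of one synthetic hairpin.

    ``internal_loops`` lists ``(stem_index, size_5p, size_3p)`` loops placed
    between stem pair ``stem_index`` and ``stem_index + 1`` (1-based from
    the hairpin base).  Overhangs are signed: positive = 3' overhang.
    """

    stem_len: int = 22
    loop_len: int = 8
    internal_loops: tuple[tuple[int, int, int], ...] = ()
    basal_overhang: int = 2
    apical_overhang: int = 2
    tail5: int = 6
    tail3: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.stem_len < 2:
            raise UnrealizableSpec("stem_len must be >= 2")
        if self.loop_len < 3:
            raise UnrealizableSpec("loop_len must be >= 3")
        if self.tail5 < max(0, -self.basal_overhang):
            raise UnrealizableSpec(
                f"5' tail of {self.tail5} nt cannot host basal overhang "
                f"{self.basal_overhang}"
            )
        if self.tail3 < max(0, self.basal_overhang):
            raise UnrealizableSpec(
                f"3' tail of {self.tail3} nt cannot host basal overhang "
                f"{self.basal_overhang}"
            )
        if abs(self.apical_overhang) >= self.loop_len:
            raise UnrealizableSpec(
                f"apical overhang {self.apical_overhang} exceeds loop clearance "
                f"{self.loop_len}"
            )
        for k, s5, s3 in self.internal_loops:
            if not 1 <= k < self.stem_len:
                raise UnrealizableSpec(f"internal loop index {k} outside stem")
            if s5 < 0 or s3 < 0 or (s5 == 0 and s3 == 0):
                raise UnrealizableSpec("internal loop sizes must be >= 0, not both 0")


def generate_hairpin(
    spec: HairpinSpec,
    hairpin_id: str = "syn-hairpin-1",
    rng: np.random.Generator | None = None,
) -> HairpinRecord:
    """Build one hairpin realizing the spec's overhangs exactly.

    Deterministic under a fixed ``spec.seed`` (an explicit ``rng`` overrides
    it, for cohort substreams).  Stems use Watson-Crick pairs; loops and
    tails are uniform random bases.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    il = {k: (s5, s3) for k, s5, s3 in spec.internal_loops}

    # lay out positions; stems recorded as (five_pos, stem_index)
    five_pair_pos: dict[int, int] = {}
    three_pair_pos: dict[int, int] = {}
    pos = 0
    unpaired: list[int] = []

    pos += spec.tail5
    unpaired.extend(range(1, spec.tail5 + 1))
    for k in range(1, spec.stem_len + 1):
        pos += 1
        five_pair_pos[k] = pos
        if k in il:
            s5 = il[k][0]
            unpaired.extend(range(pos + 1, pos + s5 + 1))
            pos += s5
    unpaired.extend(range(pos + 1, pos + spec.loop_len + 1))
    pos += spec.loop_len
    for k in range(spec.stem_len, 0, -1):
        pos += 1
        three_pair_pos[k] = pos
        if k - 1 in il:
            s3 = il[k - 1][1]
            unpaired.extend(range(pos + 1, pos + s3 + 1))
            pos += s3
    unpaired.extend(range(pos + 1, pos + spec.tail3 + 1))
    pos += spec.tail3
    n = pos

    pairing = [0] * n
    for k in range(1, spec.stem_len + 1):
        i, j = five_pair_pos[k], three_pair_pos[k]
        pairing[i - 1] = j
        pairing[j - 1] = i

    # sequence: WC-complementary stems, uniform loops/tails
    seq = [""] * n
    for k in range(1, spec.stem_len + 1):
        base = str(rng.choice(_BASES))
        seq[five_pair_pos[k] - 1] = base
        seq[three_pair_pos[k] - 1] = _COMPLEMENT[base]
    for i in unpaired:
        seq[i - 1] = str(rng.choice(_BASES))

    # matures realizing the designed overhangs
    a0 = five_pair_pos[1]
    b0 = three_pair_pos[1]
    c0 = five_pair_pos[spec.stem_len]
    d0 = three_pair_pos[spec.stem_len]
    o_b, o_a = spec.basal_overhang, spec.apical_overhang
    s5 = a0 + min(0, o_b)
    e3 = b0 + max(0, o_b)
    e5 = c0 + max(0, o_a)
    s3 = d0 + min(0, o_a)
    if not (1 <= s5 <= e5 < s3 <= e3 <= n):
        raise UnrealizableSpec(
            f"mature layout infeasible: [{s5},{e5}] / [{s3},{e3}] in [1,{n}]"
        )
    matures = (
        MatureAnnotation(FIVE_PRIME, s5, e5),
        MatureAnnotation(THREE_PRIME, s3, e3),
    )
    return HairpinRecord(
        id=hairpin_id,
        species=species_of(hairpin_id),
        sequence="".join(seq),
        pairing=tuple(pairing),
        matures=matures,
    )


# ---------------------------------------------------------------------------
# overhang joint distributions
# ---------------------------------------------------------------------------

def independent_joint(
    p_short: float = 0.2, p_long: float = 0.1
) -> dict[tuple[int, int], float]:
    """Product joint over lengths {1,2,3} with shared marginal
    (p_short, 1 - p_short - p_long, p_long)."""
    q = {1: p_short, 2: 1 - p_short - p_long, 3: p_long}
    if min(q.values()) < 0:
        raise ValueError("p_short + p_long must not exceed 1")
    return {(b, a): q[b] * q[a] for b in (1, 2, 3) for a in (1, 2, 3)}


def coherent_mixture(
    p_short: float = 0.2,
    p_long: float = 0.1,
    coherent_fraction: float = 0.2,
) -> dict[tuple[int, int], float]:
    """Mixture: (1 - f) independent product + f perfectly coherent diagonal.

    The coherent component draws one length from the shared marginal and
    uses it at both sites, emulating coupled Drosha/Dicer imprecision.
    """
    q = {1: p_short, 2: 1 - p_short - p_long, 3: p_long}
    f = coherent_fraction
    joint = {}
    for b in (1, 2, 3):
        for a in (1, 2, 3):
            joint[(b, a)] = (1 - f) * q[b] * q[a] + (f * q[b] if a == b else 0.0)
    return joint


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: study-like species composition: human+mouse are a minority of animal
#: hairpins, as in miRBase release-scale data
DEFAULT_SPECIES_PROBS = {
    "hsa": 0.10, "mmu": 0.08, "dme": 0.28, "cel": 0.28, "gga": 0.26,
}

#: per-region SNP placement rates, SNPs per kb, following the conserved-to-
#: variable hierarchy seed < mature < pre-miRNA < flanks
DEFAULT_SNP_RATES = {
    "seed": 5.0,
    "mature_excl_seed": 8.0,
    "premirna_excl_mature": 12.0,
    "flank": 20.0,
}


def mirtron_offset_distribution() -> dict[int, float]:
    """Mirtron branchpoint offsets: concentrated at 18-24 nt upstream of the
    3' splice site, with the remainder spread over the expected 10-40 window."""
    dist = {o: 0.3 / 31 for o in range(10, 41)}
    for o in range(18, 25):
        dist[o] += 0.7 / 7
    return dist


def intron_offset_distribution() -> dict[int, float]:
    """Plain-intron offsets: mostly inside 10-40 but with a broader tail."""
    dist = {o: 0.2 / 71 for o in range(0, 71)}
    for o in range(10, 41):
        dist[o] += 0.8 / 31
    return dist


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    ``overhang_joint`` maps (basal, apical) length pairs to probabilities
    (see :func:`independent_joint` / :func:`coherent_mixture`).
    ``mirtron_fraction`` applies to human/mouse records only, mirroring the
    mirtron catalog's species coverage.
    """

    n: int
    overhang_joint: Mapping[tuple[int, int], float] = field(
        default_factory=independent_joint
    )
    snp_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SNP_RATES)
    )
    disease_fraction: float = 0.3
    mirtron_fraction: float = 0.16
    robust_fraction: float = 0.5
    species_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_PROBS)
    )
    bp_offset_distribution: Mapping[int, float] = field(
        default_factory=mirtron_offset_distribution
    )
    stem_len: int = 22
    loop_len: int = 8
    internal_loop_prob: float = 0.3
    seed: int = 0


def _sample_discrete(
    rng: np.random.Generator, dist: Mapping, size: int
) -> list:
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def generate_hairpin_set(
    cohort: CohortSpec,
) -> tuple[list[HairpinRecord], pd.DataFrame]:
    """Generate a cohort of hairpins plus the designed-truth table.

    One global seed sequence per cohort; each record gets its own spawned
    substream, so cohorts are reproducible and records independent.  The
    truth table carries the designed overhang pair and the tag assignments
    for recovery tests.
    """
    if cohort.n == 0:
        return [], pd.DataFrame(
            columns=["id", "species", "basal", "apical", "mirtron", "disease", "robust"]
        )
    root = np.random.SeedSequence(cohort.seed)
    master = np.random.default_rng(root.spawn(1)[0])
    substreams = root.spawn(cohort.n + 1)[1:]

    pairs = _sample_discrete(master, dict(cohort.overhang_joint), cohort.n)
    species = _sample_discrete(master, dict(cohort.species_probs), cohort.n)
    mirtron_draw = master.random(cohort.n)
    disease_draw = master.random(cohort.n)
    robust_draw = master.random(cohort.n)

    records: list[HairpinRecord] = []
    rows = []
    for i in range(cohort.n):
        o_b, o_a = pairs[i]
        rng = np.random.default_rng(substreams[i])
        internal_loops: tuple[tuple[int, int, int], ...] = ()
        if rng.random() < cohort.internal_loop_prob:
            k = int(rng.integers(cohort.stem_len // 3, 2 * cohort.stem_len // 3))
            size = int(rng.integers(1, 4))
            internal_loops = ((k, size, size),)
        spec = HairpinSpec(
            stem_len=cohort.stem_len,
            loop_len=cohort.loop_len,
            internal_loops=internal_loops,
            basal_overhang=int(o_b),
            apical_overhang=int(o_a),
        )
        hid = f"{species[i]}-sim-{i:05d}"
        rec = generate_hairpin(spec, hairpin_id=hid, rng=rng)
        is_hs_mm = species[i] in ("hsa", "mmu")
        tags = []
        mirtron = bool(is_hs_mm and mirtron_draw[i] < cohort.mirtron_fraction)
        disease = bool(disease_draw[i] < cohort.disease_fraction)
        robust = bool(robust_draw[i] < cohort.robust_fraction)
        if mirtron:
            tags.append("mirtron")
        elif is_hs_mm:
            tags.append("non-mirtron")
        if disease:
            tags.append("disease")
        if robust:
            tags.append("robust")
        records.append(rec.with_tags(*tags))
        rows.append(
            {"id": hid, "species": species[i], "basal": int(o_b), "apical": int(o_a),
             "mirtron": mirtron, "disease": disease, "robust": robust}
        )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SNPs and branchpoints
# ---------------------------------------------------------------------------

def _rate_for(snp_rates: Mapping[str, float], label: str) -> float:
    if label in snp_rates:
        return float(snp_rates[label])
    if label in FLANK_REGIONS and "flank" in snp_rates:
        return float(snp_rates["flank"])
    return 0.0


def generate_snps(
    records: Iterable[HairpinRecord],
    snp_rates: Mapping[str, float] | None = None,
    seed: int = 0,
    flank_width: int = DEFAULT_FLANK_WIDTH,
    common_fraction: float = 0.5,
) -> list[SnpRecord]:
    """Place SNPs position-by-position at designed per-region rates.

    Each position of each region is hit independently with probability
    ``rate/1000`` (rates are per kb), so recovered densities are binomial
    around the design.  Flags are common/rare with ``common_fraction``;
    minor allele frequencies are drawn consistently with the flag
    (common = MAF > 0.01).
    """
    if snp_rates is None:
        snp_rates = DEFAULT_SNP_RATES
    rng = np.random.default_rng(seed)
    snps: list[SnpRecord] = []
    for rec in records:
        if not rec.matures:
            continue
        part = partition_regions(rec, flank_width)
        for label in HAIRPIN_REGIONS + FLANK_REGIONS:
            rate = _rate_for(snp_rates, label)
            if rate <= 0:
                continue
            p = rate / 1000.0
            for s, e in part.regions[label]:
                hits = np.nonzero(rng.random(e - s + 1) < p)[0]
                for off in hits:
                    if rng.random() < common_fraction:
                        flag, maf = "common", float(rng.uniform(0.011, 0.5))
                    else:
                        flag, maf = "rare", float(rng.uniform(1e-4, 0.01))
                    snps.append(SnpRecord(rec.id, s + int(off), flag, round(maf, 5)))
    return snps


def generate_branchpoints(
    mirtron_hairpins: Iterable[HairpinRecord],
    offset_distribution: Mapping[int, float] | None = None,
    seed: int = 0,
) -> list[BranchpointRecord]:
    """Sample one branchpoint per mirtron hairpin.

    Offsets are drawn from ``offset_distribution`` (counted upstream from
    the 3' splice site, offset 0 = last intron nucleotide) and mapped to
    hairpin coordinates by 3'-coterminality.  Offsets that would fall
    before the hairpin start are skipped with a warning.
    """
    if offset_distribution is None:
        offset_distribution = mirtron_offset_distribution()
    if any(o < 0 for o in offset_distribution):
        raise ValueError("offsets must be nonnegative")
    rng = np.random.default_rng(seed)
    hairpins = list(mirtron_hairpins)
    offsets = _sample_discrete(rng, dict(offset_distribution), len(hairpins))
    out: list[BranchpointRecord] = []
    for rec, off in zip(hairpins, offsets):
        bp_pos = rec.length - int(off)
        if bp_pos < 1:
            logger.warning("%s: offset %d exceeds hairpin length; skipped", rec.id, off)
            continue
        out.append(
            BranchpointRecord(
                intron_id=f"{rec.id}-intron",
                offset_3ss=int(off),
                hairpin_id=rec.id,
                bp_position=bp_pos,
            )
        )
    return out


def generate_intron_branchpoints(
    n: int,
    offset_distribution: Mapping[int, float] | None = None,
    seed: int = 0,
    prefix: str = "intron",
) -> list[BranchpointRecord]:
    """Plain (non-mirtron) intron branchpoints: offsets only, no hairpin link."""
    if offset_distribution is None:
        offset_distribution = intron_offset_distribution()
    rng = np.random.default_rng(seed)
    offsets = _sample_discrete(rng, dict(offset_distribution), n)
    return [
        BranchpointRecord(intron_id=f"{prefix}-{i:05d}", offset_3ss=int(off))
        for i, off in enumerate(offsets)
    ]


def synthetic_substitution_rates(
    n_positions: int = 22, seed: int = 0
) -> dict[int, float]:
    """Relative per-position substitution rates with the two-group step.

    Paired, conserved mature positions (seed 2-8 and the additional binding
    site 13-16) get low rates; the variable single-stranded positions (the
    ends and the center) get high rates, with within-group jitter and no
    within-group trend.
    """
    rng = np.random.default_rng(seed)
    low_positions = set(range(2, 9)) | set(range(13, 17))
    rates = {}
    for p in range(1, n_positions + 1):
        if p in low_positions:
            rates[p] = round(float(rng.uniform(0.7, 1.0)), 4)
        else:
            rates[p] = round(float(rng.uniform(1.5, 2.1)), 4)
    return rates


# ---------------------------------------------------------------------------
# emitting a full cohort to disk
# ---------------------------------------------------------------------------

def emit_cohort(cohort: CohortSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic study to ``out_dir`` in ingest's dialects.

    Produces FASTA + structure TSV + mature TSV, SNP TSV, branchpoint TSV
    (mirtron-linked plus plain-intron rows), substitution-rate TSV, mirtron
    / disease / robust id lists, and a truth JSON with the design.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = generate_hairpin_set(cohort)
    paths = {
        "fasta": out / "hairpins.fa",
        "structures": out / "structures.tsv",
        "matures": out / "matures.tsv",
        "snps": out / "snps.tsv",
        "branchpoints": out / "branchpoints.tsv",
        "rates": out / "substitution_rates.tsv",
        "mirtron_ids": out / "mirtron_ids.txt",
        "disease_ids": out / "disease_ids.txt",
        "robust_ids": out / "robust_ids.txt",
        "truth": out / "truth.json",
    }
    write_hairpins(records, paths["fasta"], paths["structures"], paths["matures"])

    snps = generate_snps(records, cohort.snp_rates, seed=cohort.seed + 1)
    pd.DataFrame(
        [(s.hairpin_id, s.position, s.maf, s.flag) for s in snps],
        columns=["hairpin_id", "position", "maf", "flag"],
    ).to_csv(paths["snps"], sep="\t", index=False)

    mirtrons = [r for r in records if "mirtron" in r.tags]
    bps = generate_branchpoints(mirtrons, cohort.bp_offset_distribution,
                                seed=cohort.seed + 2)
    bps += generate_intron_branchpoints(max(len(mirtrons) * 4, 50),
                                        seed=cohort.seed + 3)
    pd.DataFrame(
        [(b.intron_id, b.offset_3ss, b.hairpin_id or "", b.bp_position or "")
         for b in bps],
        columns=["intron_id", "bp_offset_from_3ss", "hairpin_id", "bp_hairpin_position"],
    ).to_csv(paths["branchpoints"], sep="\t", index=False)

    rates = synthetic_substitution_rates(seed=cohort.seed + 4)
    pd.DataFrame(sorted(rates.items()), columns=["position", "rate"]).to_csv(
        paths["rates"], sep="\t", index=False
    )

    for key, column in (("mirtron_ids", "mirtron"), ("disease_ids", "disease"),
                        ("robust_ids", "robust")):
        ids = truth.loc[truth[column], "id"] if len(truth) else []
        paths[key].write_text("".join(f"{i}\n" for i in ids))

    design = {
        "n": cohort.n,
        "seed": cohort.seed,
        "overhang_joint": {f"{b},{a}": p for (b, a), p in cohort.overhang_joint.items()},
        "snp_rates": dict(cohort.snp_rates),
        "disease_fraction": cohort.disease_fraction,
        "mirtron_fraction": cohort.mirtron_fraction,
        "truth": truth.to_dict(orient="records"),
    }
    paths["truth"].write_text(json.dumps(design, indent=1))
    return paths


# ---------------------------------------------------------------------------
# random nested structures (for oracle tests)
# ---------------------------------------------------------------------------

def random_dot_bracket(
    rng: np.random.Generator,
    n: int,
    p_open: float = 0.4,
    min_loop: int = 3,
) -> str:
    """A random valid nested dot-bracket string of length ``n``.

    Grown left to right: open a pair when room remains, close the innermost
    open pair once the minimum hairpin loop size is respected, otherwise
    emit a dot.  Unclosable opens are converted to dots at the end.
    """
    chars: list[str] = []
    stack: list[int] = []
    for pos in range(1, n + 1):
        remaining = n - pos
        can_open = remaining >= min_loop + 1 + len(stack)
        can_close = bool(stack) and (pos - stack[-1] - 1) >= min_loop
        r = rng.random()
        if can_open and r < p_open:
            stack.append(pos)
            chars.append("(")
        elif can_close and r < p_open + 0.35:
            stack.pop()
            chars.append(")")
        else:
            chars.append(".")
    for pos in stack:
        chars[pos - 1] = "."
    return "".join(chars)
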