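# Methods

This note documents the models, conventions and design choices behind
`mirfoot`, and what its synthetic-data verification does and does not
establish about real data.

## Data model

A hairpin is a sequence over {A,C,G,U} with a base-pairing table that must
be a nested involution (no pseudoknots) of the same length, plus up to two
mature annotations. All coordinates are 1-based, inclusive and
hairpin-relative; converters to other conventions belong at file
boundaries. `T` and lowercase input are normalized to uppercase RNA.
Records with non-canonical nucleotides or more than two annotated matures
are excluded at load time with a recorded reason, as are records with a
missing or length-mismatched structure. When two matures exist the
left-hand one is the 5′ arm; a single mature is assigned 5′ or 3′ by which
side of the hairpin midpoint its own midpoint falls on.

Input structures are accepted as per-record `id<TAB>dot-bracket` lines or
Vienna `>id` blocks rather than drawn ASCII structure diagrams; dot-bracket
is the interoperable standard and any nested structure is accepted.
Structures with several stems are not repaired: the duplex search is
restricted to base pairs joining the two mature intervals, which also
selects the relevant terminal loop.

## Duplex geometry and overhangs

The basal closing pair is `(a, π(a))` with `a` the smallest 5′-mature
position paired into the 3′ mature; the apical pair uses the largest such
position. Overhangs are counted as excess nucleotides beyond the closing
pair regardless of their own pairing state:

    basal  = (e3 − b) − (a − s5)
    apical = (e5 − c) − (d − s3)

Positive values are 3′ overhangs, so a canonical duplex scores (+2, +2)
and atypical 5′ overhangs are negative. The `hanging_end` variant replaces
the closing-pair positions with the outermost/innermost mature positions
paired to *anything*, so only genuinely single-stranded ends count; the
two variants coincide whenever the terminal mature nucleotides are paired
to the partner mature, and the variant label is carried in all output.
Overhang magnitudes above 15 nt are flagged as suspect structures
(typically mispredicted terminal loops) but still reported; statistics can
include or exclude them explicitly.

## Overhang coherence and the independence null

Coherence between the two processing sites is measured two ways. First, a
Spearman rank correlation (midrank ties) over observed (basal, apical)
pairs; the p-value is asymptotic by default, or by permutation of the
pairing with ≥10,000 shuffles — for n ≤ 6 the permutation test enumerates
all n! orderings and is exact. Second, restricted to near-canonical
lengths {1, 2, 3} nt ≡ {short, canonical, long}, the null model of
independent overhangs with a *shared* marginal:

    P(i, j) = q_i q_j,   q = (p_short, 1 − p_short − p_long, p_long)

Under this model the log-likelihood collapses to a multinomial over
row+column margins, so the maximum-likelihood estimate is the closed form
`q_i = (row_i + col_i) / 2n`; a numerical least-squares fit on frequencies
and a 4-parameter per-site variant are provided behind flags because the
choice between them is genuinely open — maximum likelihood is the default
and both can be reported. Goodness of fit is the likelihood-ratio
statistic against the saturated multinomial (df = 8 − #parameters).
Coherent processing appears as obs/exp > 1 in the short/short and
long/long diagonal cells; note that obs/exp is computed against the
*refitted* marginals, which absorb part of any planted enrichment (a
2×-enriched cell reads below 2 under the fit).

## End-to-loop distances

For a mature end whose terminal nucleotide `t` is paired, the scan runs
along the backbone in both directions: the nearest unpaired position `u`
outside the mature gives `d_out = |u − t| − 1`, the nearest unpaired
position inside the mature gives `d_in = −|u − t|`; the smaller magnitude
wins and ties return the outside value (the loop-counting rule concerns
loops upstream of the cleavage site; tie events are recorded per end).
Ends with an unpaired terminal nucleotide, and ends with no single-stranded
neighbour within the hairpin, are reported as undefined with a reason. The
scan never crosses to the partner arm in practice because an unpaired
nucleotide (the terminal loop at the latest) is always reached first.

## UNF profiles

The unpaired-nucleotide frequency at aligned mature position `p` is the
fraction of contributing hairpins whose nucleotide at that position is
single-stranded. Positions count from the mature 5′ end; negative
positions are the upstream flank and there is no position 0. A record
enters a position's denominator only if the mapped hairpin coordinate
exists and, inside the mature, only up to its own mature length — so long
matures do not inherit denominators from short ones and flank positions
beyond the hairpin are dropped. The default flank width for profiles is
10 nt. Functional position groups used in summaries: seed 2–8, additional
binding site 13–16, transition 9 and 17–19. The rank correlation between a
UNF profile and a per-position substitution-rate table runs over their
shared positions (at least 3 required).

## SNP densities

Each hairpin partitions into disjoint regions: seed (mature positions 2–8,
both arms, clipped to short matures), mature-excluding-seed,
pre-miRNA-excluding-matures, and upstream/downstream flanks of
configurable width (default 200 nt, a width consistent with how flanking
regions are conventionally taken). Flank coordinates extend the hairpin
axis (≤ 0 upstream, > length downstream). Density is `N_snp × 1000 / L`
per kb with counts and lengths pooled over the dataset per region class,
which makes it additive under any split of a region. Rare/common
stratification (common = minor allele frequency > 0.01) is a filter over
one pipeline, not a separate pipeline; flank densities are reported per
flank and pooled, since either convention is defensible. SNP occurrence
per sequence is the mean count of within-hairpin SNPs per pre-miRNA in the
four disease × mirtron groups, zeros included; empty groups are reported
as undefined rather than failing.

## Branchpoints

Offsets are counted upstream from the 3′ splice site with offset 0 the
intron's last nucleotide; the expected window is the closed interval
[10, 40] nt. Mapping a branchpoint into its mirtron hairpin assumes
3′-coterminality (`position = length − offset`) unless an explicit hairpin
position is supplied — 3′-tailed mirtrons must supply one. Compartments
are decided against the terminal loop `[ls, le]`: before it, inside it, or
in the 3′ strand; `d_loop = position − le` (adjacent nucleotide = 1,
defined only in the 3′ strand), `d_dicer = s3 − position` with `s3` the 5′
end of the 3′ miRNA (negative inside the miRNA), `d_3end = length −
position`. The same conventions apply to mirtron-linked and plain-intron
records, so comparisons between them are convention-free, and every report
echoes the convention block.

## Synthetic cohorts

One generated hairpin is an unpaired 5′ tail, a Watson–Crick stem
(default 22 bp; G·U pairs off for the simplest structures satisfying the
invariants) optionally interrupted by internal loops, a terminal loop
(default 8 nt), the mirrored 3′ strand and a 3′ tail. Matures are placed
so the overhang formulas return the designed values exactly: positive
overhangs extend into the adjacent tail or loop, negative ones pull the
mature start across the closing pair. A spec whose overhangs cannot be
realized (tail or loop clearance too small) is rejected rather than
silently adjusted.

Cohort defaults emulate study-scale composition: human+mouse are a
minority of species (~18%), the mirtron fraction among them is 0.16
(mirroring a mirtron catalog of ~464 against ~2,438 non-mirtrons), the
shared overhang marginal is (0.2, 0.7, 0.1) — canonical overhangs 3.5×
and 7× more frequent than short and long ones, matching the observed
depletion ordering — and ~30% of hairpins carry one central internal loop.
Planted SNP rates default to 5 / 8 / 12 / 20 per kb for seed / mature /
pre-miRNA / flanks, following the conserved-to-variable hierarchy at
realistic human SNP-density scale. Mirtron branchpoint offsets concentrate
at 18–24 nt with the remainder over the 10–40 window; plain-intron offsets
are broader (80% in-window). Randomness uses one seed sequence per cohort
with deterministically spawned per-record substreams, so cohorts are
reproducible and artifacts byte-stable. The generator emits exactly the
file dialects the ingest module reads, plus a truth JSON.

What passing on synthetic data shows — and does not. Recovery tests prove
the estimators invert the generator: overhang formulas return planted
values on clean stems, densities converge to planted rates binomially,
offsets and loop distances come back exactly. They do not validate
behaviour on thermodynamically realistic folds, multi-stem or mispredicted
structures beyond the suspect-flag pathway, or the real positional UNF
profile (generated internal loops sit mid-stem at random, so cohort UNF
profiles lack the real seed/center/end shape; the UNF–substitution
correlation is therefore demonstrated on rate tables constructed to follow
structure). Sequence content is uniform apart from stem complementarity,
so base-composition analyses on synthetic data test bookkeeping, not
biology.

## Numerical and scale choices

Verification cohorts use 1,000 hairpins for exact-recovery checks, 10,000
pairs for distributional recovery (marginal estimates resolve to ±0.01,
the smallest near-canonical cell expects ~100 counts), and 10,000
permutations for permutation p-values; these sizes give each check clear
resolution while keeping the whole suite fast on a single CPU. Degenerate
inputs fail loudly and specifically: constant vectors in the rank
correlation, empty count tables, hairpins with no base pairs, specs whose
overhangs are unrealizable. Boundary fits (a marginal at 0 or 1) are
flagged rather than rejected. Known limitations: multiloop structures are
resolved by mature proximity rather than repaired; the hanging-end
overhang variant is one defensible reading of "hanging end" and is always
labelled in output; and branchpoint distance conventions (inclusive
counting, adjacent = 1) are fixed choices documented here and in every
report header rather than derivable facts.
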