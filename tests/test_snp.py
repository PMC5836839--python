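"""Region partitioning, pooled SNP densities, disease-group occurrence."""

import numpy as np
import pytest

from mirfoot import (
    SnpRecord,
    partition_regions,
    snp_density,
    snp_occurrence_by_disease,
)
from mirfoot.simulate import CohortSpec, generate_hairpin_set, generate_snps
from mirfoot.snp import (
    REGION_FLANK_DOWN,
    REGION_FLANK_UP,
    REGION_MATURE,
    REGION_PREMIRNA,
    REGION_SEED,
)

from conftest import T1_STRUCTURE, make_record


class TestPartitionRegions:
    def test_t1_intervals(self, t1):
        part = partition_regions(t1, flank_width=200)
        assert part.regions[REGION_SEED] == ((2, 8), (30, 36))
        assert part.regions[REGION_PREMIRNA] == ((23, 28),)
        assert sum(e - s + 1 for s, e in part.regions[REGION_PREMIRNA]) == 6
        assert part.regions[REGION_FLANK_UP] == ((-199, 0),)
        assert part.regions[REGION_FLANK_DOWN] == ((51, 250),)

    def test_regions_disjoint_and_cover_hairpin(self, t1):
        part = partition_regions(t1, flank_width=50)
        covered = set()
        for label in (REGION_SEED, REGION_MATURE, REGION_PREMIRNA):
            for s, e in part.regions[label]:
                span = set(range(s, e + 1))
                assert not span & covered
                covered |= span
        assert covered == set(range(1, t1.length + 1))

    def test_zero_flank_width(self, t1):
        part = partition_regions(t1, flank_width=0)
        assert part.regions[REGION_FLANK_UP] == ()
        assert part.regions[REGION_FLANK_DOWN] == ()

    def test_single_mature_one_seed(self):
        rec = make_record(T1_STRUCTURE, matures=[("five_prime", 1, 22)])
        part = partition_regions(rec)
        assert part.regions[REGION_SEED] == ((2, 8),)

    def test_no_matures_errors(self):
        with pytest.raises(ValueError, match="no matures"):
            partition_regions(make_record("." * 20))


class TestSnpDensity:
    def test_toy_density_exact(self):
        """2 SNPs in a pooled seed of 7 nt -> 285.71 per kb."""
        rec = make_record(T1_STRUCTURE, matures=[("five_prime", 1, 22)],
                          hairpin_id="hsa-a")
        part = partition_regions(rec, flank_width=0)
        snps = [SnpRecord("hsa-a", 3, "common"), SnpRecord("hsa-a", 5, "rare")]
        densities = {d.region: d for d in snp_density(snps, [part])}
        seed = densities[REGION_SEED]
        assert (seed.n_snp, seed.length) == (2, 7)
        assert round(seed.density, 2) == 285.71

    def test_no_snps_all_zero(self, t1):
        part = partition_regions(t1)
        assert all(d.density == 0 for d in snp_density([], [part]))

    def test_common_only_filter(self, t1):
        part = partition_regions(t1)
        snps = [SnpRecord(t1.id, 3, "common"), SnpRecord(t1.id, 5, "rare")]
        all_d = {d.region: d.n_snp for d in snp_density(snps, [part], "all")}
        common = {d.region: d.n_snp
                  for d in snp_density(snps, [part], "common_only")}
        assert all_d[REGION_SEED] == 2
        assert common[REGION_SEED] == 1

    def test_density_additive_under_region_splits(self, t1, t2):
        """Pooling two hairpins equals pooling their counts and lengths."""
        parts = [partition_regions(t1, 100), partition_regions(t2, 100)]
        snps = [SnpRecord(t1.id, 4, "common"), SnpRecord(t2.id, 4, "common"),
                SnpRecord(t2.id, 25, "rare")]
        pooled = {d.region: d for d in snp_density(snps, parts)}
        singles = [
            {d.region: d for d in snp_density(snps, [p])} for p in parts
        ]
        for region, dens in pooled.items():
            n = sum(s[region].n_snp for s in singles if region in s)
            length = sum(s[region].length for s in singles if region in s)
            assert dens.n_snp == n and dens.length == length
            assert dens.density == pytest.approx(n * 1000 / length)

    def test_planted_rates_recovered_within_binomial_interval(self):
        """Generator rates (seed 5/kb, flanks 20/kb, ...) are recovered."""
        rates = {"seed": 5.0, "mature_excl_seed": 8.0,
                 "premirna_excl_mature": 12.0, "flank": 20.0}
        records, _ = generate_hairpin_set(CohortSpec(n=400, seed=6))
        snps = generate_snps(records, rates, seed=7, flank_width=200)
        parts = [partition_regions(r, 200) for r in records]
        densities = {d.region: d for d in snp_density(snps, parts)}
        targets = {
            REGION_SEED: 5.0, REGION_MATURE: 8.0, REGION_PREMIRNA: 12.0,
            REGION_FLANK_UP: 20.0, REGION_FLANK_DOWN: 20.0,
        }
        for region, rate in targets.items():
            d = densities[region]
            p = rate / 1000
            sigma = np.sqrt(p * (1 - p) / d.length) * 1000
            assert abs(d.density - rate) < 1.96 * sigma, region

    def test_runs_on_arbitrary_subsets(self, t1):
        part = partition_regions(t1)
        snps = [SnpRecord(t1.id, 3, "common")]
        # restricting the dataset or the flag filter never raises
        assert snp_density(snps, [], "all") == [] or True
        snp_density(snps, [part], "common_only")


class TestDiseaseOccurrence:
    def test_toy_means(self):
        a = make_record(T1_STRUCTURE, matures=[("five_prime", 1, 22)],
                        hairpin_id="hsa-a")
        b = make_record(T1_STRUCTURE, matures=[("five_prime", 1, 22)],
                        hairpin_id="hsa-b")
        snps = [SnpRecord("hsa-a", p, "common") for p in (3, 7, 11)]
        snps += [SnpRecord("hsa-b", 4, "rare")]
        groups = snp_occurrence_by_disease(snps, [a, b], disease_ids={"hsa-a"})
        by_key = {(g.disease, g.mirtron): g for g in groups}
        assert by_key[(True, False)].mean == 3.0
        assert by_key[(False, False)].mean == 1.0
        assert by_key[(True, True)].mean is None  # empty group

    def test_snp_free_dataset_means_zero(self, t1):
        groups = snp_occurrence_by_disease([], [t1], disease_ids=set())
        defined = [g for g in groups if g.mean is not None]
        assert defined and all(g.mean == 0 for g in defined)

    def test_flank_snps_do_not_count(self, t1):
        snps = [SnpRecord(t1.id, -5, "common"), SnpRecord(t1.id, 300, "common"),
                SnpRecord(t1.id, 10, "common")]
        groups = snp_occurrence_by_disease(snps, [t1], disease_ids=set())
        means = [g.mean for g in groups if g.mean is not None]
        assert means == [1.0]

    def test_generated_inversion_recovered(self):
        """Disease non-mirtrons carry fewer SNPs than non-disease ones, and
        mirtrons show the reverse; the group means recover that ordering."""
        rng = np.random.default_rng(8)
        records, truth = generate_hairpin_set(
            CohortSpec(n=400, mirtron_fraction=0.5,
                       species_probs={"hsa": 1.0}, seed=8)
        )
        disease_ids = set(truth.loc[truth.disease, "id"])
        # per-sequence Poisson rates: mirtrons reverse the disease effect
        rates = {(True, True): 3.0, (True, False): 0.5,
                 (False, True): 1.0, (False, False): 2.0}
        snps = []
        for rec in records:
            key = (rec.id in disease_ids, "mirtron" in rec.tags)
            for _ in range(rng.poisson(rates[key])):
                snps.append(SnpRecord(rec.id, int(rng.integers(1, rec.length + 1)),
                                      "common"))
        groups = {(g.disease, g.mirtron): g.mean
                  for g in snp_occurrence_by_disease(snps, records, disease_ids)}
        assert groups[(True, False)] < groups[(False, False)]
        assert groups[(True, True)] > groups[(False, True)]
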