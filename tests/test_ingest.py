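"""Parsing, loading, exclusion rules and dataset partitioning."""

import numpy as np
import pytest
from _oracles import match_brackets_by_elimination

from mirfoot import (
    HairpinRecord,
    StructureError,
    load_aux_tables,
    load_hairpins,
    parse_dot_bracket,
    partition_datasets,
    write_hairpins,
)
from mirfoot.ingest import pairing_to_dot_bracket
from mirfoot.simulate import random_dot_bracket

from conftest import make_record


class TestParseDotBracket:
    @pytest.mark.parametrize(
        "db,expected",
        [
            ("(((...)))", (9, 8, 7, 0, 0, 0, 3, 2, 1)),
            (".........", (0,) * 9),
            ("", ()),
        ],
    )
    def test_examples(self, db, expected):
        assert parse_dot_bracket(db) == expected

    @pytest.mark.parametrize("db", ["((.)", "(..", ".)", "(x)"])
    def test_malformed_raises_with_position(self, db):
        with pytest.raises(StructureError) as exc:
            parse_dot_bracket(db)
        assert "position" in str(exc.value)

    def test_agrees_with_elimination_oracle_on_random_structures(self, rng):
        """Stack parser matches an innermost-pair-elimination matcher."""
        for _ in range(1000):
            n = int(rng.integers(10, 80))
            db = random_dot_bracket(rng, n)
            pairing = parse_dot_bracket(db)
            oracle = match_brackets_by_elimination(db)
            for i, j in enumerate(pairing, start=1):
                assert oracle.get(i, 0) == j

    def test_round_trip_through_dot_bracket(self, rng):
        for _ in range(50):
            db = random_dot_bracket(rng, 60)
            assert pairing_to_dot_bracket(parse_dot_bracket(db)) == db


class TestRecordInvariants:
    def test_pseudoknot_rejected(self):
        # pairs (1,3) and (2,4) cross
        with pytest.raises(StructureError):
            HairpinRecord("x", "x", "ACGU", (3, 4, 1, 2))

    def test_non_involution_rejected(self):
        with pytest.raises(StructureError):
            HairpinRecord("x", "x", "ACGU", (3, 0, 2, 0))

    def test_overlapping_matures_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_record(
                "." * 30,
                matures=[("five_prime", 1, 15), ("three_prime", 10, 25)],
            )


def _write_fixture(tmp_path, entries, mature_rows):
    fasta = tmp_path / "h.fa"
    struct = tmp_path / "s.tsv"
    mat = tmp_path / "m.tsv"
    with open(fasta, "w") as fh:
        for hid, seq, _ in entries:
            fh.write(f">{hid}\n{seq}\n")
    with open(struct, "w") as fh:
        for hid, _, db in entries:
            if db is not None:
                fh.write(f"{hid}\t{db}\n")
    with open(mat, "w") as fh:
        fh.write("hairpin_id\tmature_id\tstart\tend\n")
        for hid, mid, s, e in mature_rows:
            fh.write(f"{hid}\t{mid}\t{s}\t{e}\n")
    return fasta, struct, mat


class TestLoadHairpins:
    def test_exclusion_rules(self, tmp_path):
        """Non-canonical nucleotides and >2 matures are study exclusions."""
        entries = [
            ("hsa-a", "ACGUACGUAC", ".........."),
            ("hsa-b", "ACGNACGUAC", ".........."),
            ("hsa-c", "ACGUACGUAC", ".........."),
        ]
        matures = [("hsa-c", f"m{i}", i + 1, i + 2) for i in (0, 3, 6)]
        result = load_hairpins(*_write_fixture(tmp_path, entries, matures))
        assert [r.id for r in result.records] == ["hsa-a"]
        assert ("hsa-b", "non-canonical nucleotide") in result.excluded
        assert ("hsa-c", "more than two matures") in result.excluded

    def test_missing_and_mismatched_structure_rejected(self, tmp_path):
        entries = [
            ("hsa-a", "ACGUACGUAC", "((......))"),
            ("hsa-b", "ACGUACGUAC", "((....))"),  # too short
            ("hsa-c", "ACGUACGUAC", None),
        ]
        result = load_hairpins(*_write_fixture(tmp_path, entries, []))
        reasons = dict(result.excluded)
        assert result.ids() == {"hsa-a"}
        assert reasons["hsa-b"] == "structure length mismatch"
        assert reasons["hsa-c"] == "missing structure"

    def test_t_and_case_normalized(self, tmp_path):
        entries = [("hsa-a", "acgtACGT", "." * 8)]
        result = load_hairpins(*_write_fixture(tmp_path, entries, []))
        assert result.records[0].sequence == "ACGUACGU"

    def test_round_trip(self, tmp_path, t1, t2):
        """Write then reload yields identical records."""
        paths = (tmp_path / "o.fa", tmp_path / "o.tsv", tmp_path / "om.tsv")
        write_hairpins([t1, t2], *paths)
        reloaded = load_hairpins(*paths)
        assert not reloaded.excluded
        for orig, back in zip([t1, t2], reloaded.records):
            assert back.id == orig.id
            assert back.sequence == orig.sequence
            assert back.pairing == orig.pairing
            assert back.matures == orig.matures

    def test_vienna_structure_dialect(self, tmp_path):
        fasta = tmp_path / "h.fa"
        fasta.write_text(">hsa-a\nACGUACGUA\n")
        struct = tmp_path / "s.txt"
        struct.write_text(">hsa-a\nACGUACGUA\n(((...)))\n")
        result = load_hairpins(fasta, struct)
        assert result.records[0].dot_bracket() == "(((...)))"


class TestPartition:
    def _toys(self):
        ids = ["hsa-x", "hsa-y", "mmu-z", "dme-a", "dme-b"]
        return [make_record("." * 10, hairpin_id=i) for i in ids]

    def test_example_sizes(self):
        part = partition_datasets(self._toys(), {"hsa-x"})
        assert part.sizes() == (5, 2, 2, 1)

    def test_empty_mirtron_list(self):
        part = partition_datasets(self._toys(), set())
        assert part.hs_mm_mirtrons == []

    def test_disjoint_cover_of_hs_mm(self):
        part = partition_datasets(self._toys(), {"hsa-x", "mmu-z", "dme-a"})
        hs_mm = {r.id for r in part.hs_mm_mirtrons} | {
            r.id for r in part.hs_mm_non_mirtrons
        }
        assert hs_mm == {"hsa-x", "hsa-y", "mmu-z"}
        assert not (
            {r.id for r in part.hs_mm_mirtrons}
            & {r.id for r in part.hs_mm_non_mirtrons}
        )
        # dme-a is not human/mouse: it stays in the animal sets only
        assert "dme-a" not in hs_mm

    def test_orphan_mirtron_ids_recorded(self):
        part = partition_datasets(self._toys(), {"hsa-x", "hsa-missing"})
        assert part.orphan_mirtron_ids == ["hsa-missing"]

    def test_robust_restriction_shrinks_every_subset(self):
        toys = self._toys()
        full = partition_datasets(toys, {"hsa-x"})
        robust = [t for t in toys if t.id in {"hsa-x", "dme-a"}]
        small = partition_datasets(robust, {"hsa-x"})
        assert all(a <= b for a, b in zip(small.sizes(), full.sizes()))


class TestAuxTables:
    def test_snp_fixture_with_malformed_row(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text(
            "hairpin_id\tposition\tmaf\tflag\n"
            "hsa-a\t5\t0.2\tcommon\n"
            "hsa-a\tnotanumber\t0.2\tcommon\n"
            "hsa-b\t-3\t0.005\trare\n"
            "hsa-b\t12\t0.3\tcommon\n"
        )
        snps = load_aux_tables("snp", path)
        assert len(snps) == 3
        assert {s.flag for s in snps} == {"common", "rare"}

    def test_snp_flag_derived_from_maf(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text(
            "hairpin_id\tposition\tmaf\n" "hsa-a\t5\t0.2\n" "hsa-a\t6\t0.002\n"
        )
        snps = load_aux_tables("snp", path)
        assert [s.flag for s in snps] == ["common", "rare"]

    def test_rates_table_size(self, tmp_path):
        path = tmp_path / "rates.tsv"
        path.write_text(
            "position\trate\n"
            + "".join(f"{p}\t{p * 0.1:.1f}\n" for p in range(1, 26))
        )
        rates = load_aux_tables("rates", path)
        assert len(rates) == 25
        assert rates[10] == pytest.approx(1.0)

    def test_idlist_deduplicated(self, tmp_path):
        path = tmp_path / "ids.txt"
        path.write_text("hsa-a\nhsa-b\nhsa-a\n\n# comment\n")
        assert load_aux_tables("idlist", path) == {"hsa-a", "hsa-b"}

    def test_unknown_kind_is_usage_error(self, tmp_path):
        with pytest.raises(ValueError, match="unknown aux table kind"):
            load_aux_tables("nonsense", tmp_path / "x")
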