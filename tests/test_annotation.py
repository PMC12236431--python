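"""Hit-table parsing, tiered e-value filtering, and presence-matrix building."""

import pytest
from hypothesis import given, settings, strategies as st

from b1profiler.errors import ConfigurationError, ConsistencyError, ParseError
from b1profiler.hits import (
    GeneHit, build_presence_matrix, filter_hits, parse_hit_table,
)
from b1profiler.synthetic import generate_genome_set, write_domtbl


def _hit(protein, family, evalue, bit=100.0, genome=None):
    return GeneHit(
        protein_id=protein,
        genome_id=genome or protein.rsplit("_", 1)[0],
        family_id=family,
        full_seq_evalue=evalue,
        bit_score=bit,
    )


class TestParsing:
    def test_comment_only_file_yields_nothing(self, tmp_path):
        p = tmp_path / "empty.domtbl"
        p.write_text("# a comment\n# another\n\n")
        assert parse_hit_table(p, format="domtbl") == []

    def test_domtbl_roundtrip_against_fixture_writer(self, tmp_path):
        gs = generate_genome_set({"AOA_prototroph": 2, "SAR11_HMP_aux": 2}, seed=11)
        path = tmp_path / "hits.domtbl"
        write_domtbl(gs.hits, path)
        parsed = parse_hit_table(path, format="domtbl")
        assert len(parsed) == len(gs.hits)
        for orig, back in zip(gs.hits, parsed):
            assert back.protein_id == orig.protein_id
            assert back.genome_id == orig.genome_id
            assert back.family_id == orig.family_id
            assert back.full_seq_evalue == pytest.approx(orig.full_seq_evalue, rel=0.05)
            assert back.bit_score == pytest.approx(orig.bit_score, abs=0.05)
            assert back.alignment_coords == orig.alignment_coords

    def test_malformed_evalue_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "P_001\tG1\tTIGR00190\t1e-20\t85.2\t10-200\n"
            "P_002\tG1\tTIGR00190\tnot_a_number\t85.2\t10-200\n"
        )
        with pytest.raises(ParseError, match=":2"):
            parse_hit_table(p, format="tsv")

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("only\tthree\tcolumns\n")
        with pytest.raises(ParseError, match="6 tab-separated"):
            parse_hit_table(p, format="tsv")

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("")
        with pytest.raises(ConfigurationError):
            parse_hit_table(p, format="csv")

    def test_tsv_row_values(self, tmp_path):
        p = tmp_path / "ok.tsv"
        p.write_text("G1_00001\tG1\tTIGR00190\t1e-20\t85.2\t10-200\n")
        (hit,) = parse_hit_table(p, format="tsv")
        assert hit.full_seq_evalue == 1e-20
        assert hit.bit_score == 85.2
        assert hit.alignment_coords == (10, 200)


class TestFiltering:
    def test_strict_tier_removes_mid_evalue_b1_hit(self, catalog):
        # thiC is a verified-tier family: 1e-12 passes the general tier but
        # not the strict one, so the hit must be removed.
        out = filter_hits([_hit("G1_1", "TIGR00190", 1e-12)], catalog)
        assert out == []

    def test_general_tier_retains_non_strict_hit(self, catalog):
        # aprA (K00394) sits in the general tier: 1e-11 survives.
        out = filter_hits([_hit("G1_1", "K00394", 1e-11)], catalog)
        assert len(out) == 1

    @pytest.mark.parametrize("family,evalue,kept", [
        ("TIGR00190", 1e-15, True),   # strict boundary inclusive
        ("TIGR00190", 1.01e-15, False),
        ("K00394", 1e-10, True),      # general boundary inclusive
        ("K00394", 1.01e-10, False),
    ])
    def test_inclusive_boundaries(self, catalog, family, evalue, kept):
        out = filter_hits([_hit("G1_1", family, evalue)], catalog)
        assert (len(out) == 1) is kept

    def test_unknown_family_dropped(self, catalog):
        assert filter_hits([_hit("G1_1", "PF99999", 1e-40)], catalog) == []

    def test_best_hit_per_protein(self, catalog):
        hits = [
            _hit("G1_1", "TIGR00190", 1e-30, bit=200.0),
            _hit("G1_1", "TIGR00097", 1e-40, bit=150.0),  # lower score loses
        ]
        out = filter_hits(hits, catalog)
        assert [h.family_id for h in out] == ["TIGR00190"]

    def test_best_hit_ties_break_by_evalue_then_family(self, catalog):
        by_evalue = filter_hits([
            _hit("G1_1", "TIGR00190", 1e-30, bit=200.0),
            _hit("G1_1", "TIGR00097", 1e-40, bit=200.0),
        ], catalog)
        assert by_evalue[0].family_id == "TIGR00097"
        by_family = filter_hits([
            _hit("G1_1", "TIGR00190", 1e-30, bit=200.0),
            _hit("G1_1", "PF01964", 1e-30, bit=200.0),
        ], catalog)
        assert by_family[0].family_id == "PF01964"

    def test_threshold_validation(self, catalog):
        with pytest.raises(ConfigurationError):
            filter_hits([], catalog, general_threshold=1e-15, strict_threshold=1e-10)
        with pytest.raises(ConfigurationError):
            filter_hits([], catalog, general_threshold=0.0, strict_threshold=0.0)

    def test_filtering_idempotent(self, catalog):
        gs = generate_genome_set({"SUP05_prototroph": 3}, seed=2, decoy_rate=1.0)
        once = filter_hits(gs.hits, catalog)
        assert filter_hits(once, catalog) == once

    @given(strict_exp=st.floats(min_value=15.0, max_value=40.0))
    @settings(max_examples=25, deadline=None)
    def test_lower_strict_threshold_never_adds_hits(self, strict_exp):
        from b1profiler.catalog import default_catalog
        cat = default_catalog()
        gs = generate_genome_set({"Nitrospina_prototroph": 3}, seed=9, decoy_rate=0.5)
        base = len(filter_hits(gs.hits, cat))
        tighter = len(filter_hits(gs.hits, cat, strict_threshold=10.0 ** -strict_exp))
        assert tighter <= base


class TestPresenceMatrix:
    def test_no_hits_all_zero_rows(self, catalog):
        m = build_presence_matrix([], catalog, ["A", "B", "C"])
        assert m.shape[0] == 3
        assert (m.to_numpy() == 0).all()

    def test_multi_copy_gene_counted(self, catalog):
        hits = [
            _hit("G1_1", "TIGR00693", 1e-30),  # thiE
            _hit("G1_2", "TIGR00693", 1e-28),
        ]
        m = build_presence_matrix(hits, catalog, ["G1"])
        assert m.loc["G1", "thiE"] == 2

    def test_unknown_genome_is_consistency_error(self, catalog):
        with pytest.raises(ConsistencyError, match="G9"):
            build_presence_matrix([_hit("G9_1", "TIGR00190", 1e-30)], catalog, ["G1"])

    def test_complete_genomes_recover_planted_genotypes_exactly(self, catalog):
        gs = generate_genome_set(
            {"SUP05_prototroph": 2, "Flavobacteria_salvage": 2}, seed=4)
        kept = filter_hits(gs.hits, catalog)
        m = build_presence_matrix(kept, catalog, [x.genome_id for x in gs.meta])
        from b1profiler.synthetic import ARCHETYPES
        for row in gs.truth.itertuples(index=False):
            planted = ARCHETYPES[row.archetype].genes
            observed = m.loc[row.genome_id]
            assert {s: c for s, c in observed.items() if c > 0} == dict(planted)

    def test_decoys_above_thresholds_do_not_change_matrix(self, catalog):
        clean = generate_genome_set({"SAR202_HMP_aux": 4}, seed=21, decoy_rate=0.0)
        noisy = generate_genome_set({"SAR202_HMP_aux": 4}, seed=21, decoy_rate=0.5)
        genomes = [x.genome_id for x in clean.meta]
        m_clean = build_presence_matrix(filter_hits(clean.hits, catalog), catalog, genomes)
        m_noisy = build_presence_matrix(filter_hits(noisy.hits, catalog), catalog, genomes)
        assert m_clean.equals(m_noisy)
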