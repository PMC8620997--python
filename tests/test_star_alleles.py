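"""Star-allele definition loading, haplotype matching and activity scoring."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from cypmeta.star_alleles import (
    AlleleDefinitionTable,
    DefinitionError,
    StarAlleleDefinition,
    VariantSite,
    activity_score,
    haplotype_from_alleles,
    load_allele_definitions,
    match_haplotype,
)


class TestDefinitionLoading:
    def test_minimal_legal_table(self, tmp_path):
        tsv = tmp_path / "mini.tsv"
        tsv.write_text(
            "gene\tallele\trsid\tchrom\tpos\tref\talt\tfunction\tactivity_value\n"
            "CYP2D6\t*1\t\t\t\t\t\tnormal\t1\n"
            "CYP2D6\t*4\trs3892097\t22\t42524947\tC\tT\tnone\t0\n"
        )
        table = load_allele_definitions(tsv)
        assert len(table.alleles) == 2
        assert table.allele("*4").function_class == "none"

    def test_duplicate_allele_rejected(self, tmp_path):
        tsv = tmp_path / "dup.tsv"
        tsv.write_text(
            "gene\tallele\trsid\tchrom\tpos\tref\talt\tfunction\tactivity_value\n"
            "CYP2D6\t*1\t\t\t\t\t\tnormal\t1\n"
            "CYP2D6\t*4\trs3892097\t22\t42524947\tC\tT\tnone\t0\n"
            "CYP2D6\t*6\trs5030655\t22\t42525085\tTA\tT\tnone\t0\n"
            "CYP2D6\t*4\trs1065852\t22\t42526694\tG\tA\tnone\t0\n"
        )
        # interleaved duplicate: *4 appears, then *6, then *4 again
        with pytest.raises(DefinitionError, match="duplicate"):
            load_allele_definitions(tsv)

    def test_missing_wildtype_rejected(self):
        with pytest.raises(DefinitionError, match=r"\*1"):
            AlleleDefinitionTable(
                gene="CYP2D6",
                alleles=[
                    StarAlleleDefinition(
                        "*4", "CYP2D6",
                        (VariantSite("rs3892097", "22", 42524947, "C", "T"),),
                        "none", 0.0,
                    )
                ],
            )

    def test_variant_outside_region_rejected(self):
        with pytest.raises(DefinitionError, match="outside"):
            AlleleDefinitionTable(
                gene="CYP2D6",
                alleles=[
                    StarAlleleDefinition("*1", "CYP2D6", (), "normal", 1.0),
                    StarAlleleDefinition(
                        "*4", "CYP2D6",
                        (VariantSite("rs0", "22", 99_000_000, "C", "T"),),
                        "none", 0.0,
                    ),
                ],
                region=("22", 41_522_500, 43_526_883),
            )

    def test_bundled_cyp2c19_function_classes(self, cyp2c19_table):
        # the canonical loss-of-function and gain-of-function assignments
        assert cyp2c19_table.allele("*2").function_class == "none"
        assert cyp2c19_table.allele("*3").function_class == "none"
        assert cyp2c19_table.allele("*17").function_class == "increased"

    def test_activity_function_consistency_enforced(self):
        with pytest.raises(DefinitionError, match="inconsistent"):
            StarAlleleDefinition(
                "*4", "CYP2D6",
                (VariantSite("rs3892097", "22", 42524947, "C", "T"),),
                "none", 1.0,
            )


class TestHaplotypeMatching:
    def test_reference_haplotype_defaults_to_wildtype(self, cyp2d6_table):
        hap = haplotype_from_alleles([], cyp2d6_table)
        call = match_haplotype(hap, cyp2d6_table)
        assert call.allele_name == "*1"
        assert call.is_default_wildtype
        assert call.matched_variants == 0

    def test_single_variant_allele_matched(self, cyp2c19_table):
        hap = haplotype_from_alleles(["*2"], cyp2c19_table)
        assert match_haplotype(hap, cyp2c19_table).allele_name == "*2"

    def test_superset_allele_beats_subset(self, cyp2d6_table):
        # *4 (two defining variants) contains *10's single variant
        hap = haplotype_from_alleles(["*4"], cyp2d6_table)
        call = match_haplotype(hap, cyp2d6_table)
        assert call.allele_name == "*4"
        assert call.matched_variants == 2

    def test_maximal_match_against_brute_force(self, toy_table):
        """Oracle: enumerate every haplotype over the toy sites and pick the
        fully-contained allele with the most defining variants by hand."""
        sites = [v.id for v in toy_table.variant_sites]
        defs = {
            a.name: {v.id for v in a.defining_variants}
            for a in toy_table.alleles
            if a.defining_variants
        }
        for bits in itertools.product([0, 1], repeat=len(sites)):
            hap = dict(zip(sites, bits))
            present = {s for s, b in hap.items() if b}
            full = {n: vs for n, vs in defs.items() if vs <= present}
            if full:
                best_size = max(len(vs) for vs in full.values())
                expected = {n for n, vs in full.items() if len(vs) == best_size}
            else:
                expected = {"*1"}
            assert match_haplotype(hap, toy_table).allele_name in expected

    def test_missing_site_counts_as_reference(self, cyp2d6_table):
        hap = haplotype_from_alleles(["*4"], cyp2d6_table)
        hap["rs3892097"] = None  # lose one of *4's two defining variants
        call = match_haplotype(hap, cyp2d6_table)
        assert call.allele_name == "*10"  # the remaining variant still matches *10
        assert call.missing_defining_sites == 1

    @settings(deadline=None, derandomize=True)
    @given(
        bits=st.lists(st.integers(0, 1), min_size=7, max_size=7),
        order=st.permutations(range(8)),
    )
    def test_matching_invariant_to_table_row_order(self, cyp2d6_table, bits, order):
        sites = [v.id for v in cyp2d6_table.variant_sites]
        hap = dict(zip(sites, bits))
        shuffled = AlleleDefinitionTable(
            gene=cyp2d6_table.gene,
            alleles=[cyp2d6_table.alleles[i] for i in order],
            build=cyp2d6_table.build,
        )
        assert match_haplotype(hap, cyp2d6_table) == match_haplotype(hap, shuffled)

    @settings(deadline=None, derandomize=True)
    @given(bits=st.lists(st.integers(0, 1), min_size=7, max_size=7),
           extra=st.integers(0, 6))
    def test_adding_variant_never_decreases_match(self, cyp2d6_table, bits, extra):
        sites = [v.id for v in cyp2d6_table.variant_sites]
        hap = dict(zip(sites, bits))
        before = match_haplotype(hap, cyp2d6_table).matched_variants
        hap[sites[extra]] = 1
        after = match_haplotype(hap, cyp2d6_table).matched_variants
        assert after >= before


class TestActivityScore:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            (("*1", "*1"), 2.0),
            (("*4", "*4"), 0.0),
            (("*1", "*4"), 1.0),
            (("*1", "*41"), 1.5),  # CPIC diplotype-score convention
            (("*4", "*10"), 0.5),
            (("*10", "*41"), 1.0),
        ],
    )
    def test_additivity(self, cyp2d6_table, pair, expected):
        assert activity_score(*pair, cyp2d6_table) == expected

    @settings(deadline=None, derandomize=True)
    @given(st.sampled_from(["*1", "*3", "*4", "*6", "*9", "*10", "*17", "*41"]),
           st.sampled_from(["*1", "*3", "*4", "*6", "*9", "*10", "*17", "*41"]))
    def test_symmetry(self, cyp2d6_table, a, b):
        assert activity_score(a, b, cyp2d6_table) == activity_score(b, a, cyp2d6_table)

    def test_unknown_allele_raises(self, cyp2d6_table):
        with pytest.raises(LookupError):
            activity_score("*1", "*99", cyp2d6_table)

    def test_cyp2c19_not_scorable(self, cyp2c19_table):
        with pytest.raises(ValueError):
            activity_score("*1", "*2", cyp2c19_table)
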