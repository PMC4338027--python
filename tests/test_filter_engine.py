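"""Column filters, compound logic, inheritance filters, stats, paging."""

import itertools

import pytest

from adviser.annotation_engine import annotate
from adviser.filter_engine import (CompoundFilter, FilterError, FilterExpr,
                                   FilterStack, apply_compound, apply_filter,
                                   inheritance_filter, load_trio_genotypes,
                                   paginate, parse_expression, summary_stats,
                                   PRESETS)
from adviser.variant_io import AnnotationRow, read_variants


def row(i, **cols):
    block = ("chrT", str(i), str(i + 1), cols.pop("vtype", "snp"),
             "A", "C", "het", str(i))
    return AnnotationRow(block, cols)


@pytest.fixture(scope="module")
def af_table():
    afs = ["0.001", "0.02", None, "0.005", "0.3"]
    return [row(i, maxAF=af, effect=["missense"] if i % 2 else ["synonymous"])
            for i, af in enumerate(afs)]


@pytest.fixture(scope="module")
def trio_table(trio, reference, sources):
    path, manifest = trio
    records, _, _ = read_variants(path)
    rows = [annotate(r, sources, None, reference.genome, str(i))[0]
            for i, r in enumerate(records, 1)]
    gts = load_trio_genotypes(path, "CHILD", "MOTHER", "FATHER")
    return rows, gts, manifest


class TestApplyFilter:
    def test_numeric_lt_skips_nulls(self, af_table):
        kept = apply_filter(af_table, FilterExpr("maxAF", "lt", 0.01))
        assert [r.variant_block[1] for r in kept] == ["0", "3"]

    def test_contains_any_semantics(self):
        r = row(0, effect=["missense", "synonymous"])
        assert FilterExpr("effect", "contains", "missense").matches(r)
        assert FilterExpr("effect", "eq", "synonymous").matches(r)

    def test_is_null_keeps_dash_cells(self, af_table):
        kept = apply_filter(af_table, FilterExpr("maxAF", "is_null"))
        assert [r.variant_block[1] for r in kept] == ["2"]

    def test_null_fails_numeric_and_eq(self, af_table):
        assert not FilterExpr("maxAF", "eq", "0.001").matches(af_table[2])
        assert not FilterExpr("maxAF", "ge", 0).matches(af_table[2])

    def test_unknown_column_names_available(self, af_table):
        with pytest.raises(FilterError, match="maxAF"):
            apply_filter(af_table, FilterExpr("nope", "eq", 1))

    def test_in_set_and_ne(self, af_table):
        kept = apply_filter(af_table, FilterExpr("maxAF", "in_set",
                                                 ["0.001", "0.3"]))
        assert len(kept) == 2
        kept = apply_filter(af_table, FilterExpr("effect", "ne", "missense"))
        assert all(r.columns["effect"] == ["synonymous"] for r in kept)

    def test_variant_block_columns_filterable(self, af_table):
        kept = apply_filter(af_table, FilterExpr("begin", "ge", 3))
        assert len(kept) == 2

    def test_filters_only_remove_rows(self, af_table):
        kept = apply_filter(af_table, FilterExpr("maxAF", "lt", 1))
        assert all(any(r is s for s in af_table) for r in kept)


class TestCompound:
    def test_and_is_intersection(self, af_table):
        f1 = FilterExpr("maxAF", "lt", 0.01)
        f2 = FilterExpr("effect", "eq", "missense")
        both = apply_compound(af_table, CompoundFilter("and", (f1, f2)))
        a, b = apply_filter(af_table, f1), apply_filter(af_table, f2)
        assert {id(r) for r in both} == {id(r) for r in a} & {id(r) for r in b}

    def test_or_is_union(self, af_table):
        f1 = FilterExpr("maxAF", "eq", "0.001")
        f2 = FilterExpr("maxAF", "eq", "0.3")
        union = apply_compound(af_table, CompoundFilter("or", (f1, f2)))
        assert len(union) == 2

    def test_inclusion_exclusion_identity(self, trio_table):
        rows, _, _ = trio_table
        f1 = FilterExpr("maxAF", "lt", 0.01)
        f2 = FilterExpr("effect", "contains", "missense")
        A = apply_filter(rows, f1)
        B = apply_filter(rows, f2)
        AB = apply_compound(rows, CompoundFilter("and", (f1, f2)))
        AoB = apply_compound(rows, CompoundFilter("or", (f1, f2)))
        assert len(AB) + len(AoB) == len(A) + len(B)

    def test_nested_tree_equals_truth_table(self, trio_table):
        rows, _, _ = trio_table
        a = FilterExpr("region", "eq", "coding")
        b = FilterExpr("maxAF", "is_null")
        c = FilterExpr("effect", "contains", "intronic")
        tree = CompoundFilter("and", (a, CompoundFilter("or", (b, c))))
        got = apply_compound(rows, tree)
        expected = [r for r in rows
                    if a.matches(r) and (b.matches(r) or c.matches(r))]
        assert [id(r) for r in got] == [id(r) for r in expected]

    def test_expression_parser(self, trio_table):
        rows, _, _ = trio_table
        tree = parse_expression("maxAF<0.01 && effect~=missense")
        direct = CompoundFilter("and", (FilterExpr("maxAF", "lt", "0.01"),
                                        FilterExpr("effect", "contains",
                                                   "missense")))
        assert [id(r) for r in apply_compound(rows, tree)] == \
            [id(r) for r in apply_compound(rows, direct)]

    def test_presets_parse_and_apply(self, trio_table):
        rows, _, _ = trio_table
        for name, expr in PRESETS.items():
            apply_compound(rows, parse_expression(expr))


class TestInheritance:
    @pytest.mark.parametrize("mode", ["de_novo", "recessive_hom",
                                      "compound_het"])
    def test_exact_planted_recovery(self, trio_table, mode):
        rows, gts, manifest = trio_table
        got, skipped = inheritance_filter(rows, gts, mode)
        assert skipped == 0
        assert {r.key for r in got} == set(manifest[mode])

    def test_de_novo_definition(self):
        r = row(0, gene=["G1"])
        trio = {"child": {r.key: "0/1"}, "mother": {r.key: "0/0"},
                "father": {r.key: "0/0"}}
        got, _ = inheritance_filter([r], trio, "de_novo")
        assert got == [r]

    def test_recessive_hom_definition(self):
        r = row(0, gene=["G1"])
        trio = {"child": {r.key: "1/1"}, "mother": {r.key: "0/1"},
                "father": {r.key: "0/1"}}
        got, _ = inheritance_filter([r], trio, "recessive_hom")
        assert got == [r]

    def test_compound_het_requires_both_parental_origins(self):
        r1, r2, r3, r4 = (row(i, gene=["GX"] if i < 2 else ["GY"])
                          for i in range(4))
        trio = {
            "child": {r.key: "0/1" for r in (r1, r2, r3, r4)},
            # GX: one variant from each parent; GY: both from the mother
            "mother": {r1.key: "0/1", r2.key: "0/0",
                       r3.key: "0/1", r4.key: "0/1"},
            "father": {r1.key: "0/0", r2.key: "0/1",
                       r3.key: "0/0", r4.key: "0/0"},
        }
        got, _ = inheritance_filter([r1, r2, r3, r4], trio, "compound_het")
        assert got == [r1, r2]

    def test_dominant_with_affected_parent(self):
        r = row(0)
        trio = {"child": {r.key: "0/1"}, "mother": {r.key: "0/1"},
                "father": {r.key: "0/0"}}
        got, _ = inheritance_filter([r], trio, "dominant",
                                    affected_parent="mother")
        assert got == [r]
        got, _ = inheritance_filter([r], trio, "dominant",
                                    affected_parent="father")
        assert got == []

    def test_missing_genotype_site_excluded_and_counted(self):
        r1, r2 = row(0), row(1)
        trio = {"child": {r1.key: "0/1", r2.key: "./."},
                "mother": {r1.key: "0/0", r2.key: "0/0"},
                "father": {r1.key: "0/0", r2.key: "0/0"}}
        got, skipped = inheritance_filter([r1, r2], trio, "de_novo")
        assert got == [r1] and skipped == 1

    def test_missing_sample_is_configuration_error(self):
        with pytest.raises(FilterError):
            inheritance_filter([], {"child": {}, "mother": {}}, "de_novo")

    def test_unknown_trio_sample_name(self, trio):
        path, _ = trio
        with pytest.raises(FilterError):
            load_trio_genotypes(path, "CHILD", "MOTHER", "AUNT")


class TestStackStatsPaging:
    def test_undo_redo_restores_exact_rows(self, af_table):
        fs = FilterStack(af_table)
        f1 = FilterExpr("maxAF", "lt", 0.1)
        f2 = FilterExpr("effect", "eq", "missense")
        after1 = list(fs.apply(f1))
        fs.apply(f2)
        assert [id(r) for r in fs.undo()] == [id(r) for r in after1]
        assert [id(r) for r in fs.redo()] == \
            [id(r) for r in af_table if f1.matches(r) and f2.matches(r)]

    def test_new_apply_truncates_redo_tail(self, af_table):
        fs = FilterStack(af_table)
        fs.apply(FilterExpr("maxAF", "lt", 0.1))
        fs.undo()
        fs.apply(FilterExpr("effect", "eq", "missense"))
        redone = fs.redo()     # nothing to redo: unchanged
        assert [id(r) for r in redone] == [id(r) for r in fs.current()]
        assert all(r.columns["effect"] == ["missense"] for r in redone)

    def test_stack_equals_replay_from_scratch(self, trio_table):
        rows, _, _ = trio_table
        filters = [FilterExpr("maxAF", "is_null"),
                   FilterExpr("region", "ne", "coding"),
                   FilterExpr("varType", "eq", "snp")]
        fs = FilterStack(rows)
        for f in filters:
            fs.apply(f)
        fs.undo()
        fs.undo()
        fs.redo()
        replay = rows
        for f in filters[:2]:
            replay = apply_filter(replay, f)
        assert [id(r) for r in fs.current()] == [id(r) for r in replay]

    def test_summary_counts(self):
        rows = [row(i, effect=["missense"] if i < 3 else ["synonymous"],
                    adviserClinical="3")
                for i in range(10)]
        st = summary_stats(rows)
        assert st["effect"]["missense"] == {"count": 3, "rate": 0.3}
        assert st["adviser_class"]["3"]["count"] == 10
        assert sum(v["count"] for v in st["effect"].values()) == 10

    def test_most_severe_effect_counts_once(self):
        rows = [row(0, effect=["synonymous", "nonsense"])]
        st = summary_stats(rows)
        assert st["effect"] == {"nonsense": {"count": 1, "rate": 1.0}}

    def test_empty_table_stats(self):
        st = summary_stats([])
        assert st["n"] == 0 and st["effect"] == {}

    def test_stats_order_invariant(self, af_table):
        for perm in itertools.permutations(af_table):
            assert summary_stats(list(perm)) == summary_stats(af_table)

    def test_pagination_slices(self):
        rows = [row(i) for i in range(2500)]
        assert len(paginate(rows, 1)) == 1000
        assert len(paginate(rows, 3)) == 500
        assert paginate(rows, 4) == []
        assert paginate([], 1) == []

    def test_page_size_override(self):
        rows = [row(i) for i in range(25)]
        assert [r.variant_block[1] for r in paginate(rows, 2, 10)] == \
            [str(i) for i in range(10, 20)]
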