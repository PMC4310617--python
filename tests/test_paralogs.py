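import numpy as np
import pandas as pd
import pytest

from promarch.expression import BreadthClass
from promarch.paralogs import (
    EventClass,
    TaxonGroupAssignment,
    age_group_summary,
    build_divergence_records,
    classify_event,
    divergence_analysis,
    enumerate_all_pairs,
    jaccard_repertoire,
    select_youngest_pairs,
)


class TestJaccard:
    def test_identical_nonempty_sets(self):
        assert jaccard_repertoire({"A", "B"}, {"B", "A"}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard_repertoire({"A"}, {"B"}) == 0.0

    def test_partial_overlap(self):
        assert jaccard_repertoire({"A", "B"}, {"B", "C"}) == pytest.approx(1 / 3)

    def test_both_empty_defined_zero(self):
        assert jaccard_repertoire(set(), set()) == 0.0

    def test_symmetric_and_one_iff_equal(self, rng):
        pool = list("ABCDEFGHIJ")
        for _ in range(50):
            x = set(rng.choice(pool, size=rng.integers(1, 6), replace=False))
            y = set(rng.choice(pool, size=rng.integers(1, 6), replace=False))
            assert jaccard_repertoire(x, y) == jaccard_repertoire(y, x)
            assert (jaccard_repertoire(x, y) == 1.0) == (x == y)

    def test_multiplicity_ignored(self):
        assert jaccard_repertoire(["A", "A", "B"], ["A", "B", "B"]) == 1.0


class TestPairEnumeration:
    @pytest.mark.parametrize("n,expected", [(2, 1), (5, 10), (10, 45)])
    def test_binomial_counts(self, n, expected):
        assert len(enumerate_all_pairs([f"g{i}" for i in range(n)])) == expected

    def test_below_two_members(self):
        assert enumerate_all_pairs(["only"]) == []

    def test_count_formula_against_brute_force(self):
        for n in range(2, 60):
            members = [f"g{i}" for i in range(n)]
            pairs = enumerate_all_pairs(members)
            assert len(pairs) == n * (n - 1) // 2
            assert len(set(map(frozenset, pairs))) == len(pairs)  # all distinct


def _pair_frame(rows):
    return pd.DataFrame(
        rows, columns=["family", "node", "taxon", "gene.x", "gene.y", "familySide.x", "familySide.y"]
    )


class TestYoungestPairs:
    def test_three_gene_family(self):
        # ((A,B)_young, C)_old: the two young daughters contribute exactly
        # their mutual pair; the outgroup keeps one pair through the old node
        pairs = _pair_frame([
            ("f1", "n_young", "Primate", "A", "B", 1, 2),
            ("f1", "n_old", "Vertebrate", "A", "C", 1, 2),
            ("f1", "n_old", "Vertebrate", "B", "C", 1, 2),
        ])
        got = select_youngest_pairs(pairs)
        young = got[(got["gene.x"] == "A") & (got["gene.y"] == "B")]
        assert len(young) == 1
        assert len(got) <= len(pairs)
        # C's youngest pair is through n_old (tie broken deterministically)
        assert ((got["gene.y"] == "C") | (got["gene.x"] == "C")).sum() == 1

    def test_same_side_pairs_dropped(self):
        pairs = _pair_frame([("f1", "n1", "Primate", "A", "B", 1, 1)])
        assert len(select_youngest_pairs(pairs)) == 0

    def test_missing_age_errors(self):
        pairs = _pair_frame([("f1", "n1", "Martian", "A", "B", 1, 2)])
        with pytest.raises(ValueError, match="age"):
            select_youngest_pairs(pairs)

    def test_every_retained_pair_is_a_per_gene_minimum(self, small_world):
        data = small_world["paralogs"]
        assignment = TaxonGroupAssignment()
        got = select_youngest_pairs(data.pairs, assignment)
        assert len(got) <= len(data.pairs)
        valid = data.pairs[data.pairs["familySide.x"] != data.pairs["familySide.y"]]
        ages = valid["taxon"].map(assignment.age_index)
        min_age: dict[str, int] = {}
        for (gx, gy), a in zip(valid[["gene.x", "gene.y"]].itertuples(index=False), ages):
            for g in (gx, gy):
                min_age[g] = min(min_age.get(g, 99), a)
        for row in got.itertuples(index=False):
            a = assignment.age_index(row.taxon)
            gx, gy = getattr(row, "_3"), getattr(row, "_4")
            assert a == min_age[gx] or a == min_age[gy]


class TestEventClassification:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (BreadthClass.HOUSEKEEPING, BreadthClass.HOUSEKEEPING, EventClass.HOUSEKEEPING_CONSERVED),
            (BreadthClass.NARROW, BreadthClass.NARROW, EventClass.TISSUE_SP_CONSERVED),
            (BreadthClass.NARROW, BreadthClass.HOUSEKEEPING, EventClass.TRANSFORMATIVE),
            (BreadthClass.HOUSEKEEPING, BreadthClass.NARROW, EventClass.TRANSFORMATIVE),
            (BreadthClass.INTERMEDIATE, BreadthClass.NARROW, EventClass.OTHER),
            (BreadthClass.UNEXPRESSED, BreadthClass.HOUSEKEEPING, EventClass.OTHER),
        ],
    )
    def test_trichotomy_plus_other(self, x, y, expected):
        assert classify_event(x, y) == expected


@pytest.fixture(scope="module")
def records(small_world):
    data = small_world["paralogs"]
    return build_divergence_records(data.pairs, data.repertoires, data.expression)


class TestDivergenceAnalysis:
    def test_planted_coupling_recovered(self, records):
        res = divergence_analysis(records)
        assert res.r > 0.15 and res.p < 1e-3

    def test_randomized_pairs_destroy_coupling(self, records, rng):
        shuffled = records.copy()
        shuffled["coexpr"] = rng.permutation(shuffled["coexpr"].to_numpy())
        assert abs(divergence_analysis(shuffled).r) < 0.1

    def test_stratified_analysis_runs(self, records):
        res = divergence_analysis(records, breadth_stratum="narrow")
        assert res.n >= 3

    def test_too_small_stratum_rejected(self, records):
        tiny = records.iloc[:2]
        with pytest.raises(ValueError):
            divergence_analysis(tiny)


class TestAgeGroups:
    def test_planted_monotone_group_means(self, small_world):
        data = small_world["paralogs"]
        records = build_divergence_records(data.pairs, data.repertoires, data.expression)
        summary, tests = age_group_summary(records)
        means = summary["mean_boe"].to_numpy()
        # planted: older duplications are broader (allow small local noise on
        # the small fixture by checking the overall trend)
        assert means[-1] > means[0]
        assert np.all(np.diff(summary["mean_tfbs"].to_numpy()) > -1.0)
        assert summary["n"].sum() == len(records)

    def test_holm_adjustment_never_below_raw(self, small_world):
        data = small_world["paralogs"]
        records = build_divergence_records(data.pairs, data.repertoires, data.expression)
        _, tests = age_group_summary(records)
        assert (tests["p_holm"] >= tests["p_raw"] - 1e-15).all()

    def test_group_sizes_sum_to_total(self, small_world):
        data = small_world["paralogs"]
        records = build_divergence_records(data.pairs, data.repertoires, data.expression)
        summary, _ = age_group_summary(records)
        assert int(summary["n"].sum()) == len(records)
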