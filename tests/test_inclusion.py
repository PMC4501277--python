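"""Directional inclusion index and its category/focal summaries."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diseasome import (
    ContractViolationError,
    DiseasePair,
    ElementProfile,
    IcdCode,
    InclusionRecord,
    IntegrityError,
    all_directed_inclusions,
    focal_directionality,
    focal_role_values,
    inclusion_index,
    load_default_chapters,
    project_disease_pairs,
    same_category_summary,
    summarize_distribution,
)

F = Fraction


class TestInclusionIndex:
    def test_directional_hand_example(self):
        X = frozenset({"g1", "g2", "g3"})
        Y = frozenset({"g2", "g3", "g4", "g5"})
        assert inclusion_index(X, Y) == F(2, 3)
        assert inclusion_index(Y, X) == F(1, 2)

    def test_subset_gives_one(self):
        assert inclusion_index(frozenset({"a"}), frozenset({"a", "b"})) == 1

    def test_identity_and_disjoint(self):
        X = frozenset({"a", "b"})
        assert inclusion_index(X, X) == 1
        assert inclusion_index(X, frozenset({"c"})) == 0

    def test_empty_x_rejected(self):
        with pytest.raises(ContractViolationError):
            inclusion_index(frozenset(), frozenset({"a"}))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_independent_set_arithmetic(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        universe = int(rng.integers(2, 500))
        X = frozenset(int(v) for v in rng.integers(0, universe, size=rng.integers(1, 60)))
        Y = frozenset(int(v) for v in rng.integers(0, universe, size=rng.integers(1, 60)))
        tau_xy, tau_yx = inclusion_index(X, Y), inclusion_index(Y, X)
        shared = len(set(X).intersection(Y))  # independent recomputation
        assert tau_xy == F(shared, len(X))
        assert 0 <= tau_xy <= 1 and 0 <= tau_yx <= 1
        assert tau_xy * len(X) == tau_yx * len(Y) == shared


class TestDirectedRecords:
    def _profiles(self):
        return [
            ElementProfile(IcdCode("C34"), frozenset({"g1", "g2", "g3"}), "gene"),
            ElementProfile(IcdCode("J45"), frozenset({"g2", "g3", "g4", "g5"}), "gene"),
            ElementProfile(IcdCode("Q10"), frozenset({"g9"}), "gene"),
        ]

    def test_two_records_per_pair_with_equal_shared(self):
        profiles = self._profiles()
        pairs = project_disease_pairs(profiles)
        records = all_directed_inclusions(profiles, pairs)
        assert len(records) == 2 * len(pairs) == 2
        fwd = next(r for r in records if r.x == "C34")
        rev = next(r for r in records if r.x == "J45")
        assert fwd.shared == rev.shared == 2
        assert fwd.tau == F(2, 3) and rev.tau == F(1, 2)

    def test_matches_brute_force_over_ordered_pairs(self, small_study):
        from diseasome import build_bipartite, disease_profiles, normalize_symbols

        normed, _ = normalize_symbols(small_study.disease_gene, small_study.hgnc)
        profiles = disease_profiles(build_bipartite(normed))
        pairs = project_disease_pairs(profiles)
        records = all_directed_inclusions(profiles, pairs)
        assert len(records) == 2 * len(pairs)
        by = {p.entity: p.elements for p in profiles}
        got = {(r.x, r.y): r.tau for r in records}
        # independent brute force over every ordered pair
        expected = {}
        for x in by:
            for y in by:
                if x != y and by[x] & by[y]:
                    expected[(x, y)] = F(len(by[x] & by[y]), len(by[x]))
        assert got == expected

    def test_missing_profile_is_integrity_error(self):
        profiles = self._profiles()[:1]
        pair = DiseasePair(
            x=IcdCode("C34"), y=IcdCode("J45"), shared=frozenset({"g2"}), mode="gene"
        )
        with pytest.raises(IntegrityError):
            all_directed_inclusions(profiles, [pair])


def _rec(x, y, n_x, n_y, shared):
    return InclusionRecord(
        x=IcdCode(x), y=IcdCode(y), mode="gene", n_x=n_x, n_y=n_y,
        shared=shared, tau=F(shared, n_x),
    )


class TestSummaries:
    def test_linear_interpolation_quartiles(self):
        s = summarize_distribution([0.2, 0.4, 0.6, 0.8, 1.0], "x")
        assert (s.q1, s.median, s.q3) == (0.4, 0.6, 0.8)
        assert (s.min, s.max, s.n) == (0.2, 1.0, 5)

    def test_same_category_filters_cross_chapter_records(self):
        table = load_default_chapters()
        records = [
            _rec("C34", "D10", 2, 2, 1),   # both C00-D49
            _rec("C34", "J45", 2, 2, 2),   # cross-chapter: contributes nowhere
            _rec("J45", "J40", 4, 4, 2),   # both J00-J99
        ]
        summaries = {s.group: s for s in same_category_summary(records, table)}
        assert set(summaries) == {"C00-D49", "J00-J99"}
        assert summaries["C00-D49"].median == 0.5
        assert summaries["J00-J99"].n == 1

    def test_constant_distribution_collapses(self):
        records = [_rec("C34", "D10", 3, 5, 3), _rec("C30", "D11", 2, 9, 2)]
        (s,) = same_category_summary(records, load_default_chapters())
        assert s.min == s.max == 1.0

    def test_group_sizes_sum_to_same_chapter_record_count(self, small_study):
        from diseasome import (
            build_bipartite,
            disease_profiles,
            normalize_symbols,
        )

        normed, _ = normalize_symbols(small_study.disease_gene, small_study.hgnc)
        profiles = disease_profiles(build_bipartite(normed))
        pairs = project_disease_pairs(profiles)
        records = all_directed_inclusions(profiles, pairs)
        table = load_default_chapters()
        summaries = same_category_summary(records, table)
        n_same = sum(1 for r in records if table.id_of(r.x) == table.id_of(r.y))
        assert sum(s.n for s in summaries) == n_same


class TestFocalDirectionality:
    def test_role_assignment_hand_example(self):
        records = [_rec("C34", "J45", 2, 2, 1), _rec("J45", "C34", 2, 2, 2)]
        fd = focal_directionality(records, "C00-D49", load_default_chapters())
        assert fd.as_X.n == 1 and fd.as_X.median == 0.5
        assert fd.as_Y.n == 1 and fd.as_Y.median == 1.0

    def test_untouched_focal_chapter_gives_empty_roles(self):
        records = [_rec("J45", "J40", 2, 2, 1)]
        fd = focal_directionality(records, "C00-D49", load_default_chapters())
        assert fd.as_X is None and fd.as_Y is None

    def test_within_focal_pairs_excluded(self):
        records = [_rec("C34", "D10", 2, 2, 1)]
        fd = focal_directionality(records, "C00-D49", load_default_chapters())
        assert fd.as_X is None and fd.as_Y is None

    def test_partner_split_partitions_the_overall_role(self, small_study):
        from diseasome import build_bipartite, disease_profiles, normalize_symbols

        normed, _ = normalize_symbols(small_study.disease_gene, small_study.hgnc)
        profiles = disease_profiles(build_bipartite(normed))
        records = all_directed_inclusions(profiles, project_disease_pairs(profiles))
        table = load_default_chapters()
        focal = "C00-D49"
        as_x, as_y = focal_role_values(records, focal, table)
        # independent recount straight from the records
        n_as_x = sum(
            1
            for r in records
            if table.id_of(r.x) == focal and table.id_of(r.y) != focal
        )
        n_as_y = sum(
            1
            for r in records
            if table.id_of(r.y) == focal and table.id_of(r.x) != focal
        )
        overall = focal_directionality(records, focal, table)
        split = focal_directionality(records, focal, table, split_by_partner=True)
        if overall.as_X is not None:
            assert sum(s.n for s in split.as_X) == overall.as_X.n == n_as_x
        if overall.as_Y is not None:
            assert sum(s.n for s in split.as_Y) == overall.as_Y.n == n_as_y
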