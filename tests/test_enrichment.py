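"""Contingency construction, two-tailed Fisher test, and prediction ranking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from diseasome import (
    ContractViolationError,
    GeneSymbol,
    IcdCode,
    PathwayId,
    candidate_gene_set,
    contingency_table,
    enrich_predictions,
    fisher_two_tailed,
    write_predictions,
)
from conftest import fisher_enumeration_oracle

P = PathwayId
G = GeneSymbol

NG = frozenset({P("ko1"), P("ko2"), P("ko3")})
ND = frozenset({P("ko2"), P("ko3"), P("ko4"), P("ko5")})


class TestCandidateGenes:
    def test_set_difference(self):
        profiles = {G("G1"): frozenset({P("ko1")}), G("G2"): frozenset({P("ko2")})}
        assert candidate_gene_set(profiles, frozenset({G("G1")})) == {G("G2")}

    def test_all_genes_known_gives_empty_set(self):
        profiles = {G("G1"): frozenset({P("ko1")})}
        assert candidate_gene_set(profiles, frozenset({G("G1"), G("G2")})) == set()

    def test_pathwayless_gene_never_a_candidate(self):
        profiles = {G("G1"): frozenset()}
        assert candidate_gene_set(profiles, frozenset()) == set()


class TestContingencyTable:
    def test_paper_literal_construction(self):
        t = contingency_table(NG, ND, N=10, mode="paper_literal")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 4, 6)

    def test_conventional_construction(self):
        t = contingency_table(NG, ND, N=10, mode="conventional")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 2, 5)

    def test_disjoint_sets(self):
        t = contingency_table(NG, frozenset({P("ko9")}), N=10)
        assert t.a == 0 and t.b == len(NG)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ContractViolationError):
            contingency_table(NG, ND, N=4)

    def test_conventional_tight_universe_boundary(self):
        # N = |union| is the tightest legal universe: d collapses to zero
        t = contingency_table(NG, ND, N=5, mode="conventional")
        assert t.d == 0 and t.c == 2


class TestFisherTwoTailed:
    @pytest.mark.parametrize(
        "table, expected",
        [([[1, 0], [0, 1]], 1.0), ([[2, 0], [3, 0]], 1.0), ([[0, 5], [5, 0]], None)],
    )
    def test_degenerate_and_tied_tables(self, table, expected):
        p = fisher_two_tailed(table)
        oracle = fisher_enumeration_oracle(*[v for row in table for v in row])
        assert p == pytest.approx(oracle, abs=1e-12)
        if expected is not None:
            assert p == pytest.approx(expected)

    def test_spec_style_example_against_enumeration(self):
        assert fisher_two_tailed([[5, 2], [3, 10]]) == pytest.approx(
            fisher_enumeration_oracle(5, 2, 3, 10), abs=1e-9
        )

    def test_transpose_invariance(self):
        for a, b, c, d in [(5, 2, 3, 10), (1, 7, 4, 2), (0, 3, 6, 1)]:
            assert fisher_two_tailed([[a, b], [c, d]]) == pytest.approx(
                fisher_two_tailed([[a, c], [b, d]]), rel=1e-12
            )

    def test_agrees_with_scipy_reference(self):
        rng_tables = [(5, 2, 3, 10), (8, 1, 2, 12), (0, 9, 9, 0), (4, 4, 4, 4),
                      (30, 5, 10, 200), (1, 100, 2, 300)]
        for cells in rng_tables:
            a, b, c, d = cells
            assert fisher_two_tailed([[a, b], [c, d]]) == pytest.approx(
                fisher_exact([[a, b], [c, d]])[1], rel=1e-9, abs=1e-12
            )

    def test_negative_cell_rejected(self):
        with pytest.raises(ContractViolationError):
            fisher_two_tailed([[1, -1], [0, 2]])

    def test_large_margins_stay_finite(self):
        p = fisher_two_tailed([[300, 50], [40, 5000]])
        assert 0.0 <= p <= 1.0 and p == p  # no NaN/inf

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.tuples(*(st.integers(0, 8),) * 4))
    def test_matches_enumeration_on_small_tables(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        assert fisher_two_tailed([[a, b], [c, d]]) == pytest.approx(
            fisher_enumeration_oracle(a, b, c, d), abs=1e-9
        )

    def test_monotone_in_overlap_for_paper_literal_margins(self):
        """With N_g, N_d, N fixed, growing the overlap a tracks the oracle exactly."""
        N, n_g, n_d = 40, 6, 12
        for a in range(0, n_g + 1):
            b = n_g - a
            p = fisher_two_tailed([[a, b], [n_d, N - n_d]])
            assert p == pytest.approx(
                fisher_enumeration_oracle(a, b, n_d, N - n_d), abs=1e-9
            )


def _toy_universe():
    paths = [P(f"ko{i}") for i in range(20)]
    diseases = {
        IcdCode("C34"): frozenset(paths[:10]),
        IcdCode("J45"): frozenset(paths[8:14]),
    }
    candidates = {
        G("HIT1"): frozenset(paths[:8]),       # covers 80% of C34's profile
        G("BG1"): frozenset(paths[12:14]),
        G("BG2"): frozenset(paths[18:20]),     # shares nothing with any disease
    }
    return candidates, diseases


class TestEnrichPredictions:
    def test_only_sharing_pairs_evaluated(self):
        candidates, diseases = _toy_universe()
        res = enrich_predictions(candidates, diseases, alpha=1.0)
        evaluated = {(p.gene, p.code) for p in res.evaluated}
        assert (G("BG2"), IcdCode("C34")) not in evaluated
        assert (G("HIT1"), IcdCode("C34")) in evaluated

    def test_alpha_one_keeps_every_evaluated_pair(self):
        candidates, diseases = _toy_universe()
        res = enrich_predictions(candidates, diseases, alpha=1.0)
        assert len(res.predictions) == res.n_evaluated

    def test_threshold_is_inclusive(self):
        # p-values {0.0005-ish, larger}: only pairs at or below alpha survive
        candidates, diseases = _toy_universe()
        res = enrich_predictions(candidates, diseases, alpha=1.0)
        cutoff = res.evaluated[0].p_value
        res2 = enrich_predictions(candidates, diseases, alpha=cutoff)
        assert all(p.p_value <= cutoff for p in res2.predictions)
        assert {(p.gene, p.code) for p in res2.predictions} == {
            (p.gene, p.code) for p in res.evaluated if p.p_value <= cutoff
        }

    def test_planted_pair_ranks_first_against_recomputed_oracle(self):
        candidates, diseases = _toy_universe()
        res = enrich_predictions(candidates, diseases, alpha=1.0)
        top = res.predictions[0]
        assert (top.gene, top.code) == (G("HIT1"), IcdCode("C34"))
        # recompute every p with the enumeration oracle and re-sort
        universe = frozenset().union(*diseases.values())
        expected = []
        for g, gp in candidates.items():
            gp = gp & universe
            for code, dp in diseases.items():
                a = len(gp & dp)
                if a == 0:
                    continue
                b = len(gp) - a
                oracle_p = fisher_enumeration_oracle(a, b, len(dp), len(universe) - len(dp))
                expected.append((oracle_p, -a, g, code))
        expected.sort()
        got = [(p.p_value, -p.shared_pathways, p.gene, p.code) for p in res.evaluated]
        assert [e[2:] for e in expected] == [g[2:] for g in got]
        for e, g_ in zip(expected, got):
            assert g_[0] == pytest.approx(e[0], abs=1e-9)

    def test_ranks_are_dense_and_deterministic(self, tmp_path):
        candidates, diseases = _toy_universe()
        res = enrich_predictions(candidates, diseases, alpha=1.0)
        assert [p.rank for p in res.predictions] == list(
            range(1, len(res.predictions) + 1)
        )
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_predictions(res, out1)
        write_predictions(enrich_predictions(candidates, diseases, alpha=1.0), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_empty_inputs_give_empty_output(self):
        res = enrich_predictions({}, {}, alpha=0.5)
        assert res.predictions == [] and res.n_evaluated == 0

    def test_universe_all_counts_candidate_only_pathways(self):
        candidates, diseases = _toy_universe()
        res_d = enrich_predictions(candidates, diseases, alpha=1.0)
        res_a = enrich_predictions(candidates, diseases, alpha=1.0, universe="all")
        assert res_d.universe_size == 14  # pathways linked to diseases
        assert res_a.universe_size == 16  # + BG2's two extra pathways

    def test_bh_filter_is_no_looser_than_raw(self):
        candidates, diseases = _toy_universe()
        raw = enrich_predictions(candidates, diseases, alpha=0.05)
        bh = enrich_predictions(candidates, diseases, alpha=0.05, bh=True)
        kept_raw = {(p.gene, p.code) for p in raw.predictions}
        kept_bh = {(p.gene, p.code) for p in bh.predictions}
        assert kept_bh <= kept_raw
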