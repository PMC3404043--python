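"""Enrichment: exact-oracle equivalence, slim collapsing, BH adjustment."""

import math

import numpy as np
import pytest

from stratde import (
    SlimMapping,
    SyntheticSpec,
    Term,
    TermAnnotation,
    adjust_pvalues,
    collapse_to_slim,
    fisher_enrichment,
    simulate_annotation,
    simulate_counts,
)
from stratde.io_formats import ConfigError
from stratde.sim import true_de_genes


def hypergeom_upper_tail(k, N, K, n):
    """Independent exact oracle: P(X >= k) by integer enumeration."""
    lo, hi = k, min(n, K)
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(lo, hi + 1))
    return num / math.comb(N, n)


def annotation_of(genes_by_acc):
    return TermAnnotation({
        acc: Term(acc, acc, "biological_process", frozenset(genes))
        for acc, genes in genes_by_acc.items()
    })


class TestFisherEnrichment:
    def test_worked_margin(self):
        # N=10, K=5, n=4, k=4: p = C(5,4)C(5,0)/C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        term_genes = {f"g{i}" for i in range(5)}
        de = {f"g{i}" for i in range(4)}  # all four annotated
        res = fisher_enrichment(de, universe, annotation_of({"GO:1": term_genes}))
        assert res.loc[0, ["k", "n", "K", "N"]].tolist() == [4, 4, 5, 10]
        assert res.loc[0, "p"] == pytest.approx(5 / 210, abs=1e-15)

    def test_term_equal_to_universe_gives_p_one(self):
        universe = {"a", "b", "c"}
        res = fisher_enrichment({"a"}, universe, annotation_of({"GO:1": universe}))
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_k_zero_gives_p_one(self):
        res = fisher_enrichment(
            {"a"}, {"a", "b", "c", "d"}, annotation_of({"GO:1": {"b", "c"}})
        )
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_exact_oracle_on_margin_sweep(self, rng):
        # random margins up to N=50 against the enumeration oracle
        for _ in range(300):
            N = int(rng.integers(2, 51))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            genes = [f"g{i}" for i in range(N)]
            perm = rng.permutation(N)
            universe = set(genes)
            term = {genes[i] for i in perm[:K]}
            de = set(rng.choice(genes, size=n, replace=False))
            k = len(term & de)
            res = fisher_enrichment(de, universe, annotation_of({"GO:1": term}))
            assert res.loc[0, "p"] == pytest.approx(
                hypergeom_upper_tail(k, N, K, n), abs=1e-12
            )

    def test_monotone_in_k(self):
        # moving one more DE gene into the term can only shrink p
        universe = {f"g{i}" for i in range(30)}
        de = {f"g{i}" for i in range(10)}
        ps = []
        for k in range(0, 9):
            term = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(20, 20 + (8 - k))}
            res = fisher_enrichment(de, universe, annotation_of({"GO:1": term}))
            ps.append(res.loc[0, "p"])
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_de_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="zzz"):
            fisher_enrichment({"zzz"}, {"a"}, annotation_of({"GO:1": {"a"}}))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            fisher_enrichment(set(), set(), annotation_of({"GO:1": {"a"}}))

    def test_terms_outside_universe_omitted_and_sorted(self):
        universe = {"a", "b", "c", "d"}
        ann = annotation_of({"GO:2": {"a", "b"}, "GO:1": {"a", "b"}, "GO:3": {"zzz"}})
        res = fisher_enrichment({"a", "b"}, universe, ann)
        assert list(res["acc"]) == ["GO:1", "GO:2"]  # tie on p broken by acc


@pytest.fixture(scope="module")
def small_truth():
    _, truth = simulate_counts(SyntheticSpec(n_genes=2000, seed=17))
    return truth


class TestNullAndPlantedBehaviour:
    def test_null_annotation_pvalues_not_anticonservative(self, small_truth):
        ann = simulate_annotation(small_truth, 200, 0, 1.0, seed=23)
        universe = set(small_truth["gene_id"])
        de = true_de_genes(small_truth)
        res = fisher_enrichment(de, universe, ann)
        # stochastically >= uniform: empirical CDF at alpha below alpha + slack
        for alpha in (0.05, 0.1, 0.25):
            assert (res["p"] <= alpha).mean() <= alpha + 0.06

    def test_planted_term_ranks_first(self, small_truth):
        hits = 0
        for rep in range(50):
            ann = simulate_annotation(small_truth, 30, 1, 50.0, seed=100 + rep)
            universe = set(small_truth["gene_id"])
            de = true_de_genes(small_truth)
            res = fisher_enrichment(de, universe, ann)
            hits += res.iloc[0]["acc"] == "GO:SIM0001"
        assert hits / 50 >= 0.95


class TestSlim:
    def test_union_semantics(self):
        ann = TermAnnotation(
            {
                "GO:1": Term("GO:1", "one", "cellular_component", frozenset({"a", "b", "c"})),
                "GO:2": Term("GO:2", "two", "cellular_component", frozenset({"b", "c", "d"})),
            },
            SlimMapping(
                {"GO:1": "GO:S", "GO:2": "GO:S", "GO:S": "GO:S"},
                {"GO:S": "slim"},
                {"GO:S": "cellular_component"},
            ),
        )
        out = collapse_to_slim(ann)
        assert set(out.terms) == {"GO:S"}
        assert out.terms["GO:S"].genes == frozenset({"a", "b", "c", "d"})

    def test_identity_mapping_preserves_annotation(self):
        terms = {
            "GO:1": Term("GO:1", "one", "biological_process", frozenset({"a"})),
            "GO:2": Term("GO:2", "two", "biological_process", frozenset({"b"})),
        }
        ann = TermAnnotation(
            dict(terms),
            SlimMapping(
                {"GO:1": "GO:1", "GO:2": "GO:2"},
                {"GO:1": "one", "GO:2": "two"},
                {"GO:1": "biological_process", "GO:2": "biological_process"},
            ),
        )
        out = collapse_to_slim(ann)
        assert {acc: t.genes for acc, t in out.terms.items()} == {
            acc: t.genes for acc, t in terms.items()
        }

    def test_missing_mapping_is_config_error(self):
        ann = annotation_of({"GO:1": {"a"}})
        with pytest.raises(ConfigError, match="slim"):
            collapse_to_slim(ann)


class TestAdjustPvalues:
    def test_none_copies_p(self):
        res = fisher_enrichment(
            {"a"}, {"a", "b", "c"}, annotation_of({"GO:1": {"a"}, "GO:2": {"b"}})
        )
        out = adjust_pvalues(res, "none")
        assert (out["q"] == out["p"]).all()

    def test_bh_step_up_hand_computed(self):
        import pandas as pd

        res = pd.DataFrame({
            "acc": ["GO:1", "GO:2", "GO:3"], "name": ["", "", ""],
            "namespace": ["biological_process"] * 3,
            "k": [1, 1, 1], "n": [1, 1, 1], "K": [1, 1, 1], "N": [3, 3, 3],
            "p": [0.01, 0.02, 0.03],
        })
        out = adjust_pvalues(res, "bh")
        np.testing.assert_allclose(out["q"], [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_term_bh_equals_p(self):
        res = fisher_enrichment({"a"}, {"a", "b"}, annotation_of({"GO:1": {"a"}}))
        out = adjust_pvalues(res, "bh")
        assert out.loc[0, "q"] == pytest.approx(out.loc[0, "p"])
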