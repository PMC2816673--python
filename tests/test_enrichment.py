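"""Unit tests for hypergeometric / Fisher overlap statistics and kb tests."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from moduledisease.enrichment import (
    KnowledgeBase,
    concordance_table,
    diseases_treated_comparison,
    diseases_treated_count,
    druggable_family_enrichment,
    fisher_exact_one_sided,
    hypergeom_sf,
    pairwise_drug_overlap,
    pairwise_gene_overlap,
    read_knowledge_base,
    write_knowledge_base,
)
from moduledisease.simulate import KBParams, SimulationConfig, generate_knowledge_base


def hypergeom_sf_enumeration(k, K, n, N):
    """Exact rational upper tail by direct enumeration."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
    return total


class TestHypergeomSf:
    def test_zero_overlap_certain(self):
        assert hypergeom_sf(0, 5, 4, 10) == 1.0

    def test_small_enumeration_value(self):
        # only C(5,4)C(5,0) of the C(10,4) draws reach an overlap of 4
        assert hypergeom_sf(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_matches_enumeration_exhaustively(self):
        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    if min(K, n) > N:
                        continue
                    for k in range(0, min(K, n) + 1):
                        exact = float(hypergeom_sf_enumeration(k, K, n, N))
                        assert hypergeom_sf(k, K, n, N) == pytest.approx(
                            exact, rel=1e-9, abs=1e-12
                        )

    def test_strict_tail_shifts_by_one(self):
        assert hypergeom_sf(3, 5, 4, 10, strict=True) == pytest.approx(
            hypergeom_sf(4, 5, 4, 10), rel=1e-12
        )

    def test_extreme_tail_finite_and_monotone(self):
        ps = [hypergeom_sf(k, 5000, 500, 100_000) for k in range(0, 325, 25)]
        assert all(p > 0 for p in ps)
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert hypergeom_sf(320, 5000, 500, 100_000) < 1e-280

    def test_bound_violations_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_sf(6, 5, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_sf(1, 11, 4, 10)


class TestFisherOneSided:
    def test_enumeration_small_tables(self):
        assert fisher_exact_one_sided(2, 0, 0, 2) == pytest.approx(1 / 6, rel=1e-9)
        assert fisher_exact_one_sided(1, 1, 1, 1) == pytest.approx(5 / 6, rel=1e-9)

    def test_identity_with_hypergeometric(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b + c + d == 0:
                continue
            assert fisher_exact_one_sided(a, b, c, d) == pytest.approx(
                hypergeom_sf(int(a), int(a + b), int(a + c), int(a + b + c + d)),
                rel=1e-12,
            )

    def test_matches_scipy_greater(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(0, 25, size=4))
            if a + b + c + d == 0:
                continue
            ref = fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
            assert fisher_exact_one_sided(a, b, c, d) == pytest.approx(ref, rel=1e-9)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_one_sided(0, 0, 0, 0)


@pytest.fixture(scope="module")
def kb():
    cfg = SimulationConfig(
        seed=13, n_genes=300, n_diseases=5,
        kb_params=KBParams(
            genes_per_disease=15,
            gene_overlaps=[("d00", "d01", 5)],
            drug_overlaps=[("d02", "d03", 2)],
        ),
    )
    return generate_knowledge_base(cfg)


class TestPairwiseOverlaps:
    def test_planted_gene_overlap_reported(self, kb):
        out = pairwise_gene_overlap(kb, [("d00", "d01")])
        row = out.iloc[0]
        assert row.k == 5
        exact = float(hypergeom_sf_enumeration(5, 15, 15, row.N))
        assert row.p == pytest.approx(exact, rel=1e-9)

    def test_disjoint_sets(self):
        kb = KnowledgeBase(disease_genes={"a": {"g1"}, "b": {"g2"}})
        out = pairwise_gene_overlap(kb, [("a", "b")])
        assert out.iloc[0].k == 0 and out.iloc[0].p == 1.0

    def test_identical_sets_minimal_p(self):
        kb = KnowledgeBase(
            disease_genes={"a": {"g1", "g2", "g3"}, "b": {"g1", "g2", "g3"},
                           "c": {"g4", "g5"}}
        )
        out = pairwise_gene_overlap(kb, [("a", "b")], N=5)
        assert out.iloc[0].k == 3
        assert out.iloc[0].p == pytest.approx(
            float(hypergeom_sf_enumeration(3, 3, 3, 5)), rel=1e-9
        )

    def test_missing_disease_skipped_with_warning(self, kb, caplog):
        with caplog.at_level("WARNING"):
            out = pairwise_gene_overlap(kb, [("d00", "ghost")])
        assert out.empty
        assert "skipped" in caplog.text

    def test_drug_overlap_counts_shared_indications(self, kb):
        out = pairwise_drug_overlap(kb, [("d02", "d03")])
        assert out.iloc[0].k == 2
        assert out.iloc[0].N == kb.n_drugs


class TestConcordance:
    def test_printed_contingency_table(self):
        """The published 2x2 of correlation-significant vs gene-sharing pairs."""
        p = fisher_exact_one_sided(19, 63, 54, 329)
        assert p == pytest.approx(0.033, abs=5e-4)

    def test_table_construction_and_p(self):
        tests = pd.DataFrame(
            {
                "disease_a": [a for a, b in combinations("ABCDE", 2)],
                "disease_b": [b for a, b in combinations("ABCDE", 2)],
                "k": 0, "K": 1, "n": 1, "N": 10,
                "p": [0.001, 0.5, 0.002, 0.9, 0.9, 0.003, 0.9, 0.9, 0.9, 0.9],
            }
        )
        sig = {("A", "B"), ("A", "D"), ("B", "C")}
        (a, b, c, d), p = concordance_table(sig, tests, p_cut=0.01)
        assert (a, b, c, d) == (2, 1, 1, 6)
        assert p == pytest.approx(fisher_exact_one_sided(2, 1, 1, 6), rel=1e-12)

    def test_perfect_concordance_toy(self):
        rows = []
        for i, (a, b) in enumerate(combinations("ABCDEFG", 2)):
            rows.append((a, b, 0.001 if i < 10 else 0.5))
        tests = pd.DataFrame(rows, columns=["disease_a", "disease_b", "p"])
        sig = {(r.disease_a, r.disease_b) for r in tests.itertuples() if r.p < 0.01}
        # 21 pairs total: 10 concordant significant, 11 concordant null
        (a, b, c, d), p = concordance_table(sig, tests, 0.01)
        assert (a, b, c, d) == (10, 0, 0, 11)
        assert p == pytest.approx(hypergeom_sf(10, 10, 10, 21), rel=1e-12)

    def test_independent_classifications_rarely_significant(self):
        n_sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pairs = list(combinations([f"d{i}" for i in range(12)], 2))
            tests = pd.DataFrame(
                {
                    "disease_a": [a for a, _ in pairs],
                    "disease_b": [b for _, b in pairs],
                    "p": np.where(rng.random(len(pairs)) < 0.2, 0.001, 0.5),
                }
            )
            sig = {p for p in pairs if rng.random() < 0.2}
            _, p = concordance_table(sig, tests, 0.01)
            n_sig += p < 0.05
        assert n_sig <= 2  # independent labels: significant in <=10% of seeds

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            concordance_table(set(), pd.DataFrame(columns=["disease_a", "disease_b", "p"]))


class TestDruggability:
    def _kb(self):
        return KnowledgeBase(
            drug_targets={"drugA": {"g1"}, "drugB": {"g5"}},
            gene_families={"g1": "f1", "g2": "f1", "g3": "f2", "g4": "f2",
                           "g5": "f3", "g6": "f3", "g7": "f4"},
        )

    def test_family_sharing_marks_druggable(self):
        kb = self._kb()
        universe = {f"g{i}" for i in range(1, 9)}  # g8 has no family annotation
        test = druggable_family_enrichment(kb, {"g1", "g2", "g7"}, universe)
        # druggable = {g1, g2, g5, g6}; signature overlap = {g1, g2}
        assert (test.k, test.K, test.n, test.N) == (2, 4, 3, 8)
        assert test.p == pytest.approx(
            float(hypergeom_sf_enumeration(2, 4, 3, 8)), rel=1e-9
        )

    def test_no_targets_gives_p_one(self):
        kb = KnowledgeBase(gene_families={"g1": "f1"})
        test = druggable_family_enrichment(kb, {"g1"}, {"g1", "g2"})
        assert test.K == 0 and test.k == 0 and test.p == 1.0

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            druggable_family_enrichment(self._kb(), set(), {"g1"})


class TestDiseasesTreated:
    def _kb(self):
        return KnowledgeBase(
            drug_targets={"dr1": {"g1"}, "dr2": {"g1", "g2"}, "dr3": {"g3"}},
            drug_indications={"dr1": {"a", "b"}, "dr2": {"b", "c"}, "dr3": {"a"}},
        )

    def test_count_is_union_over_drugs(self):
        kb = self._kb()
        assert diseases_treated_count(kb, "g1") == 3  # {a,b} | {b,c}
        assert diseases_treated_count(kb, "g2") == 2
        assert diseases_treated_count(kb, "g3") == 1

    def test_identical_sets_no_difference(self):
        kb = self._kb()
        mean_sig, mean_all, p = diseases_treated_comparison(
            kb, {"g1", "g2", "g3"}, n_perm=200, seed=1
        )
        assert mean_sig == pytest.approx(mean_all)
        assert p == pytest.approx(1.0, abs=0.01)

    def test_planted_high_indication_targets_significant(self):
        targets = {f"dr{i}": {f"g{i}"} for i in range(40)}
        indications = {
            f"dr{i}": ({"x", "y", "z", "w"} if i < 5 else {"x"}) for i in range(40)
        }
        kb = KnowledgeBase(drug_targets=targets, drug_indications=indications)
        mean_sig, mean_all, p = diseases_treated_comparison(
            kb, {f"g{i}" for i in range(5)}, n_perm=2000, seed=1
        )
        assert mean_sig > mean_all
        assert p < 0.05

    def test_subset_requirement(self):
        with pytest.raises(ValueError):
            diseases_treated_comparison(self._kb(), {"ghost"}, n_perm=10)


class TestKnowledgeBaseIO:
    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=21, n_diseases=4)
        kb = generate_knowledge_base(cfg)
        write_knowledge_base(kb, tmp_path)
        back = read_knowledge_base(tmp_path)
        assert back.disease_genes == kb.disease_genes
        assert back.drug_targets == kb.drug_targets
        assert back.drug_indications == kb.drug_indications
        assert back.gene_families == kb.gene_families
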