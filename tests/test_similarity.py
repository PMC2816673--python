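"""Unit tests for partial Spearman similarity, clustering and export."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from moduledisease.similarity import (
    cluster_diseases,
    export_network,
    pairwise_disease_similarity,
    partial_corr_one,
    partial_corr_two,
    spearman,
)


def residual_partial_spearman(x, y, z1, z2):
    """Oracle: correlation of least-squares residuals of ranked x, y on ranked (z1, z2)."""
    rx, ry, rz1, rz2 = (rankdata(v) for v in (x, y, z1, z2))
    Z = np.column_stack([np.ones_like(rz1), rz1, rz2])
    rx_res = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ry_res = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    return float(np.corrcoef(rx_res, ry_res)[0, 1])


class TestSpearman:
    def test_monotone_identity(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        expected = float(np.corrcoef(rankdata(x), rankdata(y))[0, 1])
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)
        assert spearman(x, y) == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))


class TestPartialCorrOne:
    def test_methods_formula_value(self):
        assert partial_corr_one(0.6, 0.4, 0.5) == pytest.approx(0.5040, abs=1e-4)

    def test_independent_conditioner_is_identity(self):
        assert partial_corr_one(0.37, 0.0, 0.0) == pytest.approx(0.37)

    def test_degenerate_denominator_flagged(self):
        assert np.isnan(partial_corr_one(0.5, 1.0, 0.2))


class TestPartialCorrTwo:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=30)
        z1, z2 = rng.normal(size=30), rng.normal(size=30)
        assert partial_corr_two(x, x, z1, z2) == pytest.approx(1.0, abs=1e-10)

    def test_matches_residualization_oracle(self, rng):
        for _ in range(25):
            x, y, z1, z2 = (rng.normal(size=50) for _ in range(4))
            y = y + 0.5 * x + 0.3 * z1  # give the pair real structure
            got = partial_corr_two(x, y, z1, z2)
            assert got == pytest.approx(residual_partial_spearman(x, y, z1, z2), abs=1e-8)

    def test_conditioning_order_symmetric(self, rng):
        x, y, z1, z2 = (rng.normal(size=40) for _ in range(4))
        assert partial_corr_two(x, y, z1, z2) == pytest.approx(
            partial_corr_two(x, y, z2, z1), abs=1e-10
        )

    def test_uncorrelated_conditioners_reduce_to_spearman(self):
        # z1, z2 constructed rank-orthogonal to x and y
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
        z1 = np.array([1.0, 8.0, 2.0, 7.0, 3.0, 6.0, 4.0, 5.0])
        base = spearman(x, y)
        rho_xz = spearman(x, z1)
        if abs(rho_xz) < 0.05:  # guard: construction really is near-orthogonal
            got = partial_corr_two(x, y, z1, z1[::-1])
            assert got == pytest.approx(base, abs=0.05)

    def test_rank_invariance_under_monotone_transform(self, rng):
        x, y, z1, z2 = (rng.normal(size=40) for _ in range(4))
        got = partial_corr_two(x, y, z1, z2)
        assert partial_corr_two(np.exp(x), y**3 + 2 * y, z1, z2) == pytest.approx(
            got, abs=1e-12
        )


class TestPairwise:
    def _matrices(self, rng, n_modules=30, diseases=("dA", "dB", "dC")):
        mrs = pd.DataFrame(
            rng.normal(size=(n_modules, len(diseases))), columns=list(diseases)
        )
        ctrl = pd.DataFrame(
            rng.normal(size=(n_modules, len(diseases))), columns=list(diseases)
        )
        return mrs, ctrl

    def test_duplicate_columns_give_rho_one(self, rng):
        mrs, ctrl = self._matrices(rng)
        mrs["dB"] = mrs["dA"]
        ctrl["dB"] = ctrl["dA"]
        sim = pairwise_disease_similarity(mrs, ctrl)
        assert sim.rho("dA", "dB") == pytest.approx(1.0, abs=1e-10)

    def test_symmetry_and_range(self, rng):
        mrs, ctrl = self._matrices(rng)
        sim = pairwise_disease_similarity(mrs, ctrl)
        for row in sim.pairs.itertuples():
            assert -1.0 - 1e-12 <= row.rho <= 1.0 + 1e-12
            assert sim.rho(row.disease_a, row.disease_b) == sim.rho(
                row.disease_b, row.disease_a
            )

    def test_pairwise_missing_restriction(self, rng):
        mrs, ctrl = self._matrices(rng)
        mrs.loc[:5, "dA"] = np.nan
        ctrl.loc[6:8, "dB"] = np.nan
        sim = pairwise_disease_similarity(mrs, ctrl)
        row = sim.pairs[(sim.pairs.disease_a == "dA") & (sim.pairs.disease_b == "dB")]
        assert int(row.n_modules.iloc[0]) == 30 - 6 - 3

    def test_too_few_shared_modules_undefined(self, rng):
        mrs, ctrl = self._matrices(rng, n_modules=5)
        mrs.loc[:2, "dA"] = np.nan  # leaves 2 shared modules for dA pairs
        sim = pairwise_disease_similarity(mrs, ctrl)
        assert np.isnan(sim.rho("dA", "dB"))


class TestClustering:
    def _sim(self, rho_ab, rho_ac, rho_bc):
        pairs = pd.DataFrame(
            {
                "disease_a": ["A", "A", "B"],
                "disease_b": ["B", "C", "C"],
                "rho": [rho_ab, rho_ac, rho_bc],
                "n_modules": 10,
                "p": np.nan,
                "significant": False,
            }
        )
        from moduledisease.similarity import SimilarityResult

        return SimilarityResult(diseases=["A", "B", "C"], pairs=pairs)

    def test_hand_agglomeration(self):
        dendro = cluster_diseases(self._sim(0.9, 0.1, 0.2))
        heights = dendro.merge_heights()
        assert heights[0] == pytest.approx(0.1)  # (A,B) merge at 1-0.9
        assert heights[1] == pytest.approx(0.85)  # C joins at mean(0.9, 0.8)

    def test_heights_non_decreasing(self, rng):
        mrs = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("ABCDEF"))
        ctrl = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("ABCDEF"))
        dendro = cluster_diseases(pairwise_disease_similarity(mrs, ctrl))
        h = dendro.merge_heights()
        assert (np.diff(h) >= -1e-12).all()

    def test_two_diseases_single_merge(self):
        from moduledisease.similarity import SimilarityResult

        pairs = pd.DataFrame(
            {"disease_a": ["A"], "disease_b": ["B"], "rho": [0.4],
             "n_modules": 10, "p": np.nan, "significant": False}
        )
        dendro = cluster_diseases(SimilarityResult(["A", "B"], pairs))
        assert dendro.merge_heights()[0] == pytest.approx(0.6)
        assert dendro.to_newick().count(",") == 1

    def test_permutation_invariant_topology(self):
        d1 = cluster_diseases(self._sim(0.9, 0.1, 0.2))
        sim2 = self._sim(0.9, 0.1, 0.2)
        sim2.diseases = ["C", "A", "B"]  # label order permuted; pairs unchanged
        d2 = cluster_diseases(sim2)
        assert d1.to_newick() == d2.to_newick()


class TestExportNetwork:
    def _sim_with_p(self, rng):
        mrs = pd.DataFrame(rng.normal(size=(30, 3)), columns=["dA", "dB", "dC"])
        ctrl = pd.DataFrame(rng.normal(size=(30, 3)), columns=["dA", "dB", "dC"])
        sim = pairwise_disease_similarity(mrs, ctrl)
        sim.pairs["p"] = [0.001, 0.5, 0.8]
        return sim

    def test_threshold_filtering_and_attrs(self, rng, tmp_path):
        sim = self._sim_with_p(rng)
        edges = export_network(sim, 0.01, tmp_path / "n.sif", tmp_path / "n.tsv")
        assert len(edges) == 1
        assert edges.rho.iloc[0] == pytest.approx(sim.pairs.rho.iloc[0])
        assert (tmp_path / "n.sif").read_text().count("similar_to") == 1

    def test_no_pass_empty_with_header(self, rng, tmp_path):
        sim = self._sim_with_p(rng)
        sim.pairs["p"] = 0.9
        export_network(sim, 0.01, None, tmp_path / "n.tsv")
        out = pd.read_csv(tmp_path / "n.tsv", sep="\t")
        assert list(out.columns) == ["disease_a", "disease_b", "rho", "p"]
        assert out.empty

    def test_threshold_one_exports_all_defined(self, rng):
        sim = self._sim_with_p(rng)
        assert len(export_network(sim, 1.0)) == 3
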