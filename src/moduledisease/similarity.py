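"""Disease-disease similarity by partial Spearman correlation.

The similarity between two diseases is the Spearman correlation of their
module-response vectors conditioned on both diseases' control module
responses, which removes shared tissue/cell-type structure from the
comparison.  Conditioning uses the classical recursion

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

applied twice for two conditioning variables; on ranks this is equivalent
to correlating the least-squares residuals of the ranked vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "partial_corr_one",
    "partial_corr_two",
    "SimilarityResult",
    "pairwise_disease_similarity",
    "Dendrogram",
    "cluster_diseases",
    "export_network",
]

# a partial correlation is undefined when a conditioning correlation is
# this close to +/-1 (denominator underflow)
_DENOM_EPS = 1e-12


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson on average-tie ranks.

    Returns NaN (with a warning) if either vector is constant after ranking.
    Requires at least 3 paired observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >=3 paired observations")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("constant vector after ranking; correlation undefined")
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def partial_corr_one(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z from pairwise correlations.

    Undefined (NaN) when either conditioning correlation is +/-1.
    """
    denom2 = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom2 <= _DENOM_EPS:
        return float("nan")
    return (r_xy - r_xz * r_yz) / np.sqrt(denom2)


def _rank_matrix(*vectors) -> np.ndarray:
    return np.vstack([rankdata(np.asarray(v, dtype=float)) for v in vectors])


def partial_corr_two(x, y, z1, z2) -> float:
    """Second-order partial Spearman correlation r_xy.z1z2.

    All four vectors are ranked once (average ties); every intermediate
    correlation is Pearson on those ranks, then the one-variable recursion
    is applied twice.  NaN when any vector is constant after ranking or an
    intermediate denominator vanishes.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need >=4 complete observations")
    ranks = _rank_matrix(x, y, z1, z2)
    if np.any(np.ptp(ranks, axis=1) == 0):
        warnings.warn("constant vector after ranking; partial correlation undefined")
        return float("nan")
    r = np.corrcoef(ranks)
    if 1.0 - r[2, 3] ** 2 <= _DENOM_EPS:
        # collinear conditioning set: conditioning on both equals conditioning
        # on either one (matches the rank-residualization definition)
        return partial_corr_one(r[0, 1], r[0, 2], r[1, 2])
    r_xy_z1 = partial_corr_one(r[0, 1], r[0, 2], r[1, 2])
    r_xz2_z1 = partial_corr_one(r[0, 3], r[0, 2], r[3, 2])
    r_yz2_z1 = partial_corr_one(r[1, 3], r[1, 2], r[3, 2])
    if np.isnan(r_xy_z1) or np.isnan(r_xz2_z1) or np.isnan(r_yz2_z1):
        return float("nan")
    return partial_corr_one(r_xy_z1, r_xz2_z1, r_yz2_z1)


@dataclass
class SimilarityResult:
    """Pairwise partial-Spearman similarities between diseases.

    ``pairs`` has one row per unordered disease pair with columns
    disease_a, disease_b, rho, n_modules, p, significant (p and
    significant are NaN/False until a null model fills them in).
    """

    diseases: list[str]
    pairs: pd.DataFrame = field(repr=False)

    def rho(self, a: str, b: str) -> float:
        m = self.pairs
        row = m[
            ((m.disease_a == a) & (m.disease_b == b))
            | ((m.disease_a == b) & (m.disease_b == a))
        ]
        if row.empty:
            raise KeyError((a, b))
        return float(row.rho.iloc[0])

    def rho_matrix(self) -> pd.DataFrame:
        """Symmetric rho matrix with unit diagonal (NaN for undefined pairs)."""
        mat = pd.DataFrame(np.eye(len(self.diseases)), index=self.diseases, columns=self.diseases)
        for row in self.pairs.itertuples():
            mat.loc[row.disease_a, row.disease_b] = row.rho
            mat.loc[row.disease_b, row.disease_a] = row.rho
        return mat

    def assign_pvalues(self, null_values: np.ndarray) -> None:
        """Fill empirical p per pair from a pooled null (one-sided, positive)."""
        from .nulls import empirical_pvalue

        self.pairs["p"] = [
            empirical_pvalue(r, null_values) if np.isfinite(r) else np.nan
            for r in self.pairs.rho
        ]

    def mark_significant(self, p_threshold: float) -> None:
        self.pairs["significant"] = self.pairs.p < p_threshold


def pairwise_disease_similarity(
    mrs: pd.DataFrame, ctrl: pd.DataFrame
) -> SimilarityResult:
    """Partial Spearman similarity for every unordered disease pair.

    For diseases (a, b) the correlation of MRS columns M_a, M_b is
    conditioned on both control-response columns C_a, C_b, restricted to
    modules non-missing in all four vectors.  Pairs with fewer than 4 such
    modules are undefined (rho = NaN).
    """
    if not mrs.columns.equals(ctrl.columns) or not mrs.index.equals(ctrl.index):
        raise ValueError("MRS and control matrices must be aligned")
    diseases = list(mrs.columns)
    if len(diseases) < 2:
        raise ValueError("need at least two diseases")
    M = mrs.to_numpy(dtype=float)
    C = ctrl.to_numpy(dtype=float)
    finite = np.isfinite(M) & np.isfinite(C)
    rows = []
    for ia, ib in combinations(range(len(diseases)), 2):
        mask = finite[:, ia] & finite[:, ib]
        n_used = int(mask.sum())
        if n_used < 4:
            rho = np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = partial_corr_two(
                    M[mask, ia], M[mask, ib], C[mask, ia], C[mask, ib]
                )
        rows.append((diseases[ia], diseases[ib], rho, n_used))
    pairs = pd.DataFrame(rows, columns=["disease_a", "disease_b", "rho", "n_modules"])
    pairs["p"] = np.nan
    pairs["significant"] = False
    return SimilarityResult(diseases=diseases, pairs=pairs)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over diseases at distance 1 - rho."""

    labels: list[str]
    linkage_matrix: np.ndarray = field(repr=False)

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def name(node: int) -> str:
            if node < n:
                return self.labels[node]
            left, right, h, _ = self.linkage_matrix[node - n]
            left, right = int(left), int(right)
            bl_l = h - heights[left]
            bl_r = h - heights[right]
            return f"({name(left)}:{bl_l:.6g},{name(right)}:{bl_r:.6g})"

        for k, row in enumerate(self.linkage_matrix):
            heights[n + k] = row[2]
        return name(n + len(self.linkage_matrix) - 1) + ";"


def cluster_diseases(sim: SimilarityResult) -> Dendrogram:
    """Average-linkage hierarchical clustering at distance d = 1 - rho.

    Undefined pairs are imputed at rho = 0 (distance 1) for the tree only;
    the imputation is logged and never affects significance.  Labels are
    sorted so equal-distance merges break ties lexicographically.
    """
    if len(sim.diseases) < 2:
        raise ValueError("need at least two diseases to cluster")
    labels = sorted(sim.diseases)
    mat = sim.rho_matrix().loc[labels, labels].to_numpy(dtype=float)
    n_undef = int(np.isnan(mat).sum() // 2)
    if n_undef:
        log.warning("imputing rho=0 for %d undefined pair(s) in clustering", n_undef)
        mat = np.nan_to_num(mat, nan=0.0)
    np.fill_diagonal(mat, 1.0)
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(labels=labels, linkage_matrix=Z)


def export_network(
    sim: SimilarityResult,
    p_threshold: float,
    sif_path=None,
    attr_path=None,
) -> pd.DataFrame:
    """Edge list of significant disease correlations (empirical p < threshold).

    Optionally writes a Cytoscape SIF file and an edge-attribute TSV with
    rho (edge strength) and p.
    """
    if sim.pairs.p.isna().all() and p_threshold < 1.0:
        raise ValueError("empirical p-values missing; run the null model first")
    edges = sim.pairs[
        (sim.pairs.p < p_threshold) | ((p_threshold >= 1.0) & sim.pairs.rho.notna())
    ][["disease_a", "disease_b", "rho", "p"]].reset_index(drop=True)
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for row in edges.itertuples():
                fh.write(f"{row.disease_a}\tsimilar_to\t{row.disease_b}\n")
    if attr_path is not None:
        edges.to_csv(attr_path, sep="\t", index=False, na_rep="NA")
    return edges
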