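"""Randomization null models and empirical significance.

Significance of disease correlations is assessed against a background
distribution built by (a) degree-preserving rewiring of the gene-module
bipartite graph and (b) shuffling disease/control sample labels within
each study, then recomputing module response scores and all pairwise
partial correlations.  The whole process is repeated R times (default
100) and the resulting correlations are pooled into one background
distribution.  The module-signature test uses a catalog-randomization-
only null over the per-module median absolute MRS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import (
    ExpressionStudy,
    control_gene_z,
    gene_response_combined,
    zscore_normalize,
)
from .modules import ModuleCatalog, assemble_matrices, compute_control_response, compute_mrs
from .similarity import pairwise_disease_similarity

log = logging.getLogger(__name__)

__all__ = [
    "NullEnsemble",
    "randomize_catalog",
    "shuffle_labels",
    "build_null",
    "build_median_null",
    "empirical_pvalue",
    "fdr_at_threshold",
]

# attempted double-edge swaps per membership link during catalog rewiring
SWAP_FACTOR = 10


@dataclass
class NullEnsemble:
    """Pooled null statistics from R randomization replicates."""

    kind: str  # 'correlation' or 'median_abs_mrs'
    replicates: int
    seed: int
    replicate_values: list[np.ndarray] = field(repr=False)

    @property
    def values(self) -> np.ndarray:
        """All null values pooled across replicates (finite only)."""
        pooled = np.concatenate(self.replicate_values) if self.replicate_values else np.empty(0)
        return pooled[np.isfinite(pooled)]


def randomize_catalog(catalog: ModuleCatalog, seed) -> ModuleCatalog:
    """Degree-preserving randomization of gene-module assignments.

    Random double-edge swaps on the bipartite membership graph: links
    (m1, g1) and (m2, g2) are rewired to (m1, g2), (m2, g1) unless the
    rewiring would duplicate a membership.  ``SWAP_FACTOR * n_edges``
    swaps are attempted; failed attempts are skipped.  Module sizes and
    per-gene module counts are exactly preserved.

    ``seed`` may be an int or a numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    module_ids = catalog.module_ids
    gene_lists: list[list[str]] = [list(catalog[m]) for m in module_ids]
    member_sets: list[set[str]] = [set(g) for g in gene_lists]
    edges: list[tuple[int, int]] = [  # (module index, position within module)
        (mi, gi) for mi, genes in enumerate(gene_lists) for gi in range(len(genes))
    ]
    n_edges = len(edges)
    if n_edges < 2:
        return ModuleCatalog(
            {m: tuple(g) for m, g in zip(module_ids, gene_lists)},
            {m: catalog.description(m) for m in module_ids},
        )
    picks = rng.integers(0, n_edges, size=(SWAP_FACTOR * n_edges, 2))
    for e1, e2 in picks:
        if e1 == e2:
            continue
        m1, i1 = edges[e1]
        m2, i2 = edges[e2]
        if m1 == m2:
            continue
        g1 = gene_lists[m1][i1]
        g2 = gene_lists[m2][i2]
        if g1 == g2 or g2 in member_sets[m1] or g1 in member_sets[m2]:
            continue
        gene_lists[m1][i1] = g2
        gene_lists[m2][i2] = g1
        member_sets[m1].remove(g1)
        member_sets[m1].add(g2)
        member_sets[m2].remove(g2)
        member_sets[m2].add(g1)
    return ModuleCatalog(
        {m: tuple(g) for m, g in zip(module_ids, gene_lists)},
        {m: catalog.description(m) for m in module_ids},
    )


def shuffle_labels(study: ExpressionStudy, seed) -> ExpressionStudy:
    """Permute disease/control labels within a study; values untouched.

    Group sizes are preserved (a permutation reassigns the same multiset
    of labels to the same samples).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(study.labels))
    new = pd.Series(study.labels.to_numpy()[perm], index=study.labels.index)
    return study.with_labels(new)


def _studies_by_disease(studies: list[ExpressionStudy]) -> dict[str, list[ExpressionStudy]]:
    grouped: dict[str, list[ExpressionStudy]] = {}
    for s in studies:
        grouped.setdefault(s.disease_id, []).append(s)
    return grouped


def compute_response_matrices(
    studies: list[ExpressionStudy],
    catalog: ModuleCatalog,
    min_genes: int = 2,
    z_cache: dict[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MRS and control-response matrices for a compendium.

    ``z_cache`` maps study_id -> precomputed z matrix (z-scores do not
    depend on labels, so null replicates can reuse them).
    """
    columns: dict[str, tuple[pd.Series, pd.Series]] = {}
    for disease_id, group in _studies_by_disease(studies).items():
        z_list = [
            z_cache[s.study_id] if z_cache is not None else zscore_normalize(s)
            for s in group
        ]
        labels_list = [s.labels for s in group]
        grv = gene_response_combined(z_list, labels_list, disease_id)
        ctrl_z = control_gene_z(z_list, labels_list)
        mrs_col, _ = compute_mrs(grv.scores, catalog, min_genes)
        ctrl_col, _ = compute_control_response(ctrl_z, catalog, min_genes)
        columns[disease_id] = (mrs_col, ctrl_col)
    return assemble_matrices(columns)


def build_null(
    studies: list[ExpressionStudy],
    catalog: ModuleCatalog,
    replicates: int = 100,
    seed: int = 0,
    min_genes: int = 2,
    max_failure_fraction: float = 0.10,
) -> NullEnsemble:
    """Background distribution of disease correlations.

    Each replicate rewires the module catalog, shuffles sample labels
    within every study, recomputes MRS/control matrices and all pairwise
    partial Spearman correlations; correlations are pooled across
    replicates and pairs.  Aborts if more than ``max_failure_fraction``
    of replicates raise.
    """
    rng = np.random.default_rng(seed)
    z_cache = {s.study_id: zscore_normalize(s) for s in studies}
    replicate_values: list[np.ndarray] = []
    failures = 0
    for _ in range(replicates):
        try:
            rand_cat = randomize_catalog(catalog, rng)
            shuffled = [shuffle_labels(s, rng) for s in studies]
            mrs, ctrl = compute_response_matrices(
                shuffled, rand_cat, min_genes, z_cache=z_cache
            )
            sim = pairwise_disease_similarity(mrs, ctrl)
            replicate_values.append(sim.pairs.rho.to_numpy(dtype=float))
        except Exception:  # noqa: BLE001 - per-replicate failures are counted
            failures += 1
            log.exception("null replicate failed")
            if failures > max_failure_fraction * replicates:
                raise RuntimeError(
                    f"{failures} of {replicates} null replicates failed"
                ) from None
    return NullEnsemble(
        kind="correlation",
        replicates=replicates,
        seed=seed,
        replicate_values=replicate_values,
    )


def build_median_null(
    studies: list[ExpressionStudy],
    catalog: ModuleCatalog,
    replicates: int = 100,
    seed: int = 0,
    min_genes: int = 2,
) -> NullEnsemble:
    """Background distribution of per-module median |MRS|.

    Only the gene-module assignments are randomized (no label shuffling):
    gene scores are computed once on the observed labels and re-aggregated
    under each rewired catalog.
    """
    rng = np.random.default_rng(seed)
    scores_by_disease: dict[str, pd.Series] = {}
    for disease_id, group in _studies_by_disease(studies).items():
        z_list = [zscore_normalize(s) for s in group]
        labels_list = [s.labels for s in group]
        scores_by_disease[disease_id] = gene_response_combined(
            z_list, labels_list, disease_id
        ).scores
    replicate_values: list[np.ndarray] = []
    for _ in range(replicates):
        rand_cat = randomize_catalog(catalog, rng)
        cols = {}
        for disease_id, scores in scores_by_disease.items():
            col, _ = compute_mrs(scores, rand_cat, min_genes)
            cols[disease_id] = col
        mrs = pd.DataFrame(cols)
        medians = mrs.abs().median(axis=1, skipna=True).to_numpy(dtype=float)
        replicate_values.append(medians)
    return NullEnsemble(
        kind="median_abs_mrs",
        replicates=replicates,
        seed=seed,
        replicate_values=replicate_values,
    )


def empirical_pvalue(observed: float, null_values: np.ndarray) -> float:
    """One-sided empirical p with the add-one rule.

    p = (1 + #{null >= observed}) / (1 + #null); never returns 0.
    """
    null_values = np.asarray(null_values, dtype=float)
    null_values = null_values[np.isfinite(null_values)]
    if null_values.size == 0:
        raise ValueError("null distribution is empty")
    return float((1 + np.sum(null_values >= observed)) / (1 + null_values.size))


def empirical_pvalues(observed: np.ndarray, null_values: np.ndarray) -> np.ndarray:
    """Vectorized :func:`empirical_pvalue` over an array of observed values."""
    null_values = np.asarray(null_values, dtype=float)
    null_values = null_values[np.isfinite(null_values)]
    if null_values.size == 0:
        raise ValueError("null distribution is empty")
    observed = np.asarray(observed, dtype=float)
    srt = np.sort(null_values)
    n_ge = srt.size - np.searchsorted(srt, observed, side="left")
    p = (1 + n_ge) / (1 + srt.size)
    return np.where(np.isfinite(observed), p, np.nan)


def fdr_at_threshold(
    observed: np.ndarray, ensemble: NullEnsemble, p_threshold: float
) -> float | None:
    """Empirical FDR (percent) at a p-value cutoff.

    FDR = (mean per-replicate count of null statistics whose pooled
    empirical p falls below the cutoff) / (observed discoveries), as a
    percentage.  None when there are no observed discoveries.
    """
    observed = np.asarray(observed, dtype=float)
    observed = observed[np.isfinite(observed)]
    pooled = ensemble.values
    if observed.size == 0 or pooled.size == 0:
        raise ValueError("observed and null sets must be nonempty")
    n_disc = int(np.sum(empirical_pvalues(observed, pooled) < p_threshold))
    if n_disc == 0:
        return None
    per_rep = [
        int(np.sum(empirical_pvalues(rep[np.isfinite(rep)], pooled) < p_threshold))
        for rep in ensemble.replicate_values
    ]
    return 100.0 * float(np.mean(per_rep)) / n_disc
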