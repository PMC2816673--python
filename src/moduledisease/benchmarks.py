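"""Synthetic benchmark studies: oracle gaps, calibration and recovery.

These routines run the pipeline end-to-end on seeded synthetic compendia
with known planted structure and summarize how well it behaves: numerical
agreement between the regression scores / partial correlations and their
independent least-squares oracles, false-positive calibration of the
randomization null, and recovery of planted disease pairs and signature
modules.  They are used by the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .expression import gene_response_combined, gene_response_single, zscore_normalize
from .nulls import (
    build_median_null,
    build_null,
    compute_response_matrices,
    empirical_pvalues,
)
from .signature import select_signature
from .similarity import partial_corr_two, pairwise_disease_similarity
from .simulate import (
    SimulationConfig,
    generate_disease_compendium,
    generate_module_catalog,
)

__all__ = [
    "combined_t_oracle_gap",
    "partial_spearman_oracle_gap",
    "null_calibration",
    "planted_pair_recovery",
    "signature_recovery",
]


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % (2**31))


def combined_t_oracle_gap(seed: int = 0, n_genes: int = 200) -> float:
    """Max |combined regression t - pooled two-sample t| on a single study."""
    rng = np.random.default_rng(seed)
    import pandas as pd

    values = pd.DataFrame(
        rng.normal(size=(n_genes, 10)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(10)],
    )
    labels = pd.Series(["disease"] * 5 + ["control"] * 5, index=values.columns)
    z = zscore_normalize(values)
    pooled = gene_response_single(z, labels)
    combined = gene_response_combined([z], [labels]).scores
    return float(np.nanmax(np.abs(combined.to_numpy() - pooled.to_numpy())))


def _residual_partial_spearman(x, y, z1, z2) -> float:
    """Oracle: correlate lstsq residuals of ranked x, y on ranked (z1, z2)."""
    rx, ry, rz1, rz2 = (rankdata(v) for v in (x, y, z1, z2))
    Z = np.column_stack([np.ones_like(rz1), rz1, rz2])
    rx_res = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ry_res = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    return float(np.corrcoef(rx_res, ry_res)[0, 1])


def partial_spearman_oracle_gap(
    seed: int = 0, n_draws: int = 100, length: int = 50
) -> float:
    """Max |recursion - rank-residualization| over random vector draws."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        x, y, z1, z2 = (rng.normal(size=length) for _ in range(4))
        y = y + rng.uniform(-1, 1) * x + rng.uniform(-1, 1) * z1
        gap = abs(partial_corr_two(x, y, z1, z2) - _residual_partial_spearman(x, y, z1, z2))
        worst = max(worst, gap)
    return worst


def null_calibration(
    seed: int = 0,
    n_seeds: int = 3,
    n_diseases: int = 10,
    n_modules: int = 200,
    replicates: int = 100,
    p_cut: float = 0.01,
) -> tuple[float, int]:
    """Fraction of disease pairs called significant on effect-free data.

    Simulates ``n_seeds`` compendia with no planted dysregulation, runs the
    full similarity + randomization-null pipeline on each and pools the
    empirical-p calls.  Returns (fraction significant at ``p_cut``, total
    number of pairs tested).
    """
    n_sig = 0
    n_total = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=_child_seed(seed, 0, i),
            n_diseases=n_diseases,
            n_modules=n_modules,
            effect_size=0.0,
        )
        catalog = generate_module_catalog(cfg)
        studies, _ = generate_disease_compendium(cfg, catalog)
        mrs, ctrl = compute_response_matrices(studies, catalog)
        sim = pairwise_disease_similarity(mrs, ctrl)
        null = build_null(
            studies, catalog, replicates=replicates, seed=_child_seed(seed, 1, i)
        )
        p = empirical_pvalues(sim.pairs.rho.to_numpy(dtype=float), null.values)
        n_sig += int(np.nansum(p < p_cut))
        n_total += int(np.isfinite(p).sum())
    return n_sig / n_total, n_total


def planted_pair_recovery(
    seed: int = 0,
    n_seeds: int = 10,
    replicates: int = 100,
    p_cut: float = 0.01,
) -> tuple[float, int]:
    """Recovery rate of planted correlated disease pairs.

    Each run plants two disease pairs sharing dysregulated modules at
    Jaccard 0.8 with a 3-sigma effect.  A run counts as a success when
    every planted pair out-ranks all non-planted pairs by rho AND is
    declared significant at ``p_cut`` against the randomization null.
    Returns (success fraction, n_seeds).
    """
    planted = [("d00", "d01", 0.8), ("d02", "d03", 0.8)]
    planted_sets = [frozenset(p[:2]) for p in planted]
    n_success = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=_child_seed(seed, 2, i),
            n_diseases=10,
            n_modules=200,
            planted_pairs=planted,
            modules_per_disease=10,
            effect_size=3.0,
            noise_sd=1.0,
        )
        catalog = generate_module_catalog(cfg)
        studies, _ = generate_disease_compendium(cfg, catalog)
        mrs, ctrl = compute_response_matrices(studies, catalog)
        sim = pairwise_disease_similarity(mrs, ctrl)
        null = build_null(
            studies, catalog, replicates=replicates, seed=_child_seed(seed, 3, i)
        )
        sim.assign_pvalues(null.values)
        is_planted = sim.pairs.apply(
            lambda r: frozenset((r.disease_a, r.disease_b)) in planted_sets, axis=1
        )
        rho_planted = sim.pairs.rho[is_planted]
        rho_rest = sim.pairs.rho[~is_planted]
        ranked_above = float(rho_planted.min()) > float(rho_rest.max())
        significant = bool((sim.pairs.p[is_planted] < p_cut).all())
        n_success += ranked_above and significant
    return n_success / n_seeds, n_seeds


def signature_recovery(
    seed: int = 0,
    n_seeds: int = 10,
    replicates: int = 100,
    p_cut: float = 0.01,
    mrs_threshold: float = 1.5,
) -> tuple[float, float, int]:
    """Sensitivity and false-selection rate for planted signature modules.

    Plants 10 signature modules dysregulated (consistent sign, 3-sigma
    effect) in 80% of 25 diseases, runs the median-|MRS| catalog-
    randomization null and the two-stage filter requiring differential
    expression in more than half of the diseases.  Returns (mean
    sensitivity, mean fraction of non-planted modules selected, n_seeds).
    """
    n_diseases = 25
    min_diseases = 13  # more than half of the diseases
    sens, fpr = [], []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=_child_seed(seed, 4, i),
            n_diseases=n_diseases,
            n_modules=200,
            n_signature_modules=10,
            signature_disease_fraction=0.8,
            modules_per_disease=10,
            effect_size=3.0,
            noise_sd=1.0,
        )
        catalog = generate_module_catalog(cfg)
        studies, truth = generate_disease_compendium(cfg, catalog)
        mrs, _ = compute_response_matrices(studies, catalog)
        null = build_median_null(
            studies, catalog, replicates=replicates, seed=_child_seed(seed, 5, i)
        )
        res = select_signature(mrs, null, p_cut, mrs_threshold, min_diseases)
        selected = set(res.index[res.in_signature])
        planted = set(truth.signature_modules)
        sens.append(len(selected & planted) / len(planted))
        n_neg = len(res) - len(planted)
        fpr.append(len(selected - planted) / n_neg)
    return float(np.mean(sens)), float(np.mean(fpr)), n_seeds
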