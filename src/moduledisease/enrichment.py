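"""Overlap and enrichment statistics over a disease/drug knowledge base.

Implements the hypergeometric upper-tail test used for shared disease
genes, shared drugs and druggable-family enrichment, the one-sided
Fisher's exact concordance test between expression-based and gene-based
disease similarity, and a permutation comparison of how many diseases
the drugs of signature targets treat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

log = logging.getLogger(__name__)

__all__ = [
    "KnowledgeBase",
    "OverlapTest",
    "hypergeom_sf",
    "fisher_exact_one_sided",
    "pairwise_gene_overlap",
    "pairwise_drug_overlap",
    "concordance_table",
    "druggable_family_enrichment",
    "diseases_treated_comparison",
    "read_knowledge_base",
    "write_knowledge_base",
]


def hypergeom_sf(k: int, K: int, n: int, N: int, strict: bool = False) -> float:
    """Upper-tail hypergeometric probability of an overlap of k items.

    Probability that two sets of sizes K and n drawn from a universe of N
    items share at least k members, P(X >= k); with ``strict=True`` the
    tail is exclusive, P(X > k).  Computed in log space so extreme tails
    (down to ~1e-300) stay finite and monotone.
    """
    if not (0 <= k <= min(K, n) and max(K, n) <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    lo = k + 1 if strict else k
    hi = min(K, n)
    if lo <= 0:
        return 1.0
    if lo > hi:
        return 0.0
    # sum the tail from log-pmfs (gammaln-based) so tails below the double
    # underflow threshold of a direct sf computation stay finite
    xs = np.arange(lo, hi + 1)
    logp = logsumexp(hypergeom.logpmf(xs, N, K, n))
    return float(min(np.exp(logp), 1.0))


def fisher_exact_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (upper-tail) Fisher's exact test on a 2x2 table.

    Probability, at fixed margins, of a table at least as concordant as
    (a, b; c, d); identically hypergeom_sf(a, a+b, a+c, a+b+c+d).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return hypergeom_sf(a, a + b, a + c, a + b + c + d)


@dataclass
class OverlapTest:
    """A single hypergeometric overlap test: k of K vs n in a universe of N."""

    k: int
    K: int
    n: int
    N: int
    p: float


@dataclass
class KnowledgeBase:
    """Disease-gene, drug-target, drug-indication and gene-family maps."""

    disease_genes: dict[str, set[str]] = field(default_factory=dict)
    drug_targets: dict[str, set[str]] = field(default_factory=dict)
    drug_indications: dict[str, set[str]] = field(default_factory=dict)
    gene_families: dict[str, str] = field(default_factory=dict)

    @property
    def all_disease_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.disease_genes.values():
            out.update(genes)
        return out

    @property
    def n_drugs(self) -> int:
        return len(set(self.drug_indications) | set(self.drug_targets))

    @property
    def all_drug_targets(self) -> set[str]:
        out: set[str] = set()
        for genes in self.drug_targets.values():
            out.update(genes)
        return out

    def disease_drugs(self) -> dict[str, set[str]]:
        """Invert drug -> indications into disease -> set of drugs."""
        out: dict[str, set[str]] = {}
        for drug, diseases in self.drug_indications.items():
            for d in diseases:
                out.setdefault(d, set()).add(drug)
        return out

    def target_drugs(self) -> dict[str, set[str]]:
        """Invert drug -> targets into target gene -> set of drugs."""
        out: dict[str, set[str]] = {}
        for drug, genes in self.drug_targets.items():
            for g in genes:
                out.setdefault(g, set()).add(drug)
        return out


def _overlap_tests(
    sets: dict[str, set[str]],
    pairs: list[tuple[str, str]],
    N: int,
    strict: bool = False,
) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        if a not in sets or b not in sets:
            log.warning("pair (%s, %s) skipped: missing from knowledge base", a, b)
            continue
        sa, sb = sets[a], sets[b]
        k = len(sa & sb)
        p = hypergeom_sf(k, len(sa), len(sb), N, strict=strict)
        rows.append((a, b, k, len(sa), len(sb), N, p))
    return pd.DataFrame(
        rows, columns=["disease_a", "disease_b", "k", "K", "n", "N", "p"]
    )


def pairwise_gene_overlap(
    kb: KnowledgeBase,
    pairs: list[tuple[str, str]],
    N: int | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Shared-disease-gene overlap tests for the given disease pairs.

    The universe N defaults to the number of distinct disease-associated
    genes in the knowledge base.
    """
    if N is None:
        N = len(kb.all_disease_genes)
    return _overlap_tests(kb.disease_genes, pairs, N, strict=strict)


def pairwise_drug_overlap(
    kb: KnowledgeBase,
    pairs: list[tuple[str, str]],
    N_drugs: int | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Shared-drug overlap tests (diseases mapped to their indicated drugs).

    The universe defaults to the total number of drugs in the knowledge
    base.  Diseases with no indicated drug are skipped with a warning.
    """
    if N_drugs is None:
        N_drugs = kb.n_drugs
    return _overlap_tests(kb.disease_drugs(), pairs, N_drugs, strict=strict)


def concordance_table(
    similarity_significant: set[tuple[str, str]],
    overlap_tests: pd.DataFrame,
    p_cut: float = 0.01,
) -> tuple[tuple[int, int, int, int], float]:
    """Cross-tabulate expression similarity against knowledge-base overlap.

    Each pair in ``overlap_tests`` is classified by whether it is an
    expression-significant correlation and whether its overlap p is below
    ``p_cut``; returns the 2x2 table (a, b, c, d) = (both, overlap-only,
    correlation-only, neither) and its one-sided Fisher p.
    """
    if overlap_tests.empty:
        raise ValueError("empty pair universe")
    sig = {frozenset(p) for p in similarity_significant}
    a = b = c = d = 0
    for row in overlap_tests.itertuples():
        corr_sig = frozenset((row.disease_a, row.disease_b)) in sig
        over_sig = row.p < p_cut
        if over_sig and corr_sig:
            a += 1
        elif over_sig:
            b += 1
        elif corr_sig:
            c += 1
        else:
            d += 1
    return (a, b, c, d), fisher_exact_one_sided(a, b, c, d)


def druggable_genes(kb: KnowledgeBase, universe: set[str]) -> set[str]:
    """Genes in ``universe`` whose protein family contains a drug target.

    Genes without a family annotation are never druggable.
    """
    target_families = {
        kb.gene_families[g] for g in kb.all_drug_targets if g in kb.gene_families
    }
    return {
        g for g in universe if kb.gene_families.get(g) in target_families
    }


def druggable_family_enrichment(
    kb: KnowledgeBase,
    signature_genes: set[str],
    universe_genes: set[str],
    strict: bool = False,
) -> OverlapTest:
    """Enrichment of druggable-family genes among signature-module genes.

    A gene is druggable iff its protein family contains at least one known
    drug-target gene.  Tests k = |druggable & signature| against
    K = |druggable in universe|, n = |signature|, N = |universe|.
    """
    if not signature_genes:
        raise ValueError("empty signature gene set")
    druggable = druggable_genes(kb, universe_genes)
    sig = signature_genes & universe_genes
    k = len(druggable & sig)
    p = hypergeom_sf(k, len(druggable), len(sig), len(universe_genes), strict=strict)
    return OverlapTest(k=k, K=len(druggable), n=len(sig), N=len(universe_genes), p=p)


def diseases_treated_count(kb: KnowledgeBase, target: str) -> int:
    """Distinct diseases treated by any drug targeting ``target``."""
    diseases: set[str] = set()
    for drug in kb.target_drugs().get(target, set()):
        diseases.update(kb.drug_indications.get(drug, set()))
    return len(diseases)


def diseases_treated_comparison(
    kb: KnowledgeBase,
    signature_targets: set[str],
    all_targets: set[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Do signature drug targets treat more diseases than targets overall?

    Per target, counts the distinct diseases across the indications of all
    drugs hitting it.  Returns (mean over signature targets, mean over all
    targets, one-sided permutation p) where the permutation resamples
    |signature_targets| targets from all targets n_perm times.
    """
    if all_targets is None:
        all_targets = kb.all_drug_targets
    if not signature_targets <= all_targets:
        raise ValueError("signature targets must be a subset of all targets")
    target_drugs = kb.target_drugs()
    counts: dict[str, int] = {}
    for t in sorted(all_targets):
        diseases: set[str] = set()
        for drug in target_drugs.get(t, set()):
            diseases.update(kb.drug_indications.get(drug, set()))
        counts[t] = len(diseases)
    all_counts = np.array([counts[t] for t in sorted(all_targets)], dtype=float)
    sig_counts = np.array([counts[t] for t in sorted(signature_targets)], dtype=float)
    mean_sig = float(sig_counts.mean())
    mean_all = float(all_counts.mean())
    rng = np.random.default_rng(seed)
    m = len(sig_counts)
    perm_means = np.array(
        [all_counts[rng.choice(all_counts.size, size=m, replace=False)].mean() for _ in range(n_perm)]
    )
    p = float((1 + np.sum(perm_means >= mean_sig)) / (1 + n_perm))
    return mean_sig, mean_all, p


# -- knowledge-base I/O ---------------------------------------------------

_KB_FILES = {
    "disease_genes": ("disease_gene.tsv", ["disease_id", "gene_id"]),
    "drug_targets": ("drug_target.tsv", ["drug_id", "gene_id"]),
    "drug_indications": ("drug_indication.tsv", ["drug_id", "disease_id"]),
}


def write_knowledge_base(kb: KnowledgeBase, directory) -> None:
    """Write the four knowledge-base TSVs into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, (fname, cols) in _KB_FILES.items():
        mapping: dict[str, set[str]] = getattr(kb, attr)
        rows = [(k, v) for k in sorted(mapping) for v in sorted(mapping[k])]
        pd.DataFrame(rows, columns=cols).to_csv(
            directory / fname, sep="\t", index=False
        )
    rows = [(g, f) for g, f in sorted(kb.gene_families.items())]
    pd.DataFrame(rows, columns=["gene_id", "family_id"]).to_csv(
        directory / "gene_family.tsv", sep="\t", index=False
    )


def read_knowledge_base(directory) -> KnowledgeBase:
    directory = Path(directory)
    kb = KnowledgeBase()
    for attr, (fname, cols) in _KB_FILES.items():
        df = pd.read_csv(directory / fname, sep="\t", dtype=str)
        mapping: dict[str, set[str]] = {}
        for key, val in zip(df[cols[0]], df[cols[1]]):
            mapping.setdefault(key, set()).add(val)
        setattr(kb, attr, mapping)
    fam = pd.read_csv(directory / "gene_family.tsv", sep="\t", dtype=str)
    kb.gene_families = dict(zip(fam.gene_id, fam.family_id))
    return kb


def all_disease_pairs(kb: KnowledgeBase) -> list[tuple[str, str]]:
    """All unordered pairs of diseases present in the disease-gene map."""
    return list(combinations(sorted(kb.disease_genes), 2))
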