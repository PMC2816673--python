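"""Seeded synthetic compendia with known planted structure.

The generator emulates the statistical shape of a disease expression
compendium assembled from public microarray studies: several experiments
per disease, each with disease and control samples in the same tissue;
gene-level batch offsets between experiments; module-level up/down
dysregulation in the disease samples; designated disease pairs that share
dysregulated modules at a chosen Jaccard overlap; "signature" modules
dysregulated with a consistent sign across most diseases; and a
disease/drug knowledge base with planted gene and drug overlaps.  Every
output is deterministic for a fixed seed, and all planted structure is
recorded in a :class:`GroundTruth` for downstream recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import KnowledgeBase
from .exceptions import ConfigurationError
from .expression import CONTROL, DISEASE, ExpressionStudy
from .modules import ModuleCatalog

__all__ = [
    "KBParams",
    "SimulationConfig",
    "GroundTruth",
    "generate_module_catalog",
    "generate_disease_compendium",
    "generate_knowledge_base",
]

# fixed spawn keys so each generator has an independent, named substream
_STREAM_CATALOG = 0
_STREAM_COMPENDIUM = 1
_STREAM_KB = 2


@dataclass
class KBParams:
    """Sizes and planted overlaps for the synthetic knowledge base.

    ``gene_overlaps`` / ``drug_overlaps`` list (disease_a, disease_b, k)
    triples; the generator plants exactly k shared disease genes (shared
    indicated drugs) for those pairs and keeps the pair's remaining items
    disjoint.
    """

    genes_per_disease: int = 25
    gene_overlaps: list[tuple[str, str, int]] = field(default_factory=list)
    n_drugs: int = 60
    targets_per_drug: int = 3
    indications_per_drug: int = 3
    drug_overlaps: list[tuple[str, str, int]] = field(default_factory=list)
    n_families: int = 50


@dataclass
class SimulationConfig:
    """All knobs of the synthetic compendium.

    ``effect_size`` is the mean shift applied to disease samples of
    dysregulated-module genes, in units of the within-group standard
    deviation (``noise_sd``).  ``experiment_offset_sd`` scales per-gene,
    per-study additive batch offsets shared by all samples of a study.
    ``planted_pairs`` lists (disease_a, disease_b, jaccard) triples whose
    dysregulated module sets overlap at the given Jaccard coefficient.
    ``n_signature_modules`` modules are dysregulated with a consistent
    sign in a ``signature_disease_fraction`` of all diseases.
    """

    seed: int = 0
    n_genes: int = 500
    n_modules: int = 100
    module_size_range: tuple[int, int] = (4, 10)
    n_diseases: int = 10
    studies_per_disease: int | tuple[int, int] = 2
    samples_per_group: int = 4
    effect_size: float = 3.0
    noise_sd: float = 1.0
    experiment_offset_sd: float = 1.0
    modules_per_disease: int = 10
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    n_signature_modules: int = 0
    signature_disease_fraction: float = 0.8
    gene_dropout: float = 0.0
    kb_params: KBParams = field(default_factory=KBParams)

    def disease_ids(self) -> list[str]:
        return [f"d{i:02d}" for i in range(self.n_diseases)]

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        lo, hi = self.module_size_range
        if min(self.n_genes, self.n_modules + 1, self.n_diseases) <= 0:
            raise ConfigurationError("counts must be positive")
        if lo < 1 or hi < lo:
            raise ConfigurationError("module_size_range must satisfy 1 <= min <= max")
        if hi > self.n_genes:
            raise ConfigurationError("module_size_range max exceeds n_genes")
        if self.samples_per_group < 2:
            raise ConfigurationError("samples_per_group must be >= 2")
        if not 0.0 <= self.gene_dropout < 1.0:
            raise ConfigurationError("gene_dropout must be in [0, 1)")
        known = set(self.disease_ids())
        for a, b, j in self.planted_pairs:
            if a not in known or b not in known:
                raise ConfigurationError(f"planted pair ({a}, {b}) references unknown disease")
            if not 0.0 <= j <= 1.0:
                raise ConfigurationError("planted-pair overlap must be in [0, 1]")
        for a, b, _k in self.kb_params.gene_overlaps + self.kb_params.drug_overlaps:
            if a not in known or b not in known:
                raise ConfigurationError(f"kb overlap ({a}, {b}) references unknown disease")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class GroundTruth:
    """Planted structure of a synthetic compendium.

    ``dysregulated`` maps disease -> {module_id: +1/-1}; ``signature_modules``
    maps module_id -> sign; ``correlated_pairs`` lists the planted
    (disease_a, disease_b, jaccard) triples; kb overlaps echo the planted
    knowledge-base intersections.
    """

    dysregulated: dict[str, dict[str, int]] = field(default_factory=dict)
    correlated_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    signature_modules: dict[str, int] = field(default_factory=dict)
    gene_overlaps: list[tuple[str, str, int]] = field(default_factory=list)
    drug_overlaps: list[tuple[str, str, int]] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            dysregulated={d: dict(m) for d, m in raw["dysregulated"].items()},
            correlated_pairs=[tuple(p) for p in raw["correlated_pairs"]],
            signature_modules=dict(raw["signature_modules"]),
            gene_overlaps=[tuple(p) for p in raw["gene_overlaps"]],
            drug_overlaps=[tuple(p) for p in raw["drug_overlaps"]],
        )


def generate_module_catalog(config: SimulationConfig) -> ModuleCatalog:
    """Random gene-module catalog: n_modules sets drawn from the gene pool.

    Module sizes are uniform over ``module_size_range``; genes are sampled
    without replacement within a module but may belong to many modules.
    """
    config.validate()
    rng = config._rng(_STREAM_CATALOG)
    genes = np.array(config.gene_ids())
    lo, hi = config.module_size_range
    modules: dict[str, list[str]] = {}
    for m in range(config.n_modules):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        modules[f"m{m:04d}"] = list(members)
    return ModuleCatalog(modules)


def _plant_module_sets(
    config: SimulationConfig, rng: np.random.Generator, module_ids: list[str]
) -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Choose dysregulated module sets honoring signature and pair overlaps."""
    diseases = config.disease_ids()
    pool = list(module_ids)
    rng.shuffle(pool)

    # signature modules come off the top of the shuffled pool, half up half down
    signature: dict[str, int] = {}
    for i in range(min(config.n_signature_modules, len(pool))):
        signature[pool.pop()] = 1 if i % 2 == 0 else -1

    dys: dict[str, dict[str, int]] = {d: {} for d in diseases}
    n_sig_dis = int(round(config.signature_disease_fraction * len(diseases)))
    for mod, sign in signature.items():
        hit = rng.choice(len(diseases), size=n_sig_dis, replace=False)
        for di in hit:
            dys[diseases[di]][mod] = sign

    m = config.modules_per_disease
    paired = {d for a, b, _ in config.planted_pairs for d in (a, b)}

    def draw(k: int) -> list[str]:
        take = pool[:k]
        if len(take) < k:
            raise ConfigurationError("not enough modules for the requested planting")
        del pool[:k]
        return take

    # planted pairs: shared block of size s with s/(2m - s) = jaccard
    for a, b, j in config.planted_pairs:
        s = int(round(2 * m * j / (1 + j))) if j > 0 else 0
        shared = draw(s)
        only_a = draw(m - s)
        only_b = draw(m - s)
        for mod in shared:
            sign = 1 if rng.random() < 0.5 else -1
            dys[a][mod] = sign
            dys[b][mod] = sign
        for mod in only_a:
            dys[a][mod] = 1 if rng.random() < 0.5 else -1
        for mod in only_b:
            dys[b][mod] = 1 if rng.random() < 0.5 else -1

    # remaining diseases: independent random module sets
    for d in diseases:
        if d in paired:
            continue
        avail = [mid for mid in pool]
        pick = rng.choice(len(avail), size=min(m, len(avail)), replace=False)
        for i in pick:
            dys[d][avail[i]] = 1 if rng.random() < 0.5 else -1
    return dys, signature


def generate_disease_compendium(
    config: SimulationConfig, catalog: ModuleCatalog
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Simulate all studies of all diseases plus the planted ground truth.

    Baseline expression is i.i.d. Gaussian(0, noise_sd); each study adds a
    per-gene batch offset Gaussian(0, experiment_offset_sd) shared by all
    its samples; genes of a disease's dysregulated modules are shifted by
    sign * effect_size * noise_sd in the disease samples only (summed when
    a gene sits in several dysregulated modules).  With ``gene_dropout``
    > 0 each gene-module effect is independently omitted with that
    probability.
    """
    config.validate()
    if len(catalog) == 0:
        raise ConfigurationError("catalog is empty")
    rng = config._rng(_STREAM_COMPENDIUM)
    genes = config.gene_ids()
    gene_pos = {g: i for i, g in enumerate(genes)}
    module_ids = catalog.module_ids

    if config.effect_size == 0:
        dys, signature = {d: {} for d in config.disease_ids()}, {}
    else:
        dys, signature = _plant_module_sets(config, rng, module_ids)

    studies: list[ExpressionStudy] = []
    nspg = config.samples_per_group
    for d in config.disease_ids():
        effect = np.zeros(len(genes))
        for mod, sign in dys[d].items():
            for g in catalog[mod]:
                if config.gene_dropout and rng.random() < config.gene_dropout:
                    continue
                effect[gene_pos[g]] += sign * config.effect_size * config.noise_sd
        spd = config.studies_per_disease
        n_studies = (
            int(rng.integers(spd[0], spd[1] + 1)) if isinstance(spd, tuple) else spd
        )
        for s in range(n_studies):
            study_id = f"{d}_s{s}"
            base = rng.normal(0.0, config.noise_sd, size=(len(genes), 2 * nspg))
            offsets = rng.normal(0.0, config.experiment_offset_sd, size=(len(genes), 1))
            base += offsets
            base[:, :nspg] += effect[:, None]  # first nspg columns are disease
            samples = [f"{study_id}_dis{j}" for j in range(nspg)] + [
                f"{study_id}_ctl{j}" for j in range(nspg)
            ]
            values = pd.DataFrame(
                base, index=pd.Index(genes, name="gene_id"), columns=samples
            )
            labels = pd.Series(
                [DISEASE] * nspg + [CONTROL] * nspg, index=values.columns
            )
            studies.append(ExpressionStudy(study_id, d, values, labels))

    truth = GroundTruth(
        dysregulated=dys,
        correlated_pairs=list(config.planted_pairs) if config.effect_size else [],
        signature_modules=signature,
        gene_overlaps=list(config.kb_params.gene_overlaps),
        drug_overlaps=list(config.kb_params.drug_overlaps),
    )
    return studies, truth


def _disjoint_sample(
    rng: np.random.Generator, pool: list[str], k: int, exclude: set[str]
) -> set[str]:
    avail = [x for x in pool if x not in exclude]
    if len(avail) < k:
        raise ConfigurationError("item pool exhausted while planting overlaps")
    idx = rng.choice(len(avail), size=k, replace=False)
    return {avail[i] for i in idx}


def generate_knowledge_base(config: SimulationConfig) -> KnowledgeBase:
    """Synthetic disease-gene / drug-target / drug-indication / family maps.

    Planted gene overlaps give the stated pairs exactly k shared disease
    genes (their remaining genes disjoint); planted drug overlaps give the
    stated pairs exactly k drugs indicated for both diseases, and no other
    drug is indicated for both members of a planted pair.
    """
    config.validate()
    rng = config._rng(_STREAM_KB)
    p = config.kb_params
    genes = config.gene_ids()
    diseases = config.disease_ids()
    m = p.genes_per_disease

    disease_genes: dict[str, set[str]] = {}
    claimed: set[str] = set()
    planted_gene = {(a, b): k for a, b, k in p.gene_overlaps}
    for a, b, k in p.gene_overlaps:
        if k > m:
            raise ConfigurationError("planted gene overlap exceeds genes_per_disease")
        shared = _disjoint_sample(rng, genes, k, claimed)
        claimed |= shared
        only_a = _disjoint_sample(rng, genes, m - k, claimed)
        claimed |= only_a
        only_b = _disjoint_sample(rng, genes, m - k, claimed)
        claimed |= only_b
        disease_genes[a] = shared | only_a
        disease_genes[b] = shared | only_b
    for d in diseases:
        if d not in disease_genes:
            disease_genes[d] = _disjoint_sample(rng, genes, m, claimed)
            claimed |= disease_genes[d]

    drug_ids = [f"drug{i:03d}" for i in range(p.n_drugs)]
    drug_targets = {
        drug: set(rng.choice(genes, size=p.targets_per_drug, replace=False))
        for drug in drug_ids
    }
    planted_drug_pairs = {frozenset((a, b)) for a, b, _ in p.drug_overlaps}
    drug_indications: dict[str, set[str]] = {}
    free = list(drug_ids)
    for a, b, k in p.drug_overlaps:
        if k > len(free):
            raise ConfigurationError("drug pool exhausted while planting overlaps")
        for _ in range(k):
            drug = free.pop()
            extra = p.indications_per_drug - 2
            others = _disjoint_sample(rng, diseases, max(extra, 0), {a, b}) if extra > 0 else set()
            drug_indications[drug] = {a, b} | others
    for drug in free:
        while True:
            ind = set(
                rng.choice(
                    diseases,
                    size=min(p.indications_per_drug, len(diseases)),
                    replace=False,
                )
            )
            if not any(pair <= ind for pair in planted_drug_pairs):
                break
        drug_indications[drug] = ind

    families = [f"fam{i:03d}" for i in range(p.n_families)]
    gene_families = {g: families[int(rng.integers(0, len(families)))] for g in genes}

    kb = KnowledgeBase(
        disease_genes=disease_genes,
        drug_targets=drug_targets,
        drug_indications=drug_indications,
        gene_families=gene_families,
    )
    # planted drug overlaps must come out exact; guard against accidental extras
    dd = kb.disease_drugs()
    for a, b, k in p.drug_overlaps:
        assert len(dd.get(a, set()) & dd.get(b, set())) == k
    for (a, b), k in planted_gene.items():
        assert len(disease_genes[a] & disease_genes[b]) == k
    return kb


def simulate_all(
    config: SimulationConfig, out_dir=None
) -> tuple[list[ExpressionStudy], ModuleCatalog, KnowledgeBase, GroundTruth]:
    """Generate catalog, compendium and knowledge base; optionally write them."""
    catalog = generate_module_catalog(config)
    studies, truth = generate_disease_compendium(config, catalog)
    kb = generate_knowledge_base(config)
    if out_dir is not None:
        from .enrichment import write_knowledge_base
        from .io import write_compendium
        from .modules import write_gmt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_compendium(studies, out_dir / "expression")
        write_gmt(catalog, out_dir / "modules.gmt")
        write_knowledge_base(kb, out_dir / "kb")
        truth.to_json(out_dir / "ground_truth.json")
    return studies, catalog, kb, truth
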