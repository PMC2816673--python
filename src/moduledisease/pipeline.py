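"""End-to-end pipeline: scores -> MRS -> similarity -> null -> signature -> enrichment.

A single :class:`PipelineConfig` (YAML-loadable) drives the whole
analysis; every stage writes its table under the output directory and a
manifest JSON records files, parameters, seed and per-file checksums so
reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as md_io
from .enrichment import (
    KnowledgeBase,
    all_disease_pairs,
    concordance_table,
    pairwise_drug_overlap,
    pairwise_gene_overlap,
    read_knowledge_base,
)
from .exceptions import ConfigurationError
from .expression import control_gene_z, gene_response_combined, zscore_normalize
from .modules import (
    assemble_matrices,
    compute_control_response,
    compute_mrs,
    read_gmt,
    write_matrix_tsv,
)
from .nulls import (
    build_median_null,
    build_null,
    fdr_at_threshold,
)
from .signature import select_signature
from .similarity import cluster_diseases, export_network, pairwise_disease_similarity
from .simulate import SimulationConfig, simulate_all

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and seed for one pipeline run.

    Either point ``expression_dir``/``gmt_path``/``kb_dir`` at existing
    inputs, or provide ``simulate`` (a :class:`SimulationConfig`) to
    generate them into the output directory first.
    """

    out_dir: str = "results"
    expression_dir: str | None = None
    gmt_path: str | None = None
    kb_dir: str | None = None
    simulate: SimulationConfig | None = None
    p_cut: float = 0.01
    mrs_threshold: float = 1.5
    min_diseases: int = 20
    min_genes: int = 2
    replicates: int = 100
    seed: int = 0

    def validate(self) -> None:
        if min(self.p_cut, self.mrs_threshold) <= 0 or self.min_genes < 1:
            raise ConfigurationError("thresholds must be positive")
        if self.simulate is None:
            for name in ("expression_dir", "gmt_path", "kb_dir"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ConfigurationError(
                        f"{name} missing or nonexistent and no simulate block given"
                    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            kb = sim.pop("kb_params", None)
            if kb is not None:
                from .simulate import KBParams

                sim["kb_params"] = KBParams(**kb)
            if "module_size_range" in sim:
                sim["module_size_range"] = tuple(sim["module_size_range"])
            if "planted_pairs" in sim:
                sim["planted_pairs"] = [tuple(p) for p in sim["planted_pairs"]]
            sim = SimulationConfig(**sim)
        return cls(simulate=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _derived_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(stream,)).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the output manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage 0: inputs (simulated or loaded)
    if config.simulate is not None:
        log.info("simulating inputs")
        studies, catalog, kb, _truth = simulate_all(config.simulate, out_dir=out / "input")
    else:
        studies = md_io.read_compendium(config.expression_dir)
        catalog = read_gmt(config.gmt_path)
        kb = read_knowledge_base(config.kb_dir)

    # stage 1+2: gene response scores and MRS/control matrices
    log.info("scoring %d studies", len(studies))
    by_disease: dict[str, list] = {}
    for s in studies:
        by_disease.setdefault(s.disease_id, []).append(s)
    vectors = []
    columns = {}
    for disease_id, group in by_disease.items():
        z_list = [zscore_normalize(s) for s in group]
        labels_list = [s.labels for s in group]
        grv = gene_response_combined(z_list, labels_list, disease_id)
        vectors.append(grv)
        ctrl_z = control_gene_z(z_list, labels_list)
        mrs_col, _ = compute_mrs(grv.scores, catalog, config.min_genes)
        ctrl_col, _ = compute_control_response(ctrl_z, catalog, config.min_genes)
        columns[disease_id] = (mrs_col, ctrl_col)
    mrs, ctrl = assemble_matrices(columns)
    md_io.write_scores(vectors, out / "scores.tsv")
    write_matrix_tsv(mrs, out / "mrs.tsv")
    write_matrix_tsv(ctrl, out / "control.tsv")

    # stage 3: pairwise partial-Spearman similarity
    sim = pairwise_disease_similarity(mrs, ctrl)

    # stage 4: randomization null, empirical p, FDR
    log.info("building null (%d replicates)", config.replicates)
    null = build_null(
        studies,
        catalog,
        replicates=config.replicates,
        seed=_derived_seed(config.seed, 1),
        min_genes=config.min_genes,
    )
    sim.assign_pvalues(null.values)
    sim.mark_significant(config.p_cut)
    observed = sim.pairs.rho.to_numpy(dtype=float)
    fdr = fdr_at_threshold(observed, null, config.p_cut)
    sim.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False, na_rep="NA")
    np.savetxt(out / "null_correlations.tsv", null.values, fmt="%.6g")
    with open(out / "fdr.json", "w") as fh:
        json.dump(
            {"p_threshold": config.p_cut, "fdr_percent": fdr,
             "n_significant": int(sim.pairs.significant.sum())},
            fh, indent=2,
        )

    # stage 5: clustering + network export
    dendro = cluster_diseases(sim)
    (out / "tree.nwk").write_text(dendro.to_newick() + "\n")
    export_network(sim, config.p_cut, out / "network.sif", out / "network_edges.tsv")

    # stage 6: signature modules
    median_null = build_median_null(
        studies,
        catalog,
        replicates=config.replicates,
        seed=_derived_seed(config.seed, 2),
        min_genes=config.min_genes,
    )
    sig = select_signature(
        mrs, median_null, config.p_cut, config.mrs_threshold, config.min_diseases
    )
    sig.to_csv(out / "signature.tsv", sep="\t", na_rep="NA")

    # stage 7: enrichment statistics
    enrich_dir = out / "enrich"
    enrich_dir.mkdir(exist_ok=True)
    sig_pairs = {
        (r.disease_a, r.disease_b) for r in sim.pairs.itertuples() if r.significant
    }
    pairs = all_disease_pairs(kb)
    gene_overlap = pairwise_gene_overlap(kb, pairs)
    drug_overlap = pairwise_drug_overlap(kb, pairs)
    gene_overlap.to_csv(enrich_dir / "gene_overlap.tsv", sep="\t", index=False)
    drug_overlap.to_csv(enrich_dir / "drug_overlap.tsv", sep="\t", index=False)
    summary: dict = {}
    if not gene_overlap.empty:
        table, fisher_p = concordance_table(sig_pairs, gene_overlap, config.p_cut)
        summary["concordance"] = {"table": table, "fisher_p": fisher_p}
    sig_modules = sig.index[sig.in_signature]
    sig_genes = {g for m in sig_modules for g in catalog[m]}
    if sig_genes:
        from .enrichment import diseases_treated_comparison, druggable_family_enrichment

        universe = set(g for mod in catalog.values() for g in mod)
        test = druggable_family_enrichment(kb, sig_genes, universe)
        summary["druggable_family"] = asdict(test)
        sig_targets = sig_genes & kb.all_drug_targets
        if sig_targets:
            mean_sig, mean_all, p = diseases_treated_comparison(
                kb, sig_targets, n_perm=2000, seed=_derived_seed(config.seed, 3)
            )
            summary["diseases_treated"] = {
                "mean_signature_targets": mean_sig,
                "mean_all_targets": mean_all,
                "p": p,
                "n_signature_targets": len(sig_targets),
            }
    with open(enrich_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    # manifest with checksums over every non-log output
    files = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "parameters": {
            "p_cut": config.p_cut,
            "mrs_threshold": config.mrs_threshold,
            "min_diseases": config.min_diseases,
            "min_genes": config.min_genes,
            "replicates": config.replicates,
        },
        "files": files,
        "checksums": {f: _sha256(out / f) for f in files},
        "fdr_percent": fdr,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
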