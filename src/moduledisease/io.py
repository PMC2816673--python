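"""Plain-text I/O for expression compendia and result tables.

Formats: one expression TSV per study (rows = genes, first column
gene_id, remaining columns samples), a sample-metadata TSV
(sample_id, study_id, disease_id, label), GMT for the module catalog
(see :mod:`moduledisease.modules`) and TSVs for the knowledge base
(see :mod:`moduledisease.enrichment`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .expression import ExpressionStudy, GeneResponseVector

META_COLUMNS = ["sample_id", "study_id", "disease_id", "label"]


def write_compendium(studies: list[ExpressionStudy], directory) -> None:
    """Write per-study expression TSVs plus a joint metadata.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for s in studies:
        s.values.to_csv(directory / f"{s.study_id}.tsv", sep="\t", index_label="gene_id")
        for sample in s.sample_ids:
            meta_rows.append((sample, s.study_id, s.disease_id, s.labels[sample]))
    pd.DataFrame(meta_rows, columns=META_COLUMNS).to_csv(
        directory / "metadata.tsv", sep="\t", index=False
    )


def read_compendium(directory, metadata_path=None) -> list[ExpressionStudy]:
    """Read the expression directory written by :func:`write_compendium`."""
    directory = Path(directory)
    meta = pd.read_csv(metadata_path or directory / "metadata.tsv", sep="\t", dtype=str)
    studies = []
    for study_id, group in meta.groupby("study_id", sort=True):
        values = pd.read_csv(directory / f"{study_id}.tsv", sep="\t", index_col="gene_id")
        labels = pd.Series(
            group.label.to_numpy(), index=pd.Index(group.sample_id, name="sample_id")
        )
        labels = labels.reindex(values.columns)
        disease_id = group.disease_id.iloc[0]
        studies.append(ExpressionStudy(str(study_id), str(disease_id), values, labels))
    return studies


def write_scores(vectors: list[GeneResponseVector], path) -> None:
    """Gene response scores as TSV: gene_id, disease_id, score, n_samples."""
    frames = []
    for v in vectors:
        df = pd.DataFrame(
            {
                "gene_id": v.scores.index,
                "disease_id": v.disease_id,
                "score": v.scores.to_numpy(),
                "n_samples": v.coverage.to_numpy(),
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_scores(path) -> list[GeneResponseVector]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    out = []
    for disease_id, group in df.groupby("disease_id", sort=True):
        idx = pd.Index(group.gene_id, name="gene_id")
        out.append(
            GeneResponseVector(
                disease_id=str(disease_id),
                scores=pd.Series(group.score.to_numpy(), index=idx, name="score"),
                coverage=pd.Series(
                    group.n_samples.to_numpy(dtype=int), index=idx, name="n_samples"
                ),
            )
        )
    return out
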