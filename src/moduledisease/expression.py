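"""Expression normalization and per-gene disease response scores.

Each disease is represented by one or more case/control expression studies
(experiments).  Every sample column is z-score normalized, making values
comparable across arrays and platforms.  The response score S_ik of gene i
in disease k is the t-statistic contrasting disease against control
samples; when a disease has several studies the score comes from a fixed-
effects regression

    Y = b0 + b1 * X + sum_k gamma_k * I_k + eps

where X is the disease indicator (1 = disease, 0 = control) and the I_k
are experiment indicators (reference-cell coding, first study absorbed
into the intercept).  S_ik is the t-statistic of b1; with a single study
this is exactly the pooled-variance two-sample t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateSampleError

__all__ = [
    "DISEASE",
    "CONTROL",
    "ExpressionStudy",
    "GeneResponseVector",
    "zscore_normalize",
    "gene_response_single",
    "gene_response_combined",
    "control_gene_z",
]

DISEASE = "disease"
CONTROL = "control"


@dataclass
class ExpressionStudy:
    """One experiment: a genes x samples matrix with case/control labels.

    ``values`` rows are genes, columns are samples; ``labels`` is indexed by
    sample id with entries 'disease' or 'control'.  Every study must have at
    least two disease and two control samples.
    """

    study_id: str
    disease_id: str
    values: pd.DataFrame
    labels: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.labels.index):
            raise ValueError(
                f"study {self.study_id!r}: sample columns and label index differ"
            )
        if self.values.index.has_duplicates:
            raise ValueError(f"study {self.study_id!r}: duplicate gene ids")
        bad = set(self.labels.unique()) - {DISEASE, CONTROL}
        if bad:
            raise ValueError(f"study {self.study_id!r}: unknown labels {sorted(bad)}")
        n_dis = int((self.labels == DISEASE).sum())
        n_ctl = int((self.labels == CONTROL).sum())
        if n_dis < 2 or n_ctl < 2:
            raise ValueError(
                f"study {self.study_id!r}: need >=2 disease and >=2 control "
                f"samples, got {n_dis} disease / {n_ctl} control"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def with_labels(self, labels: pd.Series) -> "ExpressionStudy":
        """Copy of the study with a replacement label vector."""
        return ExpressionStudy(self.study_id, self.disease_id, self.values, labels)


@dataclass
class GeneResponseVector:
    """Per-gene disease response scores for one disease.

    ``scores`` maps gene id -> t-statistic (NaN marks genes whose score is
    undefined, e.g. zero residual variance); ``coverage`` maps gene id ->
    total number of samples used.
    """

    disease_id: str
    scores: pd.Series
    coverage: pd.Series


def zscore_normalize(study: ExpressionStudy | pd.DataFrame) -> pd.DataFrame:
    """Z-score every sample column: z_ij = (g_ij - mean(g_j)) / sd(g_j).

    Sample standard deviation (ddof=1).  A constant column cannot be scaled
    and raises :class:`DegenerateSampleError` naming the sample.
    """
    values = study.values if isinstance(study, ExpressionStudy) else study
    sd = values.std(axis=0, ddof=1)
    degenerate = sd[(sd == 0) | sd.isna()]
    if len(degenerate):
        raise DegenerateSampleError(
            f"constant sample column(s): {list(degenerate.index)}"
        )
    return (values - values.mean(axis=0)) / sd


def _group_masks(labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    lab = labels.to_numpy()
    return lab == DISEASE, lab == CONTROL


def gene_response_single(z: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Pooled-variance two-sample t-statistic per gene (disease - control).

    Identical to the regression t of the disease coefficient in the single-
    study model.  Genes with zero pooled variance get NaN (a warning reports
    how many).
    """
    dis, ctl = _group_masks(labels)
    n1, n2 = int(dis.sum()), int(ctl.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 samples per group")
    x = z.to_numpy(dtype=float)
    m1 = x[:, dis].mean(axis=1)
    m2 = x[:, ctl].mean(axis=1)
    ss1 = ((x[:, dis] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x[:, ctl] - m2[:, None]) ** 2).sum(axis=1)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, np.nan)
    n_bad = int(np.isnan(t).sum())
    if n_bad:
        warnings.warn(f"{n_bad} gene(s) with zero pooled variance scored as missing")
    return pd.Series(t, index=z.index, name="t")


def _ols_t_disease(x_design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """t-statistic of the disease coefficient (column 1) for each column of y."""
    n, p = x_design.shape
    if n <= p or np.linalg.matrix_rank(x_design) < p:
        return np.full(y.shape[1], np.nan)
    xtx = x_design.T @ x_design
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (x_design.T @ y)
    resid = y - x_design @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    var_b1 = sigma2 * xtx_inv[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_b1 > 0, beta[1] / np.sqrt(var_b1), np.nan)
    return t


def gene_response_combined(
    z_list: list[pd.DataFrame],
    labels_list: list[pd.Series],
    disease_id: str = "",
) -> GeneResponseVector:
    """Combined disease response scores across one or more studies.

    For each gene, the model Y = b0 + b1*X + sum gamma_k*I_k is fitted by
    least squares over the concatenated samples of all studies containing
    the gene; the reported score is the t-statistic of b1.  Genes measured
    in only a subset of studies are scored on that subset (the indicator
    set shrinks accordingly).  Rank-deficient designs and zero residual
    variance yield NaN scores with a warning.
    """
    if not z_list or len(z_list) != len(labels_list):
        raise ValueError("z_list and labels_list must be non-empty and aligned")
    n_studies = len(z_list)

    # gene -> tuple of study indices containing it, preserving first-seen order
    membership: dict[str, list[int]] = {}
    for s, z in enumerate(z_list):
        for g in z.index:
            membership.setdefault(g, []).append(s)

    patterns: dict[tuple[int, ...], list[str]] = {}
    for g, studies in membership.items():
        patterns.setdefault(tuple(studies), []).append(g)

    scores: dict[str, float] = {}
    coverage: dict[str, int] = {}
    n_bad = 0
    for pat, genes in patterns.items():
        ys, xs, inds = [], [], []
        for j, s in enumerate(pat):
            z = z_list[s]
            ys.append(z.loc[genes].to_numpy(dtype=float).T)  # samples x genes
            dis, _ = _group_masks(labels_list[s])
            xs.append(dis.astype(float))
            one_hot = np.zeros((z.shape[1], len(pat) - 1))
            if j > 0:  # reference-cell coding: first study in pattern absorbed
                one_hot[:, j - 1] = 1.0
            inds.append(one_hot)
        y = np.vstack(ys)
        x1 = np.concatenate(xs)
        design = np.column_stack([np.ones_like(x1), x1, np.vstack(inds)])
        t = _ols_t_disease(design, y)
        n_obs = y.shape[0]
        n_bad += int(np.isnan(t).sum())
        for g, tv in zip(genes, t):
            scores[g] = float(tv)
            coverage[g] = n_obs
    if n_bad:
        warnings.warn(
            f"{n_bad} gene(s) with undefined combined t-statistic scored as missing"
        )
    idx = pd.Index(list(scores), name="gene_id")
    return GeneResponseVector(
        disease_id=disease_id,
        scores=pd.Series(scores, index=idx, name="score", dtype=float),
        coverage=pd.Series(coverage, index=idx, name="n_samples", dtype=int),
    )


def control_gene_z(
    z_list: list[pd.DataFrame], labels_list: list[pd.Series]
) -> pd.Series:
    """Per-gene mean z-score over all control samples across studies.

    Genes absent from every control sample are absent from the result.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for z, labels in zip(z_list, labels_list):
        _, ctl = _group_masks(labels)
        if not ctl.any():
            continue
        sub = z.to_numpy(dtype=float)[:, ctl]
        s = sub.sum(axis=1)
        for g, v in zip(z.index, s):
            sums[g] = sums.get(g, 0.0) + float(v)
            counts[g] = counts.get(g, 0) + sub.shape[1]
    idx = pd.Index(list(sums), name="gene_id")
    vals = [sums[g] / counts[g] for g in idx]
    return pd.Series(vals, index=idx, name="control_z", dtype=float)
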