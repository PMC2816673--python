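"""Functional-module catalog and Module Response Score matrices.

A functional module is a gene set standing in for a protein complex or
pathway.  The catalog of all modules is viewed as a bipartite gene-module
graph: a gene is linked to every module that contains it.  The Module
Response Score (MRS) of module i in disease k is the mean of the per-gene
disease response scores (t-statistics) of the module's member genes; the
companion control-response matrix holds the mean control z-score of the
same genes.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import GmtFormatError

__all__ = [
    "ModuleCatalog",
    "read_gmt",
    "write_gmt",
    "compute_mrs",
    "compute_control_response",
    "assemble_matrices",
]


class ModuleCatalog(Mapping):
    """Immutable mapping of module id -> tuple of member gene ids.

    Parameters
    ----------
    modules
        Mapping of module id to an ordered collection of gene ids.  Modules
        must be non-empty and may not contain duplicate genes; a gene may
        belong to several modules.
    descriptions
        Optional mapping of module id to a free-text description (kept for
        GMT round-trips).
    """

    def __init__(
        self,
        modules: Mapping[str, Sequence[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        clean: dict[str, tuple[str, ...]] = {}
        for mid, genes in modules.items():
            genes = tuple(genes)
            if not genes:
                raise ValueError(f"module {mid!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"module {mid!r} contains duplicate genes")
            clean[str(mid)] = tuple(str(g) for g in genes)
        self._modules = clean
        self._descriptions = dict(descriptions or {})

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, mid: str) -> tuple[str, ...]:
        return self._modules[mid]

    def __iter__(self) -> Iterator[str]:
        return iter(self._modules)

    def __len__(self) -> int:
        return len(self._modules)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModuleCatalog):
            return NotImplemented
        return self._modules == other._modules

    def __repr__(self) -> str:
        return f"ModuleCatalog({len(self)} modules, {len(self.genes())} genes)"

    # -- derived views ----------------------------------------------------
    @property
    def module_ids(self) -> list[str]:
        return list(self._modules)

    def description(self, mid: str) -> str:
        return self._descriptions.get(mid, "")

    def genes(self) -> list[str]:
        """Sorted union of all member genes."""
        out: set[str] = set()
        for genes in self._modules.values():
            out.update(genes)
        return sorted(out)

    def sizes(self) -> dict[str, int]:
        """Genes per module (one side of the bipartite degree sequence)."""
        return {mid: len(g) for mid, g in self._modules.items()}

    def gene_degrees(self) -> dict[str, int]:
        """Modules per gene (the other side of the degree sequence)."""
        deg: dict[str, int] = {}
        for genes in self._modules.values():
            for g in genes:
                deg[g] = deg.get(g, 0) + 1
        return deg

    def edges(self) -> list[tuple[str, str]]:
        """All (module_id, gene_id) membership links."""
        return [(mid, g) for mid, genes in self._modules.items() for g in genes]

    def membership_indices(self, gene_index: pd.Index) -> tuple[np.ndarray, np.ndarray]:
        """Row/column index arrays of the module x gene incidence matrix.

        Membership links whose gene is absent from ``gene_index`` are
        dropped.  Rows follow ``self.module_ids`` order.
        """
        pos = {g: i for i, g in enumerate(gene_index)}
        rows, cols = [], []
        for r, (mid, genes) in enumerate(self._modules.items()):
            for g in genes:
                c = pos.get(g)
                if c is not None:
                    rows.append(r)
                    cols.append(c)
        return np.asarray(rows, dtype=np.intp), np.asarray(cols, dtype=np.intp)


def read_gmt(path) -> ModuleCatalog:
    """Read a GMT gene-set file (module id, description, member genes)."""
    modules: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}: line {lineno}: expected id, description and at "
                    f"least one gene, got {len(fields)} field(s)"
                )
            mid, desc, genes = fields[0], fields[1], fields[2:]
            if mid in modules:
                raise GmtFormatError(f"{path}: line {lineno}: duplicate module id {mid!r}")
            modules[mid] = genes
            descriptions[mid] = desc
    return ModuleCatalog(modules, descriptions)


def write_gmt(catalog: ModuleCatalog, path) -> None:
    """Write a catalog as GMT; read_gmt(write_gmt(c)) == c."""
    with open(path, "w") as fh:
        for mid, genes in catalog.items():
            fh.write("\t".join([mid, catalog.description(mid), *genes]) + "\n")


def _module_means(
    values: pd.Series, catalog: ModuleCatalog, min_genes: int
) -> tuple[pd.Series, pd.Series]:
    """Mean of ``values`` over each module's genes, with a contributor count.

    Modules with fewer than ``min_genes`` finite contributing values are NaN.
    """
    rows, cols = catalog.membership_indices(values.index)
    v = values.to_numpy(dtype=float)
    n_mod = len(catalog)
    finite = np.isfinite(v[cols]) if len(cols) else np.empty(0, dtype=bool)
    counts = np.bincount(rows[finite], minlength=n_mod) if len(cols) else np.zeros(n_mod)
    sums = (
        np.bincount(rows[finite], weights=v[cols][finite], minlength=n_mod)
        if len(cols)
        else np.zeros(n_mod)
    )
    with np.errstate(invalid="ignore"):
        means = np.where(counts >= max(min_genes, 1), sums / np.maximum(counts, 1), np.nan)
    idx = pd.Index(catalog.module_ids, name="module_id")
    return pd.Series(means, index=idx), pd.Series(counts.astype(int), index=idx)


def compute_mrs(
    scores: pd.Series, catalog: ModuleCatalog, min_genes: int = 2
) -> tuple[pd.Series, pd.Series]:
    """One MRS column: per-module mean of gene response scores.

    Parameters
    ----------
    scores
        Gene response t-statistics indexed by gene id (NaN = unscored).
    catalog
        Module membership.
    min_genes
        Minimum number of scored member genes for a module entry to be
        reported; below it the entry is missing (NaN), never an error.

    Returns
    -------
    (mrs, n_genes_used) as aligned Series over the catalog's modules.
    """
    if scores.empty:
        raise ValueError("scores is empty")
    return _module_means(scores, catalog, min_genes)


def compute_control_response(
    control_z: pd.Series, catalog: ModuleCatalog, min_genes: int = 2
) -> tuple[pd.Series, pd.Series]:
    """One control-response column: per-module mean of control z-scores."""
    if control_z.empty:
        raise ValueError("control_z is empty")
    return _module_means(control_z, catalog, min_genes)


def assemble_matrices(
    columns: Mapping[str, tuple[pd.Series, pd.Series]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-disease (mrs, control) column pairs into aligned matrices.

    ``columns`` maps disease id -> (mrs_column, control_column), or is a
    sequence of such (disease_id, (mrs, control)) pairs; all columns must
    share the same module index.  Column order follows input order.
    """
    items = list(columns.items()) if isinstance(columns, Mapping) else list(columns)
    ids = [d for d, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate disease ids")
    mrs = pd.DataFrame({d: c[0] for d, c in items})
    ctrl = pd.DataFrame({d: c[1] for d, c in items})
    mrs.columns.name = ctrl.columns.name = "disease_id"
    return mrs, ctrl


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    """Matrix TSV with 'NA' as the missing-value token."""
    df.to_csv(path, sep="\t", na_rep="NA", index_label="module_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
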