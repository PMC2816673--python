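"""Common disease-state signature modules.

A module enters the signature by a two-stage filter: (1) the median of
its absolute MRS values across diseases is significantly higher than
expected under catalog randomization (empirical p below ``p_cut``), and
(2) it is strongly differentially expressed (|MRS| above
``mrs_threshold``) in at least ``min_diseases`` diseases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nulls import NullEnsemble, empirical_pvalues

__all__ = [
    "median_abs_mrs",
    "count_de_diseases",
    "select_signature",
]


def median_abs_mrs(mrs_row) -> float:
    """Median of |M_ik| over non-missing diseases (NaN if all missing)."""
    vals = np.asarray(mrs_row, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(np.median(np.abs(vals)))


def count_de_diseases(mrs_row, mrs_threshold: float) -> int:
    """Number of diseases with |M_ik| strictly above ``mrs_threshold``."""
    if mrs_threshold <= 0:
        raise ValueError("mrs_threshold must be positive")
    vals = np.asarray(mrs_row, dtype=float)
    vals = vals[np.isfinite(vals)]
    return int(np.sum(np.abs(vals) > mrs_threshold))


def select_signature(
    mrs: pd.DataFrame,
    null_ensemble: NullEnsemble,
    p_cut: float = 0.01,
    mrs_threshold: float = 1.5,
    min_diseases: int = 20,
) -> pd.DataFrame:
    """Apply the two-stage signature filter to an MRS matrix.

    ``null_ensemble`` must be a median-|MRS| null built with catalog
    randomization only (see :func:`moduledisease.nulls.build_median_null`).
    Returns one row per module with all intermediate statistics:
    median_abs_mrs, empirical_p, n_diseases_de and the in_signature flag
    (in_signature == (empirical_p < p_cut) and (n_diseases_de >= min_diseases)).
    """
    if null_ensemble is None:
        raise ValueError("a median-|MRS| null ensemble is required")
    if null_ensemble.kind != "median_abs_mrs":
        raise ValueError(
            f"expected a median_abs_mrs null ensemble, got {null_ensemble.kind!r}"
        )
    medians = np.array([median_abs_mrs(row) for _, row in mrs.iterrows()])
    pvals = empirical_pvalues(medians, null_ensemble.values)
    counts = np.array([count_de_diseases(row, mrs_threshold) for _, row in mrs.iterrows()])
    result = pd.DataFrame(
        {
            "median_abs_mrs": medians,
            "empirical_p": pvals,
            "n_diseases_de": counts,
        },
        index=pd.Index(mrs.index, name="module_id"),
    )
    result["in_signature"] = (result.empirical_p < p_cut) & (
        result.n_diseases_de >= min_diseases
    )
    result["in_signature"] = result["in_signature"].fillna(False)
    return result
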