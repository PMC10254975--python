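"""Reference-based blood cell-type deconvolution from methylation.

Estimates the proportions of the six major leukocyte subtypes (CD8 T
cells, CD4 T cells, natural killer cells, B cells, monocytes,
granulocytes) in each whole-blood sample by constrained projection of
the sample's beta values at a discriminating CpG panel onto
purified-cell reference profiles: per sample, minimise
``|| profile @ w - beta ||^2`` subject to ``w >= 0`` and (optionally)
``sum(w) = 1``.  The non-negative problem is solved by NNLS; the
sum-to-one constraint is applied by renormalisation.  The resulting
proportions enter the association design matrix as covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import expit

__all__ = ["CELL_TYPES", "estimate_cell_proportions", "generate_reference_panel"]

CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")

#: Dirichlet mean of a typical adult whole-blood leukocyte mix.
BLOOD_MEAN = {"CD8T": 0.08, "CD4T": 0.16, "NK": 0.06, "Bcell": 0.06,
              "Mono": 0.08, "Gran": 0.56}


def estimate_cell_proportions(
    beta: pd.DataFrame,
    panel: pd.DataFrame,
    sum_to_one: bool = True,
) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions.

    Parameters
    ----------
    beta
        CpG x sample beta matrix; only rows matching panel CpGs are used.
        Panel CpGs missing from ``beta`` are ignored (at least one must
        overlap).
    panel
        CpG x cell-type reference profile matrix with entries in [0, 1].
    sum_to_one
        Renormalise each sample's non-negative solution to sum to 1.

    Returns
    -------
    sample x cell-type proportion matrix.
    """
    if panel.shape[1] < 2:
        raise ValueError("reference panel needs at least 2 cell types")
    if panel.index.has_duplicates:
        raise ValueError("reference panel CpG ids must be unique")
    common = panel.index.intersection(beta.index)
    if len(common) == 0:
        raise ValueError("no overlap between panel CpGs and beta matrix rows")
    # sort for an ordering-invariant result
    common = common.sort_values()
    A = panel.loc[common].to_numpy(dtype=float)
    B = beta.loc[common].to_numpy(dtype=float)
    W = np.empty((beta.shape[1], panel.shape[1]))
    for i in range(B.shape[1]):
        w, _ = nnls(A, B[:, i])
        if sum_to_one:
            total = w.sum()
            w = w / total if total > 0 else np.full_like(w, 1.0 / len(w))
        W[i] = w
    return pd.DataFrame(W, index=beta.columns, columns=panel.columns)


def generate_reference_panel(
    cpg_ids,
    rng: np.random.Generator,
    cell_types=CELL_TYPES,
    separation: float = 2.0,
) -> pd.DataFrame:
    """Synthetic purified-cell reference profiles.

    Each cell type gets an independent logit-normal methylation profile
    over the given CpGs; ``separation`` scales the logit-space spread
    between types, so larger values make the panel more discriminating.
    """
    cpg_ids = pd.Index(cpg_ids)
    if cpg_ids.has_duplicates:
        raise ValueError("panel CpG ids must be unique")
    base = rng.normal(0.0, 1.0, size=(len(cpg_ids), 1))
    types = rng.normal(0.0, separation, size=(len(cpg_ids), len(cell_types)))
    return pd.DataFrame(
        expit(base + types), index=cpg_ids, columns=list(cell_types)
    )
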