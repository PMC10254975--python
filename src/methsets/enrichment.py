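"""Over-representation analysis of gene lists against a GMT database.

One-sided hypergeometric test per term: with a universe of N genes, K
of which belong to the term and a query of n genes overlapping the term
in k, p = P(X >= k) for X ~ Hypergeometric(N, K, n).  Up- and
downregulated gene lists are intended to be tested separately.  The
universe defaults to the genes actually measured (platform coverage
correction), not the whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .io import read_gmt
from .lm import bh_fdr

__all__ = ["AnnotationDB", "ora_test"]


@dataclass
class AnnotationDB:
    """Named gene sets restricted to a gene universe."""

    sets: dict          # term id -> (description, frozenset of genes)
    universe: frozenset

    @classmethod
    def from_gmt(cls, path, universe) -> "AnnotationDB":
        universe = frozenset(universe)
        raw = read_gmt(path)
        sets = {
            term: (desc, frozenset(genes) & universe)
            for term, (desc, genes) in raw.items()
        }
        return cls(sets=sets, universe=universe)


def ora_test(query, db: AnnotationDB, min_overlap: int = 1) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each DB term.

    Query genes outside the universe are dropped with a warning.  Terms
    overlapping the query in fewer than ``min_overlap`` genes are
    skipped.  Returns a table (term, name, k, K, n, N, p, fdr) sorted by
    p.
    """
    if len(db.universe) == 0:
        raise ValueError("empty gene universe")
    query = set(query)
    outside = query - db.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped"
        )
    query &= db.universe
    N, n = len(db.universe), len(query)
    rows = []
    for term, (desc, members) in db.sets.items():
        K = len(members)
        k = len(query & members)
        if k < min_overlap:
            continue
        # P(X >= k) = survival function at k-1
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "name": desc, "k": k, "K": K, "n": n, "N": N, "p": p})
    tab = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p"])
    tab["fdr"] = bh_fdr(tab["p"].to_numpy()) if len(tab) else []
    return tab.sort_values("p").reset_index(drop=True)
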