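"""Direction-by-region gene sets from EWAS results.

CpGs that reach family-wise (Bonferroni) significance and are annotated
to genes define 16 gene sets: for each of 8 genomic-region categories
(TSS1500, TSS200, 5'UTR, first exon, gene body, 3'UTR, exon boundary,
and promoter = TSS1500 + TSS200 + 5'UTR + first exon combined) one set
of genes carrying hypomethylated CpGs in that region and one carrying
hypermethylated CpGs.  Genes already detected as differentially
expressed (or supplied in a user blacklist) are removed, so the sets
probe coordinated expression changes missed by single-gene analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ARRAY_REGIONS",
    "REGION_CATEGORIES",
    "PROMOTER_PARTS",
    "GeneSet",
    "select_significant_dmps",
    "build_gene_sets",
]

#: region labels as annotated on the array
ARRAY_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "ExonBnd")
#: the promoter category is the union of these array labels
PROMOTER_PARTS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
#: the 8 categories over which sets are defined
REGION_CATEGORIES = ARRAY_REGIONS + ("Promoter",)
DIRECTIONS = ("hypo", "hyper")


@dataclass
class GeneSet:
    """Named gene set for one (region category, methylation direction)."""

    name: str
    region: str
    direction: str
    members: frozenset
    provenance: tuple = field(default_factory=tuple)  # (probe, gene) pairs

    def __len__(self) -> int:
        return len(self.members)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def select_significant_dmps(
    ewas: pd.DataFrame, n_tests: int, alpha: float = 0.05
) -> tuple[pd.DataFrame, list]:
    """Retain probes with p strictly below the Bonferroni threshold
    ``alpha / n_tests`` and classify their direction by coefficient sign
    (hypo < 0 < hyper).

    ``ewas`` needs columns ``coef`` and ``p`` indexed by probe id.
    Significant probes with a coefficient of exactly 0 have no defined
    direction; they are excluded and reported in the second return value.
    """
    thr = bonferroni_threshold(n_tests, alpha)
    sig = ewas[ewas["p"] < thr].copy()
    undefined = list(sig.index[sig["coef"] == 0])
    sig = sig[sig["coef"] != 0]
    sig["direction"] = np.where(sig["coef"] < 0, "hypo", "hyper")
    return sig[["coef", "p", "direction"]], undefined


def build_gene_sets(
    dmps: pd.DataFrame,
    annotation,
    exclude_genes=frozenset(),
) -> tuple[list[GeneSet], dict]:
    """Build the 16 (region category x direction) gene sets.

    A gene is a member of set (R, dir) when at least one significant
    probe with direction ``dir`` is annotated to that gene with region
    label in R (the promoter category unions the four promoter-proximal
    labels).  Multi-gene probes contribute to every linked gene;
    unannotated (intergenic) probes contribute nothing.  Genes in
    ``exclude_genes`` (e.g. FDR-significant DEGs) are removed.  Empty
    sets are kept with size 0.  The report counts contributing probes
    and exclusions.
    """
    exclude_genes = frozenset(exclude_genes)
    gene_map = annotation.gene_map
    known = set(annotation.probes.index)
    unknown = [p for p in dmps.index if p not in known]
    if unknown:
        raise KeyError(f"probes absent from annotation: {unknown[:5]}")

    links = gene_map[gene_map["probe"].isin(dmps.index)]
    links = links.merge(
        dmps[["direction"]], left_on="probe", right_index=True, how="inner"
    )

    sets: list[GeneSet] = []
    excluded_hits = set()
    for region in REGION_CATEGORIES:
        labels = PROMOTER_PARTS if region == "Promoter" else {region}
        in_region = links[links["region"].isin(labels)]
        for direction in DIRECTIONS:
            hits = in_region[in_region["direction"] == direction]
            kept = hits[~hits["gene"].isin(exclude_genes)]
            excluded_hits |= set(hits["gene"]) & exclude_genes
            sets.append(
                GeneSet(
                    name=f"{region}_{direction}",
                    region=region,
                    direction=direction,
                    members=frozenset(kept["gene"]),
                    provenance=tuple(
                        sorted(zip(kept["probe"], kept["gene"]))
                    ),
                )
            )
    report = {
        "n_dmps": int(len(dmps)),
        "n_dmps_gene_linked": int(links["probe"].nunique()),
        "n_excluded_genes_hit": len(excluded_hits),
        "excluded_genes_hit": sorted(excluded_hits),
        "set_sizes": {s.name: len(s) for s in sets},
    }
    return sets, report
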