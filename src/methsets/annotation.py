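"""Probe annotation: genomic location and per-(gene, region) links.

A probe may link to zero genes (intergenic), one gene, or several genes
(e.g. overlapping transcripts annotated "PALM2;PALM2-AKAP2"-style), and
each link carries its own region label, so a probe sitting in the body
of gene A and the TSS200 of gene B is represented exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ProbeAnnotation"]


@dataclass
class ProbeAnnotation:
    """Per-CpG location plus a tidy (probe, gene, region) link table."""

    probes: pd.DataFrame    # index: probe id; columns: chrom, pos
    gene_map: pd.DataFrame  # columns: probe, gene, region (one row per link)

    def __post_init__(self):
        missing = set(self.gene_map["probe"]) - set(self.probes.index)
        if missing:
            raise ValueError(f"gene_map names unknown probes: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(sorted(self.gene_map["gene"].unique()), name="gene")

    def links_for(self, probe: str) -> pd.DataFrame:
        return self.gene_map[self.gene_map["probe"] == probe]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per probe with ';'-joined genes/regions."""
        joined = (
            self.gene_map.groupby("probe")
            .agg(genes=("gene", ";".join), regions=("region", ";".join))
            if len(self.gene_map)
            else pd.DataFrame(columns=["genes", "regions"])
        )
        out = self.probes.join(joined)
        out[["genes", "regions"]] = out[["genes", "regions"]].fillna("")
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeAnnotation":
        rows = []
        for probe, r in df.iterrows():
            genes = str(r.get("genes", "") or "")
            regions = str(r.get("regions", "") or "")
            if genes and genes != "nan":
                for g, reg in zip(genes.split(";"), regions.split(";")):
                    rows.append({"probe": probe, "gene": g, "region": reg})
        gene_map = pd.DataFrame(rows, columns=["probe", "gene", "region"])
        return cls(probes=df[["chrom", "pos"]].copy(), gene_map=gene_map)
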