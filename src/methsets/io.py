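"""Plain-text I/O: TSV matrices and tables, GMT gene-set files.

Matrices are written as TSV with a header row and the feature id in the
first column; GMT is the standard tab-separated gene-set format
(set name, description, members).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "read_id_list",
]


def write_matrix(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_id_list(path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gmt(path) -> dict:
    """Parse GMT into {term: (description, [genes])}; duplicate term ids
    are an error."""
    sets: dict = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: GMT line needs name, description, members")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in sets:
            raise ValueError(f"{path}:{ln}: duplicate term id {term!r}")
        sets[term] = (desc, genes)
    return sets


def write_gmt(sets, path) -> None:
    """Write gene sets to GMT.  Accepts {term: (description, iterable)}
    or an iterable of objects with .name/.region/.direction/.members."""
    lines = []
    if isinstance(sets, dict):
        items = [(t, d, genes) for t, (d, genes) in sets.items()]
    else:
        items = [
            (s.name, f"{s.region}|{s.direction}", s.members) for s in sets
        ]
    for term, desc, genes in items:
        lines.append("\t".join([term, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")
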