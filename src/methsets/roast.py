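"""Self-contained rotation gene set testing of expression data.

Tests whether the genes of a set are, as a group, associated with the
tested design column (e.g. smoking status), using random rotations in
the subspace spanned by the tested effect and the residual space of the
linear model.  Rotation is the small-sample Monte-Carlo replacement for
permutation: one random unit direction is drawn per rotation and shared
across genes, which preserves inter-gene correlation — the property
that distinguishes rotation from gene-wise permutation.

Per gene the data are reduced to a (d+1)-vector ``z = (z_eff, z_res)``
where ``z_eff`` is the effect coordinate after adjusting for the other
covariates, ``z_res`` the d residual coordinates (d = residual df).
Moderated t-statistics use an empirical-Bayes variance prior (d0, s0^2)
estimated once from all genes and held fixed across rotations.  Set
statistics: up = mean(t), down = -mean(t), mixed = mean(|t|) (or mean
squared t).  p = (b + 1) / (nrot + 1) with b the number of rotations
whose statistic reaches the observed one.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lm import bh_fdr, estimate_prior, validate_design

__all__ = ["RoastConfig", "RoastResult", "roast_set", "roast_all_sets"]

HYPOTHESES = ("up", "down", "mixed")


@dataclass
class RoastConfig:
    """Rotation-test settings.

    ``nrot`` rotations give an achievable minimum p of 1/(nrot+1).
    ``set_statistic``: "mean" (mean moderated t; mixed = mean |t|) or
    "msq" (mean squared t for the mixed hypothesis).
    """

    nrot: int = 9999
    set_statistic: str = "mean"
    seed: int = 0
    hypotheses: tuple = HYPOTHESES

    def __post_init__(self):
        if self.nrot < 1:
            raise ValueError("nrot must be >= 1")
        if self.set_statistic not in ("mean", "msq"):
            raise ValueError("set_statistic must be 'mean' or 'msq'")
        bad = set(self.hypotheses) - set(HYPOTHESES)
        if bad:
            raise ValueError(f"unknown hypotheses: {sorted(bad)}")


@dataclass
class RoastResult:
    """Rotation-test output for one gene set."""

    name: str
    n_genes: int
    observed: dict
    p: dict
    fdr: dict = field(default_factory=dict)
    prop_up: float = float("nan")  # fraction of members with positive t


@dataclass
class _Reduction:
    """Expression data reduced to effect + residual coordinates, with the
    shared variance prior; computed once and reused across sets."""

    z_eff: pd.Series          # per gene effect coordinate
    z_res: np.ndarray         # gene x d residual coordinates
    norm2: np.ndarray         # per gene ||z||^2
    df: int
    d0: float
    s0_2: float

    def genes(self) -> pd.Index:
        return self.z_eff.index


def reduce_expression(E: pd.DataFrame, X: pd.DataFrame, test_column: str) -> _Reduction:
    """Rotate each gene's sample vector into the orthonormal basis given
    by the design's QR factorization (tested column last): one effect
    coordinate plus d residual coordinates.  The empirical-Bayes prior
    (d0, s0^2) is estimated from all genes here and held fixed."""
    if list(E.columns) != list(X.index):
        if set(E.columns) == set(X.index):
            E = E.loc[:, X.index]
        else:
            raise ValueError("expression columns and design rows differ")
    validate_design(X)
    if test_column not in X.columns:
        raise ValueError(f"tested column {test_column!r} not in design")
    cols = [c for c in X.columns if c != test_column] + [test_column]
    A = np.asarray(X[cols], dtype=float)
    n, p = A.shape
    Q, R = np.linalg.qr(A, mode="complete")
    sgn = np.sign(R[p - 1, p - 1]) or 1.0
    q_eff = sgn * Q[:, p - 1]          # effect direction, sign matched to coef
    U_res = Q[:, p:]                   # residual-space basis, n-p columns
    M = E.to_numpy(dtype=float)
    z_eff = M @ q_eff
    z_res = M @ U_res
    df = n - p
    norm2 = z_eff**2 + np.einsum("ij,ij->i", z_res, z_res)
    s2 = np.einsum("ij,ij->i", z_res, z_res) / df
    d0, s0_2 = estimate_prior(s2, df)
    return _Reduction(
        z_eff=pd.Series(z_eff, index=E.index),
        z_res=z_res,
        norm2=norm2,
        df=df,
        d0=d0,
        s0_2=s0_2,
    )


def _moderated_t(z1: np.ndarray, norm2: np.ndarray, red: _Reduction) -> np.ndarray:
    """Moderated t from effect coordinates and total squared norms.
    Residual variance is (||z||^2 - z1^2)/d; shrunk toward the prior."""
    s2 = np.maximum(norm2 - z1**2, 0.0) / red.df
    if np.isinf(red.d0):
        s2_post = np.full_like(s2, red.s0_2)
    else:
        s2_post = (red.d0 * red.s0_2 + red.df * s2) / (red.d0 + red.df)
    with np.errstate(divide="ignore", invalid="ignore"):
        return z1 / np.sqrt(s2_post)


def _set_stats(t: np.ndarray, statistic: str, axis: int = 0) -> dict:
    up = t.mean(axis=axis)
    mixed = (t**2).mean(axis=axis) if statistic == "msq" else np.abs(t).mean(axis=axis)
    return {"up": up, "down": -up, "mixed": mixed}


def roast_set(
    E: pd.DataFrame,
    X: pd.DataFrame,
    test_column: str,
    members,
    config: RoastConfig,
    _reduction: _Reduction | None = None,
    _rng: np.random.Generator | None = None,
) -> RoastResult | None:
    """Rotation test of one gene set; returns None (to be reported as
    skipped) when no member gene is present in the expression matrix."""
    red = _reduction if _reduction is not None else reduce_expression(E, X, test_column)
    idx = red.genes()
    present = idx.intersection(pd.Index(sorted(set(members))))
    if len(present) == 0:
        return None
    rng = _rng if _rng is not None else np.random.default_rng(config.seed)

    pos = idx.get_indexer(present)
    z1 = red.z_eff.to_numpy()[pos]
    zr = red.z_res[pos]
    norm2 = red.norm2[pos]
    t_obs = _moderated_t(z1, norm2, red)
    obs = {k: float(v) for k, v in _set_stats(t_obs, config.set_statistic).items()}

    Zm = np.column_stack([z1, zr])            # members x (d+1)
    dim = red.df + 1
    counts = {h: 0 for h in HYPOTHESES}
    remaining = config.nrot
    chunk = max(1, min(2000, int(4e7 // max(1, len(present)))))
    while remaining > 0:
        b = min(chunk, remaining)
        remaining -= b
        Rdir = rng.standard_normal((dim, b))
        Rdir /= np.linalg.norm(Rdir, axis=0, keepdims=True)
        Z1 = Zm @ Rdir                        # members x b rotated effect coords
        T = _moderated_t(Z1, norm2[:, None], red)
        rot = _set_stats(T, config.set_statistic)
        for h in HYPOTHESES:
            counts[h] += int(np.sum(rot[h] >= obs[h]))

    p = {
        h: (counts[h] + 1) / (config.nrot + 1)
        for h in HYPOTHESES
        if h in config.hypotheses
    }
    return RoastResult(
        name="",
        n_genes=int(len(present)),
        observed={h: obs[h] for h in config.hypotheses},
        p=p,
        prop_up=float(np.mean(t_obs > 0)),
    )


def _subseed(master_seed: int, members) -> np.random.Generator:
    """Reproducible per-set generator keyed by the master seed and the
    set's (sorted) membership, so identical sets share a rotation stream."""
    key = zlib.crc32(";".join(sorted(map(str, set(members)))).encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def roast_all_sets(
    E: pd.DataFrame,
    X: pd.DataFrame,
    test_column: str,
    sets,
    config: RoastConfig,
) -> pd.DataFrame:
    """Run :func:`roast_set` for every set and BH-adjust across sets
    separately within each hypothesis column.

    Returns a table with one row per input set (empty sets flagged with
    ``n_genes = 0`` and missing p-values).
    """
    red = reduce_expression(E, X, test_column)
    rows = []
    for gs in sets:
        members = gs.members if hasattr(gs, "members") else gs[1]
        name = gs.name if hasattr(gs, "name") else gs[0]
        res = roast_set(
            E, X, test_column, members, config,
            _reduction=red, _rng=_subseed(config.seed, members),
        )
        row = {
            "set": name,
            "region": getattr(gs, "region", ""),
            "direction": getattr(gs, "direction", ""),
            "n_genes": 0 if res is None else res.n_genes,
            "prop_up": np.nan if res is None else res.prop_up,
        }
        for h in HYPOTHESES:
            row[f"p.{h}"] = np.nan if res is None else res.p.get(h, np.nan)
        rows.append(row)
    tab = pd.DataFrame(rows).set_index("set")
    if len(tab) == 0 or tab["n_genes"].eq(0).all():
        import warnings

        warnings.warn("all gene sets are empty; nothing was tested")
    for h in HYPOTHESES:
        pcol = tab[f"p.{h}"]
        ok = pcol.notna()
        fdr = pd.Series(np.nan, index=tab.index)
        if ok.any():
            fdr[ok] = bh_fdr(pcol[ok].to_numpy())
        tab[f"FDR.{h}"] = fdr
    return tab
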