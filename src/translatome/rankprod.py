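"""Rank-product test for differential polysomal association.

For an unpaired tumour-vs-control design, every (tumour array, control
array) pair contributes one log2 fold-change column d = M_t - M_c.  Within
each column genes are ranked with 1 = most extreme in the requested
direction; the rank product of a gene is the geometric mean of its ranks
across columns.  Consistently extreme genes obtain rank products far below
what chance allows, which is quantified by a permutation null:

* ``scheme="columns"`` permutes every column independently across genes
  (the classical rank-product null, exact for independent replicate
  comparisons; it also admits exhaustive enumeration for tiny problems);
* ``scheme="arrays"`` permutes gene labels within each *array* of the
  underlying M-value table and recomputes all pairwise fold changes and
  ranks.  This preserves the correlation between comparison columns that
  share an array (all-pairs columns are strongly dependent) and is the
  calibrated default for the pipeline.

Each permutation null yields a p-value
``p_g = (1 + #{null RP <= RP_g}) / (1 + n_perm * G)`` and the percentage of
false prediction ``pfp_g = p_g * G / rank_g`` where rank_g is the gene's
position in the direction's ordered candidate list.  Every gene appears in
both the UP and the DOWN list.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .preprocess import MValueTable

logger = logging.getLogger(__name__)

MAX_EXHAUSTIVE = 200_000  # cap on (G!)^k for exhaustive enumeration


@dataclass
class FCMatrix:
    """Gene x comparison matrix of pairwise log2 fold changes."""

    data: pd.DataFrame
    pairs: list[tuple[str, str]]
    m: MValueTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.values).all():
            raise ValueError("non-finite fold changes")
        if len(self.pairs) != self.data.shape[1]:
            raise ValueError("pair provenance does not match column count")


@dataclass
class RankProdResult:
    """Per-gene fold change, ranks, p-values and pfp for both directions."""

    table: pd.DataFrame
    n_perm: int
    scheme: str


def pairwise_fold_changes(m: MValueTable) -> FCMatrix:
    """One column per (tumour array, control array) pair: M_t - M_c."""
    tum, ctl = m.tumour_arrays, m.control_arrays
    if not tum or not ctl:
        raise ValueError("need at least one tumour and one control array")
    cols = {}
    pairs = []
    for t in tum:
        for c in ctl:
            cols[f"{t}|{c}"] = m.values[t] - m.values[c]
            pairs.append((t, c))
    return FCMatrix(data=pd.DataFrame(cols), pairs=pairs, m=m)


def _ranks(d: np.ndarray, direction: str) -> np.ndarray:
    """Column-wise ranks, 1 = most extreme in ``direction``, ties averaged."""
    if direction == "up":
        return stats.rankdata(-d, axis=0)
    if direction == "down":
        return stats.rankdata(d, axis=0)
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def rank_product(fc: FCMatrix, direction: str = "up") -> pd.Series:
    """Geometric mean of within-column ranks."""
    r = _ranks(fc.data.values, direction)
    rp = np.exp(np.log(r).mean(axis=1))
    return pd.Series(rp, index=fc.data.index, name=f"rp_{direction}")


def _fast_ranks_both(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer up/down ranks via argsort (permuted continuous data: no ties)."""
    G, k = d.shape
    order = np.argsort(-d, axis=0)
    r_up = np.empty((G, k), dtype=np.int64)
    r_up[order, np.arange(k)] = np.arange(1, G + 1)[:, None]
    return r_up, G + 1 - r_up


def _null_logrp_columns(log_ranks: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Null log-RPs: permute each column's ranks independently.

    Columns are sorted first: a uniform permutation of a multiset does not
    depend on its input order, so this leaves the null distribution unchanged
    while making the sampled null exactly invariant to gene relabelling.
    """
    base = np.sort(log_ranks, axis=0)
    out = np.empty((n_perm, log_ranks.shape[0]))
    for i in range(n_perm):
        out[i] = rng.permuted(base, axis=0).mean(axis=1)
    return out.ravel()


def _null_logrp_arrays(
    m: MValueTable, pairs: list[tuple[str, str]], n_perm: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Null log-RPs for both directions by permuting genes within arrays."""
    arrays = list(m.values.columns)
    col_idx = {a: i for i, a in enumerate(arrays)}
    ti = np.array([col_idx[t] for t, _ in pairs])
    ci = np.array([col_idx[c] for _, c in pairs])
    M = m.values.values
    G = M.shape[0]
    n_arr = M.shape[1]
    log_table = np.concatenate([[np.nan], np.log(np.arange(1, G + 1))])
    base_idx = np.tile(np.arange(G)[:, None], (1, n_arr))
    arr_cols = np.arange(n_arr)
    up = np.empty((n_perm, G))
    dn = np.empty((n_perm, G))
    for i in range(n_perm):
        # explicit per-array gene permutations, drawn independently of the
        # data values so negating M negates the permuted matrix exactly
        idx = rng.permuted(base_idx, axis=0)
        Mp = M[idx, arr_cols]
        dp = Mp[:, ti] - Mp[:, ci]
        r_up, r_dn = _fast_ranks_both(dp)
        up[i] = log_table[r_up].mean(axis=1)
        dn[i] = log_table[r_dn].mean(axis=1)
    return up.ravel(), dn.ravel()


def _exhaustive_null_products(ranks: np.ndarray) -> np.ndarray:
    """Pooled null rank products over all per-column permutations."""
    G, k = ranks.shape
    if math.factorial(G) ** k > MAX_EXHAUSTIVE:
        raise ValueError("problem too large for exhaustive enumeration")
    perms = list(itertools.permutations(range(G)))
    cols = [ranks[:, j] for j in range(k)]
    out = []
    for assignment in itertools.product(perms, repeat=k):
        prod = np.ones(G)
        for j, p in enumerate(assignment):
            prod *= cols[j][list(p)]
        out.append(prod)
    return np.concatenate(out)


def permutation_pfp(
    fc: FCMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    direction: str = "up",
    scheme: str = "columns",
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Permutation p-values and pfp for one direction.

    Returns a DataFrame with ``rp``, ``rank``, ``pval`` and ``pfp``.  With
    ``exhaustive=True`` (columns scheme only) the null is enumerated over all
    per-column permutations and the p-value is the exact tail probability
    (no +1 smoothing); otherwise ``n_perm`` sampled permutations are used
    with +1 smoothing to avoid zero p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = fc.data.values
    G = d.shape[0]
    r = _ranks(d, direction)
    rp = np.exp(np.log(r).mean(axis=1))
    rank_pos = stats.rankdata(rp, method="ordinal").astype(int)

    if exhaustive:
        if scheme != "columns":
            raise ValueError("exhaustive enumeration is defined for scheme='columns'")
        null_prod = np.sort(_exhaustive_null_products(r))
        obs_prod = r.prod(axis=1)
        counts = np.searchsorted(null_prod, obs_prod, side="right")
        pval = counts / null_prod.size
    else:
        if seed is None:
            raise ValueError("seed is required for sampled permutations")
        rng = np.random.default_rng(seed)
        if scheme == "columns":
            null = np.sort(_null_logrp_columns(np.log(r), n_perm, rng))
        elif scheme == "arrays":
            if fc.m is None:
                raise ValueError("scheme='arrays' requires FCMatrix.m provenance")
            up_null, dn_null = _null_logrp_arrays(fc.m, fc.pairs, n_perm, rng)
            null = np.sort(up_null if direction == "up" else dn_null)
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        counts = np.searchsorted(null, np.log(rp), side="right")
        pval = (1.0 + counts) / (1.0 + n_perm * G)

    pfp = pval * G / rank_pos
    return pd.DataFrame(
        {"rp": rp, "rank": rank_pos, "pval": pval, "pfp": pfp}, index=fc.data.index
    )


def rank_product_test(
    m: MValueTable,
    n_perm: int = 1000,
    seed: int | None = None,
    scheme: str = "arrays",
    monotonize_pfp: bool = False,
) -> RankProdResult:
    """Full two-directional rank-product analysis of an M-value table.

    FC is reported on the linear scale, 2**mean(d) over all pairwise
    comparisons.  pfp is reported raw by default; ``monotonize_pfp`` applies
    a cumulative minimum from the bottom of each ranked list.
    """
    fc = pairwise_fold_changes(m)
    res = {}
    if scheme == "arrays":
        # one permutation pass yields the null for both directions
        if seed is None:
            raise ValueError("seed is required for sampled permutations")
        rng = np.random.default_rng(seed)
        up_null, dn_null = _null_logrp_arrays(m, fc.pairs, n_perm, rng)
        for direction, null in (("up", up_null), ("down", dn_null)):
            r = _ranks(fc.data.values, direction)
            rp = np.exp(np.log(r).mean(axis=1))
            rank_pos = stats.rankdata(rp, method="ordinal").astype(int)
            G = rp.size
            counts = np.searchsorted(np.sort(null), np.log(rp), side="right")
            pval = (1.0 + counts) / (1.0 + n_perm * G)
            res[direction] = pd.DataFrame(
                {"rp": rp, "rank": rank_pos, "pval": pval, "pfp": pval * G / rank_pos},
                index=fc.data.index,
            )
    else:
        for direction in ("up", "down"):
            res[direction] = permutation_pfp(
                fc, n_perm=n_perm, seed=seed, direction=direction, scheme=scheme
            )
    table = pd.DataFrame(
        {
            "FC": 2.0 ** fc.data.values.mean(axis=1),
            "rank_up": res["up"]["rank"],
            "rp_up": res["up"]["rp"],
            "pval_up": res["up"]["pval"],
            "pfp_up": res["up"]["pfp"],
            "rank_down": res["down"]["rank"],
            "rp_down": res["down"]["rp"],
            "pval_down": res["down"]["pval"],
            "pfp_down": res["down"]["pfp"],
        },
        index=fc.data.index,
    )
    table.index.name = "gene"
    if monotonize_pfp:
        for dcol, rcol in (("pfp_up", "rank_up"), ("pfp_down", "rank_down")):
            order = table[rcol].sort_values(ascending=False).index
            table.loc[order, dcol] = np.minimum.accumulate(table.loc[order, dcol])
    return RankProdResult(table=table, n_perm=n_perm, scheme=scheme)


def significant_genes(
    res: RankProdResult, fc_threshold: float = 2.0, pfp_threshold: float = 0.2
) -> tuple[list[str], list[str]]:
    """UP/DOWN gene lists at the fold-change and pfp thresholds.

    UP: linear FC >= fc_threshold and pfp_up < pfp_threshold; DOWN:
    FC <= 1/fc_threshold and pfp_down < pfp_threshold.  Sorted by rank.
    """
    if fc_threshold <= 0 or pfp_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    t = res.table
    up = t[(t["FC"] >= fc_threshold) & (t["pfp_up"] < pfp_threshold)]
    down = t[(t["FC"] <= 1.0 / fc_threshold) & (t["pfp_down"] < pfp_threshold)]
    return (
        list(up.sort_values("rank_up").index),
        list(down.sort_values("rank_down").index),
    )


def volcano_table(res: RankProdResult) -> pd.DataFrame:
    """Two-arm volcano table: every gene appears once per direction arm."""
    t = res.table
    arms = []
    for arm, pcol in (("up", "pval_up"), ("down", "pval_down")):
        arms.append(
            pd.DataFrame(
                {
                    "gene": t.index,
                    "FC": t["FC"].values,
                    "neg_log10_pval": -np.log10(t[pcol].values),
                    "arm": arm,
                }
            )
        )
    return pd.concat(arms, ignore_index=True)


def pearson_distance_matrix(m: MValueTable) -> pd.DataFrame:
    """Array x array matrix of 1 - Pearson correlation of M profiles."""
    v = m.values.values
    if v.shape[1] < 2:
        raise ValueError("need at least 2 arrays")
    sds = v.std(axis=0)
    for aid, sd in zip(m.values.columns, sds):
        if sd == 0:
            raise ValueError(f"array {aid!r} has zero variance")
    d = 1.0 - np.corrcoef(v.T)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=m.values.columns, columns=m.values.columns)


def average_linkage_tree(dist: pd.DataFrame) -> str:
    """Average-linkage agglomeration of a distance matrix, as Newick."""
    condensed = squareform(np.clip(dist.values, 0, None), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    tree = hierarchy.to_tree(Z)
    labels = list(dist.index)

    def _newick(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = _newick(node.left, node.dist)
        right = _newick(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({_newick(tree.left, tree.dist)},{_newick(tree.right, tree.dist)});"
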