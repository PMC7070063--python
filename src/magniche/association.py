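"""Patristic distances and (partial) Mantel permutation tests.

The Mantel statistic is the Spearman correlation over the upper-triangle
entries of two distance matrices; its null distribution comes from jointly
permuting rows and columns of the first matrix.  Tests are one-sided
(positive association) with the add-one rule, so p >= 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import rankdata

INTER_DOMAIN_DISTANCE = 5.0


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_perm: int
    n_entities: int


def patristic_distances(
    trees: dendropy.Tree | list[dendropy.Tree],
    domains: dict[str, str] | None = None,
    inter_domain: float = INTER_DOMAIN_DISTANCE,
) -> pd.DataFrame:
    """Tip-to-tip path-length sums; cross-domain pairs get a constant.

    ``trees`` is one tree or one per domain; ``domains`` maps tip label to
    a domain name (all tips of one tree must share a domain).  Pairs whose
    tips live in different domains (hence different trees) are assigned
    ``inter_domain`` (chosen above any within-tree distance).
    """
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    tip_domain: dict[str, str] = {}
    tip_tree: dict[str, dendropy.Tree] = {}
    for k, tree in enumerate(trees):
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            tip_tree[label] = tree
            tip_domain[label] = (
                domains.get(label, f"tree{k}") if domains else f"tree{k}"
            )
    taxa = sorted(tip_tree)
    if not taxa:
        raise ValueError("no labeled tips found on any tree")

    pdms = {id(t): t.phylogenetic_distance_matrix() for t in trees}
    leaf_lookup = {
        (id(t), leaf.taxon.label): leaf.taxon
        for t in trees
        for leaf in t.leaf_node_iter()
    }
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = taxa[i], taxa[j]
            if tip_domain[a] != tip_domain[b]:
                d = inter_domain
            else:
                tree = tip_tree[a]
                d = pdms[id(tree)].patristic_distance(
                    leaf_lookup[(id(tree), a)], leaf_lookup[(id(tree), b)]
                )
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=taxa, columns=taxa)


def _aligned(*matrices: pd.DataFrame) -> tuple[np.ndarray, ...]:
    ids = list(matrices[0].index)
    for m in matrices[1:]:
        if set(m.index) != set(ids):
            raise ValueError("distance matrices cover different entity sets")
    arrays = []
    for m in matrices:
        a = m.loc[ids, ids].to_numpy(dtype=float)
        if not np.allclose(a, a.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        arrays.append(a)
    return tuple(arrays)


def _triu_ranks(matrix: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    ranks = rankdata(matrix[rows, cols])
    ranks = ranks - ranks.mean()
    norm = np.sqrt((ranks**2).sum())
    if norm == 0:
        raise ValueError("constant distance matrix")
    return ranks / norm


def mantel(
    dx: pd.DataFrame,
    dy: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
) -> MantelResult:
    """One-sided Mantel test with Spearman statistic.

    p = (1 + #{permutations with rho >= observed}) / (1 + n_perm), null
    generated by jointly permuting rows and columns of ``dx``.
    """
    x, y = _aligned(dx, dy)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 entities")
    rows, cols = np.triu_indices(n, k=1)
    ry = _triu_ranks(y, rows, cols)
    rx = _triu_ranks(x, rows, cols)
    observed = float(rx @ ry)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = _triu_ranks(x[np.ix_(perm, perm)], rows, cols)
        if rp @ ry >= observed - 1e-12:
            hits += 1
    return MantelResult(
        statistic=observed,
        p_value=(1 + hits) / (1 + n_perm),
        n_perm=n_perm,
        n_entities=n,
    )


def _partial_stat(rx: np.ndarray, ry: np.ndarray, rz: np.ndarray) -> float:
    r_xy = float(rx @ ry)
    r_xz = float(rx @ rz)
    r_yz = float(ry @ rz)
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        raise ValueError("degenerate partial correlation: |rho| = 1 with control")
    return (r_xy - r_xz * r_yz) / np.sqrt(denom)


def partial_mantel(
    dx: pd.DataFrame,
    dy: pd.DataFrame,
    dz: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
    method: str = "raw",
) -> MantelResult:
    """Partial Mantel test: Spearman association of dx and dy given dz.

    Statistic rho_xy.z = (rho_xy - rho_xz rho_yz)/sqrt((1-rho_xz^2)(1-rho_yz^2))
    over upper-triangle rank vectors; one-sided add-one p.  ``method``
    selects the null: "raw" permutes ``dx`` rows+columns and recomputes;
    "residual" permutes the matrix of dx-on-dz regression residuals
    instead (Freedman-Lane style).
    """
    if method not in ("raw", "residual"):
        raise ValueError("method must be 'raw' or 'residual'")
    x, y, z = _aligned(dx, dy, dz)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 entities")
    rows, cols = np.triu_indices(n, k=1)
    ry = _triu_ranks(y, rows, cols)
    rz = _triu_ranks(z, rows, cols)
    rx = _triu_ranks(x, rows, cols)
    observed = _partial_stat(rx, ry, rz)

    perm_source = x
    if method == "residual":
        xv, zv = x[rows, cols], z[rows, cols]
        beta = np.polyfit(zv, xv, 1)
        resid = xv - np.polyval(beta, zv)
        perm_source = np.zeros_like(x)
        perm_source[rows, cols] = resid
        perm_source = perm_source + perm_source.T

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = _triu_ranks(perm_source[np.ix_(perm, perm)], rows, cols)
        if _partial_stat(rp, ry, rz) >= observed - 1e-12:
            hits += 1
    return MantelResult(
        statistic=observed,
        p_value=(1 + hits) / (1 + n_perm),
        n_perm=n_perm,
        n_entities=n,
    )
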