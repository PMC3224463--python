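"""Phylogenetically independent contrasts and zero-intercept trait correlation.

Closely related species inherit similar trait values, so naive cross-species
correlations overweight dense clades.  Felsenstein's independent contrasts
remove this pseudo-replication: assuming traits evolve by Brownian motion on
the tree, standardized differences at the internal nodes are mutually
independent with equal variance.

The pruning recursion: for sibling subtrees i, j with values x_i, x_j and
(extended) branch lengths v_i, v_j, emit the standardized contrast

    c = (x_i - x_j) / sqrt(v_i + v_j)

set the ancestral value to the precision-weighted mean
(x_i/v_i + x_j/v_j)/(1/v_i + 1/v_j), and inflate the parent branch by
v_i v_j/(v_i + v_j).  Multifurcations are resolved with zero-length
bifurcations (logged).

Because the sign of each contrast depends on an arbitrary child ordering,
correlations between two contrast sets are computed after jointly flipping
each pair so the x-member is nonnegative, and the regression is forced
through the origin: if one trait did not change at a node, no change is
expected in the other.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastSet",
    "CorrelationResult",
    "parse_newick",
    "compute_contrasts",
    "correlate_contrasts",
    "run_trait_correlations",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts, one per internal bifurcation (postorder)."""

    node_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.node_ids) != len(self.values):
            raise ValueError("node_ids and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite contrast values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CorrelationResult:
    spearman_rho: float
    p_value: float
    r_squared_origin: float
    slope_origin: float
    n_contrasts: int
    spearman_rho_plain: float
    p_value_plain: float


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree, requiring branch lengths everywhere.

    Raises ValueError on malformed text, duplicate tip labels, or any
    non-root edge lacking a branch length.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(lbl is None for lbl in labels):
        raise ValueError("unlabelled tip in Newick input")
    dupes = {lbl for lbl in labels if labels.count(lbl) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            where = node.taxon.label if node.taxon else "an internal node"
            raise ValueError(f"missing branch length above {where}")
        if node.edge.length < 0:
            raise ValueError(f"negative branch length above {node}")
    return tree


def _resolved_clone(tree: dendropy.Tree) -> dendropy.Tree:
    """Deterministic binary resolution: any multifurcation is split by
    grouping the first two children under a zero-length node."""
    tree = tree.clone(depth=1)
    resolved = 0
    for node in list(tree.preorder_node_iter()):
        while len(node.child_nodes()) > 2:
            c1, c2 = node.child_nodes()[:2]
            node.remove_child(c1)
            node.remove_child(c2)
            joint = dendropy.Node()
            joint.add_child(c1)
            joint.add_child(c2)
            joint.edge.length = 0.0
            node.insert_child(0, joint)
            resolved += 1
    if resolved:
        logger.info("resolved %d multifurcation(s) with zero-length branches", resolved)
    return tree


def compute_contrasts(
    tree: dendropy.Tree, trait: Mapping[str, float]
) -> ContrastSet:
    """Felsenstein pruning over one trait; n_tips - 1 contrasts on a binary tree."""
    work = _resolved_clone(tree)
    for leaf in work.leaf_node_iter():
        if leaf.taxon.label not in trait:
            raise KeyError(f"no trait value for tip {leaf.taxon.label!r}")
    node_ids: list[str] = []
    values: list[float] = []
    counter = itertools.count(1)

    def prune(node: dendropy.Node) -> tuple[float, float]:
        edge = node.edge.length if node.edge.length is not None else 0.0
        children = node.child_nodes()
        if not children:
            return float(trait[node.taxon.label]), edge
        if len(children) == 1:  # degree-2 node: pass through, lengths add
            x, v = prune(children[0])
            return x, v + edge
        (x1, v1), (x2, v2) = (prune(c) for c in children)
        denom = v1 + v2
        if denom <= 0:
            raise ValueError(
                "both sibling branches have zero length; "
                "standardized contrast undefined"
            )
        node_ids.append(node.label or f"node{next(counter)}")
        values.append((x1 - x2) / math.sqrt(denom))
        anc = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2) if v1 > 0 and v2 > 0 else (
            x2 if v1 == 0 else x1
        )
        return anc, edge + v1 * v2 / denom

    prune(work.seed_node)
    return ContrastSet(node_ids=tuple(node_ids), values=np.asarray(values))


def _positivize(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sign = np.where(x < 0, -1.0, 1.0)
    return x * sign, y * sign


def _spearman_t_p(rho: float, n: int) -> float:
    """Two-sided p for Spearman rho via the t-approximation with n-1 df
    (one parameter is spent on the through-origin slope)."""
    df = n - 1
    if df <= 0 or math.isnan(rho):
        return math.nan
    if abs(rho) >= 1.0:
        return 0.0
    t = abs(rho) * math.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(t, df))


def exact_spearman_p(cx: ContrastSet, cy: ContrastSet) -> float:
    """Exact permutation two-sided p for Spearman's rho on positivized pairs.

    Enumerates all n! orderings; practical for n <= 10 (slow at the top end).
    """
    if len(cx) != len(cy):
        raise ValueError("contrast count mismatch")
    n = len(cx)
    if n > 10:
        raise ValueError("exact permutation p supported for n <= 10")
    x, y = _positivize(cx.values, cy.values)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        total += 1
        if r >= obs - 1e-12:
            count += 1
    return count / total


def correlate_contrasts(cx: ContrastSet, cy: ContrastSet) -> CorrelationResult:
    """Zero-intercept correlation between two contrast sets.

    Reports through-origin slope Σxy/Σx² and uncentred R² = (Σxy)²/(Σx²Σy²),
    Spearman's rho (midrank ties) on the jointly positivized pairs with a
    t-approximate p (df = n-1), and the plain Spearman on the raw pairs.
    """
    if len(cx) != len(cy):
        raise ValueError(f"contrast count mismatch: {len(cx)} vs {len(cy)}")
    n = len(cx)
    if n < 2:
        raise ValueError("need at least 2 contrasts")
    x_raw, y_raw = cx.values, cy.values
    x, y = _positivize(x_raw, y_raw)
    sxx = float(x @ x)
    syy = float(y @ y)
    sxy = float(x @ y)
    slope = sxy / sxx if sxx > 0 else math.nan
    r2 = (sxy * sxy) / (sxx * syy) if sxx > 0 and syy > 0 else 0.0
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        rho = math.nan
    else:
        rho = float(stats.spearmanr(x, y).statistic)
    p = _spearman_t_p(rho, n)
    if np.ptp(x_raw) == 0 or np.ptp(y_raw) == 0:
        rho_plain, p_plain = math.nan, math.nan
    else:
        plain = stats.spearmanr(x_raw, y_raw)
        rho_plain, p_plain = float(plain.statistic), float(plain.pvalue)
    return CorrelationResult(
        spearman_rho=rho,
        p_value=p,
        r_squared_origin=r2,
        slope_origin=slope,
        n_contrasts=n,
        spearman_rho_plain=rho_plain,
        p_value_plain=p_plain,
    )


def run_trait_correlations(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Contrast correlations for the requested trait-column pairs.

    ``traits`` is indexed by species (tree tip labels).  Species missing a
    value for either trait of a pair are pruned from the tree for that pair
    (logged); fewer than 3 remaining species is an error.
    """
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = set(traits.index) - tip_labels
    if unknown:
        raise KeyError(f"trait species not on the tree: {sorted(unknown)}")
    rows = []
    for col_x, col_y in pairs:
        for col in (col_x, col_y):
            if col not in traits.columns:
                raise KeyError(f"trait column {col!r} not in table")
        cols = [col_x] if col_x == col_y else [col_x, col_y]
        sub = traits[cols].dropna()
        keep = sorted(set(sub.index))
        if len(keep) < 3:
            raise ValueError(
                f"pair ({col_x}, {col_y}): only {len(keep)} species with both "
                "traits; need >= 3"
            )
        if len(keep) < len(tip_labels):
            logger.info(
                "pair (%s, %s): pruning %d species lacking trait values",
                col_x,
                col_y,
                len(tip_labels) - len(keep),
            )
            work = tree.extract_tree_with_taxa_labels(keep)
        else:
            work = tree
        cx = compute_contrasts(work, sub[col_x].to_dict())
        cy = cx if col_y == col_x else compute_contrasts(work, sub[col_y].to_dict())
        res = correlate_contrasts(cx, cy)
        rows.append(
            {
                "trait_x": col_x,
                "trait_y": col_y,
                "n_contrasts": res.n_contrasts,
                "spearman_rho": res.spearman_rho,
                "p_value": res.p_value,
                "r_squared_origin": res.r_squared_origin,
                "slope_origin": res.slope_origin,
                "spearman_rho_plain": res.spearman_rho_plain,
                "p_value_plain": res.p_value_plain,
            }
        )
    return pd.DataFrame(rows)
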