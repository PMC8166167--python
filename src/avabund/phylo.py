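"""Phylogenetic signal in species-level traits: Blomberg's K.

K compares the observed ratio of the ordinary trait variance to the
phylogenetically corrected variance with its expectation under Brownian
motion on the given tree.  K ~ 1 under BM, K ~ 0 when trait values are
unrelated to the phylogeny.  Significance comes from a tip-shuffling
randomization test, and results over a posterior sample of trees are
pooled with Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from ._utils import as_rng


@dataclass
class PhyloVCV:
    """Brownian-motion variance–covariance structure of a rooted tree.

    ``C[i, j]`` is the shared branch length from the root to the most recent
    common ancestor of tips i and j; the diagonal holds root-to-tip
    distances.
    """

    tips: list[str]
    C: np.ndarray
    depth: float

    @classmethod
    def from_tree(cls, tree: dendropy.Tree, terminal_epsilon: float = 1e-8
                  ) -> "PhyloVCV":
        """Build the VCV by one preorder pass over node depths.

        Zero-length terminal branches get ``terminal_epsilon`` added so C
        stays invertible.
        """
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        n = len(tips)
        idx = {label: i for i, label in enumerate(tips)}
        C = np.zeros((n, n))

        depth: dict[int, float] = {}
        for nd in tree.preorder_node_iter():
            # the stem edge above the root is shared by all tips; excluded
            el = 0.0 if nd.parent_node is None else (nd.edge.length or 0.0)
            if nd.is_leaf() and el <= 0:
                el += terminal_epsilon
            depth[id(nd)] = (depth.get(id(nd.parent_node), 0.0)
                             if nd.parent_node is not None else 0.0) + el

        # postorder: the MRCA depth of tips in different child subtrees
        below: dict[int, np.ndarray] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                i = idx[nd.taxon.label]
                C[i, i] = depth[id(nd)]
                below[id(nd)] = np.array([i])
            else:
                kids = [below.pop(id(ch)) for ch in nd.child_nodes()]
                d = depth[id(nd)]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        C[np.ix_(kids[a], kids[b])] = d
                        C[np.ix_(kids[b], kids[a])] = d
                below[id(nd)] = np.concatenate(kids)
        return cls(tips=tips, C=C, depth=float(np.max(np.diag(C))))


def _align_trait(trait, tips: list[str]) -> np.ndarray:
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    if isinstance(trait, dict):
        missing = [t for t in tips if t not in trait]
        extra = [t for t in trait if t not in set(tips)]
        if missing or extra:
            raise ValueError(
                f"trait/tip mismatch; missing from trait: {missing[:5]}, "
                f"not on tree: {extra[:5]}")
        return np.array([float(trait[t]) for t in tips])
    x = np.asarray(trait, dtype=float)
    if x.shape != (len(tips),):
        raise ValueError("unnamed trait vector must match tip count")
    return x


def _as_vcv(tree) -> PhyloVCV:
    return tree if isinstance(tree, PhyloVCV) else PhyloVCV.from_tree(tree)


def _k_statistic(x: np.ndarray, cho, u: np.ndarray, denom: float,
                 expected: float) -> float:
    n = x.size
    mse0 = np.sum((x - x.mean()) ** 2) / (n - 1)
    a_hat = float(u @ x) / denom
    w = cho_solve(cho, x)
    mse = (float(x @ w) - a_hat * a_hat * denom) / (n - 1)
    if mse <= 0:
        raise np.linalg.LinAlgError("non-positive phylogenetic MSE")
    return (mse0 / mse) / expected


def _k_setup(vcv: PhyloVCV):
    n = len(vcv.tips)
    try:
        cho = cho_factor(vcv.C)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("singular phylogenetic covariance") from exc
    u = cho_solve(cho, np.ones(n))
    denom = float(u.sum())
    expected = (np.trace(vcv.C) - n / denom) / (n - 1)
    return cho, u, denom, expected


def blomberg_k(tree, trait) -> float:
    """Blomberg's K of a tip trait on a rooted tree with branch lengths.

    With C the BM covariance matrix, the phylogenetic mean is
    a = (1'C^-1 x)/(1'C^-1 1); K is the ratio MSE0/MSE of the ordinary to
    the phylogenetically corrected mean squared error, divided by its BM
    expectation (tr C - n / 1'C^-1 1) / (n - 1).
    """
    vcv = _as_vcv(tree)
    x = _align_trait(trait, vcv.tips)
    if x.size < 3:
        raise ValueError("Blomberg's K needs at least 3 tips")
    if np.var(x) == 0:
        raise ValueError("trait has zero variance")
    cho, u, denom, expected = _k_setup(vcv)
    return _k_statistic(x, cho, u, denom, expected)


def k_randomization_test(
    tree, trait, nperm: int = 999, seed=None, return_null: bool = False
):
    """One-sided tip-shuffling test of K against the no-signal null.

    p = (1 + #{K* >= K_obs}) / (nperm + 1) over ``nperm`` random
    permutations of trait values across tips.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    rng = as_rng(seed)
    vcv = _as_vcv(tree)
    x = _align_trait(trait, vcv.tips)
    cho, u, denom, expected = _k_setup(vcv)
    k_obs = _k_statistic(x, cho, u, denom, expected)
    null = np.empty(nperm)
    for i in range(nperm):
        null[i] = _k_statistic(rng.permutation(x), cho, u, denom, expected)
    p = (1.0 + np.sum(null >= k_obs)) / (nperm + 1.0)
    if return_null:
        return k_obs, float(p), null
    return k_obs, float(p)


@dataclass
class PooledSignal:
    """Rubin-pooled phylogenetic-signal result over a set of trees."""

    k_pooled: float
    se_pooled: float
    p_pooled: float
    m_trees: int
    per_tree: pd.DataFrame = field(repr=False)


def pool_across_trees(
    k_values,
    p_values,
    within_var=None,
    df: int = 999,
) -> PooledSignal:
    """Pool per-tree (K, p) pairs with Rubin's rules.

    K: pooled estimate is the mean; total variance is the mean within-tree
    variance (variance of each tree's permutation distribution of K, 0 if
    not supplied) plus (1 + 1/m) times the between-tree variance.

    p: each p is mapped to a t statistic via the two-sided inverse t with
    ``df`` degrees of freedom (the permutation count), the statistics are
    Rubin-pooled with unit within-variance, and the pooled statistic is
    mapped back to a two-sided p (Licht–Rubin).  Not strictly monotone in
    every per-tree p for extreme mixtures; see the methods note.
    """
    k = np.asarray(k_values, dtype=float)
    p = np.asarray(p_values, dtype=float)
    m = k.size
    if m < 2 or p.size != m:
        raise ValueError("need matching K and p for at least 2 trees")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    if within_var is None:
        wv = np.zeros(m)
    else:
        wv = np.broadcast_to(np.asarray(within_var, dtype=float), (m,))

    k_pooled = float(k.mean())
    between = float(k.var(ddof=1))
    total_var = float(wv.mean()) + (1.0 + 1.0 / m) * between
    se_pooled = float(np.sqrt(total_var))

    t_j = stats.t.ppf(1.0 - p / 2.0, df)
    t_bar = float(t_j.mean())
    b_t = float(np.var(t_j, ddof=1))
    t_total = 1.0 + (1.0 + 1.0 / m) * b_t
    stat = t_bar / np.sqrt(t_total)
    p_pooled = float(np.clip(2.0 * stats.t.sf(stat, df), np.nextafter(0, 1), 1.0))

    per_tree = pd.DataFrame({"K": k, "p": p, "within_var": wv})
    return PooledSignal(k_pooled, se_pooled, p_pooled, m, per_tree)
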