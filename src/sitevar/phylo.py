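"""Tree building and tree-aware sequence variability profiles.

CS is the site-specific relative evolutionary rate inferred by an empirical
Bayes procedure: a neighbor-joining tree is built from Poisson-corrected
distances, site likelihoods are computed with Felsenstein's pruning algorithm
under the JTT model, rate heterogeneity is modelled with a discrete gamma
prior (equal-probability categories) whose shape is fitted by maximizing the
marginal log-likelihood, and each site's rate is the posterior mean over
categories, normalized to a mean of 1 over sites.

ET is the real-valued evolutionary trace: a UPGMA tree (topology only;
branch lengths are ignored) defines nested partitions of the sequences into
n = 1..M-1 groups by descending merge order, and the trace is

    ET_i = 1 + sum_n (1/n) sum_g s_ig

with s_ig the Shannon entropy of column i restricted to group g. Both CS and
ET are variability-oriented (higher = faster / more variable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .io import GAP, MSAlignment, SiteProfile
from .substitution import AA_INDEX, SubstitutionModel, discrete_gamma, jtt_model
from .tree import PhyloTree, TreeNode

logger = logging.getLogger(__name__)

#: saturation cap for Poisson-corrected distances (p >= 0.95)
MAX_DISTANCE = 3.0


def pairwise_distances(msa: MSAlignment) -> tuple[np.ndarray, list[str]]:
    """Poisson-corrected pairwise distances d = -ln(1 - p).

    p is the fraction of differing positions over shared non-gap columns;
    saturated pairs (p >= 0.95) are capped at d = 3.0 substitutions/site.
    """
    rows = [np.array([AA_INDEX.get(c, -1) for c in r]) for r in msa.rows]
    M = len(rows)
    D = np.zeros((M, M))
    for k in range(M):
        for l in range(k + 1, M):
            both = (rows[k] >= 0) & (rows[l] >= 0)
            n = int(both.sum())
            if n == 0:
                raise ValueError(
                    f"no comparable columns between {msa.names[k]!r} "
                    f"and {msa.names[l]!r}"
                )
            p = float((rows[k][both] != rows[l][both]).mean())
            d = MAX_DISTANCE if p >= 0.95 else -np.log(1.0 - p)
            D[k, l] = D[l, k] = d
    return D, list(msa.names)


def build_nj_tree(distances: np.ndarray, names: list[str]) -> PhyloTree:
    """Saitou–Nei neighbor joining; unrooted, basal trifurcation.

    Negative branch lengths are clamped to 0 with the excess shifted to the
    sibling edge so each cherry keeps its joint length.
    """
    D = np.array(distances, dtype=float)
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name) for name in names]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        ai, aj = active[i], active[j]
        nodes[ai].length = li
        nodes[aj].length = lj
        parent = TreeNode(children=[nodes[ai], nodes[aj]])
        new = np.maximum((D[ai, :] + D[aj, :] - dij) / 2.0, 0.0)
        D = np.vstack([D, new])
        D = np.column_stack([D, np.append(new, 0.0)])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]
    # final three-way join: three-point formulas
    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = D[a, b] - la
    lc = D[a, c] - la
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(length, 0.0)
    return PhyloTree(TreeNode(children=[nodes[a], nodes[b], nodes[c]]))


def build_upgma_tree(distances: np.ndarray, names: list[str]) -> PhyloTree:
    """Average-linkage (UPGMA) clustering into a rooted ultrametric tree."""
    D = np.array(distances, dtype=float)
    n = len(names)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    nodes = {i: TreeNode(names[i], height=0.0) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(nodes) > 1:
        (i, j), dmin = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        height = dmin / 2.0
        left, right = nodes.pop(i), nodes.pop(j)
        left.length = height - left.height
        right.length = height - right.height
        parent = TreeNode(children=[left, right], height=height)
        si, sj = sizes.pop(i), sizes.pop(j)
        for k in list(nodes):
            if k == next_id:
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(k, next_id), max(k, next_id))] = (si * dik + sj * djk) / (
                si + sj
            )
        del dist[(i, j)]
        nodes[next_id] = parent
        sizes[next_id] = si + sj
        next_id += 1
    return PhyloTree(nodes.popitem()[1])


# ---------------------------------------------------------------------------
# pruning likelihood


def _leaf_indices(msa: MSAlignment, columns: list[int]) -> dict[str, np.ndarray]:
    out = {}
    for name, row in zip(msa.names, msa.rows):
        out[name] = np.array([AA_INDEX.get(row[c], -1) for c in columns])
    return out


def _site_log_likelihoods(
    leaf_idx: dict[str, np.ndarray],
    tree: PhyloTree,
    model: SubstitutionModel,
    rates: np.ndarray,
) -> np.ndarray:
    """Log-likelihood per (rate category, column), shape (K, N).

    Branch lengths are multiplied by each rate; gaps (and unknown characters)
    are missing data with all-ones partials. Per-site scaling keeps the
    computation in range for large trees.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    eigval, A, B = model.spectral()
    n_sites = len(next(iter(leaf_idx.values())))
    K = len(rates)

    def down(node: TreeNode) -> tuple[np.ndarray, np.ndarray]:
        if node.is_leaf:
            idx = leaf_idx[node.name]
            partial = np.zeros((K, 20, n_sites))
            obs = idx >= 0
            partial[:, idx[obs], np.nonzero(obs)[0]] = 1.0
            partial[:, :, ~obs] = 1.0
            return partial, np.zeros((K, n_sites))
        partial = np.ones((K, 20, n_sites))
        logscale = np.zeros((K, n_sites))
        for child in node.children:
            cpart, cscale = down(child)
            E = np.exp(np.outer(rates * child.length, eigval))  # (K, 20)
            P = np.einsum("ae,ke,eb->kab", A, E, B)
            np.clip(P, 0.0, None, out=P)
            partial *= P @ cpart
            logscale += cscale
        m = partial.max(axis=1)
        np.clip(m, np.finfo(float).tiny, None, out=m)
        partial /= m[:, None, :]
        logscale += np.log(m)
        return partial, logscale

    partial, logscale = down(tree.root)
    lik = np.einsum("a,kan->kn", model.frequencies, partial)
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def site_likelihood(
    column: dict[str, str],
    tree: PhyloTree,
    model: SubstitutionModel | None = None,
    rate: float = 1.0,
) -> float:
    """Pruning likelihood of one alignment column (leaf name -> residue)."""
    model = model or jtt_model()
    leaf_idx = {
        name: np.array([AA_INDEX.get(aa, -1)]) for name, aa in column.items()
    }
    if rate <= 0:
        raise ValueError("rate must be positive")
    for leaf in tree.leaf_names:
        leaf_idx.setdefault(leaf, np.array([-1]))
    return float(np.exp(_site_log_likelihoods(leaf_idx, tree, model, [rate])[0, 0]))


@dataclass
class RatePosterior:
    """Posterior site rates from the discrete-gamma empirical Bayes fit."""

    alpha: float
    category_rates: np.ndarray
    category_weights: np.ndarray
    site_rates: np.ndarray       # posterior mean rate per mapped site
    log_likelihood: float


def compute_cs(
    msa: MSAlignment,
    tree: PhyloTree | None = None,
    model: SubstitutionModel | None = None,
    n_categories: int = 16,
    alpha_bracket: tuple[float, float] = (0.05, 20.0),
) -> tuple[RatePosterior, SiteProfile]:
    """Empirical Bayes site-specific relative rates of evolution (CS).

    The returned profile is the posterior mean rate per site divided by its
    mean over sites, so the profile averages to 1 ("rate relative to the
    overall average").
    """
    if msa.n_rows < 3:
        raise ValueError("rate estimation needs at least 3 sequences")
    model = model or jtt_model()
    if tree is None:
        D, names = pairwise_distances(msa)
        tree = build_nj_tree(D, names)
    columns = msa.mapped_columns
    leaf_idx = _leaf_indices(msa, columns)
    leaf_idx = {k: v for k, v in leaf_idx.items() if k in set(tree.leaf_names)}

    def category_logliks(alpha: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rates, weights = discrete_gamma(alpha, n_categories)
        lls = _site_log_likelihoods(leaf_idx, tree, model, rates)
        return lls, rates, weights

    def neg_loglik(alpha: float) -> float:
        lls, _, weights = category_logliks(alpha)
        return -float(logsumexp(lls + np.log(weights)[:, None], axis=0).sum())

    res = minimize_scalar(
        neg_loglik,
        bounds=alpha_bracket,
        method="bounded",
        options={"xatol": 1e-4},
    )
    alpha = float(res.x)
    lo, hi = alpha_bracket
    if alpha - lo < 1e-3 or hi - alpha < 1e-3:
        logger.warning("gamma shape fit at bracket boundary: alpha=%.4f", alpha)

    lls, rates, weights = category_logliks(alpha)
    logpost = lls + np.log(weights)[:, None]
    logpost -= logsumexp(logpost, axis=0, keepdims=True)
    post = np.exp(logpost)
    site_rates = rates @ post
    profile = SiteProfile(site_rates / site_rates.mean(), "CS")
    posterior = RatePosterior(
        alpha=alpha,
        category_rates=rates,
        category_weights=weights,
        site_rates=site_rates,
        log_likelihood=-float(res.fun),
    )
    return posterior, profile


# ---------------------------------------------------------------------------
# real-valued evolutionary trace


def _group_entropies(
    rows: list[np.ndarray], members: list[int], n_sites: int
) -> np.ndarray:
    counts = np.zeros((21, n_sites))
    for m in members:
        idx = rows[m]
        counts[np.where(idx >= 0, idx, 20), np.arange(n_sites)] += 1
    counts = counts[:20]
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = counts / total
        terms = np.where(counts > 0, f * np.log(f), 0.0)
    ent = -terms.sum(axis=0)
    ent[total == 0] = 0.0
    return ent


def compute_et(msa: MSAlignment, tree: PhyloTree | None = None) -> SiteProfile:
    """Real-valued evolutionary trace over a UPGMA tree's nested partitions.

    Branch lengths play no role beyond defining the merge order; a fully
    conserved column scores the minimum, 1.
    """
    if msa.n_rows < 2:
        raise ValueError("evolutionary trace needs at least 2 sequences")
    if tree is None:
        D, names = pairwise_distances(msa)
        tree = build_upgma_tree(D, names)
    columns = msa.mapped_columns
    n_sites = len(columns)
    name_to_row = {n: i for i, n in enumerate(msa.names)}
    rows = [
        np.array([AA_INDEX.get(msa.rows[i][c], -1) for c in columns])
        for i in range(msa.n_rows)
    ]

    def node_height(node: TreeNode) -> float:
        if node.is_leaf:
            return 0.0
        return max(node_height(c) + c.length for c in node.children)

    ent_cache: dict[int, np.ndarray] = {}

    def entropy_of(node: TreeNode) -> np.ndarray:
        key = id(node)
        if key not in ent_cache:
            members = [name_to_row[leaf.name] for leaf in node.leaves()]
            ent_cache[key] = _group_entropies(rows, members, n_sites)
        return ent_cache[key]

    M = tree.n_leaves
    groups: list[TreeNode] = [tree.root]
    et = np.zeros(n_sites)
    for n in range(1, M):
        level = sum((entropy_of(g) for g in groups), np.zeros(n_sites))
        et += level / n
        splittable = [g for g in groups if not g.is_leaf]
        if not splittable:
            break
        nxt = max(
            splittable,
            key=lambda g: (node_height(g), min(leaf.name for leaf in g.leaves())),
        )
        groups.remove(nxt)
        groups.extend(nxt.children)
    return SiteProfile(1.0 + et, "ET")
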