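"""Co-diversification detection on symbiont genus trees.

The engine behind the node-by-node co-phylogeny scan: patristic
distances, the Hommola cospeciation statistic (a Mantel-style
permutation test over host-symbiont link pairs), node filters
(subtree size, host span, maximum tip-tip divergence), tiered
significance calls, outgroup exclusion, and a second-order test that
re-runs the whole scan on host-label-shuffled trees to estimate how
many significant nodes arise by chance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._distance import DistanceMatrix

__all__ = [
    "SymbiontTreeSet",
    "CophyloConfig",
    "HommolaResult",
    "NodeResult",
    "SecondOrderResult",
    "patristic_matrix",
    "hommola_test",
    "enumerate_testable_nodes",
    "node_scan",
    "second_order_test",
    "significant_nodes",
]

#: Significance tiers: name -> (max p, min r).  r is the Hommola Pearson
#: correlation; thresholds are strict inequalities (p < pmax and r > rmin).
TIERS: dict[str, tuple[float, float]] = {
    "relaxed": (0.05, -np.inf),
    "medium": (0.05, 0.75),
    "strict": (0.01, 0.75),
}


@dataclass
class SymbiontTreeSet:
    """A rooted genus-level symbiont tree plus its tip metadata.

    ``tip_map`` is indexed by tip label and carries at least
    ``host_species`` and ``is_outgroup`` columns (``mag_id`` optional).
    """

    tree: dendropy.Tree
    tip_map: pd.DataFrame

    def __post_init__(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        mapped = set(self.tip_map.index.astype(str))
        missing = tips - mapped
        if missing:
            raise ValueError(f"tips missing from tip_map: {sorted(missing)[:5]}")
        if "is_outgroup" not in self.tip_map.columns:
            self.tip_map = self.tip_map.assign(is_outgroup=False)
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length in symbiont tree")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def hosts(self) -> pd.Series:
        return self.tip_map["host_species"]


@dataclass
class CophyloConfig:
    """Filters and thresholds for the node-by-node scan.

    ``max_tip_tip_dist`` is a patristic distance in the tree's own
    branch-length units (substitutions per site for real genus trees).
    ``tier`` selects which significance tier the second-order test counts.
    """

    min_tips: int = 7
    min_hosts: int = 3
    max_tip_tip_dist: float = 1.0
    n_perm: int = 100
    tier: str = "strict"
    seed: int = 0
    permute: str = "both"  # "both" (hosts and symbionts) or "hosts"

    def __post_init__(self) -> None:
        if self.min_tips < 2:
            raise ValueError("min_tips must be >= 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass
class HommolaResult:
    r: float
    p: float
    n_links: int
    n_perm: int
    degenerate: bool = False


@dataclass
class NodeResult:
    node_id: str
    n_tips: int
    n_hosts: int
    max_pairwise_tip_dist: float
    r: float
    p: float
    contains_outgroup: bool
    significant_at: frozenset[str]
    degenerate: bool = False


@dataclass
class NodeFilterRecord:
    node_id: str
    n_tips: int
    n_hosts: int
    max_pairwise_tip_dist: float
    passes: bool
    reason: str | None


@dataclass
class SecondOrderResult:
    observed_count: int
    null_counts: np.ndarray
    tested_counts: np.ndarray
    empirical_p: float
    tier: str


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Pairwise sum of branch lengths along tip-to-tip paths.

    Raises if any non-root edge lacks a length.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    # root-to-node depths
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = float(node.edge.length or 0.0)
        else:
            if node.edge.length is None:
                raise ValueError("missing branch length")
            depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length)
    d = np.zeros((n, n))
    dl = np.array([depth[id(lf)] for lf in leaves])
    leafsets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = np.array([index[id(node)]])
            continue
        child_sets = [leafsets.pop(id(c)) for c in node.child_nodes()]
        # distances between leaves whose MRCA is this node
        for a, b in itertools.combinations(child_sets, 2):
            ia, ib = np.meshgrid(a, b, indexing="ij")
            vals = dl[ia] + dl[ib] - 2.0 * depth[id(node)]
            d[ia, ib] = vals
            d[ib, ia] = vals
        leafsets[id(node)] = np.concatenate(child_sets)
    return DistanceMatrix(labels, d)


def _link_pair_vectors(
    dh: np.ndarray, ds: np.ndarray, h_idx: np.ndarray, s_idx: np.ndarray, iu
) -> tuple[np.ndarray, np.ndarray]:
    hv = dh[h_idx[iu[0]], h_idx[iu[1]]]
    sv = ds[s_idx[iu[0]], s_idx[iu[1]]]
    return hv, sv


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def hommola_test(
    host_dm: DistanceMatrix,
    symbiont_dm: DistanceMatrix,
    links: list[tuple[str, str]],
    n_perm: int = 100,
    seed=None,
    permute: str = "both",
    method: str = "permutation",
) -> HommolaResult:
    """Hommola cospeciation test over host-symbiont links.

    For every unordered pair of links {(s1,h1),(s2,h2)} the host
    patristic distance d(h1,h2) is paired with the symbiont distance
    d(s1,s2); ``r`` is their Pearson correlation.  The null permutes the
    host labels and (by default) the symbiont labels of the association
    independently; ``p`` carries the +1 correction.  ``method='exact'``
    enumerates every relabelling instead (feasible only for few links).

    Zero variance in either distance vector (e.g. all symbionts from a
    single host) is flagged degenerate with r = NaN and p = 1.
    """
    if len(links) < 3:
        raise ValueError("need at least 3 host-symbiont links")
    s_idx = np.array([symbiont_dm.index_of(s) for s, _ in links])
    h_idx = np.array([host_dm.index_of(h) for _, h in links])
    dh, ds = host_dm.values, symbiont_dm.values
    L = len(links)
    iu = np.triu_indices(L, 1)
    hv, sv = _link_pair_vectors(dh, ds, h_idx, s_idx, iu)
    r_obs = _pearson(hv, sv)
    if np.isnan(r_obs):
        return HommolaResult(np.nan, 1.0, L, 0, degenerate=True)

    if method == "exact":
        perms = list(itertools.permutations(range(L)))
        count = 0
        total = 0
        sym_perms = perms if permute == "both" else [tuple(range(L))]
        for ph in perms:
            hp = h_idx[list(ph)]
            for ps in sym_perms:
                sp = s_idx[list(ps)]
                hv_p, sv_p = _link_pair_vectors(dh, ds, hp, sp, iu)
                r_p = _pearson(hv_p, sv_p)
                total += 1
                if not np.isnan(r_p) and r_p >= r_obs - 1e-12:
                    count += 1
        return HommolaResult(r_obs, count / total, L, total)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        hp = h_idx[rng.permutation(L)]
        sp = s_idx[rng.permutation(L)] if permute == "both" else s_idx
        hv_p, sv_p = _link_pair_vectors(dh, ds, hp, sp, iu)
        r_p = _pearson(hv_p, sv_p)
        if not np.isnan(r_p) and r_p >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return HommolaResult(r_obs, p, L, n_perm)


def _tiers_for(r: float, p: float) -> frozenset[str]:
    if np.isnan(r):
        return frozenset()
    return frozenset(
        name for name, (pmax, rmin) in TIERS.items() if p < pmax and r > rmin
    )


class _TreeIndex:
    """Per-tree precomputation shared across label shuffles."""

    def __init__(self, tree_set: SymbiontTreeSet):
        self.patristic = patristic_matrix(tree_set.tree)
        self.tips = self.patristic.labels
        tip_pos = {t: i for i, t in enumerate(self.tips)}
        tm = tree_set.tip_map
        self.hosts = np.array(
            [str(tm.loc[t, "host_species"]) for t in self.tips], dtype=object
        )
        self.outgroup = np.array(
            [bool(tm.loc[t, "is_outgroup"]) for t in self.tips]
        )
        # internal nodes in preorder; stable ids independent of tip order
        self.nodes: list[tuple[str, np.ndarray, float]] = []
        for k, node in enumerate(tree_set.tree.preorder_internal_node_iter()):
            idx = np.array(
                [tip_pos[lf.taxon.label] for lf in node.leaf_iter()], dtype=int
            )
            sub = self.patristic.values[np.ix_(idx, idx)]
            self.nodes.append((f"n{k}", idx, float(sub.max(initial=0.0))))


def _filter_nodes(
    index: _TreeIndex, hosts: np.ndarray, config: CophyloConfig
) -> list[NodeFilterRecord]:
    out = []
    for node_id, idx, max_dist in index.nodes:
        n_tips = len(idx)
        n_hosts = len(set(hosts[idx]))
        reason = None
        if n_tips < config.min_tips:
            reason = "too few MAGs"
        elif n_hosts < config.min_hosts:
            reason = "too few hosts"
        elif max_dist > config.max_tip_tip_dist:
            reason = "max tip-tip distance exceeded"
        out.append(
            NodeFilterRecord(node_id, n_tips, n_hosts, max_dist, reason is None, reason)
        )
    return out


def enumerate_testable_nodes(
    tree_set: SymbiontTreeSet, config: CophyloConfig
) -> list[NodeFilterRecord]:
    """Apply the subtree filters, returning pass/fail with reasons."""
    index = _TreeIndex(tree_set)
    return _filter_nodes(index, index.hosts, config)


def _scan(
    index: _TreeIndex,
    hosts: np.ndarray,
    host_dm: DistanceMatrix,
    config: CophyloConfig,
    spawn_prefix: tuple[int, ...],
) -> list[NodeResult]:
    results = []
    records = _filter_nodes(index, hosts, config)
    host_pos = {h: i for i, h in enumerate(host_dm.labels)}
    dh, ds = host_dm.values, index.patristic.values
    for k, rec in enumerate(records):
        if not rec.passes:
            continue
        _, idx, _ = index.nodes[k]
        h_idx = np.array([host_pos[h] for h in hosts[idx]])
        s_idx = idx
        L = len(idx)
        iu = np.triu_indices(L, 1)
        hv, sv = _link_pair_vectors(dh, ds, h_idx, s_idx, iu)
        r_obs = _pearson(hv, sv)
        degenerate = np.isnan(r_obs)
        if degenerate:
            r_obs, p = np.nan, 1.0
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=spawn_prefix + (k,))
            )
            count = 0
            for _ in range(config.n_perm):
                hp = h_idx[rng.permutation(L)]
                sp = s_idx[rng.permutation(L)] if config.permute == "both" else s_idx
                hv_p, sv_p = _link_pair_vectors(dh, ds, hp, sp, iu)
                r_p = _pearson(hv_p, sv_p)
                if not np.isnan(r_p) and r_p >= r_obs - 1e-12:
                    count += 1
            p = (1 + count) / (1 + config.n_perm)
        results.append(
            NodeResult(
                node_id=rec.node_id,
                n_tips=rec.n_tips,
                n_hosts=rec.n_hosts,
                max_pairwise_tip_dist=rec.max_pairwise_tip_dist,
                r=r_obs,
                p=p,
                contains_outgroup=bool(index.outgroup[idx].any()),
                significant_at=_tiers_for(r_obs, p),
                degenerate=degenerate,
            )
        )
    return results


def node_scan(
    tree_set: SymbiontTreeSet,
    host_tree: dendropy.Tree,
    config: CophyloConfig,
) -> list[NodeResult]:
    """Run the Hommola test on every testable internal node.

    Each node draws its permutation RNG stream from the master seed and
    its own stable node id, so results do not depend on scan order.
    Nodes containing outgroup tips are reported with their statistics but
    are never counted significant (see :func:`significant_nodes`).
    """
    index = _TreeIndex(tree_set)
    host_dm = patristic_matrix(host_tree)
    unknown = set(index.hosts[~index.outgroup]) - set(host_dm.labels)
    if unknown:
        raise ValueError(f"hosts absent from host tree: {sorted(unknown)}")
    # outgroup tips carry hosts outside the host tree; give them a
    # placeholder row at maximal distance so filters still see them
    host_dm = _with_placeholders(host_dm, set(index.hosts) - set(host_dm.labels))
    return _scan(index, index.hosts, host_dm, config, spawn_prefix=())


def _with_placeholders(host_dm: DistanceMatrix, extra_hosts: set) -> DistanceMatrix:
    if not extra_hosts:
        return host_dm
    labels = list(host_dm.labels) + sorted(str(h) for h in extra_hosts)
    n = len(labels)
    far = host_dm.values.max(initial=1.0) * 2.0
    vals = np.full((n, n), far)
    np.fill_diagonal(vals, 0.0)
    m = host_dm.n
    vals[:m, :m] = host_dm.values
    return DistanceMatrix(labels, vals)


def significant_nodes(results: list[NodeResult], tier: str = "strict") -> list[NodeResult]:
    """Nodes significant at ``tier``, excluding any containing outgroup tips."""
    return [
        res
        for res in results
        if tier in res.significant_at and not res.contains_outgroup
    ]


def second_order_test(
    tree_set: SymbiontTreeSet,
    host_tree: dendropy.Tree,
    config: CophyloConfig,
    n_shuffles: int = 100,
) -> SecondOrderResult:
    """Second-order permutation test on the whole node scan.

    Host assignments of non-outgroup tips are permuted uniformly
    (topology untouched), the filters and scan are re-run, and the count
    of tier-significant nodes per shuffle forms the null distribution for
    the observed count.  ``empirical_p`` carries the +1 correction.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    index = _TreeIndex(tree_set)
    host_dm = patristic_matrix(host_tree)
    unknown = set(index.hosts[~index.outgroup]) - set(host_dm.labels)
    if unknown:
        raise ValueError(f"hosts absent from host tree: {sorted(unknown)}")
    host_dm = _with_placeholders(host_dm, set(index.hosts) - set(host_dm.labels))

    observed = _scan(index, index.hosts, host_dm, config, spawn_prefix=())
    obs_count = len(significant_nodes(observed, config.tier))

    null_counts = np.zeros(n_shuffles, dtype=int)
    tested_counts = np.zeros(n_shuffles, dtype=int)
    free = np.where(~index.outgroup)[0]
    for s in range(n_shuffles):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1_000_000, s))
        )
        hosts = index.hosts.copy()
        hosts[free] = hosts[free][rng.permutation(len(free))]
        res = _scan(index, hosts, host_dm, config, spawn_prefix=(1_000_000, s))
        null_counts[s] = len(significant_nodes(res, config.tier))
        tested_counts[s] = len(res)
    empirical_p = (1 + int((null_counts >= obs_count).sum())) / (1 + n_shuffles)
    return SecondOrderResult(obs_count, null_counts, tested_counts, empirical_p, config.tier)
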