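"""Community-level statistics: beta diversity, PERMANOVA, Mantel,
phylosymbiosis resampling, accumulation curves and PCoA.

PERMANOVA follows the classical pseudo-F construction on squared
distances with free whole-sample label permutation and reports both R^2
and the sample-size-adjusted effect size omega^2 (the adonis_OmegaSq
adjustment).  The phylosymbiosis test repeatedly subsamples one sample
per host species, runs a Mantel test between the induced 5x5 community
matrix and the fixed host divergence matrix, and BH-adjusts the p-values
across iterations; with five hosts the Mantel permutation space (120) is
enumerated exactly by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from ._distance import DistanceMatrix

__all__ = [
    "PairCounts",
    "BetaDiversity",
    "PermanovaResult",
    "MantelResult",
    "PhylosymbiosisResult",
    "beta_diversity_pair",
    "pairwise_beta",
    "permanova",
    "mantel_test",
    "phylosymbiosis_test",
    "accumulation_curve",
    "pcoa",
]


@dataclass
class PairCounts:
    a: int  # shared
    b: int  # unique to first
    c: int  # unique to second


@dataclass
class BetaDiversity:
    sor: float  # Sorensen dissimilarity
    sim: float  # its turnover (Simpson) component
    sne: float  # nestedness component: sor - sim
    jac: float  # Jaccard dissimilarity
    jtu: float  # Jaccard turnover component
    counts: PairCounts


@dataclass
class PermanovaResult:
    ss_total: float
    ss_between: float
    ss_within: float
    df_effect: int
    df_resid: int
    f: float
    r2: float
    omega2: float
    p: float
    n_perm: int


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    exact: bool = False
    degenerate: bool = False


@dataclass
class PhylosymbiosisResult:
    iterations: pd.DataFrame  # columns: samples, r, p, q
    mean_q: float
    sd_q: float
    n_iter: int


def beta_diversity_pair(set_i, set_j) -> BetaDiversity:
    """Baselga partition of pairwise dissimilarity into turnover + nestedness.

    sor = (b+c)/(2a+b+c); sim = min(b,c)/(a+min(b,c)); sne = sor - sim;
    jac = (b+c)/(a+b+c); jtu = 2min(b,c)/(a+2min(b,c)).
    """
    si, sj = set(set_i), set(set_j)
    if not si and not sj:
        raise ValueError("both sets empty: dissimilarity undefined")
    a = len(si & sj)
    b = len(si - sj)
    c = len(sj - si)
    m = min(b, c)
    sor = (b + c) / (2 * a + b + c)
    sim = m / (a + m) if (a + m) > 0 else 0.0
    jtu = 2 * m / (a + 2 * m) if (a + 2 * m) > 0 else 0.0
    return BetaDiversity(
        sor=sor,
        sim=sim,
        sne=sor - sim,
        jac=(b + c) / (a + b + c),
        jtu=jtu,
        counts=PairCounts(a, b, c),
    )


def pairwise_beta(presence: pd.DataFrame, index: str = "sim") -> DistanceMatrix:
    """All-pairs beta diversity over a boolean sample x species matrix."""
    labels = list(presence.index.astype(str))
    n = len(labels)
    vals = np.zeros((n, n))
    rows = [set(presence.columns[presence.iloc[i].astype(bool)]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            beta = beta_diversity_pair(rows[i], rows[j])
            vals[i, j] = vals[j, i] = getattr(beta, index)
    return DistanceMatrix(labels, vals)


def _ss_within(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    s = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            s += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return s


def permanova(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed=None
) -> PermanovaResult:
    """One-way PERMANOVA with pseudo-F, R^2, omega^2 and permutation p.

    omega^2 = (SS_b - df_e * MS_w) / (SS_t + MS_w); the permutation null
    shuffles whole-sample labels freely, and p carries the +1 correction.
    """
    if not dm.complete:
        raise ValueError("distance matrix has missing entries")
    groups = pd.Series(groups)
    if len(groups) != dm.n:
        raise ValueError("groups length does not match matrix")
    codes, uniques = pd.factorize(groups)
    k = len(uniques)
    N = dm.n
    if k < 2:
        raise ValueError("need at least 2 groups")
    if k >= N:
        raise ValueError("as many groups as samples: no residual df")
    d2 = dm.values**2
    ss_total = d2.sum() / (2.0 * N)
    ss_within = _ss_within(d2, codes, k)
    ss_between = ss_total - ss_within
    df_e, df_r = k - 1, N - k
    ms_w = ss_within / df_r
    with np.errstate(divide="ignore"):
        f = (ss_between / df_e) / ms_w if ms_w > 0 else np.inf
    r2 = ss_between / ss_total
    omega2 = (ss_between - df_e * ms_w) / (ss_total + ms_w)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_codes = codes[rng.permutation(N)]
        ssw_p = _ss_within(d2, perm_codes, k)
        if ssw_p > 0:
            f_p = ((ss_total - ssw_p) / df_e) / (ssw_p / df_r)
        else:
            f_p = np.inf
        if f_p >= f - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        ss_total, ss_between, ss_within, df_e, df_r, f, r2, omega2, p, n_perm
    )


# --- Mantel -----------------------------------------------------------------

_PAIR_INDEX_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _perm_gather_matrix(n: int) -> tuple[np.ndarray, np.ndarray]:
    """All n! label permutations as gather indices into the condensed vector."""
    if n in _PAIR_INDEX_CACHE:
        return _PAIR_INDEX_CACHE[n]
    pos = {}
    c = 0
    for i in range(n):
        for j in range(i + 1, n):
            pos[(i, j)] = c
            c += 1
    perms = np.array(list(itertools.permutations(range(n))), dtype=int)
    gather = np.empty((len(perms), c), dtype=int)
    for pi, p in enumerate(perms):
        col = 0
        for i in range(n):
            for j in range(i + 1, n):
                x, y = p[i], p[j]
                gather[pi, col] = pos[(x, y) if x < y else (y, x)]
                col += 1
    _PAIR_INDEX_CACHE[n] = (perms, gather)
    return perms, gather


def _corr_vectors(x: np.ndarray, method: str) -> np.ndarray:
    return rankdata(x) if method == "spearman" else x.astype(float)


def mantel_test(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed=None,
    exact_if_small: bool = True,
) -> MantelResult:
    """Mantel correlation between two distance matrices (one-sided, greater).

    ``r`` is the rank (Spearman, default) or Pearson correlation of the
    off-diagonal vectors; the null jointly permutes rows/columns of the
    second matrix.  For n <= 6 with ``exact_if_small`` the full n!
    permutation set is enumerated, giving an exact p with granularity
    1/n!.  Zero variance in either vector is returned flagged degenerate.
    """
    if dm1.labels != dm2.labels:
        dm2 = dm2.submatrix(dm1.labels)
    n = dm1.n
    if n < 4:
        raise ValueError("need at least 4 objects")
    xv = _corr_vectors(dm1.condensed(), method)
    yv_raw = dm2.condensed()
    yv = _corr_vectors(yv_raw, method)
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sxx = (xc**2).sum()
    syy = (yc**2).sum()
    if sxx == 0 or syy == 0:
        return MantelResult(np.nan, np.nan, 0, method, degenerate=True)
    r_obs = float((xc * yc).sum() / np.sqrt(sxx * syy))

    if exact_if_small and n <= 6:
        _, gather = _perm_gather_matrix(n)
        # permuting labels permutes the off-diagonal multiset, hence its ranks
        y_all = yv[gather]
        yc_all = y_all - yv.mean()
        r_all = (yc_all @ xc) / np.sqrt(sxx * syy)
        p = float((r_all >= r_obs - 1e-12).mean())
        return MantelResult(r_obs, p, len(gather), method, exact=True)

    rng = np.random.default_rng(seed)
    vals2 = dm2.values
    iu = np.triu_indices(n, 1)
    count = 0
    for _ in range(n_perm):
        p_idx = rng.permutation(n)
        y_p = _corr_vectors(vals2[np.ix_(p_idx, p_idx)][iu], method)
        yc_p = y_p - y_p.mean()
        r_p = (xc * yc_p).sum() / np.sqrt(sxx * (yc_p**2).sum())
        if r_p >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, method)


def phylosymbiosis_test(
    community_dm: DistanceMatrix,
    host_dm: DistanceMatrix,
    metadata: pd.DataFrame,
    n_iter: int = 1000,
    seed=None,
    method: str = "spearman",
) -> PhylosymbiosisResult:
    """Subsampled Mantel test for phylosymbiosis with BH-FDR across iterations.

    Each iteration draws one sample per host species uniformly at random,
    correlates the induced community distances with the host divergence
    matrix (exact Mantel enumeration at n = number of hosts), and records
    (r, p).  The p-values are BH-adjusted across all iterations and
    summarized as mean_q +/- sd_q.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    hosts = host_dm.labels
    by_host = {
        h: [s for s in community_dm.labels if str(metadata.loc[s, "host_species"]) == h]
        for h in hosts
    }
    empty = [h for h, ss in by_host.items() if not ss]
    if empty:
        raise ValueError(f"hosts with no samples: {empty}")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_iter):
        chosen = [ss[int(rng.integers(len(ss)))] for h, ss in by_host.items()]
        sub = community_dm.submatrix(chosen)
        sub = DistanceMatrix(hosts, sub.values)  # relabel samples by their host
        res = mantel_test(host_dm, sub, method=method, exact_if_small=True)
        records.append(
            {"samples": tuple(chosen), "r": res.r, "p": 1.0 if res.degenerate else res.p}
        )
    df = pd.DataFrame(records)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return PhylosymbiosisResult(df, float(df["q"].mean()), float(df["q"].std()), n_iter)


def accumulation_curve(
    presence: pd.DataFrame, n_orders: int = 100, seed=None
) -> np.ndarray:
    """Mean cumulative species richness over random sample orderings."""
    mat = presence.to_numpy(bool)
    n = mat.shape[0]
    if n == 0:
        raise ValueError("no samples")
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_orders, n))
    for o in range(n_orders):
        order = rng.permutation(n)
        seen = np.zeros(mat.shape[1], dtype=bool)
        for step, i in enumerate(order):
            seen |= mat[i]
            curves[o, step] = seen.sum()
    return curves.mean(axis=0)


def pcoa(dm: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (PCoA) of a distance matrix.

    Gower-centers -D^2/2 and eigendecomposes; coordinates span the
    positive eigenvalues, but the full eigenvalue spectrum (including
    negative values from non-Euclidean distances) is returned undropped.
    """
    if not dm.complete:
        raise ValueError("distance matrix has missing entries")
    n = dm.n
    d2 = dm.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    cols = [f"PCo{i+1}" for i in range(int(pos.sum()))]
    return pd.DataFrame(coords, index=dm.labels, columns=cols), evals
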