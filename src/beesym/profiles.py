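"""Species detection, SNV summaries, popANI distances and ANI clustering.

Implements the mapping-free profiling rules: a species is present in a
sample when at least 50% of its genome is covered; an intra-sample SNV
requires >=5x coverage and a minor allele at frequency >=0.05 (regions
with read ANI < 0.92 or coverage < 1x are masked); popANI counts a
substitution between two samples only at positions where their allele
sets are disjoint; MAGs cluster into species at 95% ANI with the
dRep-style quality score choosing representatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._distance import DistanceMatrix

__all__ = [
    "SnvSummary",
    "PopAniResult",
    "SpeciesClustering",
    "detect_species",
    "relative_coverage",
    "call_snvs",
    "popani_pair",
    "strain_distance_matrix",
    "cluster_by_ani",
]

_FREQ_COLS = ["freq_A", "freq_C", "freq_G", "freq_T"]


@dataclass
class SnvSummary:
    n_snvs: int
    covered_length: int
    pct_variable: float  # 100 * n_snvs / covered_length; NaN when undefined


@dataclass
class PopAniResult:
    value: float  # substitutions / compared positions; NaN when missing
    n_compared: int
    n_substitutions: int
    eligible: bool
    reason: str | None = None


@dataclass
class SpeciesClustering:
    cluster_of: dict[str, int]
    representative: dict[int, str]
    quality: pd.Series  # completeness - 5 * contamination per MAG


def detect_species(
    profiles: pd.DataFrame, breadth_threshold: float = 0.5
) -> pd.DataFrame:
    """Sample x species presence matrix: present iff breadth >= threshold."""
    if not 0.0 < breadth_threshold <= 1.0:
        raise ValueError("breadth_threshold must be in (0, 1]")
    if profiles.empty:
        return pd.DataFrame(dtype=bool)
    present = profiles.assign(
        present=profiles["breadth"] >= breadth_threshold
    )
    mat = present.pivot_table(
        index="sample_id", columns="species_id", values="present", aggfunc="any"
    )
    return mat.fillna(False).astype(bool)


def relative_coverage(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-sample species proportions of mean coverage (rows sum to 1).

    Samples whose coverages are all zero are returned as NaN rows with a
    warning rather than dropped.
    """
    mat = profiles.pivot_table(
        index="sample_id", columns="species_id", values="mean_coverage", aggfunc="sum"
    ).fillna(0.0)
    totals = mat.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) with zero total coverage; returned as NaN"
        )
    out = mat.div(totals.where(~zero), axis=0)
    return out


def _renormalize_freqs(freqs: np.ndarray, coverage: np.ndarray) -> np.ndarray:
    sums = freqs.sum(axis=1)
    covered = coverage > 0
    bad = covered & (np.abs(sums - 1.0) > 1e-6)
    if bad.any():
        raise ValueError("allele frequencies deviate from 1 by more than 1e-6")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(covered[:, None] & (sums[:, None] > 0), freqs / sums[:, None], freqs)
    return out


def call_snvs(
    sites: pd.DataFrame,
    min_cov: int = 5,
    min_freq: float = 0.05,
    read_ani_min: float = 0.92,
) -> SnvSummary:
    """Summarize intra-sample variant sites for one (species, sample).

    A site is an SNV iff coverage >= ``min_cov`` and at least two alleles
    each reach frequency >= ``min_freq``.  Sites in regions failing the
    read-ANI mask (``read_ani`` column, when present) or with coverage
    < 1 are excluded from both the SNV count and the covered length.
    """
    cov = sites["coverage"].to_numpy(float)
    keep = cov >= 1
    if "read_ani" in sites.columns:
        keep &= sites["read_ani"].to_numpy(float) >= read_ani_min
    elif "read_ani_pass" in sites.columns:
        keep &= sites["read_ani_pass"].to_numpy(bool)
    sub = sites.loc[keep]
    covered_length = int(keep.sum())
    if covered_length == 0:
        return SnvSummary(0, 0, float("nan"))
    freqs = _renormalize_freqs(
        sub[_FREQ_COLS].to_numpy(float), sub["coverage"].to_numpy(float)
    )
    cov = sub["coverage"].to_numpy(float)
    n_alleles = (freqs >= min_freq).sum(axis=1)
    is_snv = (cov >= min_cov) & (n_alleles >= 2)
    n_snvs = int(is_snv.sum())
    return SnvSummary(n_snvs, covered_length, 100.0 * n_snvs / covered_length)


def _allele_sets(freqs: np.ndarray, min_freq: float) -> np.ndarray:
    return freqs >= min_freq


def popani_pair(
    alleles_i: pd.DataFrame,
    alleles_j: pd.DataFrame,
    min_site_cov: int = 5,
    min_freq: float = 0.05,
    min_breadth: float = 0.5,
    min_mean_cov: float = 5.0,
    breadth_i: float | None = None,
    breadth_j: float | None = None,
    denominator: str = "all_covered",
) -> PopAniResult:
    """popANI dissimilarity between two samples of one species.

    The pair is eligible only if both samples have mean coverage
    >= ``min_mean_cov`` and breadth >= ``min_breadth`` (breadths may be
    supplied from genome-wide profiles; otherwise they are computed over
    the table's position universe).  Compared positions have coverage
    >= ``min_site_cov`` in both samples; the allele set at a position is
    the nucleotides at frequency >= ``min_freq``; a substitution is a
    position whose two allele sets are disjoint.  Returns substitutions /
    compared positions, or NaN (ineligible / nothing compared).

    ``denominator='multiallelic'`` restricts the denominator to compared
    positions where at least one sample carries more than one allele or
    the consensus alleles differ (the narrow reading of "considered").
    """
    ai = alleles_i.sort_values("position").reset_index(drop=True)
    aj = alleles_j.sort_values("position").reset_index(drop=True)
    merged = ai.merge(aj, on="position", suffixes=("_i", "_j"))
    if merged.empty:
        return PopAniResult(float("nan"), 0, 0, False, "no shared positions")

    def _stats(df: pd.DataFrame) -> tuple[float, float]:
        cov = df["coverage"].to_numpy(float)
        return float(cov.mean()), float((cov >= 1).mean())

    mean_i, br_i = _stats(ai)
    mean_j, br_j = _stats(aj)
    br_i = br_i if breadth_i is None else breadth_i
    br_j = br_j if breadth_j is None else breadth_j
    if mean_i < min_mean_cov or mean_j < min_mean_cov:
        return PopAniResult(float("nan"), 0, 0, False, "mean coverage below threshold")
    if br_i < min_breadth or br_j < min_breadth:
        return PopAniResult(float("nan"), 0, 0, False, "breadth below threshold")

    cov_i = merged["coverage_i"].to_numpy(float)
    cov_j = merged["coverage_j"].to_numpy(float)
    compared = (cov_i >= min_site_cov) & (cov_j >= min_site_cov)
    if not compared.any():
        return PopAniResult(float("nan"), 0, 0, False, "no compared positions")
    fi = _renormalize_freqs(
        merged[[c + "_i" for c in _FREQ_COLS]].to_numpy(float), cov_i
    )[compared]
    fj = _renormalize_freqs(
        merged[[c + "_j" for c in _FREQ_COLS]].to_numpy(float), cov_j
    )[compared]
    set_i = _allele_sets(fi, min_freq)
    set_j = _allele_sets(fj, min_freq)
    disjoint = ~(set_i & set_j).any(axis=1)
    if denominator == "all_covered":
        n_compared = int(compared.sum())
    elif denominator == "multiallelic":
        multi = (set_i.sum(axis=1) > 1) | (set_j.sum(axis=1) > 1)
        consensus_differs = fi.argmax(axis=1) != fj.argmax(axis=1)
        considered = multi | consensus_differs
        n_compared = int(considered.sum())
        disjoint = disjoint & considered
        if n_compared == 0:
            return PopAniResult(0.0, 0, 0, True, "no considered positions")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    n_sub = int(disjoint.sum())
    return PopAniResult(n_sub / n_compared, n_compared, n_sub, True)


def strain_distance_matrix(
    alleles: pd.DataFrame,
    metadata: pd.DataFrame,
    species_id: str,
    min_samples: int = 5,
    min_hosts: int = 2,
    **popani_kwargs,
) -> tuple[DistanceMatrix, dict]:
    """Pairwise popANI matrix over one species' eligible samples.

    A species is flagged analyzable only when at least ``min_samples``
    eligible samples span at least ``min_hosts`` host species.  Missing
    pairs (ineligible or nothing compared) stay NaN and masked.
    """
    sub = alleles.loc[alleles["species_id"] == species_id]
    if sub.empty:
        raise ValueError(f"no allele data for {species_id}")
    min_mean_cov = popani_kwargs.get("min_mean_cov", 5.0)
    min_breadth = popani_kwargs.get("min_breadth", 0.5)
    by_sample = {sid: df for sid, df in sub.groupby("sample_id")}
    eligible = []
    for sid, df in sorted(by_sample.items()):
        cov = df["coverage"].to_numpy(float)
        if cov.mean() >= min_mean_cov and (cov >= 1).mean() >= min_breadth:
            eligible.append(sid)
    hosts = metadata.loc[eligible, "host_species"] if eligible else pd.Series(dtype=object)
    report = {
        "species_id": species_id,
        "n_eligible": len(eligible),
        "n_hosts": int(hosts.nunique()),
        "analyzable": len(eligible) >= min_samples and hosts.nunique() >= min_hosts,
        "reason": None,
    }
    if len(eligible) < 2:
        report["reason"] = "fewer than 2 eligible samples"
        return DistanceMatrix([], np.zeros((0, 0))), report
    if not report["analyzable"]:
        report["reason"] = (
            f"needs >= {min_samples} eligible samples from >= {min_hosts} hosts"
        )
    n = len(eligible)
    vals = np.full((n, n), np.nan)
    np.fill_diagonal(vals, 0.0)
    for a in range(n):
        for b in range(a + 1, n):
            res = popani_pair(
                by_sample[eligible[a]], by_sample[eligible[b]], **popani_kwargs
            )
            if res.eligible and not np.isnan(res.value):
                vals[a, b] = vals[b, a] = res.value
    return DistanceMatrix(eligible, vals), report


def cluster_by_ani(
    ani: pd.DataFrame,
    quality: pd.DataFrame,
    threshold: float = 0.95,
) -> SpeciesClustering:
    """Average-linkage clustering of MAGs at an ANI threshold.

    ``ani`` is a square MAG x MAG similarity matrix in [0, 1]; clusters
    are cut at distance ``1 - threshold``.  ``quality`` must provide
    completeness and contamination (percent) for every MAG; the
    representative of a cluster maximizes completeness - 5*contamination,
    ties broken by lexicographic MAG id.
    """
    mags = list(ani.index.astype(str))
    missing = set(mags) - set(quality.index.astype(str))
    if missing:
        raise ValueError(f"quality missing for MAGs: {sorted(missing)[:5]}")
    vals = ani.to_numpy(float)
    if vals.shape[0] != vals.shape[1] or np.abs(vals - vals.T).max() > 1e-9:
        raise ValueError("ANI matrix must be square and symmetric")
    if vals.min() < 0 or vals.max() > 1 + 1e-12:
        raise ValueError("ANI entries must lie in [0, 1]")
    dist = 1.0 - vals
    np.fill_diagonal(dist, 0.0)
    if len(mags) == 1:
        assignments = np.array([1])
    else:
        z = linkage(squareform(dist, checks=False), method="average")
        assignments = fcluster(z, t=1.0 - threshold, criterion="distance")
    score = (
        quality["completeness"].astype(float)
        - 5.0 * quality["contamination"].astype(float)
    )
    cluster_of = {m: int(c) for m, c in zip(mags, assignments)}
    representative: dict[int, str] = {}
    for c in sorted(set(assignments)):
        members = [m for m in mags if cluster_of[m] == c]
        best = min(members, key=lambda m: (-score[m], m))
        representative[int(c)] = best
    return SpeciesClustering(cluster_of, representative, score.loc[mags])
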