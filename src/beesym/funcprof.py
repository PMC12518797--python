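"""Functional-profile math: gene detection, RPKM, feature aggregation,
genus-level CAZyme contribution shares, and robust Aitchison distances.

RPKM = reads_mapped / ((length_bp/1000) * (total_reads/1e6)).  A gene is
detected in a sample when strictly more than 5 reads map to it and
strictly more than 90% of its bases are covered.  KO and CAZyme-family
abundances are the summed RPKMs of their detected constituent genes.
The robust Aitchison distance is the Euclidean distance between rclr
rows (centered log-ratio over the positive entries only, zeros kept
at 0).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._distance import DistanceMatrix

__all__ = [
    "detect_genes",
    "rpkm",
    "add_rpkm",
    "aggregate_features",
    "cazyme_genus_share",
    "rclr_transform",
    "robust_aitchison",
]

#: CAZyme classes excluded from the genus-contribution analysis
#: (glycosyl transferases and auxiliary activities).
EXCLUDED_CAZYME_CLASSES = ("GT", "AA")


def detect_genes(
    records: pd.DataFrame, min_reads: int = 5, min_fraction: float = 0.9
) -> pd.DataFrame:
    """Rows whose gene passes the strict detection filter.

    Detected iff reads_mapped > ``min_reads`` AND fraction_bases_covered
    > ``min_fraction`` (both strict inequalities).
    """
    keep = (records["reads_mapped"] > min_reads) & (
        records["fraction_bases_covered"] > min_fraction
    )
    return records.loc[keep]


def rpkm(
    reads_mapped, length_bp, total_reads_sample
) -> float | np.ndarray:
    """Reads per kilobase of gene per million library reads."""
    total = np.asarray(total_reads_sample, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total_reads_sample must be > 0")
    length = np.asarray(length_bp, dtype=float)
    if np.any(length <= 0):
        raise ValueError("length_bp must be > 0")
    out = np.asarray(reads_mapped, dtype=float) / ((length / 1e3) * (total / 1e6))
    return float(out) if out.ndim == 0 else out


def add_rpkm(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the gene table with an ``rpkm`` column."""
    return records.assign(
        rpkm=rpkm(
            records["reads_mapped"],
            records["length_bp"],
            records["total_reads_sample"],
        )
    )


def aggregate_features(
    records: pd.DataFrame, key: str = "ko", detected_only: bool = True
) -> pd.DataFrame:
    """Sample x feature matrix of summed RPKMs (KO or cazyme_family).

    Undetected genes contribute nothing (the detection filter precedes
    aggregation); genes lacking the annotation are excluded.  Zero means
    the feature was not detected in the sample.
    """
    if key not in records.columns:
        raise KeyError(key)
    sub = detect_genes(records) if detected_only else records
    sub = sub.loc[sub[key].notna()]
    sub = add_rpkm(sub)
    mat = sub.pivot_table(
        index="sample_id", columns=key, values="rpkm", aggfunc="sum", fill_value=0.0
    )
    # keep every input sample, even if nothing was detected in it
    return mat.reindex(sorted(records["sample_id"].unique()), fill_value=0.0)


def cazyme_genus_share(
    records: pd.DataFrame,
    metadata: pd.DataFrame,
    prevalence: pd.DataFrame,
    prevalence_min: float = 0.05,
    exclude_classes: tuple[str, ...] = EXCLUDED_CAZYME_CLASSES,
) -> pd.DataFrame:
    """Per-host relative CAZyme contribution of each genus.

    For each host: per sample, sum the RPKM of detected CAZyme genes
    (families outside the excluded GT/AA classes) per genus; average the
    sums across the host's samples; normalize across genera whose
    prevalence in that host exceeds ``prevalence_min``.  ``prevalence``
    is a genus x host matrix of detection fractions.
    """
    sub = add_rpkm(detect_genes(records))
    sub = sub.loc[sub["cazyme_family"].notna()]
    cls = sub["cazyme_family"].astype(str).str.extract(r"^([A-Za-z]+)")[0]
    sub = sub.loc[~cls.isin(exclude_classes)]
    sub = sub.merge(
        metadata[["host_species"]], left_on="sample_id", right_index=True
    )
    hosts = list(dict.fromkeys(metadata["host_species"]))
    rows = {}
    for h in hosts:
        hs = sub.loc[sub["host_species"] == h]
        n_samples = (metadata["host_species"] == h).sum()
        per_sample = hs.pivot_table(
            index="sample_id", columns="genus", values="rpkm",
            aggfunc="sum", fill_value=0.0,
        )
        # average over *all* of the host's samples, absent ones counting 0
        mean_sum = per_sample.sum(axis=0) / max(n_samples, 1)
        if h in prevalence.columns:
            eligible = prevalence.index[prevalence[h] > prevalence_min]
            mean_sum = mean_sum.loc[mean_sum.index.intersection(eligible)]
        total = mean_sum.sum()
        if total == 0 or mean_sum.empty:
            warnings.warn(f"no eligible CAZyme-carrying genus in host {h}")
            rows[h] = pd.Series(dtype=float)
        else:
            rows[h] = mean_sum / total
    return pd.DataFrame(rows).T.fillna(0.0)


def rclr_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Robust centered log-ratio: center ln(x) over positive entries only.

    Zeros are treated as uninformative and stay 0 after centering; a row
    with no positive entry is an error.
    """
    vals = matrix.to_numpy(float)
    if (vals < 0).any():
        raise ValueError("negative entries in composition matrix")
    pos = vals > 0
    if not pos.any(axis=1).all():
        raise ValueError("sample with all-zero features: rclr undefined")
    logs = np.zeros_like(vals)
    np.log(vals, out=logs, where=pos)
    means = logs.sum(axis=1) / pos.sum(axis=1)
    out = np.where(pos, logs - means[:, None], 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def robust_aitchison(matrix: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between rclr-transformed samples."""
    t = rclr_transform(matrix).to_numpy(float)
    g = t @ t.T
    sq = np.diag(g)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * g, 0.0)
    return DistanceMatrix(list(matrix.index.astype(str)), np.sqrt(d2))
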