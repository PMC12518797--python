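"""Prevalence, Rohde's host-specificity index and specificity calls.

Rohde's index summarizes how concentrated a species' prevalence is on
one host: hosts are ranked by descending prevalence and the index is
S = sum_j(p_j / r_j) / sum_j(p_j).  S = 1 for a strict specialist and
(1 + 1/2 + ... + 1/H)/H for a perfectly uniform generalist over H hosts.

Species shared across hosts are further classified as host-specific at
the strain level when their popANI strain profiles cluster significantly
by host (PERMANOVA p < 0.01), mirroring the three-way categorization
species_specific / strain_specific / non_specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RohdeResult",
    "SpecificityCall",
    "prevalence_matrix",
    "rohde_index",
    "classify_specificity",
]


@dataclass
class RohdeResult:
    species_id: str | None
    index: float
    ranks: pd.Series  # host -> rank (1 = highest prevalence)
    hosts_present: int


@dataclass
class SpecificityCall:
    species_id: str
    category: str  # species_specific | strain_specific | non_specific
    p_value: float | None = None
    untested: bool = False


def prevalence_matrix(
    presence: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Species x host matrix of per-host detection fractions.

    ``presence`` is the boolean sample x species matrix; ``metadata``
    maps sample_id (index) to host_species.  Hosts without samples are
    excluded with a warning.  Returns (prevalence, per-host counts).
    """
    hosts = metadata.loc[presence.index, "host_species"]
    counts = hosts.value_counts()
    empty = counts[counts == 0]
    if len(empty):
        warnings.warn(f"hosts without samples excluded: {list(empty.index)}")
    prev = presence.groupby(hosts).mean().T  # species x host
    return prev, counts.reindex(prev.columns)


def rohde_index(
    prevalence: pd.Series, species_id: str | None = None
) -> RohdeResult:
    """Rohde's specificity index for one species' prevalence row.

    Hosts are ranked 1..H by descending prevalence, ties broken by host
    name; S = sum(p_j / r_j) / sum(p_j).  All-zero rows are undefined.
    """
    p = prevalence.astype(float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("prevalence outside [0, 1]")
    if p.sum() == 0:
        raise ValueError("species absent from all hosts: index undefined")
    order = sorted(p.index, key=lambda h: (-p[h], str(h)))
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order).reindex(p.index)
    s = float((p / ranks).sum() / p.sum())
    return RohdeResult(species_id, s, ranks, int((p > 0).sum()))


def classify_specificity(
    species_id: str,
    presence: pd.DataFrame,
    metadata: pd.DataFrame,
    strain_permanova_p: float | None = None,
    alpha: float = 0.01,
) -> SpecificityCall:
    """Three-way specificity category for one species.

    Detected in a single host -> species_specific.  Shared species with
    a strain-level PERMANOVA p below ``alpha`` -> strain_specific; shared
    with p >= alpha or with no analyzable strain data -> non_specific
    (the latter flagged untested).
    """
    if species_id not in presence.columns:
        raise KeyError(species_id)
    col = presence[species_id]
    if not col.any():
        raise ValueError(f"{species_id} absent from all samples")
    hosts = metadata.loc[col[col].index, "host_species"].unique()
    if len(hosts) == 1:
        return SpecificityCall(species_id, "species_specific")
    if strain_permanova_p is None:
        return SpecificityCall(species_id, "non_specific", None, untested=True)
    if strain_permanova_p < alpha:
        return SpecificityCall(species_id, "strain_specific", strain_permanova_p)
    return SpecificityCall(species_id, "non_specific", strain_permanova_p)
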