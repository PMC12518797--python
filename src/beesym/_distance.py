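"""Square symmetric distance matrices with labels and an optional missing-pair mask.

This is the shared currency of the strain, community and co-phylogeny
modules: popANI matrices may have missing (ineligible) pairs, community
and patristic matrices are complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    """Labelled square symmetric dissimilarity matrix.

    Parameters
    ----------
    labels : ordered identifiers (samples, tips or hosts).
    values : square array; symmetric, zero diagonal, entries >= 0.
        Missing pairs are NaN and mirrored in ``mask``.
    """

    labels: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # True where the entry is defined

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if self.mask is None:
            self.mask = ~np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        finite = self.values[self.mask]
        if finite.size and (finite < -1e-12).any():
            raise ValueError("negative distances")
        with np.errstate(invalid="ignore"):
            asym = np.nan_to_num(self.values) - np.nan_to_num(self.values.T)
        if np.abs(asym).max(initial=0.0) > 1e-9 or (self.mask != self.mask.T).any():
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(np.nan_to_num(self.values)), 0.0, atol=1e-9):
            raise ValueError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def complete(self) -> bool:
        return bool(self.mask.all())

    def index_of(self, label: str) -> int:
        return self.labels.index(str(label))

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index_of(l) for l in labels]
        sub = self.values[np.ix_(idx, idx)]
        return DistanceMatrix([self.labels[i] for i in idx], sub.copy())

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) entries in row-major order."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        return cls.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))
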