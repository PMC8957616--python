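"""Core tabular containers: count tables and CLR matrices.

A :class:`CountTable` is a samples x taxa matrix of non-negative integer
read counts together with per-sample metadata (subject id, timepoint).
A :class:`ClrMatrix` is the centered log-ratio transform of such a table,
carrying provenance of the settings that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_METADATA = ("subject", "timepoint")


class TableValidationError(ValueError):
    """Raised when a count table violates its structural contract."""


@dataclass
class CountTable:
    """Samples x taxa integer abundance matrix with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are taxon ids, values are
        non-negative integers (read counts).
    metadata
        DataFrame indexed by sample id with at least ``subject`` and
        ``timepoint`` columns, covering every sample in ``counts``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].tolist()
            raise TableValidationError(f"duplicate sample ids: {dupes}")
        if c.columns.has_duplicates:
            dupes = c.columns[c.columns.duplicated()].tolist()
            raise TableValidationError(f"duplicate taxon ids: {dupes}")
        arr = c.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise TableValidationError("counts must be numeric")
            neg = np.argwhere(arr < 0)
            if neg.size:
                s, t = neg[0]
                raise TableValidationError(
                    f"negative count at sample {c.index[s]!r}, taxon {c.columns[t]!r}"
                )
            frac = np.argwhere(arr != np.floor(arr))
            if frac.size:
                s, t = frac[0]
                raise TableValidationError(
                    f"non-integer count at sample {c.index[s]!r}, taxon {c.columns[t]!r}"
                )
        missing = set(c.index) - set(self.metadata.index)
        if missing:
            raise TableValidationError(f"metadata missing samples: {sorted(missing)}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise TableValidationError(f"metadata lacks required column {col!r}")

    # -- convenience -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample read depth (row sums)."""
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids) -> "CountTable":
        sample_ids = list(sample_ids)
        return CountTable(
            counts=self.counts.loc[sample_ids].copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
        )

    def drop_sample(self, sample_id: str) -> "CountTable":
        if sample_id not in self.counts.index:
            raise KeyError(f"sample {sample_id!r} not in table")
        keep = [s for s in self.counts.index if s != sample_id]
        return self.select_samples(keep)

    def select_taxa(self, taxon_ids) -> "CountTable":
        taxon_ids = list(taxon_ids)
        return CountTable(
            counts=self.counts[taxon_ids].copy(),
            metadata=self.metadata.copy(),
        )

    def samples_for_timepoint(self, timepoint: str) -> list[str]:
        meta = self.metadata.loc[self.counts.index]
        return list(meta.index[meta["timepoint"] == timepoint])

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.metadata.loc[
            self.counts.index, list(REQUIRED_METADATA)
        ].equals(other.metadata.loc[other.counts.index, list(REQUIRED_METADATA)])


@dataclass
class ClrMatrix:
    """Centered log-ratio transformed table; rows sum to zero."""

    values: pd.DataFrame
    pseudocount: float
    provenance: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)
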