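"""In-memory containers shared across the pipeline.

The central object is :class:`OmicsBlock`, a subjects-by-features numeric
matrix with identifier metadata, a feature-kind label (``"protein"`` or
``"metabolite"``) and an optional per-subject run-day label used by the
run-day median normalization. Values are held in a pandas DataFrame whose
index is the subject identifier and whose columns are the feature
identifiers; missing measurements are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

FEATURE_KINDS = ("protein", "metabolite")


class ConfigurationError(ValueError):
    """A configuration object violates one of its invariants."""


class DataError(ValueError):
    """Input data violate a precondition of an operation."""


@dataclass
class OmicsBlock:
    """Subjects x features matrix for one omics assay.

    Parameters
    ----------
    data
        DataFrame indexed by subject id, one column per feature. NaN marks
        a missing measurement.
    kind
        ``"protein"`` or ``"metabolite"``; a single label for the block.
    run_day
        Optional per-subject run-day labels (aligned with ``data.index``),
        required only by run-day normalization.
    """

    data: pd.DataFrame
    kind: str
    run_day: Optional[pd.Series] = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ConfigurationError(
                f"feature kind must be one of {FEATURE_KINDS}, got {self.kind!r}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate subject ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate feature ids: {dups}")
        if self.run_day is not None:
            self.run_day = self.run_day.reindex(self.data.index)
            if self.run_day.isna().any():
                missing = self.run_day.index[self.run_day.isna()].tolist()
                raise DataError(f"run_day label missing for subjects: {missing}")

    # -- convenience accessors -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "OmicsBlock":
        return OmicsBlock(
            self.data.copy(),
            self.kind,
            None if self.run_day is None else self.run_day.copy(),
        )

    def with_data(self, data: pd.DataFrame) -> "OmicsBlock":
        """New block with replaced values; run-day labels follow the index."""
        run_day = None
        if self.run_day is not None:
            run_day = self.run_day.reindex(data.index)
        return OmicsBlock(data, self.kind, run_day)

    def subset_subjects(self, subject_ids) -> "OmicsBlock":
        return self.with_data(self.data.loc[subject_ids])

    def subset_features(self, feature_ids) -> "OmicsBlock":
        return self.with_data(self.data[list(feature_ids)])
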