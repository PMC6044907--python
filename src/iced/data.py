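"""Person-by-occasion data container for repeated-measures reliability models."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


class Dataset:
    """Wide repeated-measures data: one row per person, one column per occasion.

    Wraps a pandas DataFrame whose index holds unique person identifiers
    and whose columns are occasion identifiers; NaN marks a missing cell.
    An optional ``group`` series (aligned with persons) supports
    multi-group models.

    Rows with no observed cell at all are rejected: such persons carry
    no information and break person-wise FIML.
    """

    def __init__(self, values: pd.DataFrame, group: pd.Series | None = None):
        values = values.astype(float)
        if values.index.has_duplicates:
            raise ValueError("duplicate person identifiers")
        if values.columns.has_duplicates:
            raise ValueError("duplicate occasion identifiers")
        if len(values) == 0:
            raise ValueError("empty dataset")
        all_missing = values.isna().all(axis=1)
        if all_missing.any():
            bad = list(values.index[all_missing])
            raise ValueError(f"persons with all cells missing: {bad}")
        self.values = values
        if group is not None:
            group = pd.Series(group)
            if not group.index.equals(values.index):
                group = group.reindex(values.index)
            if group.isna().any():
                raise ValueError("group label missing for some persons")
        self.group = group

    # -- constructors -------------------------------------------------
    @classmethod
    def from_wide(cls, frame: pd.DataFrame, person_col: str | None = None,
                  group_col: str | None = None) -> "Dataset":
        """Build from a wide frame with a person-id column (or index)."""
        frame = frame.copy()
        if group_col is None and "group" in frame.columns:
            group_col = "group"
        group = None
        if group_col is not None and group_col in frame.columns:
            group = frame.pop(group_col)
        if person_col is not None:
            frame = frame.set_index(person_col)
            if group is not None:
                group.index = frame.index
        return cls(frame, group)

    @classmethod
    def from_long(cls, frame: pd.DataFrame, person: str = "person",
                  occasion: str = "occasion", value: str = "value",
                  group: str = "group") -> "Dataset":
        """Pivot long-format rows to wide; absent pairs become missing."""
        if len(frame) == 0:
            raise ValueError("empty long-format table")
        dup = frame.duplicated(subset=[person, occasion])
        if dup.any():
            pairs = frame.loc[dup, [person, occasion]].values.tolist()
            raise ValueError(f"duplicate (person, occasion) pairs: {pairs}")
        wide = frame.pivot(index=person, columns=occasion, values=value)
        # preserve first-appearance order (pivot sorts both axes)
        order = list(dict.fromkeys(frame[occasion]))
        wide = wide.loc[list(dict.fromkeys(frame[person])), order]
        wide.index.name = None
        wide.columns.name = None
        g = None
        if group in frame.columns:
            per = frame.groupby(person)[group].agg(lambda s: s.iloc[0])
            g = per.reindex(wide.index)
        return cls(wide, g)

    # -- basic protocol -----------------------------------------------
    @property
    def person_ids(self) -> list:
        return list(self.values.index)

    @property
    def occasions(self) -> list:
        return list(self.values.columns)

    @property
    def n_persons(self) -> int:
        return len(self.values)

    def __repr__(self) -> str:
        miss = int(self.values.isna().sum().sum())
        return (f"Dataset({self.n_persons} persons x {len(self.occasions)} "
                f"occasions, {miss} missing cells)")

    def align(self, occasions: Sequence) -> "Dataset":
        """Reorder/select columns to match a design's occasion order."""
        missing = [o for o in occasions if o not in self.values.columns]
        if missing:
            raise ValueError(f"dataset lacks occasions {missing}")
        return Dataset(self.values[list(occasions)], self.group)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, observed-mask) as numpy arrays."""
        y = self.values.to_numpy(dtype=float)
        return y, ~np.isnan(y)

    def split_groups(self) -> dict:
        """Split into one Dataset per group label (requires group)."""
        if self.group is None:
            raise ValueError("dataset has no group labels")
        out = {}
        for label in pd.unique(self.group):
            mask = (self.group == label).to_numpy()
            out[label] = Dataset(self.values.loc[mask], None)
        return out
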