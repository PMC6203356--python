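"""Minimal aligned-read records (ReadSet) used throughout the pipeline.

A ReadSet wraps a pandas DataFrame with one row per alignment:

======================  =======================================================
column                  meaning
======================  =======================================================
read_id                 query name (shared between mates of a pair)
chrom                   reference name
start                   0-based leftmost aligned position
end                     0-based exclusive alignment end (start + aligned bases)
strand                  '+' or '-'
mapq                    mapping quality, 0-255
is_paired               record comes from a paired-end library
is_first_of_pair        first-of-mate flag (implies is_paired)
======================  =======================================================

The 5' position of a read is `start` on the plus strand and `end - 1` on the
minus strand; fragment extension in the peak caller uses this convention.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COLUMNS = (
    "read_id",
    "chrom",
    "start",
    "end",
    "strand",
    "mapq",
    "is_paired",
    "is_first_of_pair",
)


class ReadSet:
    """Table of aligned reads; immutable by convention."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"ReadSet missing columns: {missing}")
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["mapq"] = df["mapq"].astype(np.int64)
        df["is_paired"] = df["is_paired"].astype(bool)
        df["is_first_of_pair"] = df["is_first_of_pair"].astype(bool)
        if validate and len(df):
            if (df["start"] < 0).any():
                raise ValueError("negative start coordinate")
            if (df["end"] < df["start"]).any():
                raise ValueError("end < start")
            if (~df["strand"].isin(["+", "-"])).any():
                raise ValueError("strand must be '+' or '-'")
            if ((df["mapq"] < 0) | (df["mapq"] > 255)).any():
                raise ValueError("mapq out of [0, 255]")
            if (df["is_first_of_pair"] & ~df["is_paired"]).any():
                raise ValueError("is_first_of_pair set on an unpaired record")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"ReadSet(n={len(self)})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadSet):
            return NotImplemented
        return self.df.equals(other.df)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "ReadSet":
        return cls(pd.DataFrame(list(records), columns=list(COLUMNS)))

    @classmethod
    def empty(cls) -> "ReadSet":
        return cls(pd.DataFrame(columns=list(COLUMNS)), validate=False)

    @classmethod
    def concat(cls, parts: Sequence["ReadSet"]) -> "ReadSet":
        if not parts:
            return cls.empty()
        return cls(
            pd.concat([p.df for p in parts], ignore_index=True), validate=False
        )

    def subset(self, indices) -> "ReadSet":
        return ReadSet(self.df.iloc[np.asarray(indices)], validate=False)

    def filter_mapq(self, min_mapq: int) -> "ReadSet":
        if min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        return ReadSet(self.df[self.df["mapq"] >= min_mapq], validate=False)

    def chrom_counts(self) -> dict[str, int]:
        return self.df["chrom"].value_counts().to_dict()

    def five_prime(self) -> np.ndarray:
        """5'-end position per read (strand-aware)."""
        minus = (self.df["strand"] == "-").to_numpy()
        pos = self.df["start"].to_numpy().copy()
        pos[minus] = self.df["end"].to_numpy()[minus] - 1
        return pos
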