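"""Shared containers: the marker map and the line-by-marker genotype matrix.

Genotype calls are dosages of the parent-B (alternate) allele: 0 = parent-A
homozygote, 1 = heterozygote, 2 = parent-B homozygote.  Absent calls use the
sentinel :data:`MISSING`; it is never treated as a dosage — every numeric path
masks it out explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sentinel for an absent genotype call (stored as -1 in the int8 matrix).
MISSING: int = -1

_ALLOWED_CALLS = frozenset({0, 1, 2, MISSING})


class MarkerMap:
    """Ordered marker coordinates: marker -> (chromosome, bp, cM).

    Markers are sorted by (chrom, pos_bp); genetic positions are
    non-decreasing within a chromosome.  This is the coordinate backbone for
    linkage simulation, flanking-marker lookup and window arithmetic.
    """

    COLUMNS = ("marker_id", "chrom", "pos_bp", "pos_cM")

    def __init__(self, table: pd.DataFrame):
        missing_cols = set(self.COLUMNS) - set(table.columns)
        if missing_cols:
            raise ValueError(f"marker map missing columns: {sorted(missing_cols)}")
        table = table.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if table["marker_id"].duplicated().any():
            dup = table.loc[table["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker_id: {dup!r}")
        if (table["pos_bp"] < 1).any():
            raise ValueError("pos_bp must be >= 1 (1-based coordinates)")
        if (table["pos_cM"] < 0).any():
            raise ValueError("pos_cM must be non-negative")
        # stable sort keeps input order for ties
        table = table.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
        for _, sub in table.groupby("chrom", sort=False):
            if (np.diff(sub["pos_cM"].to_numpy()) < 0).any():
                raise ValueError("pos_cM must be non-decreasing within a chromosome")
        self.table = table
        self._index = {m: i for i, m in enumerate(table["marker_id"])}

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._index

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def chroms(self) -> list[str]:
        return self.table["chrom"].drop_duplicates().tolist()

    def index_of(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not in map") from None

    def row(self, marker_id: str) -> pd.Series:
        return self.table.iloc[self.index_of(marker_id)]

    def chrom_slice(self, chrom: str) -> pd.DataFrame:
        """Rows for one chromosome, in map order."""
        return self.table[self.table["chrom"] == chrom]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str}))

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerMap) and self.table.equals(other.table)


@dataclass
class GenotypeMatrix:
    """Lines x markers call matrix over {0, 1, 2, MISSING}."""

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # int8, shape (n_lines, n_markers)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        bad = set(np.unique(self.calls)) - _ALLOWED_CALLS
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line_ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker_ids")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def is_missing(self) -> np.ndarray:
        return self.calls == MISSING

    def dosage(self) -> np.ndarray:
        """Float dosage matrix with NaN where the call is missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.line_ids), list(self.marker_ids), self.calls.copy())

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in matrix") from None

    def line_index(self, line_id: str) -> int:
        try:
            return self.line_ids.index(line_id)
        except ValueError:
            raise KeyError(f"line {line_id!r} not in matrix") from None

    def subset_markers(self, marker_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in marker_ids]
        return GenotypeMatrix(list(self.line_ids), list(marker_ids), self.calls[:, idx])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
        )


def trait_table(line_ids, values) -> pd.DataFrame:
    """Per-line trait values (one averaged value per line)."""
    return pd.DataFrame({"line_id": list(line_ids), "value": np.asarray(values, dtype=float)})
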