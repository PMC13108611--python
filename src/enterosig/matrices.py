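"""Samples x features abundance container and TSV/CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

KINDS = ("MAG", "KO")


@dataclass
class AbundanceMatrix:
    """Non-negative samples x features abundance table.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Non-negative counts or relative abundances.
    sample_ids, feature_ids : list of str
        Unique row / column identifiers.
    kind : {"MAG", "KO"}
        Feature layer: metagenome-assembled genomes (taxonomic) or
        KEGG Orthology groups (functional).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    kind: str = "MAG"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample ids / {len(self.feature_ids)} feature ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "MAG") -> "AbundanceMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
            kind=kind,
        )

    def subset_features(self, keep: np.ndarray) -> "AbundanceMatrix":
        keep = np.asarray(keep)
        return AbundanceMatrix(
            values=self.values[:, keep],
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[j] for j in keep],
            kind=self.kind,
        )


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance(path: str | Path, kind: str = "MAG") -> AbundanceMatrix:
    """Read a TSV/CSV abundance table (rows = samples, header = feature ids).

    The delimiter is chosen from the extension (.csv -> comma, else tab).
    Validation errors name the offending cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(
            f"{path}: missing/ragged value at sample {df.index[r]!r}, "
            f"feature {df.columns[c]!r}"
        )
    try:
        return AbundanceMatrix.from_frame(df, kind=kind)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_abundance(m: AbundanceMatrix, path: str | Path) -> None:
    path = Path(path)
    m.to_frame().to_csv(path, sep=_delimiter_for(path))
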