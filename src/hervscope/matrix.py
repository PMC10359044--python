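"""Count-matrix container shared by the preprocessing and DE stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample metadata: condition (case/control), batch, library size."""

    sample_id: str
    condition: str
    batch: str = "b1"
    library_size_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.library_size_factor <= 0:
            raise ValueError("library_size_factor must be positive")


@dataclass
class CountMatrix:
    """Integer features x samples counts plus sample metadata.

    ``counts`` is a DataFrame whose index holds feature ids and whose
    columns hold sample ids, in the same order as ``samples``.
    """

    counts: pd.DataFrame
    samples: list[SampleDesign] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = [
                SampleDesign(str(c), "unknown") for c in self.counts.columns
            ]
        if list(self.counts.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("count columns must match sample metadata order")
        if self.counts.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    # -- convenience accessors ------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([s.condition for s in self.samples])

    @property
    def batches(self) -> np.ndarray:
        return np.array([s.batch for s in self.samples])

    def subset_features(self, keep: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(keep)], list(self.samples))

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), list(self.samples))

    # -- I/O ------------------------------------------------------------------
    def to_tsv(self, counts_path: str | Path, samples_path: str | Path | None = None) -> None:
        out = self.counts.copy()
        out.index.name = "feature_id"
        out.to_csv(counts_path, sep="\t")
        if samples_path is not None:
            write_sample_sheet(self.samples, samples_path)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path | None = None) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = read_sample_sheet(samples_path) if samples_path else []
        return cls(counts, samples)


def write_sample_sheet(samples: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "condition": [s.condition for s in samples],
            "batch": [s.batch for s in samples],
            "library_size_factor": [s.library_size_factor for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleDesign(
            str(r.sample_id),
            str(r.condition),
            str(r.batch),
            float(getattr(r, "library_size_factor", 1.0)),
        )
        for r in df.itertuples()
    ]


def write_gmt(pathways: dict[str, set[str] | list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    """Write gene sets in GMT format: name<TAB>description<TAB>gene..."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            pathways[parts[0]] = set(parts[2:])
    return pathways
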