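"""Core in-memory containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, ShapeError


@dataclass
class OmicsMatrix:
    """One modality's samples × genes matrix.

    Attributes
    ----------
    values : ndarray, shape (n_samples, n_genes)
    gene_ids : list of str, unique, column order
    sample_ids : list of str, unique, row order
    modality : "expression" or "methylation"
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    modality: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ShapeError("values must be 2-D (samples × genes)")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ShapeError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.gene_ids)} genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidConfigError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidConfigError("duplicate sample ids")
        if self.modality not in ("expression", "methylation"):
            raise InvalidConfigError(f"unknown modality {self.modality!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "OmicsMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in genes]
        return OmicsMatrix(self.values[:, cols], list(genes),
                           self.sample_ids, self.modality)

    def subset_samples(self, samples: Sequence[str]) -> "OmicsMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in samples]
        return OmicsMatrix(self.values[rows, :], self.gene_ids,
                           list(samples), self.modality)

    def to_frame(self) -> pd.DataFrame:
        """Genes × samples frame (the on-disk orientation)."""
        return pd.DataFrame(self.values.T, index=self.gene_ids,
                            columns=self.sample_ids)


@dataclass
class SurvivalData:
    """Right-censored follow-up: one (time, event) pair per sample.

    time is in months and strictly positive; event is 1 for deceased,
    0 for censored.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.time = np.asarray(self.time, dtype=np.float64)
        self.event = np.asarray(self.event, dtype=np.int64)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ShapeError("time/event length must match sample count")
        if np.any(self.time <= 0):
            raise InvalidConfigError("follow-up times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise InvalidConfigError("event indicator must be 0 or 1")
        if len(set(self.sample_ids)) != n:
            raise InvalidConfigError("duplicate sample ids in survival data")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, samples: Sequence[str]) -> "SurvivalData":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in samples]
        return SurvivalData(list(samples), self.time[rows], self.event[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.sample_ids,
                             "time_months": self.time,
                             "event": self.event})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalData":
        return cls(df["sample"].astype(str).tolist(),
                   df["time_months"].to_numpy(),
                   df["event"].to_numpy())


@dataclass
class GeneAnnotation:
    """Gene → (chromosome, start) map used for genomic ordering."""

    gene_ids: list[str]
    chromosome: list[str]
    start: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.chromosome = [str(c) for c in self.chromosome]
        self.start = np.asarray(self.start, dtype=np.int64)
        n = len(self.gene_ids)
        if len(self.chromosome) != n or self.start.shape != (n,):
            raise ShapeError("annotation columns must have equal length")
        if len(set(self.gene_ids)) != n:
            raise InvalidConfigError("duplicate gene ids in annotation")
        if np.any(self.start < 0):
            raise InvalidConfigError("negative start coordinate")
        keys = set(zip(self.chromosome, self.start.tolist(), self.gene_ids))
        if len(keys) != n:
            raise InvalidConfigError("duplicate (chrom, start, gene) triple")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def lookup(self) -> dict[str, tuple[str, int]]:
        return {g: (c, int(s)) for g, c, s in
                zip(self.gene_ids, self.chromosome, self.start)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chromosome,
                             "start": self.start,
                             "end": self.start + 1,
                             "gene": self.gene_ids})


@dataclass
class GroundTruth:
    """What the synthetic generator actually planted, for scoring recovery."""

    support_x: np.ndarray
    support_y: np.ndarray
    latent: np.ndarray
    risk_coef: np.ndarray
    block_map: dict[int, int] = field(default_factory=dict)
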