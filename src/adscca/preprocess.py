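"""Harmonization and normalization with a strict fit-on-train contract.

Pipeline for expression: log2(RSEM + 1) → per-gene z-score; methylation
beta values are z-scored only. Low-variance genes (train variance below a
percentile of the train variance distribution) are dropped. Every fitted
statistic lives in a serializable PreprocessState so test folds are
transformed with train-fitted moments, never refit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import OmicsMatrix
from .errors import (AdsccaError, EmptyIntersectionError, InvalidConfigError,
                     SampleMismatchError)

#: floor applied to a zero per-gene standard deviation at fit time
SD_FLOOR = 1e-8


def harmonize_genes(x: OmicsMatrix, y: OmicsMatrix,
                    allow_subset: bool = False
                    ) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Restrict both modalities to their common genes, in identical order,
    with samples aligned to a common (sorted) order.

    Gene order is the sorted intersection; downstream stages rely on the
    positional pairing this creates. Sample sets must match exactly
    unless ``allow_subset`` permits dropping to the intersection.
    """
    common_genes = sorted(set(x.gene_ids) & set(y.gene_ids))
    if not common_genes:
        raise EmptyIntersectionError("no genes shared between modalities")
    sx, sy = set(x.sample_ids), set(y.sample_ids)
    if sx != sy:
        if not allow_subset:
            raise SampleMismatchError(
                f"sample sets differ ({len(sx - sy)} only in x, "
                f"{len(sy - sx)} only in y); pass allow_subset to intersect")
        common_samples = sorted(sx & sy)
        if not common_samples:
            raise SampleMismatchError("no samples shared between modalities")
    else:
        common_samples = sorted(sx)
    return (x.subset_genes(common_genes).subset_samples(common_samples),
            y.subset_genes(common_genes).subset_samples(common_samples))


def log_transform(x: OmicsMatrix) -> OmicsMatrix:
    """log2(v + 1) on every entry (expression counts)."""
    if np.any(x.values < 0):
        raise AdsccaError("log transform requires non-negative values")
    return OmicsMatrix(np.log2(x.values + 1.0), x.gene_ids, x.sample_ids,
                       x.modality)


@dataclass
class PreprocessState:
    """Train-fitted per-gene moments and/or variance-filter mask."""

    modality: str
    gene_ids: list[str]
    mean: Optional[np.ndarray] = None
    sd: Optional[np.ndarray] = None
    keep_mask: Optional[np.ndarray] = None
    flagged_zero_var: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        return json.dumps({
            "modality": self.modality,
            "gene_ids": self.gene_ids,
            "mean": arr(self.mean),
            "sd": arr(self.sd),
            "keep_mask": arr(self.keep_mask),
            "flagged_zero_var": self.flagged_zero_var,
        })

    @classmethod
    def from_json(cls, text: str) -> "PreprocessState":
        d = json.loads(text)
        return cls(
            modality=d["modality"],
            gene_ids=list(d["gene_ids"]),
            mean=None if d["mean"] is None else np.asarray(d["mean"]),
            sd=None if d["sd"] is None else np.asarray(d["sd"]),
            keep_mask=(None if d["keep_mask"] is None
                       else np.asarray(d["keep_mask"], dtype=bool)),
            flagged_zero_var=list(d["flagged_zero_var"]),
        )

    def _check_genes(self, x: OmicsMatrix) -> None:
        if x.gene_ids != self.gene_ids:
            raise InvalidConfigError(
                "matrix gene ids do not match the fitted state")


def zscore_fit(x: OmicsMatrix) -> PreprocessState:
    """Fit per-gene mean and standard deviation on training samples.

    Zero-variance genes get their sd floored (never a division by zero)
    and are recorded in ``flagged_zero_var``; the variance filter removes
    them whenever its percentile is positive.
    """
    if x.n_samples < 2:
        raise InvalidConfigError("z-score fit needs at least 2 samples")
    mean = x.values.mean(axis=0)
    sd = x.values.std(axis=0, ddof=0)
    flagged = [g for g, s in zip(x.gene_ids, sd) if s < SD_FLOOR]
    sd = np.maximum(sd, SD_FLOOR)
    return PreprocessState(modality=x.modality, gene_ids=list(x.gene_ids),
                           mean=mean, sd=sd, flagged_zero_var=flagged)


def zscore_apply(state: PreprocessState, x: OmicsMatrix) -> OmicsMatrix:
    """Standardize with train-fitted moments (no refitting)."""
    state._check_genes(x)
    vals = (x.values - state.mean) / state.sd
    return OmicsMatrix(vals, x.gene_ids, x.sample_ids, x.modality)


def variance_filter_fit(x: OmicsMatrix, pct: float) -> PreprocessState:
    """Mask genes whose train variance falls strictly below the ``pct``-th
    percentile of train variances (linear-interpolation percentile)."""
    if not 0.0 <= pct < 100.0:
        raise InvalidConfigError(f"pct must be in [0, 100), got {pct}")
    var = x.values.var(axis=0, ddof=0)
    if pct == 0.0:
        keep = np.ones(x.n_genes, dtype=bool)
    else:
        cutoff = np.percentile(var, pct, method="linear")
        keep = var >= cutoff
    if not keep.any():
        raise AdsccaError("variance filter removed every gene")
    return PreprocessState(modality=x.modality, gene_ids=list(x.gene_ids),
                           keep_mask=keep)


def variance_filter_apply(state: PreprocessState,
                          x: OmicsMatrix) -> OmicsMatrix:
    state._check_genes(x)
    kept = [g for g, k in zip(x.gene_ids, state.keep_mask) if k]
    return x.subset_genes(kept)


@dataclass
class FittedPreprocess:
    """The full train-fitted pipeline for one modality."""

    modality: str
    var_state: Optional[PreprocessState]
    z_state: PreprocessState

    def apply(self, x: OmicsMatrix) -> OmicsMatrix:
        if self.modality == "expression":
            x = log_transform(x)
        if self.var_state is not None:
            x = variance_filter_apply(self.var_state, x)
        return zscore_apply(self.z_state, x)


def fit_preprocess(x_train: OmicsMatrix, variance_pct: float = 10.0
                   ) -> FittedPreprocess:
    """Fit the modality-appropriate pipeline on training data only:
    (log2 for expression) → variance filter → z-score."""
    x = log_transform(x_train) if x_train.modality == "expression" else x_train
    var_state = None
    if variance_pct > 0:
        var_state = variance_filter_fit(x, variance_pct)
        x = variance_filter_apply(var_state, x)
    z_state = zscore_fit(x)
    return FittedPreprocess(x_train.modality, var_state, z_state)
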