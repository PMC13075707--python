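"""Cross-fold stability-driven feature selection.

A gene counts as selected in a fold if it appears in the sparse support
of either modality for that fold; the stable set keeps genes selected in
at least ``min_folds`` of the folds (the reference rule is 9 of 10),
which suppresses fold-specific false positives in high dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

SupportPair = tuple[Sequence[Union[int, str]], Sequence[Union[int, str]]]


@dataclass
class SelectionProfile:
    """Per-gene number of folds in which the gene was selected."""

    gene_ids: list[str]
    count: np.ndarray
    n_folds: int

    def __post_init__(self):
        self.count = np.asarray(self.count, dtype=np.int64)
        if np.any(self.count < 0) or np.any(self.count > self.n_folds):
            raise InvalidConfigError("counts must lie in [0, n_folds]")

    @property
    def frequency(self) -> np.ndarray:
        return self.count / self.n_folds

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene_ids, "count": self.count,
                             "frequency": self.frequency})


def _to_gene_ids(support: Sequence[Union[int, str]],
                 gene_ids: Sequence[str]) -> set[str]:
    out: set[str] = set()
    for s in support:
        if isinstance(s, str):
            if s not in gene_ids:
                raise IndexError(f"unknown gene id {s!r}")
            out.add(s)
        else:
            idx = int(s)
            if not 0 <= idx < len(gene_ids):
                raise IndexError(f"support index {idx} out of range")
            out.add(gene_ids[idx])
    return out


def selection_frequency(supports: Sequence[SupportPair],
                        gene_ids: Sequence[str],
                        gene_ids_y: Sequence[str] | None = None
                        ) -> SelectionProfile:
    """Count, per gene, the folds where it has nonzero weight in either
    modality (per-fold OR: a gene in both supports counts once).

    Supports may be index arrays (resolved against ``gene_ids`` for the
    first modality and ``gene_ids_y`` — default the same list — for the
    second) or gene-id sequences.
    """
    gene_ids = list(gene_ids)
    gy = list(gene_ids_y) if gene_ids_y is not None else gene_ids
    universe = list(dict.fromkeys(gene_ids + gy))
    counts = {g: 0 for g in universe}
    for support_x, support_y in supports:
        fold_genes = _to_gene_ids(support_x, gene_ids) | _to_gene_ids(support_y, gy)
        for g in fold_genes:
            counts[g] += 1
    return SelectionProfile(universe,
                            np.array([counts[g] for g in universe]),
                            n_folds=len(supports))


def stable_set(profile: SelectionProfile, min_folds: int) -> list[str]:
    """Genes selected in ≥ ``min_folds`` folds, sorted by count descending
    then gene id (deterministic for reproducible downstream sequences)."""
    if not 0 < min_folds <= profile.n_folds:
        raise InvalidConfigError(
            f"min_folds must be in (0, {profile.n_folds}], got {min_folds}")
    pairs = [(g, c) for g, c in zip(profile.gene_ids, profile.count)
             if c >= min_folds]
    pairs.sort(key=lambda gc: (-gc[1], gc[0]))
    return [g for g, _ in pairs]
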