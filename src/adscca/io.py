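"""File formats: TSV matrices (genes × samples, FireBrowse-style),
clinical survival tables, BED-like gene annotation, and the YAML run
configuration. All writers round-trip exactly through their readers."""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .containers import GeneAnnotation, OmicsMatrix, SurvivalData
from .dscca import TrainConfig
from .errors import ParseError
from .simulate import SimConfig
from .survhead import SurvHeadConfig

log = logging.getLogger("adscca")


# ---------------------------------------------------------------------------
# Omics matrices: rows = genes, first column gene symbol, columns = samples


def write_matrix_tsv(x: OmicsMatrix, path: str | Path) -> None:
    df = x.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix_tsv(path: str | Path, modality: str) -> OmicsMatrix:
    """Parse a genes × samples TSV into the samples × genes container.

    Duplicate gene symbols or sample ids, ragged rows and non-numeric
    cells are rejected with the offending symbol/line named.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene symbol {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError:
        for i, (gene, row) in enumerate(df.iterrows(), start=2):
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} for gene "
                        f"{gene!r}, sample {sample!r} (line {i})") from None
        raise
    if np.isnan(values).any():
        gi, si = np.argwhere(np.isnan(values))[0]
        raise ParseError(f"{path}: missing value for gene "
                         f"{df.index[gi]!r}, sample {df.columns[si]!r}")
    return OmicsMatrix(values.T, list(df.index.astype(str)),
                       list(df.columns.astype(str)), modality)


# ---------------------------------------------------------------------------
# Clinical survival table


def write_clinical_tsv(surv: SurvivalData, path: str | Path) -> None:
    surv.to_frame().to_csv(path, sep="\t", index=False,
                           float_format="%.17g")


def read_clinical_tsv(path: str | Path) -> SurvivalData:
    """Read (sample, time_months, event); rows with time ≤ 0 are dropped
    and counted in the log, per the overall-survival exclusion rule."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "time_months", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    ev = pd.to_numeric(df["event"], errors="coerce")
    bad = df.loc[~ev.isin([0, 1]), "event"]
    if len(bad):
        raise ParseError(f"{path}: event must be 0 or 1, got {bad.iloc[0]!r}")
    t = pd.to_numeric(df["time_months"], errors="coerce")
    if t.isna().any():
        raise ParseError(f"{path}: non-numeric time_months")
    keep = t > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("%s: excluded %d records with OS time ≤ 0", path, n_dropped)
        warnings.warn(f"excluded {n_dropped} records with OS time ≤ 0")
    return SurvivalData(df.loc[keep, "sample"].tolist(),
                        t[keep].to_numpy(), ev[keep].to_numpy())


# ---------------------------------------------------------------------------
# BED-like annotation (chrom, start, end, name; 0-based half-open)


def write_bed(ann: GeneAnnotation, path: str | Path) -> None:
    ann.to_frame().to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> GeneAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene"],
                     dtype={"chrom": str, "gene": str})
    start = pd.to_numeric(df["start"], errors="coerce")
    if start.isna().any() or (start < 0).any():
        raise ParseError(f"{path}: start must be a non-negative integer")
    return GeneAnnotation(df["gene"].tolist(), df["chrom"].tolist(),
                          start.to_numpy(dtype=np.int64))


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class CVSettings:
    k_outer: int = 10
    k_inner: int = 10
    min_folds: Optional[int] = None
    variance_pct: float = 10.0


@dataclass
class RunConfig:
    """Everything one run needs: input paths, generator settings, model
    and CV hyperparameters, seeds and the output directory."""

    expression: Optional[str] = None
    methylation: Optional[str] = None
    clinical: Optional[str] = None
    annotation: Optional[str] = None
    outdir: str = "runs/out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    dscca: TrainConfig = field(default_factory=TrainConfig)
    surv: SurvHeadConfig = field(default_factory=SurvHeadConfig)
    cv: CVSettings = field(default_factory=CVSettings)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub in (("sim", SimConfig), ("dscca", TrainConfig),
                         ("surv", SurvHeadConfig), ("cv", CVSettings)):
            section = raw.pop(key, {}) or {}
            unknown = set(section) - {f for f in sub().__dict__}
            if unknown:
                raise ParseError(f"{path}: unknown {key} keys {sorted(unknown)}")
            val = sub(**section)
            if isinstance(val, TrainConfig) and val.fixed_lambdas is not None:
                val.fixed_lambdas = tuple(val.fixed_lambdas)
            kwargs[key] = val
        known = {f for f in cls().__dict__ if f not in kwargs}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def effective_dict(self) -> dict:
        return asdict(self)
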