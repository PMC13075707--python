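"""Nested, event-stratified cross-validation orchestration.

The outer loop estimates generalization: preprocessing, sparse-CCA
feature selection and the survival head are all fitted strictly on the
outer-training samples. Within each outer-training set, an inner loop
refits the sparse-CCA model per inner fold; stability selection over the
inner folds yields that outer fold's gene panel, so no outer-test sample
ever influences gene selection or any fitted statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import GeneAnnotation, OmicsMatrix, SurvivalData
from .dscca import TrainConfig, extract_support, train_dscca
from .errors import InvalidConfigError
from .evalmetrics import (EvalReport, bonferroni, cohens_d, evaluate_risks,
                          wilcoxon_signed_rank)
from .preprocess import fit_preprocess, harmonize_genes
from .stability import selection_frequency, stable_set
from .survhead import (SurvHeadConfig, build_sequence, order_genes,
                       predict_risk, train_surv_head)


@dataclass
class FoldSplit:
    """One outer-CV partition."""

    fold_id: int
    train_ids: list[str]
    test_ids: list[str]


def stratified_folds(surv: SurvivalData, k: int = 10,
                     seed: int = 0) -> list[FoldSplit]:
    """Event-stratified k-fold partition: events and censored samples are
    shuffled (seeded) and dealt round-robin, so per-fold event counts
    differ by at most one and the folds partition the cohort."""
    n = len(surv)
    if k > n or k < 2:
        raise InvalidConfigError(f"k={k} invalid for {n} samples")
    n_events = surv.n_events
    if k > n_events or k > n - n_events:
        warnings.warn(f"k={k} exceeds the size of one stratum "
                      f"({n_events} events / {n - n_events} censored); "
                      "some folds will lack that stratum")
    rng = np.random.default_rng(seed)
    ids = np.asarray(surv.sample_ids)
    test_sets: list[list[str]] = [[] for _ in range(k)]
    for val in (1, 0):
        grp = ids[surv.event == val]
        grp = grp[rng.permutation(grp.size)]
        for i, s in enumerate(grp):
            test_sets[i % k].append(str(s))
    folds = []
    for f in range(k):
        test = sorted(test_sets[f])
        test_set = set(test)
        train = [s for s in surv.sample_ids if s not in test_set]
        folds.append(FoldSplit(f, train, test))
    return folds


@dataclass
class NestedCVConfig:
    """Settings for the full nested experiment.

    ``min_folds`` defaults to k_inner − 1 (the 9-of-10 rule at the
    reference fold count). ``hidden_width_grid`` with more than one
    entry selects the encoder width by mean inner validation canonical
    correlation.
    """

    k_outer: int = 10
    k_inner: int = 10
    min_folds: Optional[int] = None
    variance_pct: float = 10.0
    dscca: TrainConfig = field(default_factory=TrainConfig)
    surv: SurvHeadConfig = field(default_factory=SurvHeadConfig)
    hidden_width_grid: tuple[int, ...] = ()
    fallback_panel_size: int = 20
    seed: int = 0

    def resolved_min_folds(self) -> int:
        return self.min_folds if self.min_folds is not None \
            else max(1, self.k_inner - 1)


@dataclass
class RunResult:
    """Everything the nested protocol produces, plus a leakage audit
    trail (per outer fold, the inner-fold training-id sets)."""

    fold_reports: list[EvalReport]
    gene_panels: list[list[str]]
    traces: list
    fold_splits: list[FoldSplit]
    audit_inner_train_ids: list[list[set[str]]]
    chosen_widths: list[int]

    def cindexes(self) -> np.ndarray:
        return np.array([r.c_index for r in self.fold_reports])

    def aggregate(self) -> dict:
        c = self.cindexes()
        return {"mean_c_index": float(c.mean()),
                "sd_c_index": float(c.std(ddof=1)) if c.size > 1 else 0.0,
                "n_folds": len(self.fold_reports)}


def _inner_supports(x_tr: OmicsMatrix, y_tr: OmicsMatrix,
                    surv_tr: SurvivalData, cfg: NestedCVConfig,
                    width: Optional[int], seed: int
                    ) -> tuple[list, list[set[str]], float]:
    """Run the sparse-CCA model on each inner fold of an outer-training
    set; returns per-fold supports (as gene-id pairs), the audit list of
    inner training-id sets, and the mean validation correlation."""
    inner = stratified_folds(surv_tr, k=cfg.k_inner, seed=seed)
    supports = []
    audit = []
    val_corrs = []
    for fold in inner:
        audit.append(set(fold.train_ids))
        xi_tr = x_tr.subset_samples(fold.train_ids)
        yi_tr = y_tr.subset_samples(fold.train_ids)
        xi_va = x_tr.subset_samples(fold.test_ids)
        yi_va = y_tr.subset_samples(fold.test_ids)
        prep_x = fit_preprocess(xi_tr, cfg.variance_pct)
        prep_y = fit_preprocess(yi_tr, cfg.variance_pct)
        xz, yz = prep_x.apply(xi_tr), prep_y.apply(yi_tr)
        xv, yv = prep_x.apply(xi_va), prep_y.apply(yi_va)
        dcfg = TrainConfig(**{**cfg.dscca.__dict__,
                              "seed": cfg.dscca.seed + fold.fold_id,
                              **({"hidden_width": width} if width else {})})
        params, trace = train_dscca(xz.values, yz.values,
                                    xv.values, yv.values, dcfg)
        sup_x, sup_y = extract_support(params)
        supports.append(([xz.gene_ids[j] for j in sup_x],
                         [yz.gene_ids[j] for j in sup_y]))
        if trace.val_corr:
            val_corrs.append(abs(trace.val_corr[-1]))
    mean_val = float(np.mean(val_corrs)) if val_corrs else 0.0
    return supports, audit, mean_val


def run_nested_cv(x: OmicsMatrix, y: OmicsMatrix, surv: SurvivalData,
                  annotation: GeneAnnotation,
                  cfg: Optional[NestedCVConfig] = None) -> RunResult:
    """The full nested experiment on aligned inputs.

    Per outer fold: inner-fold sparse-CCA runs → stability selection
    (≥ min_folds of k_inner) → gene panel; preprocessing and the
    BiLSTM–Cox head are fitted on the outer-training samples only and
    evaluated on the held-out outer-test fold.
    """
    cfg = cfg or NestedCVConfig()
    x, y = harmonize_genes(x, y)
    surv = surv.subset(x.sample_ids)
    outer = stratified_folds(surv, k=cfg.k_outer, seed=cfg.seed)
    reports, panels, traces, audits, widths = [], [], [], [], []
    for fold in outer:
        x_tr = x.subset_samples(fold.train_ids)
        y_tr = y.subset_samples(fold.train_ids)
        surv_tr = surv.subset(fold.train_ids)
        surv_te = surv.subset(fold.test_ids)

        # inner loop: stability selection (and optional width grid)
        grid = cfg.hidden_width_grid or (None,)
        best = None
        for width in grid:
            sup, audit, val = _inner_supports(
                x_tr, y_tr, surv_tr, cfg, width,
                seed=cfg.seed + 1000 * (fold.fold_id + 1))
            if best is None or val > best[2]:
                best = (sup, audit, val, width)
        supports, audit, _, width = best
        audits.append(audit)
        widths.append(width if width is not None
                      else (cfg.dscca.hidden_width or -1))
        profile = selection_frequency(supports, x.gene_ids)
        panel = stable_set(profile, cfg.resolved_min_folds())
        if not panel:
            warnings.warn(f"outer fold {fold.fold_id}: empty stable set; "
                          "falling back to top-frequency genes")
            df = profile.to_frame().sort_values(
                ["count", "gene"], ascending=[False, True])
            panel = df["gene"].head(cfg.fallback_panel_size).tolist()
        panels.append(panel)

        # outer-train-fitted preprocessing, survival head, evaluation
        prep_x = fit_preprocess(x_tr, cfg.variance_pct)
        prep_y = fit_preprocess(y_tr, cfg.variance_pct)
        xz_tr, yz_tr = prep_x.apply(x_tr), prep_y.apply(y_tr)
        xz_te = prep_x.apply(x.subset_samples(fold.test_ids))
        yz_te = prep_y.apply(y.subset_samples(fold.test_ids))
        usable = [g for g in panel
                  if g in set(xz_tr.gene_ids) | set(yz_tr.gene_ids)]
        ordered = order_genes(usable, annotation)
        seq_tr = build_sequence(xz_tr, yz_tr, ordered)
        seq_te = build_sequence(xz_te, yz_te, ordered)
        scfg = SurvHeadConfig(**{**cfg.surv.__dict__,
                                 "seed": cfg.surv.seed + fold.fold_id})
        head = train_surv_head(seq_tr, surv_tr, scfg)
        risks = predict_risk(head, seq_te)
        reports.append(evaluate_risks(risks, surv_te))
        traces.append(None)
    return RunResult(reports, panels, traces, outer, audits, widths)


def compare_methods(cindex_a: Sequence[float], cindex_b: Sequence[float],
                    m: int = 1) -> dict:
    """Paired Wilcoxon signed-rank on per-fold C-index vectors, with
    Bonferroni adjustment for a family of ``m`` comparisons and the
    paired Cohen's d effect size."""
    a = np.asarray(cindex_a, dtype=np.float64)
    b = np.asarray(cindex_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidConfigError("per-fold C-index vectors must pair up")
    if np.all(a == b):
        p = 1.0
        d = 0.0
    else:
        p = wilcoxon_signed_rank(a, b)
        d = cohens_d(a, b)
    return {"p": float(p), "p_adjusted": float(bonferroni(p, m)),
            "cohens_d": float(d)}
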