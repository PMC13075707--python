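"""Bundled synthetic study designs.

Each function runs one self-contained experiment on generated data and
returns the quantities it measured. They are the package's reference
protocols for checking that the model behaves as designed:

* linear-limit equivalence against the closed-form CCA solution,
* sparse-support recovery through cross-fold stability selection,
* survival-head learning against the true-risk oracle,
* the gene-order shuffle test on interaction vs additive hazards,
* training-dynamics monitoring of the adaptive multi-task weights.

Problem sizes are chosen so every study runs in minutes on one CPU
while leaving a clear margin between signal and noise; the methods note
documents each design.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla

from .containers import SurvivalData
from .cv import stratified_folds
from .dscca import TrainConfig, extract_support, train_dscca
from .evalmetrics import concordance_index
from .preprocess import fit_preprocess
from .simulate import (SimConfig, assign_genomic_coordinates,
                       generate_blocked_risk, generate_paired_omics,
                       generate_survival)
from .stability import selection_frequency, stable_set
from .survhead import (SurvHeadConfig, build_sequence, order_genes,
                       predict_risk, shuffle_test, train_surv_head)


def linear_cca_first_correlation(x: np.ndarray, y: np.ndarray,
                                 reg: float = 1e-8) -> float:
    """First canonical correlation by the generalized eigenproblem
    (the closed-form oracle, independent of any gradient training)."""
    x = np.asarray(x, float) - np.asarray(x, float).mean(0)
    y = np.asarray(y, float) - np.asarray(y, float).mean(0)
    n = x.shape[0]
    sxx = x.T @ x / n + reg * np.eye(x.shape[1])
    syy = y.T @ y / n + reg * np.eye(y.shape[1])
    sxy = x.T @ y / n
    m = sla.solve(sxx, sxy) @ sla.solve(syy, sxy.T)
    return float(np.sqrt(np.max(sla.eigvals(m).real)))


def linear_limit_study(seed: int = 0, n: int = 500, p: int = 20,
                       q: int = 20, epochs: int = 300) -> dict:
    """Gaussian shared-factor data; the network in its linear,
    unpenalized limit should match the closed-form first canonical
    correlation."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    x = 0.9 * np.outer(z, rng.normal(size=p) / np.sqrt(p)) \
        + rng.normal(size=(n, p)) * 0.5
    y = 0.9 * np.outer(z, rng.normal(size=q) / np.sqrt(q)) \
        + rng.normal(size=(n, q)) * 0.5
    x = (x - x.mean(0)) / x.std(0)
    y = (y - y.mean(0)) / y.std(0)
    oracle = linear_cca_first_correlation(x, y)
    cfg = TrainConfig(epochs=epochs, batch_size=None, linear_limit=True,
                      lr=5e-3, fixed_lambdas=(1.0, 0.0, 1e-3, 1e-3),
                      weight_decay=0.0, seed=seed)
    _, trace = train_dscca(x, y, cfg=cfg)
    achieved = abs(trace.train_corr[-1])
    return {"oracle_corr": oracle, "achieved_corr": achieved,
            "gap": abs(achieved - oracle), "n": n}


def support_recovery_study(seed: int = 1, n: int = 300, p: int = 200,
                           q: int = 200, s: int = 20, k_folds: int = 10,
                           min_folds: int = 9, epochs: int = 80) -> dict:
    """Stability selection over k folds on sparse-factor data; scores the
    stable gene panel against the planted support (recall and false-
    discovery proportion)."""
    cfg = SimConfig(n=n, p=p, q=q, s=s, signal=2.0, noise_sd=1.0,
                    seed=seed)
    x, y, gt = generate_paired_omics(cfg)
    surv = generate_survival(np.zeros(n), 0.0, 0.3, seed=seed + 100,
                             sample_ids=x.sample_ids)
    truth = {x.gene_ids[j] for j in gt.support_x} \
        | {y.gene_ids[j] for j in gt.support_y}
    folds = stratified_folds(surv, k=k_folds, seed=seed)
    supports = []
    for fold in folds:
        xt = x.subset_samples(fold.train_ids)
        yt = y.subset_samples(fold.train_ids)
        px = fit_preprocess(xt, 10.0)
        py = fit_preprocess(yt, 10.0)
        xz, yz = px.apply(xt), py.apply(yt)
        tc = TrainConfig(epochs=epochs, batch_size=32, seed=fold.fold_id)
        params, _ = train_dscca(xz.values, yz.values, cfg=tc)
        sx, sy = extract_support(params)
        supports.append(([xz.gene_ids[j] for j in sx],
                         [yz.gene_ids[j] for j in sy]))
    profile = selection_frequency(supports, x.gene_ids)
    panel = set(stable_set(profile, min_folds))
    recall = len(panel & truth) / len(truth)
    fdp = len(panel - truth) / max(1, len(panel))
    return {"recall": recall, "fdp": fdp, "panel_size": len(panel),
            "truth_size": len(truth), "n": n}


def _additive_benchmark(seed: int, n: int = 400, p: int = 20,
                        coef_scale: float = 0.25, censor: float = 0.3):
    """Paired data with an additive expression-driven hazard (±coef_scale
    per gene) plus the matching genomic annotation."""
    cfg = SimConfig(n=n, p=p, q=p, s=5, signal=2.0, noise_sd=1.0, seed=seed)
    x, y, gt = generate_paired_omics(cfg)
    coef = np.random.default_rng(5).choice([-1.0, 1.0], size=p) * coef_scale
    lp = gt.raw_x @ coef
    surv = generate_survival(lp, 1.0, censor, seed=seed + 1,
                             sample_ids=x.sample_ids)
    ann = assign_genomic_coordinates(x.gene_ids, 2, 5, seed=0)
    return x, y, gt, lp, surv, ann


def survival_benchmark_study(seed: int = 0, epochs: int = 200,
                             n_control: int = 5) -> dict:
    """Train/test evaluation of the recurrent Cox head on additive-risk
    data, with the true-linear-predictor oracle and a permuted-label
    control (averaged over ``n_control`` permutations to estimate the
    control's expected concordance)."""
    x, y, gt, lp, surv, ann = _additive_benchmark(seed)
    folds = stratified_folds(surv, k=4, seed=2)
    tr, te = folds[0].train_ids, folds[0].test_ids
    px = fit_preprocess(x.subset_samples(tr), 0.0)
    py = fit_preprocess(y.subset_samples(tr), 0.0)
    ordered = order_genes(x.gene_ids, ann)
    seq_tr = build_sequence(px.apply(x.subset_samples(tr)),
                            py.apply(y.subset_samples(tr)), ordered)
    seq_te = build_sequence(px.apply(x.subset_samples(te)),
                            py.apply(y.subset_samples(te)), ordered)
    surv_tr, surv_te = surv.subset(tr), surv.subset(te)
    idx = {s: i for i, s in enumerate(x.sample_ids)}
    oracle_c = concordance_index(lp[[idx[s] for s in te]], surv_te)

    scfg = SurvHeadConfig(epochs=epochs, weight_decay=3e-2, seed=seed + 3)
    head = train_surv_head(seq_tr, surv_tr, scfg)
    test_c = concordance_index(predict_risk(head, seq_te), surv_te)

    perm_cs = []
    for k in range(n_control):
        rng = np.random.default_rng(seed + 9 + k)
        perm = rng.permutation(len(surv_tr))
        surv_perm = SurvivalData(surv_tr.sample_ids, surv_tr.time[perm],
                                 surv_tr.event[perm])
        head_p = train_surv_head(seq_tr, surv_perm, scfg)
        perm_cs.append(concordance_index(predict_risk(head_p, seq_te),
                                         surv_te))
    return {"test_cindex": float(test_c), "oracle_cindex": float(oracle_c),
            "permuted_cindex": float(np.mean(perm_cs)), "n": len(surv)}


def shuffle_study(seed: int = 0, blocked: bool = True, n: int = 400,
                  p: int = 24, n_perm: int = 20, epochs: int = 200) -> dict:
    """Genomic-order shuffle test.

    With ``blocked`` the hazard lives in products of genomically
    adjacent gene pairs (window 2), so permuting the order destroys the
    structure the recurrent head exploits; without it the hazard is
    additive and order carries no information.
    """
    cfg = SimConfig(n=n, p=p, q=p, s=0, signal=0.0, noise_sd=1.0,
                    seed=seed)
    x, y, gt = generate_paired_omics(cfg)
    if blocked:
        gt.risk_coef = np.full(p, 0.05)
        br = generate_blocked_risk(gt, window=2, interaction_strength=0.6)
        lp = br.linear_predictor(gt.raw_x)
    else:
        coef = np.random.default_rng(5).choice([-1.0, 1.0], size=p) * 0.25
        lp = gt.raw_x @ coef
    surv = generate_survival(lp, 1.0, 0.25, seed=seed + 1,
                             sample_ids=x.sample_ids)
    ann = assign_genomic_coordinates(x.gene_ids, 2, 2, seed=0)
    px = fit_preprocess(x, 0.0)
    py = fit_preprocess(y, 0.0)
    scfg = SurvHeadConfig(epochs=epochs, weight_decay=1e-3, seed=seed + 3)
    rep = shuffle_test(px.apply(x), py.apply(y), x.gene_ids, ann, surv,
                       scfg, n_perm=n_perm, seed=seed + 5)
    return {"ordered_cindex": rep.ordered_cindex,
            "mean_shuffled_cindex": rep.mean_shuffled_cindex,
            "sd_shuffled_cindex": float(np.std(rep.shuffled_cindex)),
            "cindex_drop": rep.cindex_drop,
            "oracle_cindex": float(concordance_index(lp, surv)),
            "report": rep, "n": n}


def training_dynamics_study(seed: int = 0, epochs: int = 300,
                            smooth_window: int = 31) -> dict:
    """Monitor a full adaptive run: loss components, λ trajectories and
    the smoothed total objective after the burn-in phase."""
    cfg = SimConfig(n=200, p=40, q=40, s=8, signal=2.0, noise_sd=1.0,
                    seed=seed)
    x, y, _ = generate_paired_omics(cfg)
    px = fit_preprocess(x, 10.0)
    py = fit_preprocess(y, 10.0)
    _, trace = train_dscca(px.apply(x).values, py.apply(y).values,
                           cfg=TrainConfig(epochs=epochs, batch_size=32,
                                           seed=seed + 1))
    total = np.asarray(trace.total)
    lam = np.asarray(trace.lambdas)
    comps = np.column_stack([trace.l_corr, trace.l_sparse,
                             trace.l_recon, trace.l_norm, total])
    smoothed = np.convolve(total, np.ones(smooth_window) / smooth_window,
                           mode="valid")
    after = smoothed[max(0, 50 - smooth_window // 2):]
    return {"max_smoothed_increase_after_50": float(np.diff(after).max()),
            "lambda_min": float(lam.min()), "lambda_max": float(lam.max()),
            "all_finite": bool(np.isfinite(comps).all()),
            "trace": trace, "n": cfg.n}
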