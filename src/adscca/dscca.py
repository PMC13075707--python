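"""Multi-task adaptive deep sparse CCA.

Two identity-anchored nonlinear encoders (one per omics modality) keep
the gene interface: encoded coordinate j stays anchored to gene j while
a residual branch captures nonlinear corrections. The default branch is
gene-local — h = x + φ(x) with φ a shared scalar MLP, which can undo
per-modality monotone distortions but cannot mix genes, so the sparse
gate keeps its gene-level meaning — with a dense bottleneck MLP variant
(batch norm + ReLU, genes mixed) and a near-identity linear variant
available via ``TrainConfig.encoder``. Sparse canonical weight vectors
u, v act elementwise on the encoded features; the canonical variate is
t = ⟨h, u⟩, which reduces to the linear CCA projection Xu when the
branch is inactive.

Training jointly minimizes four weighted objectives —

* correlation:    −Pearson(t_x, t_y) over the batch,
* sparsity:       ‖u‖₁ + ‖v‖₁,
* reconstruction: mean squared error of linear decoders X̂, Ŷ from h,
* normalization:  (Var(t_x) − 1)² + (Var(t_y) − 1)²,

with task weights λᵢ = 1/(2σᵢ²), σᵢ = softplus(raw_σᵢ) + floor learned by
homoscedastic-uncertainty weighting. A +log σᵢ stabilizer per task keeps
the weights from collapsing (σ → ∞ would otherwise zero every task); it
is optimized but reported separately from the weighted total.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import (AdsccaError, BatchTooSmallError, InvalidConfigError,
                     ShapeError)
from .nn import (MLP, Adam, GeneLocalMLP, Linear, Module, Tensor,
                 mean_pearson, variance)

#: softplus offset bounding λ = 1/(2σ²) from above
SIGMA_FLOOR = 1e-3
#: variance guard inside the Pearson denominator
CORR_EPS = 1e-8


@dataclass
class TrainConfig:
    """Optimization settings for the sparse-CCA network.

    Defaults follow the reference protocol (Adam at 1e-3 halved every
    100 epochs, 1000 epochs, batches of 32, weight decay 1e-4, gradient
    clipping at global norm 5); tests and the bundled experiments run
    shorter desk-scale schedules via these same knobs.
    """

    epochs: int = 1000
    lr: float = 1e-3
    lr_decay: float = 0.5
    lr_decay_every: int = 100
    batch_size: Optional[int] = 32      # None → full batch
    weight_decay: float = 1e-4
    clip_norm: float = 5.0
    encoder: str = "gene-local"         # "gene-local" | "dense" | "linear"
    hidden_width: Optional[int] = None  # dense: min(256, 4·p); local: 8
    seed: int = 0
    epsilon_select: float = 0.01
    linear_limit: bool = False
    fixed_lambdas: Optional[tuple[float, float, float, float]] = None

    def validate(self) -> None:
        if self.epochs < 0:
            raise InvalidConfigError("epochs must be ≥ 0")
        if self.lr <= 0 or self.clip_norm <= 0 or self.weight_decay < 0:
            raise InvalidConfigError("lr/clip_norm must be positive")
        if self.batch_size is not None and self.batch_size < 3:
            raise InvalidConfigError("batch_size must be ≥ 3 (or None)")
        if self.epsilon_select < 0:
            raise InvalidConfigError("epsilon_select must be ≥ 0")
        if self.encoder not in ("gene-local", "dense", "linear"):
            raise InvalidConfigError(f"unknown encoder {self.encoder!r}")


class DsccaParams(Module):
    """All trainable state: encoders, decoders, u, v and raw σ."""

    def __init__(self, p: int, q: int, cfg: TrainConfig):
        super().__init__()
        self.p, self.q = p, q
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        mode = "linear" if cfg.linear_limit else cfg.encoder
        self.encoder_mode = mode
        if mode == "linear":
            # single near-identity linear layers, no normalization
            self.encoder_x = MLP([p, p], rng, batchnorm=False,
                                 activation="none", init="identity")
            self.encoder_y = MLP([q, q], rng, batchnorm=False,
                                 activation="none", init="identity")
            self.residual = False
        elif mode == "gene-local":
            w = cfg.hidden_width or 8
            self.encoder_x = GeneLocalMLP(w, rng)
            self.encoder_y = GeneLocalMLP(w, rng)
            self.residual = True
        else:  # dense residual bottleneck (mixes genes; see docs)
            wx = cfg.hidden_width or min(256, 4 * p)
            wy = cfg.hidden_width or min(256, 4 * q)
            self.encoder_x = MLP([p, wx, p], rng, batchnorm=True)
            self.encoder_y = MLP([q, wy, q], rng, batchnorm=True)
            # zero-init the branch output so h = x at initialization
            self.encoder_x.lin1.W.data[:] = 0.0
            self.encoder_y.lin1.W.data[:] = 0.0
            self.residual = True
        self.decoder_x = Linear(p, p, rng)
        self.decoder_y = Linear(q, q, rng)
        self.u = Tensor(rng.normal(0.0, 1.0 / np.sqrt(p), size=p),
                        requires_grad=True)
        self.v = Tensor(rng.normal(0.0, 1.0 / np.sqrt(q), size=q),
                        requires_grad=True)
        self.raw_sigma = Tensor(np.zeros(4), requires_grad=True)

    # -- forward pieces --------------------------------------------------

    def encode_x_t(self, x: Tensor) -> Tensor:
        h = self.encoder_x(x)
        return x + h if self.residual else h

    def encode_y_t(self, y: Tensor) -> Tensor:
        h = self.encoder_y(y)
        return y + h if self.residual else h

    def sigmas(self) -> np.ndarray:
        return np.logaddexp(0.0, self.raw_sigma.data) + SIGMA_FLOOR


@dataclass
class LossBreakdown:
    """The four loss components, their weights, and the weighted total.

    ``sigma_penalty`` is the Σ log σᵢ stabilizer: part of the optimized
    objective under adaptive weighting, reported separately from
    ``total`` = Σ λᵢ·lᵢ.
    """

    l_corr: float
    l_sparse: float
    l_recon: float
    l_norm: float
    lambdas: tuple[float, float, float, float]
    sigmas: tuple[float, float, float, float]
    total: float
    sigma_penalty: float

    def components(self) -> dict[str, float]:
        return {"l_corr": self.l_corr, "l_sparse": self.l_sparse,
                "l_recon": self.l_recon, "l_norm": self.l_norm,
                "total": self.total}


def task_weights(raw_sigma: np.ndarray,
                 sigma_floor: float = SIGMA_FLOOR
                 ) -> tuple[np.ndarray, np.ndarray]:
    """λᵢ = 1/(2σᵢ²) with σᵢ = softplus(raw_σᵢ) + floor; always positive."""
    raw_sigma = np.asarray(raw_sigma, dtype=np.float64)
    if raw_sigma.shape != (4,):
        raise ShapeError("raw_sigma must have length 4")
    sigma = np.logaddexp(0.0, raw_sigma) + sigma_floor
    return 1.0 / (2.0 * sigma ** 2), sigma


def encode(params: DsccaParams, x: np.ndarray) -> np.ndarray:
    """Encode expression features (inference mode, running BN statistics)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != params.p:
        raise ShapeError(f"expected (n, {params.p}) input, got {x.shape}")
    params.eval()
    return params.encode_x_t(Tensor(x)).data


def encode_y(params: DsccaParams, y: np.ndarray) -> np.ndarray:
    """Encode methylation features (inference mode)."""
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 2 or y.shape[1] != params.q:
        raise ShapeError(f"expected (n, {params.q}) input, got {y.shape}")
    params.eval()
    return params.encode_y_t(Tensor(y)).data


def canonical_variate(h: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-sample variate tᵢ = Σⱼ hᵢⱼ·wⱼ — the gated sum ⟨h, w⟩, equal to
    the linear projection Xw under an identity encoder."""
    h = np.asarray(h, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if h.ndim != 2 or w.shape != (h.shape[1],):
        raise ShapeError(f"weight length {w.shape} does not match {h.shape}")
    return h @ w


def _loss_graph(params: DsccaParams, x: Tensor, y: Tensor
                ) -> tuple[Tensor, LossBreakdown]:
    """Build the differentiable objective; returns (objective, breakdown)."""
    n = x.shape[0]
    if n < 3:
        raise BatchTooSmallError(
            f"batch of {n} too small for correlation/variance terms")
    hx = params.encode_x_t(x)
    hy = params.encode_y_t(y)
    tx = hx @ params.u
    ty = hy @ params.v
    l_corr = -mean_pearson(tx, ty, eps=CORR_EPS)
    l_sparse = params.u.abs().sum() + params.v.abs().sum()
    xhat = params.decoder_x(hx)
    yhat = params.decoder_y(hy)
    l_recon = ((x - xhat) ** 2).mean() + ((y - yhat) ** 2).mean()
    l_norm = (variance(tx) - 1.0) ** 2 + (variance(ty) - 1.0) ** 2

    if params.cfg.fixed_lambdas is not None:
        lam = np.asarray(params.cfg.fixed_lambdas, dtype=np.float64)
        sig = np.sqrt(1.0 / (2.0 * np.maximum(lam, 1e-12)))
        total = (float(lam[0]) * l_corr + float(lam[1]) * l_sparse
                 + float(lam[2]) * l_recon + float(lam[3]) * l_norm)
        objective = total
        sigma_pen = 0.0
    else:
        sigma_t = params.raw_sigma.softplus() + SIGMA_FLOOR
        lam_t = 0.5 / (sigma_t ** 2)
        total = (lam_t[0] * l_corr + lam_t[1] * l_sparse
                 + lam_t[2] * l_recon + lam_t[3] * l_norm)
        pen = sigma_t.log().sum()
        objective = total + pen
        lam = lam_t.data.copy()
        sig = sigma_t.data.copy()
        sigma_pen = float(pen.data)

    bd = LossBreakdown(
        l_corr=float(l_corr.data), l_sparse=float(l_sparse.data),
        l_recon=float(l_recon.data), l_norm=float(l_norm.data),
        lambdas=tuple(lam), sigmas=tuple(sig),
        total=float(total.data), sigma_penalty=sigma_pen)
    for name, val in bd.components().items():
        if not np.isfinite(val):
            raise AdsccaError(f"non-finite loss component: {name}")
    return objective, bd


def compute_loss_components(params: DsccaParams, x: np.ndarray,
                            y: np.ndarray,
                            training: bool = False) -> LossBreakdown:
    """Evaluate the four-term loss on a batch (inference mode by default)."""
    params.train() if training else params.eval()
    _, bd = _loss_graph(params, Tensor(np.asarray(x, dtype=np.float64)),
                        Tensor(np.asarray(y, dtype=np.float64)))
    return bd


@dataclass
class TrainTrace:
    """Per-epoch training record (loss components, λ trajectories, and
    train/validation canonical correlations on full data)."""

    l_corr: list[float] = field(default_factory=list)
    l_sparse: list[float] = field(default_factory=list)
    l_recon: list[float] = field(default_factory=list)
    l_norm: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    lambdas: list[tuple[float, float, float, float]] = field(default_factory=list)
    train_corr: list[float] = field(default_factory=list)
    val_corr: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.total)

    def to_frame(self):
        lam = np.asarray(self.lambdas).reshape(-1, 4)
        d = {"epoch": np.arange(len(self.total)),
             "l_corr": self.l_corr, "l_sparse": self.l_sparse,
             "l_recon": self.l_recon, "l_norm": self.l_norm,
             "total": self.total,
             "lambda_corr": lam[:, 0], "lambda_sparse": lam[:, 1],
             "lambda_recon": lam[:, 2], "lambda_norm": lam[:, 3],
             "train_corr": self.train_corr}
        if self.val_corr:
            d["val_corr"] = self.val_corr
        import pandas as pd
        return pd.DataFrame(d)


def _full_data_corr(params: DsccaParams, x: np.ndarray,
                    y: np.ndarray) -> float:
    params.eval()
    hx = params.encode_x_t(Tensor(x)).data
    hy = params.encode_y_t(Tensor(y)).data
    tx, ty = hx @ params.u.data, hy @ params.v.data
    sx, sy = tx.std(), ty.std()
    if sx < 1e-12 or sy < 1e-12:
        return 0.0
    return float(np.corrcoef(tx, ty)[0, 1])


def train_dscca(x_train: np.ndarray, y_train: np.ndarray,
                x_val: Optional[np.ndarray] = None,
                y_val: Optional[np.ndarray] = None,
                cfg: Optional[TrainConfig] = None
                ) -> tuple[DsccaParams, TrainTrace]:
    """Fit the sparse-CCA network.

    ``x_train``/``y_train`` are preprocessed (z-scored) samples × genes
    arrays; optional validation arrays give the held-out canonical
    correlation per epoch (computed with frozen normalization
    statistics). Fully deterministic given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    x_train = np.asarray(x_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    n = x_train.shape[0]
    if y_train.shape[0] != n:
        raise ShapeError("x_train and y_train sample counts differ")
    params = DsccaParams(x_train.shape[1], y_train.shape[1], cfg)
    trace = TrainTrace()
    if cfg.epochs == 0:
        return params, trace

    no_decay = [params.u, params.v, params.raw_sigma]
    opt = Adam(params.parameters(), lr=cfg.lr,
               weight_decay=cfg.weight_decay, clip_norm=cfg.clip_norm,
               lr_decay=cfg.lr_decay, lr_decay_every=cfg.lr_decay_every,
               decay_exclude=no_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    bs = cfg.batch_size or n
    bs = min(bs, n)

    for epoch in range(cfg.epochs):
        params.train()
        order = rng.permutation(n)
        for lo in range(0, n, bs):
            idx = order[lo:lo + bs]
            if idx.size < 3:
                continue  # too small for correlation terms
            opt.zero_grad()
            objective, _ = _loss_graph(params, Tensor(x_train[idx]),
                                       Tensor(y_train[idx]))
            objective.backward()
            opt.step(epoch=epoch)
        # epoch-end trace on full data, inference mode
        bd = compute_loss_components(params, x_train, y_train)
        trace.l_corr.append(bd.l_corr)
        trace.l_sparse.append(bd.l_sparse)
        trace.l_recon.append(bd.l_recon)
        trace.l_norm.append(bd.l_norm)
        trace.total.append(bd.total)
        trace.lambdas.append(bd.lambdas)
        trace.train_corr.append(_full_data_corr(params, x_train, y_train))
        if x_val is not None and y_val is not None:
            trace.val_corr.append(_full_data_corr(params, x_val, y_val))
    return params, trace


def extract_support(params: DsccaParams,
                    epsilon_select: Optional[float] = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Indices whose normalized weight magnitude exceeds the selection
    threshold: {j : |wⱼ| / max|w| > ε}. Continuous L1 training never
    produces exact zeros, so this operationalizes 'nonzero weight'."""
    eps = params.cfg.epsilon_select if epsilon_select is None else epsilon_select
    if eps < 0:
        raise InvalidConfigError("epsilon_select must be ≥ 0")

    def sup(w: np.ndarray) -> np.ndarray:
        m = np.abs(w).max()
        if m == 0:
            warnings.warn("all-zero canonical weights: empty support")
            return np.array([], dtype=int)
        return np.flatnonzero(np.abs(w) / m > eps)

    return sup(params.u.data), sup(params.v.data)


def save_checkpoint(params: DsccaParams, trace: TrainTrace,
                    path: str | Path) -> None:
    """Binary weight checkpoint plus a JSON sidecar with u, v, σ and the
    λ trajectories."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **params.state_dict())
    side = {
        "u": params.u.data.tolist(),
        "v": params.v.data.tolist(),
        "sigmas": params.sigmas().tolist(),
        "lambda_trajectory": [list(t) for t in trace.lambdas],
        "train_corr": trace.train_corr,
        "val_corr": trace.val_corr,
    }
    path.with_suffix(".json").write_text(json.dumps(side))
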