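"""Desk-scale end-to-end training of the encoder + CRF.

The loss is the multitag negative log likelihood plus the composition
regularizer.  Gradients are computed analytically: the NLL gradient with
respect to emissions/transitions is the difference of expected state and
transition counts between the full and the label-constrained lattices;
the regularizer is backpropagated through forward-backward with the
hand-derived vector-Jacobian product in :mod:`sigcrf.crf`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import crf, regularizer
from .crf import CrfParams, NEG, Prediction
from .encoder import GROUP_INDEX, encode_backward, encode_forward, tokenize
from .grammar import StateSpace, build_state_space
from .labeler import label_record
from .model import Model, predict
from .types import SequenceRecord, SpClass


class DegenerateRunError(RuntimeError):
    """Raised when a run collapses to the minimal-n degenerate solution
    after the first epoch; callers should restart with a new seed."""

    def __init__(self, message: str, log: Optional[list] = None):
        super().__init__(message)
        self.log = log or []


@dataclass
class TrainConfig:
    epochs: int = 15
    optimizer: str = "adamax"
    lr_peak: float = 0.05
    lr_floor: float = 1e-4
    warmup_fraction: float = 0.1
    dropout: float = 0.1
    alpha: float = 0.5
    batch_size: int = 8
    seed: int = 0
    degeneracy_check: bool = True
    degeneracy_tolerance: float = regularizer.DEGENERACY_TOLERANCE
    grad_clip: float = 5.0
    emb_dim: int = 8
    hidden_dim: int = 64
    window_radius: int = 3
    max_restarts: int = 3

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class EpochLog:
    epoch: int
    nll: float
    reg: float
    degenerate: bool


@dataclass
class TrainResult:
    model: Model
    log: list[EpochLog]
    train_ids: list[str] = field(default_factory=list)
    restarts: int = 0


class Adamax:
    """Adamax (infinity-norm Adam variant) over a dict of arrays."""

    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.u = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        bc = 1.0 - self.beta1 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.u[k] = np.maximum(self.beta2 * self.u[k], np.abs(g))
            params[k] -= (lr / bc) * self.m[k] / (self.u[k] + self.eps)


def slanted_triangular_lr(step: int, total_steps: int, peak: float,
                          floor: float, warmup_fraction: float) -> float:
    """Linear warmup to ``peak`` then linear decay to ``floor``."""
    warmup = max(1, int(round(warmup_fraction * total_steps)))
    if step < warmup:
        return floor + (peak - floor) * (step + 1) / warmup
    frac = (step - warmup) / max(1, total_steps - warmup)
    return peak - (peak - floor) * frac


def _model_param_dict(model: Model) -> dict[str, np.ndarray]:
    enc, p = model.encoder, model.params
    return {
        "emb": enc.emb, "group_emb": enc.group_emb, "bos": enc.bos,
        "eos": enc.eos, "W1": enc.W1, "b1": enc.b1,
        "W_psi": p.W_psi, "b_psi": p.b_psi, "phi": p.phi,
    }


def _edges_from_lattices(em, phi, la, lb, log_z):
    counts = np.zeros_like(phi)
    for t in range(em.shape[0] - 1):
        lp = (la[t][:, None] + phi + (em[t + 1] + lb[t + 1])[None, :]) - log_z
        with np.errstate(under="ignore"):
            counts += np.exp(lp)
    return counts


def _sequence_loss_grads(record: SequenceRecord, tags, model: Model,
                         dropout_mask: Optional[np.ndarray],
                         need_reg: bool):
    """Forward pass for one sequence.

    Returns (nll, grads, reg_info) where reg_info packages what the
    second (weighted) regularizer-gradient pass needs.
    """
    space = model.space
    params = model.params
    tokens = tokenize(record.sequence)
    h, cache = encode_forward(tokens, GROUP_INDEX[record.organism_group],
                              model.encoder)
    h_eff = h if dropout_mask is None else h * dropout_mask
    em = crf.emissions(h_eff, params)
    phi = params.masked_phi(space)

    p_full, la, lb, log_z = crf.marginals(em, params, space, with_lattices=True)
    e_full = _edges_from_lattices(em, phi, la, lb, log_z)

    em_c = crf._restrict(em, tags.sets)
    la_c = crf._forward(em_c, phi, space, check_feasible=True)
    lb_c = crf._backward(em_c, phi, space)
    log_zc = float(crf._lse(la_c[-1] + np.where(space.end_allowed, 0.0, NEG),
                            axis=0))
    if log_zc < -1e20:
        raise crf.NoPathError(f"{record.id}: labels admit no path")
    with np.errstate(under="ignore"):
        p_con = np.exp(la_c + lb_c - log_zc)
    p_con /= p_con.sum(axis=1, keepdims=True)
    e_con = _edges_from_lattices(em_c, phi, la_c, lb_c, log_zc)

    nll = log_z - log_zc
    d_em = p_full - p_con
    d_phi = e_full - e_con
    d_phi[~space.allowed] = 0.0

    reg_info = None
    if need_reg and record.sp_class is not SpClass.NO_SP:
        vectors = regularizer.region_scores(p_full, record.sequence, space)
        terms = regularizer.reg_terms_and_grads(vectors)
        reg_info = (terms, em, p_full.shape)
    return nll, d_em, d_phi, em, h_eff, cache, reg_info


def train(dataset: Sequence[SequenceRecord], config: TrainConfig,
          initial_model: Optional[Model] = None,
          val_records: Optional[Sequence[SequenceRecord]] = None,
          ) -> TrainResult:
    """Train on labeled records; returns the model and per-epoch log.

    Raises :class:`DegenerateRunError` if the degeneracy check fires
    after the first epoch (the run must be discarded and restarted).
    """
    if not dataset:
        raise ValueError("empty dataset")
    model = initial_model or Model.init(
        seed=config.seed, emb_dim=config.emb_dim,
        hidden_dim=config.hidden_dim, window_radius=config.window_radius)
    space = model.space
    tag_matrices = [label_record(r, space) for r in dataset]

    rng = np.random.default_rng(config.seed)
    params = _model_param_dict(model)
    opt = Adamax(params)
    n = len(dataset)
    steps_per_epoch = math.ceil(n / config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    step = 0
    log: list[EpochLog] = []
    # degeneracy is assessed on a bounded validation slice to keep the
    # per-epoch check cheap
    val = list(val_records) if val_records is not None else list(dataset)
    if len(val) > 100:  # spread the slice across the (class-ordered) data
        val = val[:: max(1, len(val) // 100)][:100]

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_nll, epoch_reg, n_seen = 0.0, 0.0, 0
        for b0 in range(0, n, config.batch_size):
            batch_idx = order[b0:b0 + config.batch_size]
            lr = slanted_triangular_lr(step, total_steps, config.lr_peak,
                                       config.lr_floor, config.warmup_fraction)
            step += 1
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            batch: list[tuple] = []
            need_reg = config.alpha > 0.0
            for i in batch_idx:
                rec, tags = dataset[i], tag_matrices[i]
                mask = None
                if config.dropout > 0.0:
                    mask = (rng.random((len(rec.sequence),
                                        config.hidden_dim))
                            >= config.dropout) / (1.0 - config.dropout)
                batch.append((rec,) + _sequence_loss_grads(
                    rec, tags, model, mask, need_reg) + (mask,))

            # regularizer term weights need the batch-level counts
            nh_count = sum(
                1 for item in batch
                if item[7] is not None and item[7][0]["nh"] is not None)
            hc_count = sum(
                1 for item in batch
                if item[7] is not None and item[7][0]["hc"] is not None)

            bsz = len(batch)
            for (rec, nll, d_em, d_phi, em, h_eff, cache, reg_info,
                 mask) in batch:
                epoch_nll += nll
                n_seen += 1
                d_em_total = d_em / bsz
                grads["phi"] += d_phi / bsz
                if reg_info is not None:
                    terms, em_r, shape = reg_info
                    d_marg = np.zeros(shape)
                    for key, count in (("nh", nh_count), ("hc", hc_count)):
                        if terms[key] is None or count == 0:
                            continue
                        value, d_scores = terms[key]
                        epoch_reg += config.alpha * value / count
                        w = config.alpha / count
                        d_marg += w * regularizer.scores_grad_to_marginals(
                            d_scores, rec.sequence, shape, model.space)
                    if np.any(d_marg):
                        dr_em, dr_phi = crf.marginals_vjp(
                            em, model.params, model.space, d_marg)
                        d_em_total += dr_em
                        grads["phi"] += dr_phi
                grads["W_psi"] += h_eff.T @ d_em_total
                grads["b_psi"] += d_em_total.sum(axis=0)
                d_h = d_em_total @ model.params.W_psi.T
                if mask is not None:
                    d_h = d_h * mask
                enc_grads = encode_backward(d_h, cache, model.encoder)
                for k, g in enc_grads.items():
                    grads[k] += g

            if config.grad_clip > 0:
                norm = math.sqrt(sum(float((g * g).sum())
                                     for g in grads.values()))
                if norm > config.grad_clip:
                    scale = config.grad_clip / norm
                    for k in grads:
                        grads[k] *= scale
            opt.step(params, grads, lr)
            model.params.phi[~space.allowed] = NEG

        degenerate = False
        if config.degeneracy_check:
            preds = [predict(r.sequence, r.organism_group, model)
                     for r in val]
            degenerate = regularizer.detect_degenerate(
                preds, space, tolerance=config.degeneracy_tolerance)
        log.append(EpochLog(epoch=epoch, nll=epoch_nll / max(1, n_seen),
                            reg=epoch_reg / steps_per_epoch,
                            degenerate=degenerate))
        if degenerate and epoch == 1:
            raise DegenerateRunError(
                "run converged to the minimal n-region length after one "
                "epoch; restart required", log=log)

    return TrainResult(model=model, log=log,
                       train_ids=[r.id for r in dataset])


def train_with_restarts(dataset: Sequence[SequenceRecord],
                        config: TrainConfig, **kwargs) -> TrainResult:
    """Retry degenerate runs with fresh seeds, as prescribed."""
    restarts = 0
    cfg = config
    while True:
        try:
            result = train(dataset, cfg, **kwargs)
            result.restarts = restarts
            return result
        except DegenerateRunError:
            restarts += 1
            if restarts > config.max_restarts:
                raise
            cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + 1009})


# --------------------------------------------------------- cross-validation

@dataclass
class FoldModel:
    model: Model
    outer_test: int
    inner_train: int
    train_ids: list[str]
    log: list[EpochLog]


@dataclass
class CrossValResult:
    fold_models: list[FoldModel]          # 6 models
    predictions: dict[str, Prediction]    # pooled ensembled test predictions


def ensemble_predictions(preds: Sequence[Prediction],
                         space: StateSpace) -> Prediction:
    """Average class probabilities and marginals over models; re-decode
    the path from the averaged marginals under the transition mask."""
    avg_marg = np.mean([p.marginals for p in preds], axis=0)
    avg_probs = np.mean([p.class_probs for p in preds], axis=0)
    c = space.n_states
    flat = CrfParams(W_psi=np.eye(c), b_psi=np.zeros(c),
                     phi=np.where(space.allowed, 0.0, NEG))
    with np.errstate(divide="ignore"):
        em = np.where(avg_marg > 0.0, np.log(avg_marg), NEG)
    path = crf.viterbi(em, flat, space)
    order = list(SpClass)
    cs = crf.infer_cs(path, space)
    return Prediction(
        path=path, marginals=avg_marg, class_probs=avg_probs,
        predicted_class=order[int(np.argmax(avg_probs))], cs=cs,
        cs_prob=float(avg_marg[cs - 1, path[cs - 1]]) if cs else 0.0,
    )


def nested_cv(partitions: Sequence[Sequence[SequenceRecord]],
              config: TrainConfig) -> CrossValResult:
    """Threefold outer / twofold inner nested cross-validation.

    For each outer test partition, two models are trained, one on each
    of the remaining partitions (validating on the other); the test
    partition is predicted only by models that never saw it.
    """
    if len(partitions) != 3:
        raise ValueError("nested_cv requires exactly 3 partitions")
    space = build_state_space()
    fold_models: list[FoldModel] = []
    predictions: dict[str, Prediction] = {}
    for outer in range(3):
        inner_parts = [i for i in range(3) if i != outer]
        outer_preds: dict[str, list[Prediction]] = {}
        for k, inner in enumerate(inner_parts):
            train_records = list(partitions[inner])
            val = list(partitions[inner_parts[1 - k]])
            cfg = TrainConfig(**{**config.__dict__,
                                 "seed": config.seed + 97 * outer + k})
            result = train_with_restarts(train_records, cfg, val_records=val)
            fold_models.append(FoldModel(
                model=result.model, outer_test=outer, inner_train=inner,
                train_ids=result.train_ids, log=result.log))
            for rec in partitions[outer]:
                pred = predict(rec.sequence, rec.organism_group, result.model)
                outer_preds.setdefault(rec.id, []).append(pred)
        for rid, preds in outer_preds.items():
            predictions[rid] = ensemble_predictions(preds, space)
    return CrossValResult(fold_models=fold_models, predictions=predictions)
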