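"""Semi-supervised training orchestration for the double-teacher framework.

Per iteration: the student sees perturbed labeled slices (supervised Dice)
and perturbed unlabeled slices; the 2D teacher sees the same unlabeled
slices under different perturbations; the hybrid teacher sees their
pseudo-3D stacks.  Discrepancy maps between the student heads and each
teacher's final map are combined, driven toward zero by the discrepancy
loss, and gate the region-weighted consistency losses.  One SGD step
updates the student only; the 2D teacher then tracks the student by EMA.

The hybrid teacher has no EMA partner for its stem/fusion parameters (its
architecture differs from the student's there), so it follows a two-part
rule: every parameter whose name and shape mirror the student's receives
the same EMA update, while the stem and fusion layers are trained by
gradient descent on the supervised Dice loss over the labeled samples'
stacks.  This keeps the "teacher aggregates the student" principle wherever
shapes permit while still giving the 3D pathway a learning signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FrameworkConfig
from .data import Batch, BatchIterator, SemiSupervisedDataset
from .discrepancy import (DiscrepancyRateRecord, combine_discrepancy,
                          compute_anchor, compute_d1, compute_d2,
                          discrepancy_loss, discrepancy_rate)
from .losses import (LossReport, combine_consistency, dice_loss,
                     gated_consistency_loss, total_loss, total_objective)
from .models import (build_student, build_teacher2d, build_teacher_hybrid,
                     perturb_with_rng)
from .nn import SGD, HybridUNet, Module, UNet2D

__all__ = ["TrainingState", "ema_update", "init_state", "train_step", "train",
           "epoch_mean_dr", "DualTeacherSegmenter"]


def ema_update(teacher, student, eta: float, names=None):
    """theta_T <- eta * theta_T + (1 - eta) * theta_S, name-by-name.

    Accepts two modules (updated in place) or two dicts of arrays (returns a
    new dict).  ``names`` restricts the update to a subset of parameter
    names; misaligned names or shapes raise.
    """
    if isinstance(teacher, Module):
        t_params = dict(teacher.named_parameters())
        s_params = dict(student.named_parameters())
        keys = set(t_params) if names is None else set(names)
        for k in keys:
            if k not in s_params or k not in t_params:
                raise ValueError(f"parameter {k!r} missing from one network")
            tp, sp = t_params[k], s_params[k]
            if tp.data.shape != sp.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            tp.data = eta * tp.data + (1.0 - eta) * sp.data
        return teacher
    keys = set(teacher) if names is None else set(names)
    if names is None and set(teacher) != set(student):
        raise ValueError("parameter name sets differ")
    out = dict(teacher)
    for k in keys:
        t, s = np.asarray(teacher[k]), np.asarray(student[k])
        if t.shape != s.shape:
            raise ValueError(f"shape mismatch for {k!r}")
        out[k] = eta * t + (1.0 - eta) * s
    return out


@dataclass
class TrainingState:
    student: UNet2D
    teacher1: UNet2D
    teacher2: HybridUNet | None
    optimizer: SGD
    teacher2_optimizer: SGD | None
    batches: BatchIterator
    rngs: dict[str, np.random.Generator]
    iteration: int = 0
    history: list[LossReport] = field(default_factory=list)
    dr_history: list[DiscrepancyRateRecord] = field(default_factory=list)
    shared_teacher2_names: set[str] = field(default_factory=set)
    best_student_state: dict | None = None


def _perturbation_streams(seed: int) -> dict[str, np.random.Generator]:
    # fixed stream order; the labeled-student stream is untouched by whether
    # the unsupervised machinery runs, so supervised ablations match exactly
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("student_labeled", "student_unlabeled", "teacher1", "teacher2")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def init_state(dataset: SemiSupervisedDataset, cfg: FrameworkConfig) -> TrainingState:
    """Build student, teachers, optimizers and all random streams."""
    init_children = np.random.SeedSequence(cfg.init_seed).generate_state(2) % (2 ** 31)
    student = build_student(cfg.base_channels, cfg.depth, int(init_children[0]),
                            cfg.input_size)
    teacher1 = build_teacher2d(student)
    teacher2 = None
    t2_opt = None
    shared: set[str] = set()
    if cfg.use_teacher2 and not cfg.supervised_only:
        teacher2 = build_teacher_hybrid(cfg.stack_planes, cfg.base_channels,
                                        cfg.depth, int(init_children[1]))
        extra = teacher2.extra_parameter_names()
        shared = {n for n, _ in teacher2.named_parameters()} - extra
        # start the EMA-tracked part as a copy of the student (EMA from t=0)
        ema_update(teacher2, student, 0.0, names=shared)
        teacher2.set_requires_grad(False, names=shared)
        teacher2.set_requires_grad(True, names=extra)
        t2_params = {n: p for n, p in teacher2.named_parameters() if n in extra}
        t2_opt = SGD(t2_params, lr=cfg.learning_rate, momentum=cfg.momentum,
                     weight_decay=cfg.weight_decay)
    optimizer = SGD(dict(student.named_parameters()), lr=cfg.learning_rate,
                    momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    batches = BatchIterator(dataset, cfg, np.random.default_rng(cfg.data_seed))
    return TrainingState(student=student, teacher1=teacher1, teacher2=teacher2,
                         optimizer=optimizer, teacher2_optimizer=t2_opt,
                         batches=batches,
                         rngs=_perturbation_streams(cfg.perturbation_seed),
                         shared_teacher2_names=shared)


def train_step(state: TrainingState, batch: Batch, cfg: FrameworkConfig
               ) -> tuple[TrainingState, LossReport, DiscrepancyRateRecord | None]:
    """One full optimisation step; mutates and returns ``state``."""
    disc = cfg.discrepancy
    sd = cfg.perturbation_sd
    it = state.iteration

    # (1) supervised branch
    x_l = perturb_with_rng(batch.labeled_images(), sd, state.rngs["student_labeled"])
    y_l = batch.labeled_labels()
    outs_l = state.student(x_l)
    l_sup_t = dice_loss(outs_l.final, y_l)

    l_d_t = 0.0
    l_c1_t = 0.0
    l_c2_t = 0.0
    dr = None
    extra = {}
    if not cfg.supervised_only:
        # (2)-(4) forwards under distinct perturbations
        x_u = batch.unlabeled_images()
        outs_u = state.student(perturb_with_rng(x_u, sd, state.rngs["student_unlabeled"]))
        f_t1 = state.teacher1(
            perturb_with_rng(x_u, sd, state.rngs["teacher1"]), aux=False).final.data
        f_t2 = None
        if cfg.use_teacher2:
            stacks = perturb_with_rng(batch.unlabeled_stacks(), sd,
                                      state.rngs["teacher2"])
            f_t2 = state.teacher2(stacks, aux=False).final.data
        # (5)-(6) anchor and discrepancy maps
        anchor = (compute_anchor(outs_l.final.data, y_l)
                  if cfg.use_prediction_optimization else None)
        d1h, d1l, d1 = compute_d1(outs_u, f_t1, anchor, disc)
        d2 = compute_d2(outs_u, f_t2, disc) if cfg.use_teacher2 else None
        d = combine_discrepancy(d1, d2, disc)
        l_d_t = discrepancy_loss(d)
        d_data = d.data
        l_c1_t = gated_consistency_loss(outs_u.final, f_t1, d_data, disc)
        if cfg.use_teacher2:
            l_c2_t = gated_consistency_loss(outs_u.final, f_t2, d_data, disc)
        dr = discrepancy_rate(d_data, iteration=it)
        extra = dict(anchor=anchor.A if anchor is not None else float("nan"),
                     d1_high_sum=float(d1h.data.sum()),
                     d1_low_sum=float(d1l.data.sum()))
    l_dcon_t = combine_consistency(l_c1_t, l_c2_t, disc)

    # (7)-(8) total objective, student gradient step
    total_t = total_objective(l_sup_t, l_d_t, l_dcon_t, cfg.loss_weights, it)
    if not np.isfinite(total_t.data):
        raise FloatingPointError(
            f"non-finite loss at iteration {it}: sup={float(l_sup_t.data)} "
            f"disc={float(l_d_t.data) if hasattr(l_d_t, 'data') else l_d_t} "
            f"con={float(l_dcon_t.data) if hasattr(l_dcon_t, 'data') else l_dcon_t}")
    state.optimizer.zero_grad()
    total_t.backward()
    state.optimizer.step()

    # (9) teacher updates from the *updated* student
    ema_update(state.teacher1, state.student, cfg.ema_decay)
    if state.teacher2 is not None:
        ema_update(state.teacher2, state.student, cfg.ema_decay,
                   names=state.shared_teacher2_names)
        t2_out = state.teacher2(batch.labeled_stacks(), aux=False)
        l_t2 = dice_loss(t2_out.final, y_l)
        state.teacher2_optimizer.zero_grad()
        l_t2.backward()
        state.teacher2_optimizer.step()

    # (10) bookkeeping
    report = total_loss(l_sup_t, l_d_t, l_dcon_t, cfg.loss_weights, it,
                        l_dcon1=l_c1_t, l_dcon2=l_c2_t, **extra)
    state.iteration += 1
    state.history.append(report)
    if dr is not None:
        state.dr_history.append(dr)
    return state, report, dr


def train(dataset: SemiSupervisedDataset, cfg: FrameworkConfig,
          state: TrainingState | None = None,
          val_volumes=None, val_every: int = 50,
          ) -> tuple[TrainingState, pd.DataFrame]:
    """Run ``cfg.iterations`` training steps (continuing from ``state`` if given).

    With ``val_volumes`` supplied, the student is scored there every
    ``val_every`` iterations and the best-scoring parameters are kept in
    ``state.best_student_state``; otherwise the final parameters stand.
    Returns the state and the per-iteration history as a DataFrame.
    """
    from .metrics import evaluate  # local import: metrics pulls in pandas/skimage

    if state is None:
        state = init_state(dataset, cfg)
    best_dice = -np.inf
    while state.iteration < cfg.iterations:
        batch = state.batches.next_batch()
        state, report, _ = train_step(state, batch, cfg)
        if val_volumes is not None and (state.iteration % val_every == 0
                                        or state.iteration == cfg.iterations):
            dice = float(evaluate(state.student, val_volumes, cfg).means["dice"])
            if dice > best_dice:
                best_dice = dice
                state.best_student_state = state.student.state_dict()
    history = pd.DataFrame([r.as_dict() for r in state.history])
    dr_by_iter = {r.iteration: r.Dr for r in state.dr_history}
    history["Dr"] = history["iteration"].map(dr_by_iter)
    return state, history


def epoch_mean_dr(dr_records: list[DiscrepancyRateRecord],
                  iters_per_epoch: int) -> np.ndarray:
    """Average the per-iteration discrepancy rate over unlabeled-pool epochs."""
    if iters_per_epoch <= 0:
        raise ValueError("iters_per_epoch must be positive")
    values = np.asarray([r.Dr for r in dr_records], dtype=np.float64)
    n_epochs = int(np.ceil(len(values) / iters_per_epoch))
    return np.asarray([values[e * iters_per_epoch:(e + 1) * iters_per_epoch].mean()
                       for e in range(n_epochs)])


def iters_per_unlabeled_epoch(dataset: SemiSupervisedDataset,
                              cfg: FrameworkConfig) -> int:
    """Iterations in one pass over the unlabeled slice pool."""
    if cfg.supervised_only:
        return int(np.ceil(len(dataset.labeled) / cfg.labeled_per_batch))
    return int(np.ceil(len(dataset.unlabeled) / cfg.unlabeled_per_batch))


# ---------------------------------------------------------------------------
# estimator front end
# ---------------------------------------------------------------------------

try:  # sklearn gives get_params/set_params and pipeline compatibility
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass


class DualTeacherSegmenter(BaseEstimator):
    """Semi-supervised volumetric segmenter with two mean-teacher guides.

    Parameters mirror :class:`~dtmt.config.FrameworkConfig`; `fit` accepts
    either a prepared :class:`~dtmt.data.SemiSupervisedDataset` or a list of
    :class:`~dtmt.synthetic.Volume`, which is then split at the volume level
    (``labeled_fraction`` / ``test_fraction``).

    Attributes (after fit)
    ----------------------
    state_ : TrainingState with the trained student and teachers
    history_ : per-iteration loss/diagnostic DataFrame
    config_ : the materialised FrameworkConfig
    dataset_ : the SemiSupervisedDataset trained on
    """

    def __init__(self, base_channels=16, depth=4, input_size=128, iterations=400,
                 learning_rate=0.02, momentum=0.9, weight_decay=1e-4,
                 ema_decay=0.99, batch_size=8, labeled_per_batch=4,
                 context_radius=1, gamma=0.8, perturbation_sd=0.1,
                 ramp_length=100, use_teacher2=True,
                 use_prediction_optimization=True, supervised_only=False,
                 labeled_fraction=0.1, test_fraction=0.1, random_state=0):
        self.base_channels = base_channels
        self.depth = depth
        self.input_size = input_size
        self.iterations = iterations
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.ema_decay = ema_decay
        self.batch_size = batch_size
        self.labeled_per_batch = labeled_per_batch
        self.context_radius = context_radius
        self.gamma = gamma
        self.perturbation_sd = perturbation_sd
        self.ramp_length = ramp_length
        self.use_teacher2 = use_teacher2
        self.use_prediction_optimization = use_prediction_optimization
        self.supervised_only = supervised_only
        self.labeled_fraction = labeled_fraction
        self.test_fraction = test_fraction
        self.random_state = random_state

    def _make_config(self) -> FrameworkConfig:
        from .config import DiscrepancyConfig, LossWeights

        disc = (DiscrepancyConfig() if self.use_teacher2
                else DiscrepancyConfig(m=1.0, n=0.0))
        return FrameworkConfig(
            discrepancy=disc,
            loss_weights=LossWeights(ramp_length=self.ramp_length),
            ema_decay=self.ema_decay, learning_rate=self.learning_rate,
            momentum=self.momentum, weight_decay=self.weight_decay,
            batch_size=self.batch_size, labeled_per_batch=self.labeled_per_batch,
            iterations=self.iterations, input_size=self.input_size,
            context_radius=self.context_radius, gamma=self.gamma,
            base_channels=self.base_channels, depth=self.depth,
            perturbation_sd=self.perturbation_sd,
            data_seed=self.random_state, init_seed=self.random_state,
            perturbation_seed=self.random_state,
            use_teacher2=self.use_teacher2 and not self.supervised_only,
            use_prediction_optimization=self.use_prediction_optimization,
            supervised_only=self.supervised_only)

    def fit(self, X, y=None):
        from .data import split_dataset

        self.config_ = self._make_config()
        if isinstance(X, SemiSupervisedDataset):
            dataset = X
        else:
            dataset = split_dataset(list(X), self.labeled_fraction,
                                    seed=self.random_state,
                                    test_fraction=self.test_fraction,
                                    cfg=self.config_)
        self.dataset_ = dataset
        self.state_, self.history_ = train(dataset, self.config_)
        return self

    def predict_proba(self, volume) -> np.ndarray:
        from .metrics import predict_volume

        self._check_fitted()
        return predict_volume(self.state_.student, volume, self.config_)

    def predict(self, volume) -> np.ndarray:
        from .metrics import binarize

        return binarize(self.predict_proba(volume), self.config_.binarize_threshold)

    def score(self, X=None, y=None) -> float:
        """Mean test Dice over ``X`` (default: the held-out test volumes)."""
        from .metrics import evaluate

        self._check_fitted()
        volumes = list(X) if X is not None else self.dataset_.test
        return float(evaluate(self.state_.student, volumes, self.config_).means["dice"])

    def evaluate(self, X=None):
        from .metrics import evaluate

        self._check_fitted()
        volumes = list(X) if X is not None else self.dataset_.test
        return evaluate(self.state_.student, volumes, self.config_)

    def _check_fitted(self):
        if not hasattr(self, "state_"):
            raise RuntimeError("estimator is not fitted; call fit first")
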