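"""Deep Cox proportional hazards: network, objectives, training loop.

The model is a feed-forward multilayer perceptron mapping a covariate vector
to a single log-hazard score f(x); exp(f(x)) multiplies the baseline hazard.
Three training objectives are provided:

``baseline``
    The negative mean partial log-likelihood over observed events,

        L = -(1/n_E) sum_{i: d_i=1} [ f(x_i) - log sum_{j in R(o_i)} exp f(x_j) ],

    with Breslow handling of tied event times (tied events share a risk set).

``fair``
    Baseline plus a group mean-hazard parity penalty
    ``sum_k (fbar_k - fbar)^2`` weighted by ``fair_lambda``, discouraging the
    model from separating the groups' average log-hazards.

``groupdro``
    Group distributionally robust optimization: the maximum over groups of
    the group-restricted negative partial log-likelihood (events of group k
    in the numerator, normalized by that group's event count, but risk sets
    always over the ENTIRE evaluation set), with an augmented group k=0 — the
    unrestricted loss — always included so the global fit cannot collapse
    while the worst group is being optimized.

The network and backpropagation are implemented directly in numpy; all loss
gradients with respect to the scores have closed forms, and the chain rule
through the MLP is hand-written. Optimization follows stochastic gradient
descent with momentum, step learning-rate decay, weight decay, and early
stopping on the validation objective.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort_io import SurvivalCohort, Standardizer

logger = logging.getLogger("fairsurv")

OBJECTIVES = ("baseline", "fair", "groupdro")

# SELU constants (self-normalizing networks)
_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


class LossInputError(ValueError):
    """Invalid input to a training objective (e.g. no events)."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of the log-hazard network.

    An input linear layer maps p features to ``hidden_width``, followed by
    ``hidden_layers`` dense layers of the same width, SELU activations
    throughout, and a final linear projection to a single scalar. No
    normalization or dropout layers. ``linear=True`` collapses the network
    to a single linear layer (a plain Cox linear predictor), used for
    parameter-recovery checks.
    """

    input_dim: int
    hidden_width: int = 32
    hidden_layers: int = 4
    activation: str = "selu"
    linear: bool = False

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.hidden_width < 1 or self.hidden_layers < 0:
            raise ValueError("invalid architecture dimensions")
        if self.activation != "selu":
            raise ValueError("only the SELU activation is supported")

    def layer_dims(self) -> list[tuple[int, int]]:
        if self.linear:
            return [(self.input_dim, 1)]
        dims = [(self.input_dim, self.hidden_width)]
        dims += [(self.hidden_width, self.hidden_width)] * self.hidden_layers
        dims += [(self.hidden_width, 1)]
        return dims


@dataclass(frozen=True)
class TrainSpec:
    """Optimization protocol for all three objectives."""

    objective: str = "baseline"
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.001
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 5
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 5
    fair_lambda: float = 1.0
    seed: int = 0
    stratify_batches_by_group: bool = False
    dro_soft_weighting: bool = False
    dro_step_size: float = 0.01

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        for name in ("learning_rate", "batch_size", "max_epochs", "patience",
                     "lr_decay_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fair_lambda < 0:
            raise ValueError("fair_lambda must be nonnegative")


@dataclass(frozen=True)
class RiskOutput:
    """Per-subject predicted log-hazard scores, order-aligned with a cohort."""

    scores: np.ndarray
    model_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float).ravel()
        if not np.all(np.isfinite(s)):
            raise LossInputError("risk scores must be finite")
        object.__setattr__(self, "scores", s)


def _as_scores(scores) -> np.ndarray:
    if isinstance(scores, RiskOutput):
        return scores.scores
    s = np.asarray(scores, dtype=float).ravel()
    if not np.all(np.isfinite(s)):
        raise LossInputError("risk scores must be finite")
    return s


# ---------------------------------------------------------------------------
# Partial-likelihood machinery (shared by losses, gradients, Breslow)
# ---------------------------------------------------------------------------

def _cox_precompute(time: np.ndarray, scores: np.ndarray):
    """Sorted-order quantities for partial-likelihood computations.

    Returns (order, log_denom, block_id, block_last_cumidx) where
    ``log_denom[i]`` is ``log sum_{j: t_j >= t_i} exp(s_j)`` for the subject
    at sorted position i; tied times share one denominator (Breslow).
    Scores are max-shifted internally; ``log_denom`` is on the shifted scale
    and must only be combined with shifted scores.
    """
    n = time.shape[0]
    order = np.argsort(time, kind="stable")
    t = time[order]
    s = scores[order]
    new_block = np.empty(n, dtype=bool)
    new_block[0] = True
    new_block[1:] = t[1:] > t[:-1]
    block_id = np.cumsum(new_block) - 1
    block_start = np.flatnonzero(new_block)
    suffix = np.logaddexp.accumulate(s[::-1])[::-1]
    log_denom = suffix[block_start[block_id]]
    return order, t, s, log_denom, block_id, new_block


def npll_with_grad(
    scores: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    subset: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Negative mean partial log-likelihood and its score gradient.

    The numerator runs over events in ``subset`` (full set when None) and is
    normalized by the subset's event count; risk sets are built over ALL
    subjects passed in, regardless of subset.
    """
    s_raw = np.asarray(scores, dtype=float)
    shift = s_raw.max()
    s0 = s_raw - shift  # location invariance; stabilizes exp
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = s0.shape[0]
    numer = (event == 1) if subset is None else ((event == 1) & np.asarray(subset, bool))
    nE = int(numer.sum())
    if nE == 0:
        raise LossInputError("no events in the requested subset")

    order, t, s, log_denom, block_id, new_block = _cox_precompute(time, s0)
    numer_sorted = numer[order]
    value = -float(np.sum(s[numer_sorted] - log_denom[numer_sorted])) / nE

    # grad_m = -(1/nE) [ 1{m in numerator} - exp(s_m) * A_m ],
    # A_m = sum over numerator events i with t_i <= t_m of 1/denom_i
    w = np.where(numer_sorted, np.exp(-log_denom), 0.0)
    cw = np.cumsum(w)
    # include ties: events at the same time as m count, so take the cumsum at
    # the END of m's tie block
    block_last = np.flatnonzero(np.append(new_block[1:], True))
    A = cw[block_last[block_id]]
    grad_sorted = -(numer_sorted.astype(float) - np.exp(s) * A) / nE
    grad = np.empty(n)
    grad[order] = grad_sorted
    return value, grad


def neg_partial_log_likelihood(
    scores, cohort: SurvivalCohort, subset: np.ndarray | None = None
) -> float:
    """Breslow-tied negative mean partial log-likelihood (full risk sets)."""
    value, _ = npll_with_grad(_as_scores(scores), cohort.time, cohort.event, subset)
    return value


def fair_penalty_with_grad(
    scores: np.ndarray, groups: np.ndarray
) -> tuple[float, np.ndarray]:
    """Group mean-parity penalty ``sum_k (mean_k - mean)^2`` and gradient.

    Only groups present contribute. The penalty (and its gradient) is
    invariant to adding a constant to every score.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    if s.size == 0:
        raise LossInputError("empty input to fair_penalty")
    overall = s.mean()
    n = s.size
    penalty = 0.0
    grad = np.zeros(n)
    labels = np.unique(g)
    devs = []
    for k in labels:
        mask = g == k
        d = s[mask].mean() - overall
        devs.append(d)
        penalty += d * d
        grad[mask] += 2.0 * d / mask.sum()
    grad -= 2.0 * np.sum(devs) / n
    return float(penalty), grad


def fair_penalty(scores, groups) -> float:
    value, _ = fair_penalty_with_grad(_as_scores(scores), groups)
    return value


def groupdro_with_grad(
    scores: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    groups: np.ndarray,
) -> tuple[float, int, np.ndarray]:
    """Worst-case group negative partial log-likelihood, argmax, gradient.

    Term k=0 is the unrestricted loss over the full set; term k>0 restricts
    the numerator to group-k events (normalized by that group's event count)
    while keeping full risk sets. Groups with zero events are skipped.
    Returns (value, worst_group, gradient_of_the_worst_term).
    """
    g = np.asarray(groups)
    terms: dict[int, tuple[float, np.ndarray]] = {}
    terms[0] = npll_with_grad(scores, time, event, None)
    for k in np.unique(g):
        mask = g == k
        if not np.any((event == 1) & mask):
            logger.info("groupdro: group %s has no events; term skipped", k)
            continue
        terms[int(k)] = npll_with_grad(scores, time, event, mask)
    worst = max(terms, key=lambda k: terms[k][0])
    value, grad = terms[worst]
    return value, worst, grad


def groupdro_objective(
    scores, cohort: SurvivalCohort, return_group: bool = False
):
    """Max over {full cohort, each group} of the restricted partial-likelihood loss."""
    value, worst, _ = groupdro_with_grad(
        _as_scores(scores), cohort.time, cohort.event, cohort.group
    )
    return (value, worst) if return_group else value


def objective_value(
    scores, cohort: SurvivalCohort, spec: TrainSpec
) -> float:
    """The training objective evaluated with full risk sets within ``cohort``."""
    s = _as_scores(scores)
    if spec.objective == "baseline":
        return neg_partial_log_likelihood(s, cohort)
    if spec.objective == "fair":
        base = neg_partial_log_likelihood(s, cohort)
        return base + spec.fair_lambda * fair_penalty(s, cohort.group)
    value, _, _ = groupdro_with_grad(s, cohort.time, cohort.event, cohort.group)
    return value


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

def _selu(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * np.expm1(z))

def _selu_grad(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))


class CoxMLP:
    """Feed-forward log-hazard network with hand-written backprop.

    Weights and biases are initialized uniformly on
    ``(-1/sqrt(fan_in), +1/sqrt(fan_in))`` from the run seed.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in spec.layer_dims():
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(rng.uniform(-bound, bound, size=fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, X: np.ndarray) -> np.ndarray:
        return self.forward_cache(np.asarray(X, dtype=float))[0]

    def forward_cache(self, X: np.ndarray):
        """Forward pass returning (scores, cache) for backprop."""
        h = X
        pre: list[np.ndarray] = []
        post: list[np.ndarray] = [X]
        for li in range(self.n_layers):
            z = h @ self.weights[li] + self.biases[li]
            pre.append(z)
            if li < self.n_layers - 1:
                h = _selu(z)
                post.append(h)
            else:
                h = z
        return h[:, 0], (pre, post)

    def backward(self, cache, dscores: np.ndarray):
        """Gradients of a scalar loss given d(loss)/d(scores)."""
        pre, post = cache
        gW = [None] * self.n_layers
        gb = [None] * self.n_layers
        delta = np.asarray(dscores, dtype=float)[:, None]
        for li in range(self.n_layers - 1, -1, -1):
            gW[li] = post[li].T @ delta
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ self.weights[li].T) * _selu_grad(pre[li - 1])
        return gW, gb

    # -- parameter (de)serialization --------------------------------------

    def get_params(self):
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]

    def set_params(self, params):
        ws, bs = params
        self.weights = [w.copy() for w in ws]
        self.biases = [b.copy() for b in bs]

    def to_dict(self) -> dict:
        return {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, spec: ModelSpec, d: dict) -> "CoxMLP":
        model = cls(spec, seed=0)
        model.weights = [np.asarray(w, dtype=float) for w in d["weights"]]
        model.biases = [np.asarray(b, dtype=float) for b in d["biases"]]
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _batch_score_grad(
    spec: TrainSpec,
    scores: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
    dro_state: np.ndarray | None,
):
    """d(objective)/d(scores) for one mini-batch (within-batch risk sets)."""
    if spec.objective == "baseline":
        value, grad = npll_with_grad(scores, time, event)
        return value, grad, None
    if spec.objective == "fair":
        value, grad = npll_with_grad(scores, time, event)
        pen, pgrad = fair_penalty_with_grad(scores, group)
        return value + spec.fair_lambda * pen, grad + spec.fair_lambda * pgrad, None
    # groupdro
    if not spec.dro_soft_weighting:
        value, worst, grad = groupdro_with_grad(scores, time, event, group)
        return value, grad, worst
    # exponentiated-gradient soft weighting over {0} + groups (optional path)
    K = dro_state.shape[0] - 1
    losses = np.full(K + 1, np.nan)
    grads = {}
    v0, g0 = npll_with_grad(scores, time, event)
    losses[0] = v0
    grads[0] = g0
    for k in range(1, K + 1):
        mask = group == k
        if np.any((event == 1) & mask):
            losses[k], grads[k] = npll_with_grad(scores, time, event, mask)
    present = ~np.isnan(losses)
    dro_state[present] *= np.exp(spec.dro_step_size * losses[present])
    q = dro_state / dro_state.sum()
    value = float(np.nansum(np.where(present, q * losses, 0.0)))
    grad = np.zeros_like(scores)
    for k, gk in grads.items():
        grad += q[k] * gk
    return value, grad, int(np.nanargmax(losses))


@dataclass
class FittedModel:
    """A trained network plus everything needed to reuse it on new data."""

    model: CoxMLP
    model_spec: ModelSpec
    train_spec: TrainSpec
    history: list[dict] = field(default_factory=list)
    standardizer: Standardizer | None = None
    model_id: str = "dcph"

    def predict(self, cohort: SurvivalCohort) -> RiskOutput:
        if self.standardizer is not None:
            cohort = self.standardizer.apply(cohort)
        return RiskOutput(self.model.forward(cohort.covariates), self.model_id)

    def save(self, model_dir) -> None:
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        (d / "model_spec.json").write_text(json.dumps(asdict(self.model_spec)))
        (d / "train_spec.json").write_text(json.dumps(asdict(self.train_spec)))
        (d / "weights.json").write_text(json.dumps(self.model.to_dict()))
        (d / "model_id.json").write_text(json.dumps({"model_id": self.model_id}))
        if self.standardizer is not None:
            (d / "standardizer.json").write_text(json.dumps(self.standardizer.to_dict()))
        with open(d / "history.jsonl", "w") as fh:
            for rec in self.history:
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def load(cls, model_dir) -> "FittedModel":
        d = Path(model_dir)
        model_spec = ModelSpec(**json.loads((d / "model_spec.json").read_text()))
        train_spec = TrainSpec(**json.loads((d / "train_spec.json").read_text()))
        model = CoxMLP.from_dict(model_spec, json.loads((d / "weights.json").read_text()))
        std = None
        if (d / "standardizer.json").exists():
            std = Standardizer.from_dict(json.loads((d / "standardizer.json").read_text()))
        history = []
        if (d / "history.jsonl").exists():
            history = [
                json.loads(line)
                for line in (d / "history.jsonl").read_text().splitlines()
                if line.strip()
            ]
        model_id = "dcph"
        if (d / "model_id.json").exists():
            model_id = json.loads((d / "model_id.json").read_text())["model_id"]
        return cls(model, model_spec, train_spec, history, std, model_id)


def _batches(rng, n, group, spec: TrainSpec):
    """Yield mini-batch index arrays for one epoch."""
    if not spec.stratify_batches_by_group:
        perm = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            yield perm[start:start + spec.batch_size]
        return
    # group-stratified: interleave shuffled per-group streams proportionally
    order = np.concatenate([rng.permutation(np.flatnonzero(group == k))
                            for k in np.unique(group)])
    pos = rng.permutation(n)  # positions of subjects in the round-robin
    interleaved = order[np.argsort(pos, kind="stable")]
    for start in range(0, n, spec.batch_size):
        yield interleaved[start:start + spec.batch_size]


def train(
    train_cohort: SurvivalCohort,
    valid_cohort: SurvivalCohort,
    model_spec: ModelSpec,
    train_spec: TrainSpec,
    standardizer: Standardizer | None = None,
) -> FittedModel:
    """Fit the chosen objective with SGD + momentum and early stopping.

    Mini-batches use within-batch risk sets (batches are sorted by time
    internally); the reported per-epoch train/validation objectives use full
    risk sets within their respective cohorts. The validation objective is
    the model's own training objective evaluated on the validation split;
    training stops once it fails to improve for ``patience`` epochs, and the
    best-validation parameters are restored.
    """
    if standardizer is not None:
        train_cohort = standardizer.apply(train_cohort)
        valid_cohort = standardizer.apply(valid_cohort)
    ss = np.random.SeedSequence(train_spec.seed)
    init_ss, shuffle_ss = ss.spawn(2)
    model = CoxMLP(model_spec, seed=init_ss)
    rng = np.random.default_rng(shuffle_ss)
    X = train_cohort.covariates
    n = train_cohort.n

    vel_W = [np.zeros_like(w) for w in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    dro_state = np.ones(train_cohort.n_groups + 1)

    history: list[dict] = []
    best_val = np.inf
    best_params = model.get_params()
    best_epoch = -1
    stall = 0

    for epoch in range(train_spec.max_epochs):
        lr = train_spec.learning_rate * (
            train_spec.lr_decay_factor ** (epoch // train_spec.lr_decay_every)
        )
        batch_losses: list[float] = []
        skipped = 0
        worst_counts: dict[int, int] = {}
        for idx in _batches(rng, n, train_cohort.group, train_spec):
            ev = train_cohort.event[idx]
            if ev.sum() == 0:
                skipped += 1
                continue
            # sort the batch by time (risk sets within the batch)
            idx = idx[np.argsort(train_cohort.time[idx], kind="stable")]
            scores, cache = model.forward_cache(X[idx])
            try:
                loss, dscores, worst = _batch_score_grad(
                    train_spec, scores,
                    train_cohort.time[idx], train_cohort.event[idx],
                    train_cohort.group[idx], dro_state,
                )
            except LossInputError:
                skipped += 1
                continue
            if worst is not None:
                worst_counts[worst] = worst_counts.get(worst, 0) + 1
            gW, gb = model.backward(cache, dscores)
            for li in range(model.n_layers):
                gW[li] += train_spec.weight_decay * model.weights[li]
                gb[li] += train_spec.weight_decay * model.biases[li]
                vel_W[li] = train_spec.momentum * vel_W[li] + gW[li]
                vel_b[li] = train_spec.momentum * vel_b[li] + gb[li]
                model.weights[li] -= lr * vel_W[li]
                model.biases[li] -= lr * vel_b[li]
            batch_losses.append(loss)

        val = objective_value(model.forward(valid_cohort.covariates), valid_cohort, train_spec)
        rec = {
            "epoch": epoch,
            "lr": lr,
            "train_objective": float(np.mean(batch_losses)) if batch_losses else None,
            "valid_objective": float(val),
            "skipped_batches": skipped,
        }
        if train_spec.objective == "groupdro" and worst_counts:
            rec["worst_group_mode"] = max(worst_counts, key=worst_counts.get)
        history.append(rec)

        if val < best_val - 1e-12:
            best_val = val
            best_params = model.get_params()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= train_spec.patience:
                break

    model.set_params(best_params)
    history.append({"restored_epoch": best_epoch, "best_valid_objective": float(best_val)})
    return FittedModel(
        model=model,
        model_spec=model_spec,
        train_spec=train_spec,
        history=history,
        standardizer=standardizer,
        model_id=f"dcph-{train_spec.objective}-seed{train_spec.seed}",
    )
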