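"""Four neural time-to-event models for right-censored survival data.

The families and their losses:

* **deepsurv** — a multilayer perceptron (MLP) estimating the log-risk
  g(x) of a proportional-hazards model; trained with the Cox partial
  likelihood (Breslow ties), survival recovered through the Breslow
  baseline cumulative hazard: S(t|x) = exp(-H0(t) e^{g(x)}).
* **coxtime** — a relative-risk model whose score g(t, x) takes time as an
  input covariate, dropping the proportionality assumption while keeping
  the Cox partial-likelihood form; the loss averages, over event subjects
  i, log sum_{j in R_i} exp(g(T_i, x_j) - g(T_i, x_i)).
* **deephit** — a discrete-time model whose network outputs a probability
  mass function over K grid intervals plus one beyond-horizon cell;
  trained on a likelihood term blended with a ranking term controlled by
  (alpha, sigma).
* **nnet_survival** (logistic hazard) — a discrete-time model whose
  network outputs per-interval hazard logits; trained by the mean negative
  log-likelihood of the discrete survival process, equivalent to Bernoulli
  regression on the person-period expansion.

All losses accept plain numpy arrays (returning a float, convenient for
testing against brute-force oracles) or autodiff tensors (used in
training).  Time is continuous in the data; the discrete families use a
quantile-based :class:`TimeGrid` with right-closed intervals.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, fields

import numpy as np

from ._autodiff import Tensor, as_tensor
from .networks import MLP, Adam
from .encoding import DesignMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TimeGrid",
    "HyperParams",
    "SurvivalCurves",
    "TrainedModel",
    "BreslowBaseline",
    "MODEL_KINDS",
    "make_time_grid",
    "loss_cox_partial",
    "loss_cox_time",
    "loss_deephit",
    "loss_logistic_hazard",
    "breslow_cumhaz",
    "fit",
    "predict_survival",
]

MODEL_KINDS = ("deepsurv", "coxtime", "deephit", "nnet_survival")

_EPS = 1e-7  # guard inside log() of discrete-model probabilities


# ---------------------------------------------------------------------------
# time grid


@dataclass(frozen=True)
class TimeGrid:
    """Interval boundaries 0 = tau_0 < tau_1 < ... < tau_K.

    Interval k (0-based) is the right-closed (tau_k, tau_{k+1}]; a duration
    beyond tau_K is clamped into the last interval.
    """

    boundaries: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must start at 0 and strictly increase")
        object.__setattr__(self, "boundaries", b)

    @property
    def K(self) -> int:
        return len(self.boundaries) - 1

    @property
    def times(self) -> np.ndarray:
        """The K upper boundaries tau_1..tau_K (prediction times)."""
        return self.boundaries[1:]

    def interval_index(self, durations) -> np.ndarray:
        d = np.asarray(durations, dtype=float)
        idx = np.searchsorted(self.boundaries[1:], d, side="left")
        return np.minimum(idx, self.K - 1)


def make_time_grid(durations, K: int = 20, events=None) -> TimeGrid:
    """Quantile-based grid over the observed durations.

    Boundaries sit at empirical quantiles of the *event* durations (all
    durations if ``events`` is None), deduplicated; the last boundary is
    the maximum observed duration so every training duration maps into the
    grid.  Fewer distinct values than K shrink the grid with a warning.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("no durations")
    ref = d if events is None else d[np.asarray(events).astype(bool)]
    if ref.size == 0:
        ref = d
    qs = np.quantile(ref, np.linspace(0, 1, K + 1)[1:])
    qs[-1] = d.max()
    bounds = np.unique(qs[qs > 0])
    if len(bounds) < K:
        warnings.warn(f"only {len(bounds)} distinct boundaries for K={K}; grid shrunk",
                      stacklevel=2)
    return TimeGrid(np.concatenate([[0.0], bounds]))


# ---------------------------------------------------------------------------
# hyperparameters (search space of the study design, Table-style categorical
# sets plus one continuous learning-rate range)


@dataclass
class HyperParams:
    batch_size: int = 256
    epochs: int = 100
    dropout: float = 0.1
    n_layers: int = 2
    n_nodes: int = 32
    alpha: float = 0.2
    sigma: float = 0.1
    learning_rate: float = 0.01

    BATCH_SIZES = (32, 64, 128, 256, 512)
    EPOCHS = (100, 200, 300, 500)
    DROPOUTS = (0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    N_LAYERS_RANGE = (2, 5)
    N_NODES = (32, 64, 128, 256, 512)
    ALPHAS = (0.0, 0.001, 0.1, 0.2, 0.5, 0.8, 0.9, 0.99, 1.0)
    SIGMAS = (0.01, 0.1, 0.25, 0.5, 1.0, 10.0, 100.0)
    LR_RANGE = (0.0001, 0.1)

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "HyperParams":
        """Draw each field uniformly from its search set/range."""
        return cls(
            batch_size=int(rng.choice(cls.BATCH_SIZES)),
            epochs=int(rng.choice(cls.EPOCHS)),
            dropout=float(rng.choice(cls.DROPOUTS)),
            n_layers=int(rng.integers(cls.N_LAYERS_RANGE[0], cls.N_LAYERS_RANGE[1] + 1)),
            n_nodes=int(rng.choice(cls.N_NODES)),
            alpha=float(rng.choice(cls.ALPHAS)),
            sigma=float(rng.choice(cls.SIGMAS)),
            learning_rate=float(rng.uniform(*cls.LR_RANGE)),
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# losses


def _prep_outcomes(durations, events):
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events).astype(bool)
    if not e.any():
        raise ValueError("no events in batch")
    return d, e


def _maybe_float(x: Tensor, was_numpy: bool):
    return float(x.data) if was_numpy else x


def loss_cox_partial(scores, durations, events):
    """Negative Cox partial log-likelihood, averaged over event subjects.

    mean over events i of [log sum_{j: T_j >= T_i} exp(s_j) - s_i], with
    tied times sharing risk sets (Breslow convention).
    """
    was_numpy = not isinstance(scores, Tensor)
    s = as_tensor(scores).reshape(-1)
    d, e = _prep_outcomes(durations, events)

    order = np.argsort(-d, kind="stable")
    d_sorted = d[order]
    e_sorted = e[order]
    s_sorted = s[order]
    # risk set of position p is 0..q[p] where q[p] = last index with equal T
    q = np.searchsorted(-d_sorted, -d_sorted, side="right") - 1
    m = float(s.data.max())  # detached shift for exp stability
    cs = (s_sorted - m).exp().cumsum(axis=0)
    ev = np.flatnonzero(e_sorted)
    log_risk = cs[q[ev]].log() + m
    out = (log_risk - s_sorted[ev]).mean()
    return _maybe_float(out, was_numpy)


def loss_cox_time(score_fn, features, durations, events,
                  subsample: int | None = None,
                  rng: np.random.Generator | None = None):
    """Cox partial likelihood with a time-dependent score g(t, x).

    ``score_fn(t, X)`` must return one score per row of ``X`` evaluated at
    the (vector of) times ``t``; for each event i every member j of its
    risk set is scored at the event time T_i.  ``subsample`` draws a
    uniform subset of each risk set, always containing i.  When g ignores
    t this reduces exactly to :func:`loss_cox_partial`.
    """
    X = np.asarray(features, dtype=float)
    d, e = _prep_outcomes(durations, events)
    ev_idx = np.flatnonzero(e)
    if rng is None:
        rng = np.random.default_rng()

    pair_t, pair_j, seg_bounds, self_pos = [], [], [0], []
    for i in ev_idx:
        risk = np.flatnonzero(d >= d[i])
        if subsample is not None and len(risk) > subsample:
            others = risk[risk != i]
            keep = rng.choice(others, size=subsample - 1, replace=False)
            risk = np.concatenate([[i], keep])
        self_pos.append(seg_bounds[-1] + int(np.flatnonzero(risk == i)[0]))
        pair_t.append(np.full(len(risk), d[i]))
        pair_j.append(risk)
        seg_bounds.append(seg_bounds[-1] + len(risk))

    t_all = np.concatenate(pair_t)
    j_all = np.concatenate(pair_j)
    starts = np.array(seg_bounds[:-1])
    ends = np.array(seg_bounds[1:])
    self_pos = np.array(self_pos)

    s = score_fn(t_all, X[j_all])
    was_numpy = not isinstance(s, Tensor)
    s = as_tensor(s).reshape(-1)

    # per-risk-set logsumexp via a cumsum trick with detached per-segment shifts
    seg_max = np.maximum.reduceat(s.data, starts)
    shift = np.repeat(seg_max, ends - starts)
    ex = (s - shift).exp()
    cs = ex.cumsum(axis=0)
    seg_sum = cs[ends - 1] - _shifted_prefix(cs, starts)
    log_risk = seg_sum.log() + seg_max
    out = (log_risk - s[self_pos]).mean()
    return _maybe_float(out, was_numpy)


def _shifted_prefix(cs: Tensor, starts: np.ndarray) -> Tensor:
    """cs[starts-1] with a zero in place of the first segment's prefix."""
    nonzero = starts > 0
    pick = np.where(nonzero, starts - 1, 0)
    return cs[pick] * nonzero.astype(float)


def loss_deephit(pmf_logits, interval_index, events, alpha: float, sigma: float):
    """DeepHit loss: alpha * NLL + (1 - alpha) * ranking.

    Logits are n x (K+1): K grid intervals plus one beyond-horizon cell.
    The NLL term credits events with log f(k_i) and censorings with
    log(1 - F(k_i)); the ranking term averages exp(-(F_i(k_i) -
    F_j(k_i)) / sigma) over comparable pairs (i an event, k_i < k_j).
    """
    if alpha not in HyperParams.ALPHAS:
        warnings.warn(f"alpha={alpha} outside the search set", stacklevel=2)
    if sigma not in HyperParams.SIGMAS:
        warnings.warn(f"sigma={sigma} outside the search set", stacklevel=2)
    was_numpy = not isinstance(pmf_logits, Tensor)
    logits = as_tensor(pmf_logits)
    k = np.asarray(interval_index, dtype=int)
    e = np.asarray(events).astype(bool)
    n = len(k)

    f = logits.softmax(axis=1)
    F = f.cumsum(axis=1)
    rows = np.arange(n)
    f_k = f[(rows, k)]
    F_k = F[(rows, k)]
    ev = e.astype(float)
    nll = -(ev * (f_k + _EPS).log() + (1.0 - ev) * (1.0 - F_k + _EPS).log()).mean()

    ii, jj = np.nonzero(e[:, None] & (k[:, None] < k[None, :]))
    if len(ii) == 0:
        rank = as_tensor(0.0)
    else:
        diff = F[(ii, k[ii])] - F[(jj, k[ii])]
        rank = (-(diff / sigma)).exp().mean()

    out = alpha * nll + (1.0 - alpha) * rank
    return _maybe_float(out, was_numpy)


def loss_logistic_hazard(hazard_logits, interval_index, events):
    """Mean negative log-likelihood of the discrete logistic-hazard model.

    With interval hazards h_m = sigmoid(logit_m), a subject observed to
    interval k (0-based) contributes -[log h_k + sum_{m<k} log(1-h_m)] if
    the event occurred and -sum_{m<=k} log(1-h_m) if censored; equivalent
    to Bernoulli log-loss on the person-period expansion.
    """
    was_numpy = not isinstance(hazard_logits, Tensor)
    x = as_tensor(hazard_logits)
    k = np.asarray(interval_index, dtype=int)
    e = np.asarray(events).astype(bool)
    n, K = x.shape
    if k.min() < 0 or k.max() >= K:
        raise ValueError(f"interval index outside 0..{K - 1}")

    cols = np.arange(K)
    survived = cols[None, :] < k[:, None]  # intervals survived before k
    survived = survived | (~e[:, None] & (cols[None, :] == k[:, None]))
    died = e[:, None] & (cols[None, :] == k[:, None])
    # -log(1-h) = softplus(x); -log h = softplus(-x)
    out = (x.softplus() * survived.astype(float)
           + (-x).softplus() * died.astype(float)).sum(axis=1).mean()
    return _maybe_float(out, was_numpy)


# ---------------------------------------------------------------------------
# Breslow baseline hazard


@dataclass
class BreslowBaseline:
    """Step-function cumulative baseline hazard H0(t).

    ``event_times`` are the unique training event times; ``increments[i]``
    is (number of events at that time) / (risk-set denominator), so
    H0(t) = sum of increments at event times <= t.  For the time-dependent
    family the denominators were computed with scores g(T_i, x_j).
    """

    event_times: np.ndarray
    denominators: np.ndarray
    event_counts: np.ndarray

    @property
    def increments(self) -> np.ndarray:
        return self.event_counts / self.denominators

    def cumhaz(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cum = np.concatenate([[0.0], np.cumsum(self.increments)])
        idx = np.searchsorted(self.event_times, t, side="right")
        return cum[idx]

    def __call__(self, t):
        out = self.cumhaz(t)
        return out if np.ndim(t) else float(out[0])


def breslow_cumhaz(scores, durations, events) -> BreslowBaseline:
    """Breslow estimator H0(t) = sum_{event times T_i <= t} d_i / sum_{j in R_i} e^{s_j}.

    ``scores`` is either a vector (one score per subject, the
    proportional-hazards case) or a callable ``scores(t, idx)`` returning
    the scores of subjects ``idx`` evaluated at time ``t`` (the
    time-dependent case).  With all scores zero this is the Nelson-Aalen
    estimator.  No events yields H0 = 0 with a warning.
    """
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events).astype(bool)
    if not e.any():
        warnings.warn("no events: baseline cumulative hazard is identically 0",
                      stacklevel=2)
        return BreslowBaseline(np.array([]), np.array([]), np.array([]))
    times = np.unique(d[e])
    denoms = np.empty(len(times))
    counts = np.empty(len(times))
    static = not callable(scores)
    if static:
        s = np.asarray(scores, dtype=float).ravel()
    for i, t in enumerate(times):
        at_risk = np.flatnonzero(d >= t)
        sc = s[at_risk] if static else np.asarray(scores(t, at_risk), dtype=float).ravel()
        denoms[i] = np.exp(sc).sum()
        counts[i] = np.sum(e & (d == t))
    return BreslowBaseline(times, denoms, counts)


# ---------------------------------------------------------------------------
# survival curves


@dataclass
class SurvivalCurves:
    """Per-subject predicted survival S(t | x) at a common set of times.

    Values are a step function of time: S(t) for t between two stored
    times equals the value at the earlier one, and S(t) = 1 before the
    first time.
    """

    times: np.ndarray
    values: np.ndarray  # n x len(times)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def at(self, t) -> np.ndarray:
        """S(t) for every subject, step interpolation (n, or n x len(t))."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        padded = np.hstack([np.ones((self.n, 1)), self.values])
        out = padded[:, idx + 1]
        return out[:, 0] if scalar else out

    def to_frame(self, patient_ids=None):
        import pandas as pd

        return pd.DataFrame(self.values, columns=[f"t={t:g}" for t in self.times],
                            index=patient_ids)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    model_kind: str
    net: MLP
    hp: HyperParams
    seed: int
    grid: TimeGrid
    design: DesignMatrix | None = None  # fitted transform (values not needed)
    baseline: BreslowBaseline | None = None
    t_mean: float = 0.0
    t_sd: float = 1.0
    train_loss_history: list = field(default_factory=list)
    val_loss_history: list = field(default_factory=list)
    # training features retained for the time-dependent baseline
    _train_X: np.ndarray | None = None
    _train_d: np.ndarray | None = None
    _train_e: np.ndarray | None = None

    def scale_time(self, t: np.ndarray) -> np.ndarray:
        return (np.asarray(t, dtype=float) - self.t_mean) / self.t_sd

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "model_kind": self.model_kind,
            "hp": self.hp.to_dict(),
            "seed": self.seed,
            "t_mean": self.t_mean,
            "t_sd": self.t_sd,
            "net": {"in_dim": self.net.in_dim, "out_dim": self.net.out_dim,
                    "n_layers": self.net.n_layers, "n_nodes": self.net.n_nodes,
                    "dropout": self.net.dropout},
        }
        arrays = {"boundaries": self.grid.boundaries, "meta": np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)}
        for i, p in enumerate(self.net.get_state()):
            arrays[f"param_{i}"] = p
        if self.baseline is not None:
            arrays["bl_times"] = self.baseline.event_times
            arrays["bl_denoms"] = self.baseline.denominators
            arrays["bl_counts"] = self.baseline.event_counts
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        z = np.load(path)
        meta = json.loads(bytes(z["meta"]).decode())
        net = MLP(rng=np.random.default_rng(0), **meta["net"])
        net.set_state([z[f"param_{i}"] for i in range(len(net.params))])
        baseline = None
        if "bl_times" in z:
            baseline = BreslowBaseline(z["bl_times"], z["bl_denoms"], z["bl_counts"])
        return cls(model_kind=meta["model_kind"], net=net,
                   hp=HyperParams(**meta["hp"]), seed=meta["seed"],
                   grid=TimeGrid(z["boundaries"]), baseline=baseline,
                   t_mean=meta["t_mean"], t_sd=meta["t_sd"])


def _batch_loss(kind: str, net: MLP, Xb, db, eb, kb, hp: HyperParams,
                training: bool, rng, t_scaler) -> Tensor:
    if kind == "deepsurv":
        s = net.forward(Xb, training=training, rng=rng)
        return loss_cox_partial(s.reshape(-1), db, eb)
    if kind == "coxtime":
        def score_fn(t, Xj):
            inp = np.hstack([t_scaler(t)[:, None], Xj])
            return net.forward(inp, training=training, rng=rng).reshape(-1)
        return loss_cox_time(score_fn, Xb, db, eb)
    if kind == "deephit":
        logits = net.forward(Xb, training=training, rng=rng)
        return loss_deephit(logits, kb, eb, hp.alpha, hp.sigma)
    if kind == "nnet_survival":
        logits = net.forward(Xb, training=training, rng=rng)
        return loss_logistic_hazard(logits, kb, eb)
    raise ValueError(f"unknown model kind {kind!r}")


def fit(model_kind: str, design: DesignMatrix, durations, events,
        hp: HyperParams | None = None, seed: int = 0, n_intervals: int = 20,
        patience: int = 10, val_fraction: float = 0.2,
        verbose: bool = False) -> TrainedModel:
    """Train one model; deterministic given ``seed``.

    Training runs mini-batch Adam for at most ``hp.epochs`` epochs with
    early stopping (``patience`` epochs without improvement of the loss on
    a held-out ``val_fraction`` of the training rows); the best-validation
    parameters are restored.  Relative-risk families additionally get a
    Breslow baseline estimated on the full training data.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    hp = hp or HyperParams()
    rng = np.random.default_rng(seed)
    X = np.asarray(design.values, dtype=float)
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events).astype(bool)
    n = len(d)

    grid = make_time_grid(d, K=n_intervals, events=e)
    k_all = grid.interval_index(d)

    out_dim = {"deepsurv": 1, "coxtime": 1,
               "deephit": grid.K + 1, "nnet_survival": grid.K}[model_kind]
    in_dim = X.shape[1] + (1 if model_kind == "coxtime" else 0)
    net = MLP(in_dim, out_dim, n_layers=hp.n_layers, n_nodes=hp.n_nodes,
              dropout=hp.dropout, rng=rng)
    opt = Adam(net.params, lr=hp.learning_rate)

    model = TrainedModel(model_kind=model_kind, net=net, hp=hp, seed=seed,
                         grid=grid, design=design,
                         t_mean=float(d.mean()), t_sd=float(d.std() or 1.0))

    # event-stratified validation split so both sides keep events
    perm_ev = rng.permutation(np.flatnonzero(e))
    perm_ce = rng.permutation(np.flatnonzero(~e))
    n_val_ev = max(1, int(round(val_fraction * len(perm_ev)))) if len(perm_ev) > 1 else 0
    n_val_ce = int(round(val_fraction * len(perm_ce)))
    val_idx = np.concatenate([perm_ev[:n_val_ev], perm_ce[:n_val_ce]]).astype(int)
    train_idx = np.setdiff1d(np.arange(n), val_idx)

    best_val = np.inf
    best_state = net.get_state()
    since_best = 0
    for epoch in range(hp.epochs):
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), hp.batch_size):
            b = order[start:start + hp.batch_size]
            if model_kind in ("deepsurv", "coxtime") and not e[b].any():
                continue  # partial likelihood undefined without an event
            loss = _batch_loss(model_kind, net, X[b], d[b], e[b], k_all[b],
                               hp, True, rng, model.scale_time)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"{model_kind}: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        model.train_loss_history.append(float(np.mean(epoch_losses)))

        if len(val_idx):
            vloss = float(_batch_loss(model_kind, net, X[val_idx], d[val_idx],
                                      e[val_idx], k_all[val_idx], hp, False,
                                      rng, model.scale_time).data)
        else:
            vloss = model.train_loss_history[-1]
        model.val_loss_history.append(vloss)
        if verbose:
            logger.info("%s epoch %d train %.4f val %.4f", model_kind, epoch,
                        model.train_loss_history[-1], vloss)
        if vloss < best_val - 1e-9:
            best_val = vloss
            best_state = net.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    net.set_state(best_state)

    if model_kind == "deepsurv":
        scores = net.predict(X).ravel()
        model.baseline = breslow_cumhaz(scores, d, e)
    elif model_kind == "coxtime":
        def score_at(t, idx):
            inp = np.hstack([np.full((len(idx), 1), model.scale_time(t)), X[idx]])
            return net.predict(inp).ravel()
        model.baseline = breslow_cumhaz(score_at, d, e)
        model._train_X, model._train_d, model._train_e = X, d, e
    return model


# ---------------------------------------------------------------------------
# prediction


def predict_survival(model: TrainedModel, design_rows, eval_times=None) -> SurvivalCurves:
    """Predicted survival curves, one row per design row.

    ``design_rows`` must already carry the model's fitted standardization.
    Default evaluation times are the model's grid boundaries; times beyond
    the grid are clamped (step-function extrapolation) with a warning.
    """
    X = np.asarray(design_rows, dtype=float)
    if eval_times is None:
        eval_times = model.grid.times
    eval_times = np.asarray(eval_times, dtype=float)
    if eval_times.max() > model.grid.boundaries[-1] * (1 + 1e-12):
        warnings.warn("evaluation times beyond the training grid are clamped",
                      stacklevel=2)

    kind = model.model_kind
    if kind == "nnet_survival":
        h = 1.0 / (1.0 + np.exp(-model.net.predict(X)))
        S_grid = np.cumprod(1.0 - h, axis=1)
        S = _step_eval(model.grid.times, S_grid, eval_times)
    elif kind == "deephit":
        logits = model.net.predict(X)
        z = logits - logits.max(axis=1, keepdims=True)
        f = np.exp(z)
        f /= f.sum(axis=1, keepdims=True)
        F = np.cumsum(f[:, :-1], axis=1)  # overflow cell excluded: mass beyond horizon
        S_grid = np.clip(1.0 - F, 0.0, 1.0)
        S = _step_eval(model.grid.times, S_grid, eval_times)
    elif kind == "deepsurv":
        s = model.net.predict(X).ravel()
        H0 = model.baseline.cumhaz(eval_times)
        S = np.exp(-np.outer(np.exp(s), H0))
    elif kind == "coxtime":
        bl = model.baseline
        if len(bl.event_times) == 0:
            S = np.ones((X.shape[0], len(eval_times)))
        else:
            # hazard increment at event time t_i for subject x:
            #   d_i * exp(g(t_i, x)) / denom_i
            num = np.empty((X.shape[0], len(bl.event_times)))
            for i, t in enumerate(bl.event_times):
                inp = np.hstack([np.full((X.shape[0], 1), model.scale_time(t)), X])
                num[:, i] = np.exp(model.net.predict(inp).ravel())
            H = np.cumsum(num * (bl.event_counts / bl.denominators), axis=1)
            Hpad = np.hstack([np.zeros((X.shape[0], 1)), H])
            idx = np.searchsorted(bl.event_times, eval_times, side="right")
            S = np.exp(-Hpad[:, idx])
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return SurvivalCurves(times=eval_times, values=np.clip(S, 0.0, 1.0))


def _step_eval(grid_times: np.ndarray, S_grid: np.ndarray,
               eval_times: np.ndarray) -> np.ndarray:
    padded = np.hstack([np.ones((S_grid.shape[0], 1)), S_grid])
    idx = np.searchsorted(grid_times, eval_times, side="right")
    return padded[:, np.minimum(idx, S_grid.shape[1])]
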