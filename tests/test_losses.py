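"""The four survival losses against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from tallysurv import (
    loss_cox_partial,
    loss_cox_time,
    loss_deephit,
    loss_logistic_hazard,
)
from tallysurv._autodiff import Tensor
from tallysurv.networks import MLP, Adam


# ---------------------------------------------------------------------------
# independent oracles


def cox_partial_oracle(scores, durations, events):
    """O(n^2) risk-set enumeration of the mean partial-likelihood loss."""
    terms = []
    for i in range(len(scores)):
        if not events[i]:
            continue
        risk = [j for j in range(len(scores)) if durations[j] >= durations[i]]
        terms.append(math.log(sum(math.exp(scores[j] - scores[i]) for j in risk)))
    return sum(terms) / len(terms)


def cox_time_oracle(g, X, durations, events):
    """Nested-loop evaluation of the time-dependent partial likelihood."""
    terms = []
    for i in range(len(durations)):
        if not events[i]:
            continue
        risk = [j for j in range(len(durations)) if durations[j] >= durations[i]]
        gi = g(durations[i], X[i])
        terms.append(math.log(sum(math.exp(g(durations[i], X[j]) - gi) for j in risk)))
    return sum(terms) / len(terms)


def logistic_hazard_oracle(logits, k, events):
    """Bernoulli log-loss on the person-period expansion."""
    h = 1 / (1 + np.exp(-np.asarray(logits, dtype=float)))
    total = 0.0
    for i in range(len(k)):
        for m in range(k[i] + 1):  # subject i at risk in intervals 0..k_i
            if m < k[i]:
                y = 0
            else:
                y = 1 if events[i] else 0
            total += -(y * math.log(h[i, m]) + (1 - y) * math.log(1 - h[i, m]))
    return total / len(k)


def deephit_oracle(logits, k, events, alpha, sigma, eps=1e-7):
    logits = np.asarray(logits, dtype=float)
    z = logits - logits.max(axis=1, keepdims=True)
    f = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    F = np.cumsum(f, axis=1)
    n = len(k)
    nll = 0.0
    for i in range(n):
        if events[i]:
            nll -= math.log(f[i, k[i]] + eps)
        else:
            nll -= math.log(1 - F[i, k[i]] + eps)
    nll /= n
    pairs = [(i, j) for i in range(n) for j in range(n)
             if events[i] and k[i] < k[j]]
    if pairs:
        rank = np.mean([math.exp(-(F[i, k[i]] - F[j, k[i]]) / sigma)
                        for i, j in pairs])
    else:
        rank = 0.0
    return alpha * nll + (1 - alpha) * rank


# ---------------------------------------------------------------------------
# closed forms


class TestClosedForms:
    def test_equal_scores_give_log_risk_set_size(self):
        # one event (earliest), four at risk, equal scores
        d = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 0, 0]
        assert loss_cox_partial(np.zeros(4), d, e) == pytest.approx(math.log(4), abs=1e-10)

    def test_singleton_risk_set_contributes_zero(self):
        d = [1.0, 5.0]
        e = [0, 1]
        assert loss_cox_partial(np.array([0.3, -1.2]), d, e) == pytest.approx(0.0, abs=1e-12)

    def test_cox_time_constant_score_two_at_risk(self):
        g = lambda t, X: np.zeros(len(X))
        X = np.zeros((2, 1))
        assert loss_cox_time(g, X, [1.0, 2.0], [1, 0]) == pytest.approx(math.log(2), abs=1e-10)

    def test_deephit_uniform_pmf_nll_is_log_cells(self):
        """Uniform PMF over 8 cells: every event's NLL term is log 8."""
        logits = np.zeros((3, 8))
        k = np.array([0, 3, 6])
        e = np.array([1, 1, 1])
        got = loss_deephit(logits, k, e, alpha=1.0, sigma=0.1)
        assert got == pytest.approx(math.log(8), abs=1e-6)

    def test_logistic_hazard_event_first_interval(self):
        logits = np.zeros((1, 3))  # h = 0.5 everywhere
        assert loss_logistic_hazard(logits, [0], [1]) == pytest.approx(-math.log(0.5), abs=1e-10)

    def test_logistic_hazard_censored_second_interval(self):
        logits = np.zeros((1, 3))
        got = loss_logistic_hazard(logits, [1], [0])
        assert got == pytest.approx(2 * -math.log(0.5), abs=1e-10)


# ---------------------------------------------------------------------------
# oracle agreement on random batches


class TestOracleAgreement:
    def test_cox_partial_matches_risk_set_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 11))
            s = rng.normal(size=n)
            d = rng.integers(1, 6, size=n).astype(float)  # ties likely
            e = rng.integers(0, 2, size=n)
            if e.sum() == 0:
                e[rng.integers(n)] = 1
            assert loss_cox_partial(s, d, e) == pytest.approx(
                cox_partial_oracle(s, d, e), abs=1e-8)

    def test_cox_time_matches_nested_loops(self, rng):
        W = rng.normal(size=(3,))
        g_vec = lambda t, X: np.asarray(X) @ W + 0.3 * np.sin(np.asarray(t))
        g_one = lambda t, x: float(np.dot(x, W) + 0.3 * math.sin(t))
        for _ in range(100):
            n = int(rng.integers(3, 11))
            X = rng.normal(size=(n, 3))
            d = rng.integers(1, 6, size=n).astype(float)
            e = rng.integers(0, 2, size=n)
            if e.sum() == 0:
                e[rng.integers(n)] = 1
            assert loss_cox_time(g_vec, X, d, e) == pytest.approx(
                cox_time_oracle(g_one, X, d, e), abs=1e-8)

    def test_cox_time_reduces_to_cox_partial_when_g_ignores_t(self, rng):
        W = rng.normal(size=(3,))
        g = lambda t, X: np.asarray(X) @ W
        for _ in range(20):
            n = int(rng.integers(4, 11))
            X = rng.normal(size=(n, 3))
            d = rng.uniform(1, 10, size=n)
            e = rng.integers(0, 2, size=n)
            if e.sum() == 0:
                e[0] = 1
            assert loss_cox_time(g, X, d, e) == pytest.approx(
                loss_cox_partial(X @ W, d, e), abs=1e-10)

    def test_cox_time_subsample_contains_self_and_is_finite(self, rng):
        g = lambda t, X: np.asarray(X) @ np.ones(2)
        X = rng.normal(size=(30, 2))
        d = rng.uniform(1, 10, size=30)
        e = np.ones(30, dtype=int)
        out = loss_cox_time(g, X, d, e, subsample=5, rng=np.random.default_rng(0))
        assert np.isfinite(out) and out >= 0

    def test_logistic_hazard_matches_person_period_expansion(self, rng):
        for _ in range(100):
            n, K = int(rng.integers(2, 11)), int(rng.integers(2, 7))
            logits = rng.normal(size=(n, K))
            k = rng.integers(0, K, size=n)
            e = rng.integers(0, 2, size=n)
            assert loss_logistic_hazard(logits, k, e) == pytest.approx(
                logistic_hazard_oracle(logits, k, e), abs=1e-8)

    def test_deephit_matches_hand_evaluation(self, rng):
        for _ in range(100):
            n, K = int(rng.integers(2, 11)), int(rng.integers(2, 7))
            logits = rng.normal(size=(n, K + 1))
            k = rng.integers(0, K, size=n)
            e = rng.integers(0, 2, size=n)
            alpha = float(rng.choice([0.0, 0.2, 0.5, 0.9, 1.0]))
            sigma = float(rng.choice([0.1, 0.25, 1.0]))
            assert loss_deephit(logits, k, e, alpha, sigma) == pytest.approx(
                deephit_oracle(logits, k, e, alpha, sigma), abs=1e-8)

    def test_deephit_rank_term_two_subject_hand_case(self):
        """Two comparable subjects; rank term equals exp(-dF/sigma) by hand."""
        logits = np.log(np.array([[0.6, 0.3, 0.1], [0.2, 0.3, 0.5]]))
        k = np.array([0, 1])
        e = np.array([1, 0])
        sigma = 0.5
        dF = 0.6 - 0.2  # F_1(k_1) - F_2(k_1)
        expected = math.exp(-dF / sigma)
        got = loss_deephit(logits, k, e, alpha=0.0, sigma=sigma)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            loss_cox_partial(np.zeros(3), [1.0, 2.0, 3.0], [0, 0, 0])

    def test_deephit_warns_on_out_of_range_alpha(self):
        with pytest.warns(UserWarning, match="alpha"):
            loss_deephit(np.zeros((2, 4)), [0, 1], [1, 0], alpha=0.33, sigma=0.1)

    def test_logistic_hazard_bad_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            loss_logistic_hazard(np.zeros((2, 3)), [0, 3], [1, 1])


# ---------------------------------------------------------------------------
# gradients drive all four losses down on a separable batch


@pytest.mark.parametrize("kind", ["cox_partial", "cox_time", "deephit", "nnet"])
def test_losses_decrease_under_gradient_descent(kind, rng):
    n, p, K = 40, 4, 5
    X = rng.normal(size=(n, p))
    beta = np.array([1.5, -1.5, 0.0, 0.0])
    risk = X @ beta
    d = np.exp(-risk + rng.normal(scale=0.1, size=n))  # high risk dies early
    e = np.ones(n, dtype=int)
    k = np.clip(np.searchsorted(np.quantile(d, np.linspace(0, 1, K + 1)[1:-1]), d), 0, K - 1)

    out_dim = {"cox_partial": 1, "cox_time": 1, "deephit": K + 1, "nnet": K}[kind]
    net = MLP(p + (1 if kind == "cox_time" else 0), out_dim,
              n_layers=1, n_nodes=8, dropout=0.0, rng=rng)
    opt = Adam(net.params, lr=0.01)

    def compute():
        if kind == "cox_partial":
            return loss_cox_partial(net.forward(X).reshape(-1), d, e)
        if kind == "cox_time":
            def g(t, Xj):
                inp = np.hstack([np.asarray(t)[:, None], Xj])
                return net.forward(inp).reshape(-1)
            return loss_cox_time(g, X, d, e)
        if kind == "deephit":
            return loss_deephit(net.forward(X), k, e, alpha=0.5, sigma=0.25)
        return loss_logistic_hazard(net.forward(X), k, e)

    first = float(compute().data)
    for _ in range(60):
        loss = compute()
        opt.zero_grad()
        loss.backward()
        opt.step()
    last = float(compute().data)
    assert last < first
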