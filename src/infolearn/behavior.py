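"""Q-learning model of probabilistic instrumental learning.

The task presents interleaved pairs of cues; one cue of each pair is the
better option (probability 0.75 of the favourable outcome).  Reward pairs pay
+1/0 euros, punishment pairs -1/0.  Behavior is modeled with a standard
delta-rule value learner,

    Q_{t+1}(chosen) = Q_t(chosen) + alpha * delta_t,      delta_t = R_t - Q_t,

and a softmax (Gibbs) choice rule with temperature ``beta`` and a
perseveration bonus ``theta`` added to the value of the option chosen on the
previous trial of the same pair.  Q-values start at 0 (the mean of all
possible outcomes), so the first trial of a pair has delta equal to its
outcome.

Trial tables are plain pandas DataFrames with one row per trial and columns::

    subject, session, trial, pair, condition, chosen, outcome,
    prev_chosen_same_pair

``chosen`` is 1 for the better cue of the pair, 0 for the worse;
``prev_chosen_same_pair`` is -1 on a pair's first trial.  The prediction-error
table produced by :func:`compute_prediction_errors` carries the signed PE for
every trial plus its split into RPE (reward trials) and PPE (punishment
trials).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "QParams",
    "FitResult",
    "DEFAULT_BOUNDS",
    "q_update",
    "choice_probability",
    "simulate_agent",
    "negative_log_likelihood",
    "fit_qlearning",
    "compute_prediction_errors",
    "validate_trial_table",
]

TRIAL_COLUMNS = [
    "subject",
    "session",
    "trial",
    "pair",
    "condition",
    "chosen",
    "outcome",
    "prev_chosen_same_pair",
]

#: Optimization bounds for (alpha, beta, theta).  The learning rate is a
#: proper rate, beta must stay positive (it divides the values), and the
#: perseveration bonus is allowed either sign up to the outcome range.
DEFAULT_BOUNDS = ((0.0, 1.0), (1e-6, 10.0), (-2.0, 2.0))

_P_FLOOR = 1e-12


@dataclass(frozen=True)
class QParams:
    """Free parameters of the learner.

    alpha : learning rate in [0, 1].
    beta  : softmax temperature (> 0); larger values mean more exploration.
    theta : perseveration bonus added to the previously chosen option's value.
    """

    alpha: float
    beta: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not self.beta > 0.0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")


@dataclass(frozen=True)
class FitResult:
    """Best-of-multistart maximum-likelihood fit."""

    params: QParams
    nll: float
    n_starts: int
    converged: tuple[bool, ...]

    def to_json(self) -> str:
        d = asdict(self)
        d["converged"] = list(self.converged)
        return json.dumps(d, indent=2)


def q_update(q: float, outcome: float, alpha: float) -> tuple[float, float]:
    """One delta-rule update of the chosen cue's value.

    Returns ``(q_next, delta)`` with ``delta = outcome - q`` and
    ``q_next = q + alpha * delta``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    delta = outcome - q
    return q + alpha * delta, delta


def choice_probability(
    q_a: float,
    q_b: float,
    params: QParams,
    prev_choice: str | None = None,
) -> float:
    """Softmax probability of choosing option ``a``.

    ``prev_choice`` is ``"a"``, ``"b"`` or ``None`` (first trial of the pair);
    the perseveration bonus theta is added to the previously chosen option's
    value before the softmax.
    """
    if prev_choice not in (None, "a", "b", "none"):
        raise ValueError(f"prev_choice must be 'a', 'b' or None, got {prev_choice!r}")
    ua = q_a + (params.theta if prev_choice == "a" else 0.0)
    ub = q_b + (params.theta if prev_choice == "b" else 0.0)
    # stable logistic of the utility difference
    d = (ua - ub) / params.beta
    if d >= 0:
        return 1.0 / (1.0 + np.exp(-d))
    e = np.exp(d)
    return e / (1.0 + e)


def validate_trial_table(table: pd.DataFrame, require_choices: bool = True) -> None:
    """Check trial-table invariants; raise ``ValueError`` on violation."""
    if len(table) == 0:
        raise ValueError("empty trial table")
    missing = [c for c in ("session", "pair", "condition") if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad = set(table["condition"].unique()) - {"reward", "punishment"}
    if bad:
        raise ValueError(f"unknown conditions: {bad}")
    cond_per_pair = table.groupby("pair")["condition"].nunique()
    if (cond_per_pair > 1).any():
        raise ValueError("a pair id maps to more than one condition")
    if require_choices:
        for col in ("chosen", "outcome"):
            if col not in table.columns:
                raise ValueError(f"trial table missing column: {col}")
        rew = table.loc[table["condition"] == "reward", "outcome"]
        pun = table.loc[table["condition"] == "punishment", "outcome"]
        if not rew.isin([0, 1]).all():
            raise ValueError("reward-pair outcomes must be in {0, +1}")
        if not pun.isin([-1, 0]).all():
            raise ValueError("punishment-pair outcomes must be in {-1, 0}")


def _encode(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Presentation-ordered integer arrays for the sequential likelihood."""
    pair_codes, _ = pd.factorize(table["pair"], sort=False)
    chosen = table["chosen"].to_numpy(dtype=np.int64)
    outcome = table["outcome"].to_numpy(dtype=np.float64)
    return pair_codes.astype(np.int64), chosen, outcome, int(pair_codes.max()) + 1


def _forward_py(pairs, chosen, outcome, n_pairs, alpha, beta, theta):
    q = np.zeros((n_pairs, 2))
    prev = np.full(n_pairs, -1, dtype=np.int64)
    nll = 0.0
    deltas = np.empty(len(pairs))
    for i in range(len(pairs)):
        p = pairs[i]
        c = chosen[i]
        u1 = q[p, 1] + (theta if prev[p] == 1 else 0.0)
        u0 = q[p, 0] + (theta if prev[p] == 0 else 0.0)
        d = (u1 - u0) / beta
        if d >= 0:
            p1 = 1.0 / (1.0 + np.exp(-d))
        else:
            e = np.exp(d)
            p1 = e / (1.0 + e)
        pc = p1 if c == 1 else 1.0 - p1
        if pc < _P_FLOOR:
            pc = _P_FLOOR
        nll -= np.log(pc)
        delta = outcome[i] - q[p, c]
        deltas[i] = delta
        q[p, c] += alpha * delta
        prev[p] = c
    return nll, deltas


try:  # optional JIT of the sequential kernel; the fallback is pure python
    from numba import njit

    _forward = njit(cache=False)(_forward_py)
except Exception:  # pragma: no cover - numba present in the supported env
    _forward = _forward_py


def negative_log_likelihood(table: pd.DataFrame, params: QParams) -> float:
    """Negative log-likelihood (nats) of the observed choices under ``params``.

    Q-values are reset to 0 at the start of every pair; pair ids are assumed
    unique across sessions (the task generator guarantees this).  Choice
    probabilities are floored at 1e-12 to keep the objective finite.
    """
    validate_trial_table(table)
    pairs, chosen, outcome, n_pairs = _encode(table)
    nll, _ = _forward(
        pairs, chosen, outcome, n_pairs, params.alpha, params.beta, params.theta
    )
    return float(nll)


def fit_qlearning(
    table: pd.DataFrame,
    n_starts: int = 10,
    bounds: tuple = DEFAULT_BOUNDS,
    seed: int | None = None,
) -> FitResult:
    """Maximum-likelihood fit of (alpha, beta, theta) by bounded multistart.

    ``n_starts`` starting points are drawn uniformly inside ``bounds`` from a
    generator seeded with ``seed``; each start is optimized with L-BFGS-B and
    the best incumbent is returned.  Deterministic given ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    validate_trial_table(table)
    pairs, chosen, outcome, n_pairs = _encode(table)

    def objective(x):
        return _forward(pairs, chosen, outcome, n_pairs, x[0], x[1], x[2])[0]

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = lo + (hi - lo) * rng.random((n_starts, 3))

    best = None
    converged = []
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        converged.append(bool(res.success))
        if best is None or res.fun < best.fun:
            best = res
    params = QParams(alpha=float(best.x[0]), beta=float(best.x[1]), theta=float(best.x[2]))
    return FitResult(
        params=params,
        nll=float(best.fun),
        n_starts=n_starts,
        converged=tuple(converged),
    )


def compute_prediction_errors(table: pd.DataFrame, params: QParams) -> pd.DataFrame:
    """Trial-wise prediction errors under sequentially updated Q-values.

    Returns a copy of the identifying columns plus ``pe`` (signed delta),
    ``rpe`` (delta on reward trials, NaN elsewhere) and ``ppe`` (delta on
    punishment trials, NaN elsewhere).
    """
    validate_trial_table(table)
    pairs, chosen, outcome, n_pairs = _encode(table)
    _, deltas = _forward(
        pairs, chosen, outcome, n_pairs, params.alpha, params.beta, params.theta
    )
    out = table[[c for c in TRIAL_COLUMNS if c in table.columns]].copy()
    out["pe"] = deltas
    is_rew = (table["condition"] == "reward").to_numpy()
    out["rpe"] = np.where(is_rew, deltas, np.nan)
    out["ppe"] = np.where(~is_rew, deltas, np.nan)
    return out


def simulate_agent(
    layout: pd.DataFrame, params: QParams, seed: int | None = None
) -> pd.DataFrame:
    """Forward-simulate choices and outcomes on a task layout.

    ``layout`` is a task table without ``chosen``/``outcome`` but with the
    pre-drawn contingency columns ``outcome_better`` / ``outcome_worse`` (see
    :func:`infolearn.synth.generate_task`).  Choices are sampled from the
    softmax rule; outcomes are read off the pre-drawn columns.  Deterministic
    given ``seed``.
    """
    validate_trial_table(layout, require_choices=False)
    for col in ("outcome_better", "outcome_worse"):
        if col not in layout.columns:
            raise ValueError(f"layout missing contingency column {col!r}")
    rng = np.random.default_rng(seed)
    pair_codes, _ = pd.factorize(layout["pair"], sort=False)
    n_pairs = pair_codes.max() + 1
    q = np.zeros((n_pairs, 2))
    prev = np.full(n_pairs, -1, dtype=np.int64)
    ob = layout["outcome_better"].to_numpy()
    ow = layout["outcome_worse"].to_numpy()
    chosen = np.empty(len(layout), dtype=np.int64)
    outcome = np.empty(len(layout), dtype=np.float64)
    prev_col = np.empty(len(layout), dtype=np.int64)
    u = rng.random(len(layout))
    for i, p in enumerate(pair_codes):
        u1 = q[p, 1] + (params.theta if prev[p] == 1 else 0.0)
        u0 = q[p, 0] + (params.theta if prev[p] == 0 else 0.0)
        d = (u1 - u0) / params.beta
        p1 = 1.0 / (1.0 + np.exp(-d)) if d >= 0 else np.exp(d) / (1.0 + np.exp(d))
        c = 1 if u[i] < p1 else 0
        r = ob[i] if c == 1 else ow[i]
        prev_col[i] = prev[p]
        chosen[i] = c
        outcome[i] = r
        q[p, c] += params.alpha * (r - q[p, c])
        prev[p] = c
    out = layout.copy()
    out["chosen"] = chosen
    out["outcome"] = outcome
    out["prev_chosen_same_pair"] = prev_col
    return out
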