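"""Per-trial learner dynamics: state, updates, policies, and simulation.

This module is the readable, stateful implementation of every model in the
space. It is used for simulating agents on task schedules and for extracting
latent trajectories (values, per-state imitation rates). The likelihood used
for fitting lives in :mod:`socialrl._kernel` as a compiled trial loop; the
two implementations are verified against each other in the test suite.

Conventions
-----------
Options within a context are coded 0 ("a") and 1 ("b"). All value structures
start at 0; the Demonstrator policy pi_D starts uniform. Decision-bias traces
are discarded after every private choice and at block boundaries; the
accumulating DB variants (DB4-6) keep their trace across consecutive
observational trials, the non-accumulating ones (DB1-3) re-derive it from Q
on every demonstration.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .models import ModelSpec, ParameterSet

__all__ = ["LearnerAgent", "softmax_pair", "simulate_agent", "dataset_nll_reference"]


def softmax_pair(v0: float, v1: float, beta: float, kappa: float, last: int | None) -> tuple[float, float]:
    """Two-option softmax with a choice-autocorrelation bonus.

    Returns (pi(0), pi(1)) with
    pi(c) = 1 / (1 + exp(beta * [V(cbar) - V(c) - lambda(c) * kappa])),
    lambda(c) = +1 if c is the last performed action, -1 otherwise, and the
    autocorrelation term dropped when no action has been performed yet.
    """
    lam0 = 0.0 if last is None else (1.0 if last == 0 else -1.0)
    x = beta * ((v1 - v0) - lam0 * kappa)
    x = min(max(x, -700.0), 700.0)
    p0 = 1.0 / (1.0 + math.exp(x))
    if not math.isfinite(p0):
        raise FloatingPointError("non-finite choice probability")
    return p0, 1.0 - p0


class LearnerAgent:
    """Evolving learner state for one model on an n-context task.

    Attributes
    ----------
    Q : per-context [v_a, v_b] value function (bounded in [-1, 1]).
    trace : per-context decision trace for DB models; either a biased policy
        (DB1/DB4) or a decision value function Q' (DB2/3/5/6); ``None`` when
        no trace is active.
    pi_D, Q_D : per-context Demonstrator model (MB families).
    alpha_i_state : per-context imitation rate for metaVS, initialised 0.
    last_action : per-context last performed option (None before the first).
    """

    def __init__(self, spec: ModelSpec, params: ParameterSet, n_contexts: int):
        if n_contexts < 1:
            raise ValueError("need at least one context")
        self.spec = spec
        self.params = params
        self.n_contexts = n_contexts
        self.Q = [[0.0, 0.0] for _ in range(n_contexts)]
        self.trace: list[list[float] | None] = [None] * n_contexts
        self.pi_D = [[0.5, 0.5] for _ in range(n_contexts)]
        self.Q_D = [[0.0, 0.0] for _ in range(n_contexts)]
        self.alpha_i_state = [0.0] * n_contexts
        self.last_action: list[int | None] = [None] * n_contexts
        self.tau: int | None = None  # last agreement indicator (metaVS)

    # -- bookkeeping -------------------------------------------------------

    def start_block(self, context: int) -> None:
        """Block boundary: decision-bias traces do not survive it."""
        self.trace[context] = None

    def _kappa(self) -> float:
        return self.params.kappa if self.spec.use_kappa else 0.0

    def _alpha_d(self) -> float:
        return self.spec.alpha_d_value if self.spec.alpha_d_fixed else self.params.alpha_d

    def value_policy(self, context: int) -> tuple[float, float]:
        """Softmax policy derived from Q (the unbiased policy)."""
        q = self.Q[context]
        return softmax_pair(q[0], q[1], self.params.beta, self._kappa(), self.last_action[context])

    # -- demonstration processing -----------------------------------------

    def observe(self, context: int, d: int) -> None:
        """Process a demonstration of option ``d`` in ``context``."""
        if d not in (0, 1):
            raise ValueError(f"demonstration must be option 0 or 1, got {d}")
        spec, p = self.spec, self.params
        fam, var = spec.family, spec.variant
        if spec.match_updates_last_action:
            # the learner physically presses the matching key before any
            # bias applies; doing this first keeps the alpha_i = 0 reduction
            # to the baseline exact for the policy-deriving DB variants
            self.last_action[context] = d
        if fam == "RW":
            pass
        elif fam == "DB":
            accumulating = var >= 4
            rule = (var - 1) % 3  # 0: policy, 1: value, 2: symmetric value
            if rule == 0:
                if not accumulating or self.trace[context] is None:
                    self.trace[context] = list(self.value_policy(context))
                pi = self.trace[context]
                pi[d] += p.alpha_i * (1.0 - pi[d])
                pi[1 - d] = 1.0 - pi[d]
            else:
                if not accumulating or self.trace[context] is None:
                    self.trace[context] = list(self.Q[context])
                qp = self.trace[context]
                qp[d] += p.alpha_i * (1.0 - qp[d])
                if rule == 2:
                    qp[1 - d] += p.alpha_i * (-1.0 - qp[1 - d])
        elif fam == "MB":
            build = (var - 1) // 3  # 0: PU on pi_D, 1: VU on Q_D, 2: SVU on Q_D
            ad = self._alpha_d()
            if build == 0:
                piD = self.pi_D[context]
                piD[d] += ad * (1.0 - piD[d])
                piD[1 - d] = 1.0 - piD[d]
            else:
                qD = self.Q_D[context]
                qD[d] += ad * (1.0 - qD[d])
                if build == 2:
                    qD[1 - d] += ad * (-1.0 - qD[1 - d])
        elif fam == "VS":
            q = self.Q[context]
            q[d] += p.alpha_i * (1.0 - q[d])
            if var == 2:
                q[1 - d] += p.alpha_i * (-1.0 - q[1 - d])
        elif fam == "metaVS":
            q = self.Q[context]
            # agreement: does the demonstration maximise the learner's values?
            tau = 1.0 if q[d] >= q[1 - d] else 0.0
            self.tau = int(tau)
            self.alpha_i_state[context] += p.alpha_m * (tau - self.alpha_i_state[context])
            ai = self.alpha_i_state[context]
            q[d] += ai * (1.0 - q[d])
            q[1 - d] += ai * (-1.0 - q[1 - d])

    # -- action selection --------------------------------------------------

    def action_policy(self, context: int) -> tuple[float, float]:
        """Policy actually used for the next private choice."""
        spec, p = self.spec, self.params
        fam = spec.family
        if fam == "DB" and self.trace[context] is not None:
            rule = (spec.variant - 1) % 3
            if rule == 0:
                pi = self.trace[context]
                return pi[0], pi[1]
            qp = self.trace[context]
            return softmax_pair(qp[0], qp[1], p.beta, self._kappa(), self.last_action[context])
        if fam == "MB":
            build = (spec.variant - 1) // 3
            pref = self.pi_D[context] if build == 0 else self.Q_D[context]
            if pref[0] == pref[1]:
                return self.value_policy(context)  # tied model: no bias
            if spec.mb_bias == "blend":
                pi = list(self.value_policy(context))
                if build == 0:
                    piD = list(pref)
                else:
                    piD = list(
                        softmax_pair(pref[0], pref[1], p.beta, 0.0, None)
                    )
                w = p.alpha_i
                return ((1 - w) * pi[0] + w * piD[0], (1 - w) * pi[1] + w * piD[1])
            d_star = 0 if pref[0] > pref[1] else 1
            bias = (spec.variant - 1) % 3  # 0: PU, 1: VU, 2: SVU
            if bias == 0:
                pi = list(self.value_policy(context))
                pi[d_star] += p.alpha_i * (1.0 - pi[d_star])
                pi[1 - d_star] = 1.0 - pi[d_star]
                return pi[0], pi[1]
            qb = list(self.Q[context])
            qb[d_star] += p.alpha_i * (1.0 - qb[d_star])
            if bias == 2:
                qb[1 - d_star] += p.alpha_i * (-1.0 - qb[1 - d_star])
            return softmax_pair(qb[0], qb[1], p.beta, self._kappa(), self.last_action[context])
        return self.value_policy(context)

    # -- private outcome learning -----------------------------------------

    def learn(self, context: int, choice: int, outcome: float) -> None:
        """Rescorla-Wagner update after a private choice."""
        if outcome not in (1, -1, 1.0, -1.0):
            raise ValueError(f"outcome must be +1 or -1, got {outcome}")
        if choice not in (0, 1):
            raise ValueError(f"choice must be option 0 or 1, got {choice}")
        ap = self.params.alpha_p
        q = self.Q[context]
        q[choice] += ap * (outcome - q[choice])
        if self.spec.symmetric_private:
            q[1 - choice] += ap * (-outcome - q[1 - choice])
        self.trace[context] = None  # bias does not survive a private choice
        self.last_action[context] = choice


# --------------------------------------------------------------------------
# schedule traversal
# --------------------------------------------------------------------------

def _option_code(label, option_a) -> int:
    return 0 if label == option_a else 1


def simulate_agent(
    spec: ModelSpec,
    params: ParameterSet,
    schedule: pd.DataFrame,
    seed,
    record_latents: bool = False,
) -> pd.DataFrame:
    """Play one subject's schedule with a learner model; fill choices/outcomes.

    Observational trials apply the model's demonstration processing; private
    trials sample a choice from the current action policy and a +1/-1 outcome
    from the trial's winning probabilities, then apply the private update.
    Reproducible given seed. With ``record_latents`` the returned frame also
    carries the choice probability of option a, the Q values, and (metaVS)
    the per-state imitation rate at each trial.
    """
    rng = np.random.default_rng(seed)
    df = schedule.reset_index(drop=True).copy()
    contexts = {c: i for i, c in enumerate(pd.unique(df["context_id"]))}
    agent = LearnerAgent(spec, params, n_contexts=len(contexts))
    choices: list = [None] * len(df)
    outcomes: list = [None] * len(df)
    latents: list[dict] = []
    prev_block = None
    for i, row in enumerate(df.itertuples(index=False)):
        s = contexts[row.context_id]
        blk = (row.subject_id, row.session, row.block)
        if blk != prev_block:
            agent.start_block(s)
            prev_block = blk
        if row.trial_type == "observational":
            if pd.isna(row.demonstration):
                raise ValueError("observational trial without a demonstration")
            d = _option_code(row.demonstration, row.option_a)
            agent.observe(s, d)
            if record_latents:
                latents.append(
                    {"p_choice_a": np.nan, "Q_a": agent.Q[s][0], "Q_b": agent.Q[s][1],
                     "alpha_i_state": agent.alpha_i_state[s]}
                )
        elif row.trial_type == "private":
            p0, _ = agent.action_policy(s)
            c = 0 if rng.random() < p0 else 1
            p_win = row.p_win_a if c == 0 else row.p_win_b
            r = sample_outcome_inline(p_win, rng)
            choices[i] = row.option_a if c == 0 else row.option_b
            outcomes[i] = r
            if record_latents:
                latents.append(
                    {"p_choice_a": p0, "Q_a": agent.Q[s][0], "Q_b": agent.Q[s][1],
                     "alpha_i_state": agent.alpha_i_state[s]}
                )
            agent.learn(s, c, r)
        else:
            raise ValueError(f"unknown trial_type {row.trial_type!r}")
    df["choice"] = choices
    df["outcome"] = outcomes
    if record_latents:
        df = pd.concat([df, pd.DataFrame(latents, index=df.index)], axis=1)
    return df


def sample_outcome_inline(p_win: float, rng) -> int:
    return 1 if rng.random() < p_win else -1


def dataset_nll_reference(spec: ModelSpec, params: ParameterSet, dataset: pd.DataFrame,
                          floor: float = 1e-12) -> float:
    """Negative log-likelihood via the stateful agent (reference path).

    Sums -log pi(c) over private trials only, evolving state through every
    trial. Used in tests to cross-check the compiled likelihood kernel.
    """
    df = dataset.reset_index(drop=True)
    contexts = {c: i for i, c in enumerate(pd.unique(df["context_id"]))}
    agent = LearnerAgent(spec, params, n_contexts=len(contexts))
    nll = 0.0
    prev_block = None
    for row in df.itertuples(index=False):
        s = contexts[row.context_id]
        blk = (row.subject_id, row.session, row.block)
        if blk != prev_block:
            agent.start_block(s)
            prev_block = blk
        if row.trial_type == "observational":
            agent.observe(s, _option_code(row.demonstration, row.option_a))
        else:
            if pd.isna(row.choice):
                raise ValueError("private trial without a recorded choice")
            c = _option_code(row.choice, row.option_a)
            p = agent.action_policy(s)[c]
            nll -= math.log(max(p, floor))
            agent.learn(s, c, float(row.outcome))
    return nll
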