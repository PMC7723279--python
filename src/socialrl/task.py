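"""Synthetic observational bandit task: schedules, contingencies, demonstrators.

The task is a two-armed bandit with interleaved *private* trials (the learner
chooses one of two symbols and wins or loses a point) and *observational*
trials (the learner sees the choice of a Demonstrator on the same symbol
pair; the Demonstrator's outcome is never shown). Three design styles are
supported:

* ``exp1`` -- 400 trials (4 sessions x 5 blocks x 20 trials), stable 70/30
  contingencies, Private (P), Skilled-Demonstrator (SD) and
  Unskilled-Demonstrator (UD) conditions within subject, 1:1
  observational:private ratio in observational blocks.
* ``exp2`` -- 300 trials (3 x 5 x 20), stable 60/40 contingencies, P plus a
  single observational condition (SD or UD) between subjects, 1:1 ratio.
* ``exp3`` -- 300 trials on one restless symbol pair whose winning
  probabilities follow independent reflected Gaussian random walks, a 1:2
  observational:private ratio, Demonstrator correct-choice rates emulated as
  Bernoulli policies (0.84 skilled / 0.60 unskilled).

Demonstrators are Bernoulli policies choosing the reward-maximising symbol
with probability ``skill`` (0.8 for SD, 0.2 for UD in exp1/exp2). Within a
block, runs of consecutive observational trials have length 1..7 and no more
than 3 consecutive demonstrations show the same option.

Schedules are emitted as tidy pandas DataFrames (one row per trial) with
choices/outcomes left empty; :func:`socialrl.agents.simulate_agent` fills
them in.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "ChoiceContext",
    "WalkConfig",
    "DemonstratorSpec",
    "TaskConfig",
    "TRIAL_COLUMNS",
    "make_random_walk",
    "sample_outcome",
    "make_schedule",
    "generate_cohort",
    "validate_schedule",
    "ScheduleReport",
]

#: trial-log column order (CSV schema; empty fields encode missing values)
TRIAL_COLUMNS = [
    "subject_id",
    "session",
    "block",
    "trial_index",
    "condition",
    "context_id",
    "trial_type",
    "option_a",
    "option_b",
    "p_win_a",
    "p_win_b",
    "demonstration",
    "choice",
    "outcome",
]

_MAX_DEMO_RESAMPLES = 500


@dataclass(frozen=True)
class ChoiceContext:
    """A pair of symbols with complementary winning probabilities.

    ``p_correct`` is the winning probability of the better symbol; the other
    symbol wins with probability ``1 - p_correct``.
    """

    context_id: int
    p_correct: float
    labels: tuple[str, str] = ("a", "b")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError(f"p_correct must lie in [0, 1], got {self.p_correct}")
        if len(self.labels) != 2 or self.labels[0] == self.labels[1]:
            raise ValueError("labels must be two distinct symbol identifiers")


@dataclass(frozen=True)
class WalkConfig:
    """Reflected Gaussian random walk for restless contingencies."""

    start: float = 0.5
    step_sd: float = 0.03
    lower: float = 0.2
    upper: float = 0.8

    def __post_init__(self) -> None:
        if self.step_sd < 0:
            raise ValueError(f"step_sd must be nonnegative, got {self.step_sd}")
        if not self.lower < self.upper:
            raise ValueError("walk bounds must satisfy lower < upper")
        if not self.lower <= self.start <= self.upper:
            raise ValueError("walk start must lie within the bounds")


@dataclass(frozen=True)
class DemonstratorSpec:
    """Bernoulli demonstrator: chooses the reward-maximising symbol w.p. skill."""

    skill: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.skill <= 1.0:
            raise ValueError(f"skill must lie in [0, 1], got {self.skill}")


@dataclass(frozen=True)
class TaskConfig:
    """Full design of one synthetic experiment session structure."""

    experiment_style: str = "exp1"
    n_sessions: int = 4
    blocks_per_session: int = 5
    trials_per_block: int = 20
    conditions: tuple[str, ...] = ("P", "SD", "UD")
    # block-condition layout within one session (shuffled per session)
    session_layout: tuple[str, ...] = ("P", "SD", "UD", "SD", "UD")
    obs_to_private_ratio: tuple[int, int] = (1, 1)
    max_obs_run: int = 7
    max_same_option_run: int = 3
    p_correct: float = 0.7
    walk: WalkConfig | None = None
    demonstrators: dict = field(
        default_factory=lambda: {"SD": DemonstratorSpec(0.8), "UD": DemonstratorSpec(0.2)}
    )

    def __post_init__(self) -> None:
        if self.experiment_style not in ("exp1", "exp2", "exp3"):
            raise ValueError(f"unknown experiment_style {self.experiment_style!r}")
        if min(self.n_sessions, self.blocks_per_session, self.trials_per_block) < 1:
            raise ValueError("session/block/trial counts must be positive")
        if len(self.session_layout) != self.blocks_per_session:
            raise ValueError("session_layout must list one condition per block")
        if any(c not in self.conditions for c in self.session_layout):
            raise ValueError("session_layout uses a condition not in `conditions`")
        ro, rp = self.obs_to_private_ratio
        if ro < 1 or rp < 1:
            raise ValueError("obs_to_private_ratio entries must be positive")
        if self.trials_per_block % (ro + rp):
            raise ValueError(
                f"block length {self.trials_per_block} cannot realise the "
                f"{ro}:{rp} observational:private ratio exactly"
            )
        n_obs = self.trials_per_block * ro // (ro + rp)
        n_priv = self.trials_per_block - n_obs
        if math.ceil(n_obs / self.max_obs_run) > n_priv + 1:
            raise ValueError(
                "infeasible constraint combination: observational runs of at most "
                f"{self.max_obs_run} cannot be separated by {n_priv} private trials"
            )
        for cond, dem in self.demonstrators.items():
            if not isinstance(dem, DemonstratorSpec):
                raise TypeError(f"demonstrators[{cond!r}] must be a DemonstratorSpec")

    # --- canonical designs -------------------------------------------------

    @classmethod
    def exp1(cls, **overrides) -> "TaskConfig":
        """400 trials, 70/30, SD and UD within subject."""
        return cls(**overrides) if overrides else cls()

    @classmethod
    def exp2(cls, observed_condition: str = "SD", **overrides) -> "TaskConfig":
        """300 trials, 60/40, one observational condition between subjects."""
        if observed_condition not in ("SD", "UD"):
            raise ValueError("observed_condition must be 'SD' or 'UD'")
        defaults = dict(
            experiment_style="exp2",
            n_sessions=3,
            blocks_per_session=5,
            trials_per_block=20,
            conditions=("P", observed_condition),
            session_layout=("P", "P") + (observed_condition,) * 3,
            p_correct=0.6,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def exp3(cls, observed_condition: str = "SD", **overrides) -> "TaskConfig":
        """300 trials, restless contingencies, 1:2 observational:private ratio."""
        if observed_condition not in ("SD", "UD"):
            raise ValueError("observed_condition must be 'SD' or 'UD'")
        defaults = dict(
            experiment_style="exp3",
            n_sessions=1,
            blocks_per_session=10,
            trials_per_block=30,
            conditions=(observed_condition,),
            session_layout=(observed_condition,) * 10,
            obs_to_private_ratio=(1, 2),
            walk=WalkConfig(),
            demonstrators={"SD": DemonstratorSpec(0.84), "UD": DemonstratorSpec(0.60)},
        )
        defaults.update(overrides)
        return cls(**defaults)

    def n_trials(self) -> int:
        return self.n_sessions * self.blocks_per_session * self.trials_per_block

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["demonstrators"] = {k: v["skill"] for k, v in d["demonstrators"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "demonstrators" in d:
            d["demonstrators"] = {
                k: v if isinstance(v, DemonstratorSpec) else DemonstratorSpec(float(v))
                for k, v in d["demonstrators"].items()
            }
        if d.get("walk") is not None and not isinstance(d["walk"], WalkConfig):
            d["walk"] = WalkConfig(**d["walk"])
        for key in ("conditions", "session_layout", "obs_to_private_ratio"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# --------------------------------------------------------------------------
# primitive samplers
# --------------------------------------------------------------------------

def make_random_walk(walk: WalkConfig, n_trials: int, seed) -> np.ndarray:
    """Reflected Gaussian random walk of winning probabilities.

    Gaussian increments with sd ``walk.step_sd`` are reflected at the bounds,
    so values stay inside [lower, upper].
    """
    rng = np.random.default_rng(seed)
    values = np.empty(n_trials, dtype=float)
    x = float(walk.start)
    span = walk.upper - walk.lower
    for t in range(n_trials):
        values[t] = x
        x += rng.normal(0.0, walk.step_sd)
        # fold into [lower, upper] (handles arbitrarily large excursions)
        y = (x - walk.lower) % (2 * span)
        x = walk.lower + (y if y <= span else 2 * span - y)
    return values


def sample_outcome(p_win: float, rng) -> int:
    """Draw a +1/-1 outcome for a symbol whose winning probability is p_win."""
    if not 0.0 <= p_win <= 1.0:
        raise ValueError(f"winning probability must lie in [0, 1], got {p_win}")
    return 1 if rng.random() < p_win else -1


# --------------------------------------------------------------------------
# uniform composition sampling (exact, via dynamic-programming counts)
# --------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _n_compositions(n: int, k: int, lo: int, hi: int) -> int:
    """Number of ways to write n as an ordered sum of k parts in [lo, hi]."""
    if k == 0:
        return 1 if n == 0 else 0
    return sum(
        _n_compositions(n - part, k - 1, lo, hi)
        for part in range(lo, min(hi, n) + 1)
    )


def _sample_composition(n: int, k: int, lo: int, hi: int, rng) -> list[int]:
    """Uniform draw over ordered compositions of n into k parts in [lo, hi]."""
    total = _n_compositions(n, k, lo, hi)
    if total == 0:
        raise ValueError(f"no composition of {n} into {k} parts within [{lo}, {hi}]")
    parts = []
    for i in range(k):
        u = rng.integers(0, total)
        acc = 0
        for part in range(lo, min(hi, n) + 1):
            c = _n_compositions(n - part, k - i - 1, lo, hi)
            acc += c
            if u < acc:
                parts.append(part)
                n -= part
                total = c
                break
    return parts


def _block_trial_types(n_obs: int, n_priv: int, max_obs_run: int, rng) -> list[str]:
    """Interleave n_obs observational and n_priv private trials.

    Observational trials come in runs of length 1..max_obs_run separated by
    at least one private trial; the number of runs is drawn uniformly from
    the feasible range, run lengths uniformly over compositions.
    """
    if n_obs == 0:
        return ["private"] * n_priv
    k_lo = math.ceil(n_obs / max_obs_run)
    k_hi = min(n_obs, n_priv + 1)
    if k_lo > k_hi:
        raise ValueError(
            "infeasible constraint combination: cannot interleave "
            f"{n_obs} observational runs (max length {max_obs_run}) with {n_priv} private trials"
        )
    k = int(rng.integers(k_lo, k_hi + 1))
    obs_runs = _sample_composition(n_obs, k, 1, max_obs_run, rng)
    # private gaps: k-1 internal gaps >= 1, leading/trailing >= 0
    gaps = _sample_composition(n_priv - (k - 1), k + 1, 0, n_priv, rng)
    for i in range(1, k):
        gaps[i] += 1
    types: list[str] = []
    for i in range(k):
        types += ["private"] * gaps[i]
        types += ["observational"] * obs_runs[i]
    types += ["private"] * gaps[k]
    return types


def _max_run(values) -> int:
    best = run = 0
    prev = object()
    for v in values:
        run = run + 1 if v == prev else 1
        prev = v
        best = max(best, run)
    return best


def _sample_demonstrations(
    correct: np.ndarray, skill: float, max_same_run: int, rng
) -> np.ndarray:
    """Demonstrated option (0/1) per observational trial of one block.

    ``correct`` holds the reward-maximising option index for each
    observational trial (in block order). The demonstrator matches it on
    ``round(skill * n)`` trials (fractional part resolved by a Bernoulli
    draw, so the marginal correct-choice rate equals ``skill`` exactly);
    which trials match is a uniform shuffle, re-drawn until no more than
    ``max_same_run`` consecutive demonstrations show the same option.
    Fixing the per-block count keeps the headline correct-choice rate
    unbiased by the run constraint. Degenerate skills (0 or 1) yield a
    deterministic sequence for which the run constraint is vacuously
    skipped.
    """
    n = len(correct)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if skill in (0.0, 1.0):
        return (correct if skill == 1.0 else 1 - correct).astype(np.int64)
    k_base = int(math.floor(skill * n))
    frac = skill * n - k_base
    for _ in range(_MAX_DEMO_RESAMPLES):
        k = k_base + (1 if rng.random() < frac else 0)
        match = np.zeros(n, dtype=bool)
        match[rng.permutation(n)[:k]] = True
        demos = np.where(match, correct, 1 - correct).astype(np.int64)
        if _max_run(demos.tolist()) <= max_same_run:
            return demos
    raise RuntimeError(
        "could not satisfy the same-option demonstration run constraint "
        f"(<= {max_same_run}) after {_MAX_DEMO_RESAMPLES} resamples"
    )


# --------------------------------------------------------------------------
# schedule generation
# --------------------------------------------------------------------------

def make_schedule(config: TaskConfig, seed, subject_id: str = "s00") -> pd.DataFrame:
    """Generate one subject's trial schedule (choices and outcomes unfilled).

    Deterministic given (config, seed). Each exp1/exp2 block gets a fresh
    symbol pair; exp3 uses one restless pair throughout, with the winning
    probabilities of both symbols following independent reflected random
    walks.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    context_id = 0
    ro, rp = config.obs_to_private_ratio
    n_obs_block = config.trials_per_block * ro // (ro + rp)
    n_priv_block = config.trials_per_block - n_obs_block

    if config.experiment_style == "exp3":
        n_total = config.n_trials()
        walk = config.walk or WalkConfig()
        p_a = make_random_walk(walk, n_total, rng.integers(2**31))
        p_b = make_random_walk(walk, n_total, rng.integers(2**31))
    else:
        p_a = p_b = None

    t_global = 0
    for session in range(config.n_sessions):
        layout = list(config.session_layout)
        rng.shuffle(layout)
        for block, condition in enumerate(layout):
            if config.experiment_style == "exp3":
                ctx = 0  # single restless pair
            else:
                ctx = context_id
                context_id += 1
                # which physical option is the better one is randomised
                a_is_correct = bool(rng.integers(2))
            if condition == "P":
                types = ["private"] * config.trials_per_block
            else:
                types = _block_trial_types(n_obs_block, n_priv_block, config.max_obs_run, rng)
            obs_idx = [i for i, tt in enumerate(types) if tt == "observational"]

            if condition != "P":
                if config.experiment_style == "exp3":
                    correct = np.array(
                        [0 if p_a[t_global + i] >= p_b[t_global + i] else 1 for i in obs_idx],
                        dtype=np.int64,
                    )
                else:
                    correct = np.full(len(obs_idx), 0 if a_is_correct else 1, dtype=np.int64)
                skill = config.demonstrators[condition].skill
                demos = _sample_demonstrations(
                    correct, skill, config.max_same_option_run, rng
                )
            else:
                demos = np.empty(0, dtype=np.int64)

            demo_iter = iter(demos)
            for i, tt in enumerate(types):
                if config.experiment_style == "exp3":
                    pa, pb = float(p_a[t_global + i]), float(p_b[t_global + i])
                else:
                    pa = config.p_correct if a_is_correct else 1.0 - config.p_correct
                    pb = 1.0 - pa
                d = next(demo_iter) if tt == "observational" else None
                rows.append(
                    {
                        "subject_id": subject_id,
                        "session": session,
                        "block": block,
                        "trial_index": i,
                        "condition": condition,
                        "context_id": ctx,
                        "trial_type": tt,
                        "option_a": f"ctx{ctx}_a",
                        "option_b": f"ctx{ctx}_b",
                        "p_win_a": pa,
                        "p_win_b": pb,
                        "demonstration": (None if d is None else f"ctx{ctx}_{'ab'[d]}"),
                        "choice": None,
                        "outcome": None,
                    }
                )
            t_global += config.trials_per_block
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_cohort(
    config: TaskConfig, n_subjects: int, seed, subject_prefix: str = "s"
) -> pd.DataFrame:
    """Schedules for a cohort; each subject gets an independent child seed."""
    seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    frames = [
        make_schedule(config, s, subject_id=f"{subject_prefix}{i:03d}")
        for i, s in enumerate(seeds)
    ]
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

@dataclass
class ScheduleReport:
    """Per-constraint pass/fail report for a trial schedule."""

    checks: dict[str, bool]
    messages: list[str]

    @property
    def ok(self) -> bool:
        return all(self.checks.values())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"ScheduleReport(ok={self.ok})"]
        lines += [f"  [{'ok' if v else 'FAIL'}] {k}" for k, v in self.checks.items()]
        lines += [f"  - {m}" for m in self.messages]
        return "\n".join(lines)


def validate_schedule(
    schedule: pd.DataFrame,
    obs_to_private_ratio: tuple[int, int] = (1, 1),
    max_obs_run: int = 7,
    max_same_option_run: int = 3,
) -> ScheduleReport:
    """Check ratio, run-length and schema constraints; pure function.

    Malformed records are reported, never raised. P-condition blocks are
    exempt from the observational:private ratio check.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    checks = {"schema": True, "ratio": True, "obs_run_length": True, "same_option_run": True}
    messages: list[str] = []
    ro, rp = obs_to_private_ratio
    for key, block in schedule.groupby(["subject_id", "session", "block"], sort=True):
        types = block["trial_type"].tolist()
        demos = block.loc[block["trial_type"] == "observational", "demonstration"]
        if demos.isna().any():
            checks["schema"] = False
            messages.append(f"block {key}: observational trial missing demonstration")
        n_obs = types.count("observational")
        n_priv = types.count("private")
        if (block["condition"] != "P").any() and n_obs * rp != n_priv * ro:
            checks["ratio"] = False
            messages.append(
                f"block {key}: {n_obs} observational vs {n_priv} private "
                f"violates the {ro}:{rp} ratio"
            )
        run = 0
        for tt in types:
            run = run + 1 if tt == "observational" else 0
            if run > max_obs_run:
                checks["obs_run_length"] = False
                messages.append(f"block {key}: observational run exceeds {max_obs_run}")
                break
        if _max_run(demos.dropna().tolist()) > max_same_option_run:
            checks["same_option_run"] = False
            messages.append(
                f"block {key}: more than {max_same_option_run} consecutive "
                "demonstrations of the same option"
            )
    return ScheduleReport(checks=checks, messages=messages)
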