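"""Model-free behavioral signatures of imitation.

These statistics diagnose *how* demonstrations influence choices without
fitting any model:

* correct choice rate — fraction of private choices taking the symbol with
  the higher instantaneous winning probability;
* behavioral imitation rate — fraction of private choices matching the
  demonstration at a given lag (lag 1 = most recent demonstration in the
  block, lag 2 = the one before it);
* accumulation — imitation rate toward d_{t-1} minus toward d_{t-2},
  restricted to private choices immediately preceded by two consecutive
  demonstrations: a learner influenced only by the last demonstration shows
  a positive differential, one that accumulates them shows ~0;
* propagation — match rate of c_{t+1} with d_t minus that of c_{t+2} with
  d_t, over demonstrations followed by two consecutive private choices: a
  transient (decision-biasing) influence shows a positive differential, a
  value-based one persists (~0).

Eligibility windows never cross block boundaries (the symbol pair changes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelSpec, ParameterSet

__all__ = [
    "correct_choice_rate",
    "imitation_rate",
    "accumulation",
    "propagation",
    "signature_table",
    "observed_vs_simulated",
]


def _blocks(df: pd.DataFrame):
    return df.groupby(["subject_id", "session", "block"], sort=True)


def correct_choice_rate(dataset: pd.DataFrame) -> float:
    """Fraction of private choices taking the reward-maximising symbol.

    Under restless contingencies "correct" is evaluated against the
    instantaneous winning probabilities of the trial.
    """
    priv = dataset[(dataset["trial_type"] == "private") & dataset["choice"].notna()]
    if len(priv) == 0:
        raise ValueError("dataset has no private trials with recorded choices")
    best = np.where(priv["p_win_a"].to_numpy() >= priv["p_win_b"].to_numpy(),
                    priv["option_a"].to_numpy(), priv["option_b"].to_numpy())
    return float((priv["choice"].to_numpy() == best).mean())


def imitation_rate(dataset: pd.DataFrame, lag: int = 1, condition=None) -> float:
    """Fraction of private choices matching the lag-th preceding demonstration.

    The lag-th demonstration is counted over observational trials earlier in
    the same block (lag 1 = most recent). Private choices with fewer than
    ``lag`` preceding demonstrations are ineligible.
    """
    if lag not in (1, 2):
        raise ValueError("lag must be 1 or 2")
    if condition is not None:
        dataset = dataset[dataset["condition"] == condition]
    matches = []
    for _, block in _blocks(dataset):
        demos: list = []
        for row in block.itertuples(index=False):
            if row.trial_type == "observational":
                demos.append(row.demonstration)
            elif pd.notna(row.choice):
                if len(demos) >= lag:
                    matches.append(row.choice == demos[-lag])
    if not matches:
        raise ValueError(f"no eligible private choices at lag {lag}")
    return float(np.mean(matches))


def accumulation(dataset: pd.DataFrame) -> float:
    """Imitation-rate differential across the two demonstrations preceding a
    private choice (positive = only the last demonstration matters)."""
    m1, m2 = [], []
    for _, block in _blocks(dataset):
        rows = list(block.itertuples(index=False))
        for t in range(2, len(rows)):
            r, r1, r2 = rows[t], rows[t - 1], rows[t - 2]
            if (
                r.trial_type == "private" and pd.notna(r.choice)
                and r1.trial_type == "observational"
                and r2.trial_type == "observational"
            ):
                m1.append(r.choice == r1.demonstration)
                m2.append(r.choice == r2.demonstration)
    if not m1:
        raise ValueError("no private choices preceded by two consecutive demonstrations")
    return float(np.mean(m1) - np.mean(m2))


def propagation(dataset: pd.DataFrame) -> float:
    """Imitation-rate differential across the two private choices following a
    demonstration (positive = the influence decays after one choice)."""
    m1, m2 = [], []
    for _, block in _blocks(dataset):
        rows = list(block.itertuples(index=False))
        for t in range(len(rows) - 2):
            r, r1, r2 = rows[t], rows[t + 1], rows[t + 2]
            if (
                r.trial_type == "observational"
                and r1.trial_type == "private" and pd.notna(r1.choice)
                and r2.trial_type == "private" and pd.notna(r2.choice)
            ):
                m1.append(r1.choice == r.demonstration)
                m2.append(r2.choice == r.demonstration)
    if not m1:
        raise ValueError("no demonstrations followed by two consecutive private choices")
    return float(np.mean(m1) - np.mean(m2))


def signature_table(datasets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Signature summary per source ({'observed': df, 'VS2': sim_df, ...})."""
    rows = []
    for source, df in datasets.items():
        rows.append(
            {
                "source": source,
                "correct_choice_rate": correct_choice_rate(df),
                "imitation_rate_lag1": imitation_rate(df, 1),
                "imitation_rate_lag2": imitation_rate(df, 2),
                "accumulation": accumulation(df),
                "propagation": propagation(df),
            }
        )
    return pd.DataFrame(rows)


def observed_vs_simulated(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    fitted_params: dict[str, ParameterSet] | ParameterSet,
    n_sims: int = 20,
    seed=None,
) -> dict:
    """Correlate observed choice frequencies with model simulations.

    For each subject, ``n_sims`` replicates are simulated on the subject's
    own schedule with their fitted parameters; the per-trial mean simulated
    frequency of choosing option a is correlated with the observed choices
    across trials, and mean correct-choice rates are correlated across
    subjects. Returns Spearman correlations plus the regression slope and
    intercept of observed on simulated. Degenerate (constant) series yield
    NaN correlations with a flag.
    """
    from .agents import simulate_agent

    root = np.random.SeedSequence(seed)
    subjects = list(pd.unique(dataset["subject_id"]))
    obs_trials, sim_trials = [], []
    obs_subj, sim_subj = [], []
    for subj, sseq in zip(subjects, root.spawn(len(subjects))):
        df = dataset[dataset["subject_id"] == subj].reset_index(drop=True)
        params = fitted_params[subj] if isinstance(fitted_params, dict) else fitted_params
        schedule = df.copy()
        schedule["choice"] = None
        schedule["outcome"] = None
        priv = df["trial_type"] == "private"
        obs_choice_a = (df.loc[priv, "choice"] == df.loc[priv, "option_a"]).astype(float)
        sim_freq = np.zeros(int(priv.sum()))
        rates = []
        for k, child in enumerate(sseq.spawn(n_sims)):
            sim = simulate_agent(spec, params, schedule, child)
            sim_priv = sim.loc[priv]
            sim_freq += (sim_priv["choice"] == sim_priv["option_a"]).to_numpy(float)
            rates.append(correct_choice_rate(sim))
        sim_freq /= n_sims
        obs_trials.append(obs_choice_a.to_numpy())
        sim_trials.append(sim_freq)
        obs_subj.append(correct_choice_rate(df))
        sim_subj.append(float(np.mean(rates)))
    x = np.concatenate(sim_trials)
    y = np.concatenate(obs_trials)
    out: dict = {"degenerate": False}
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        out.update(degenerate=True, rho_trials=np.nan, slope=np.nan, intercept=np.nan)
    else:
        out["rho_trials"] = float(stats.spearmanr(x, y).statistic)
        slope, intercept = np.polyfit(x, y, 1)
        out["slope"], out["intercept"] = float(slope), float(intercept)
    if len(subjects) >= 3 and not np.allclose(sim_subj, sim_subj[0]):
        out["rho_subjects"] = float(stats.spearmanr(sim_subj, obs_subj).statistic)
    else:
        out["rho_subjects"] = np.nan
    return out
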