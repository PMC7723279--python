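"""Random-effects Bayesian model selection and the model-recovery harness.

Given per-subject log-evidence approximations (here: Akaike scores on the
log-evidence scale, ``-NLL - p``), random-effects selection treats the
generating model as a random variable across subjects with population
frequencies ``r ~ Dirichlet(alpha)``. A variational scheme alternates
subject-level responsibilities

    u_nk  proportional to  exp(l_nk + psi(alpha_k) - psi(sum alpha))

with the count update ``alpha_k = alpha0 + sum_n u_nk`` until convergence.
Reported quantities:

* expected model frequency  E[r_k] = alpha_k / sum(alpha) -- to be compared
  with the chance level 1/K;
* exceedance probability XP_k = P(r_k > r_j for all j != k), computed
  exactly via the Beta CDF when K = 2 and by Monte-Carlo Dirichlet sampling
  otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .fitting import FitOptions, fit_subject, sample_parameters
from .models import get_model
from .task import TaskConfig, make_schedule

__all__ = ["BMSResult", "rfx_bms", "RecoveryReport", "model_recovery"]


@dataclass
class BMSResult:
    """Posterior summary of random-effects model selection."""

    models: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance_probability: np.ndarray
    n_subjects: int
    n_iterations: int

    @property
    def chance_level(self) -> float:
        return 1.0 / len(self.models)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": list(self.models),
                "dirichlet_alpha": self.dirichlet_alpha,
                "expected_frequency": self.expected_frequency,
                "exceedance_probability": self.exceedance_probability,
                "chance_level": self.chance_level,
            }
        )


def _exceedance_mc(alpha: np.ndarray, n_samples: int, rng) -> np.ndarray:
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=len(alpha)) / n_samples


def rfx_bms(
    evidence,
    n_xp_samples: int = 1_000_000,
    seed=None,
    models: tuple[str, ...] | None = None,
    alpha0: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> BMSResult:
    """Random-effects model selection over a subjects x models evidence grid.

    ``evidence`` holds per-subject log-evidence approximations (larger =
    better); only within-subject differences matter. Uniform Dirichlet prior
    (alpha0 = 1 per model). The exceedance probability uses the exact
    two-model Beta-CDF expression when K = 2 and seeded Monte-Carlo
    otherwise.
    """
    if isinstance(evidence, pd.DataFrame):
        models = models or tuple(evidence.columns)
        L = evidence.to_numpy(dtype=float)
    else:
        L = np.asarray(evidence, dtype=float)
        models = models or tuple(f"M{i + 1}" for i in range(L.shape[1]))
    if L.ndim != 2 or L.shape[0] < 1 or L.shape[1] < 2:
        raise ValueError("evidence must be a (>=1 subjects) x (>=2 models) grid")
    if not np.isfinite(L).all():
        raise ValueError("evidence contains non-finite entries")
    n, K = L.shape
    L = L - L.max(axis=1, keepdims=True)  # per-subject shift; invariant
    alpha = np.full(K, float(alpha0))
    for it in range(1, max_iter + 1):
        w = L + special.digamma(alpha) - special.digamma(alpha.sum())
        w -= w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        delta = np.abs(alpha_new - alpha).max()
        alpha = alpha_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"rfx_bms did not converge in {max_iter} iterations (last delta {delta:.3g})"
        )
    freq = alpha / alpha.sum()
    if K == 2:
        # P(r1 > r2) = P(r1 > 1/2) with r1 ~ Beta(alpha1, alpha2)
        p1 = 1.0 - stats.beta.cdf(0.5, alpha[0], alpha[1])
        xp = np.array([p1, 1.0 - p1])
    else:
        rng = np.random.default_rng(seed)
        xp = _exceedance_mc(alpha, n_xp_samples, rng)
    return BMSResult(
        models=tuple(models),
        dirichlet_alpha=alpha,
        expected_frequency=freq,
        exceedance_probability=xp,
        n_subjects=n,
        n_iterations=it,
    )


@dataclass
class RecoveryReport:
    """Generating x fitted model grids of frequency and exceedance probability."""

    models: tuple[str, ...]
    frequency: pd.DataFrame          # rows: generating model, cols: fitted
    exceedance: pd.DataFrame
    n_subjects: int
    seed: int | None
    settings: dict

    def diagonal_exceedance(self) -> pd.Series:
        return pd.Series(np.diag(self.exceedance.to_numpy()), index=self.models)

    def is_diagonally_dominant(self) -> bool:
        xp = self.exceedance.to_numpy()
        return bool(all(np.argmax(xp[i]) == i for i in range(len(self.models))))


def model_recovery(
    model_space,
    design: TaskConfig,
    n_subjects: int = 20,
    seed=None,
    n_restarts: int = 10,
    objective: str = "nll",
    metric: str = "aic",
    params_sampler=None,
) -> RecoveryReport:
    """Simulate cohorts from each model, refit the whole space, run rfx-BMS.

    For each generating model: ``n_subjects`` agents with parameters drawn
    from the fitting priors play freshly generated schedules; every model in
    the space is fitted to each simulated subject; the per-subject scores
    (``metric``: "aic", "nll" -- as -NLL -- or "lpp") enter random-effects
    selection. Fully reproducible given ``seed``.
    """
    from .agents import simulate_agent

    specs = [get_model(m) for m in model_space]
    names = tuple(s.name for s in specs)
    if len(specs) < 2:
        raise ValueError("model recovery needs at least two models")
    if metric not in ("aic", "nll", "lpp"):
        raise ValueError("metric must be 'aic', 'nll' or 'lpp'")
    freq = np.zeros((len(specs), len(specs)))
    xp = np.zeros_like(freq)
    for g, gen_spec in enumerate(specs):
        gen_seq = np.random.SeedSequence(entropy=seed or 0, spawn_key=(g,))
        child = gen_seq.spawn(n_subjects)
        evidence = np.zeros((n_subjects, len(specs)))
        for i, sseq in enumerate(child):
            rng = np.random.default_rng(sseq)
            params = (params_sampler or sample_parameters)(gen_spec, rng)
            sched_seed = int(rng.integers(2**31))
            schedule = make_schedule(design, sched_seed, subject_id=f"{gen_spec.name}_{i:03d}")
            sim = simulate_agent(gen_spec, params, schedule, int(rng.integers(2**31)))
            fit_seed = int(rng.integers(2**31))
            for j, fit_spec in enumerate(specs):
                res = fit_subject(
                    fit_spec, sim,
                    FitOptions(objective=objective, n_restarts=n_restarts, seed=fit_seed),
                )
                evidence[i, j] = {"aic": res.aic, "nll": -res.nll, "lpp": res.lpp}[metric]
        bms = rfx_bms(evidence, seed=int(gen_seq.generate_state(1)[0] % 2**31), models=names)
        freq[g] = bms.expected_frequency
        xp[g] = bms.exceedance_probability
    idx = pd.Index(names, name="generating")
    cols = pd.Index(names, name="fitted")
    return RecoveryReport(
        models=names,
        frequency=pd.DataFrame(freq, index=idx, columns=cols),
        exceedance=pd.DataFrame(xp, index=idx, columns=cols),
        n_subjects=n_subjects,
        seed=seed,
        settings={
            "n_restarts": n_restarts,
            "objective": objective,
            "metric": metric,
            "design": design.experiment_style,
        },
    )
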