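"""Per-subject model fitting: likelihood, priors, optimisation, results.

Two objectives are supported, mirroring standard practice in trial-by-trial
model fitting of choice data:

* maximum likelihood -- minimise NLL = -log P(data | parameters, model), from
  which the model-comparison score is derived on the log-evidence scale as

      AIC = -NLL - p          (p = number of free parameters)

  Note this is the log-evidence-scale convention (larger is better), which
  differs from the textbook ``2*NLL + 2p`` by a factor of -2. It is used as
  the per-subject log-evidence approximation fed to random-effects model
  selection (:func:`socialrl.bms.rfx_bms`).

* maximum a posteriori -- maximise the log posterior probability
  LPP = log P(parameters | data, model) up to a constant, with weakly
  informative priors: Gamma(shape 1.2, scale 5) on the inverse temperature,
  Beta(1.1, 1.1) on every learning rate, and a flat prior on the
  autocorrelation weight kappa over its bound [-10, 10].

Optimisation uses bounded L-BFGS-B with multiple restarts whose starting
points are drawn from the priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._kernel import EncodedDataset, dataset_nll, encode_dataset
from .models import ModelSpec, ParameterSet, get_model

__all__ = [
    "PriorSpec",
    "DEFAULT_PRIORS",
    "FitOptions",
    "FitResult",
    "aic",
    "log_prior",
    "sample_parameters",
    "fit_subject",
    "fit_cohort",
    "SocialLearningModel",
    "SocialLearningResults",
]

KAPPA_BOUND = 10.0
BETA_MAX = 50.0
_EPS = 1e-4


@dataclass(frozen=True)
class PriorSpec:
    """Parameter priors used for LPP fitting and for drawing restart points.

    ``kappa_sd`` only shapes *sampled* kappa values (simulation cohorts and
    optimiser restarts); the LPP prior on kappa is flat and contributes 0.
    """

    beta_shape: float = 1.2
    beta_scale: float = 5.0
    rate_a: float = 1.1
    rate_b: float = 1.1
    kappa_sd: float = 1.0

    def beta_dist(self):
        return stats.gamma(a=self.beta_shape, scale=self.beta_scale)

    def rate_dist(self):
        return stats.beta(self.rate_a, self.rate_b)


DEFAULT_PRIORS = PriorSpec()


def aic(nll: float, p: int) -> float:
    """Log-evidence-scale Akaike score, -NLL - p (larger is better)."""
    if p < 0:
        raise ValueError("number of free parameters must be nonnegative")
    return -float(nll) - int(p)


def _beta_logpdf(x: float, a: float, b: float) -> float:
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - special.betaln(a, b)


def _gamma_logpdf(x: float, shape: float, scale: float) -> float:
    return ((shape - 1.0) * np.log(x) - x / scale
            - shape * np.log(scale) - special.gammaln(shape))


def log_prior(params: ParameterSet, spec: ModelSpec, priors: PriorSpec = DEFAULT_PRIORS) -> float:
    """Sum of log prior densities over the model's free parameters.

    Learning rates get Beta(1.1, 1.1), beta gets Gamma(1.2, scale 5), kappa
    is flat (contributes 0). Raises for out-of-bounds parameters.
    """
    lp = 0.0
    for name in spec.free_parameters:
        value = getattr(params, name)
        if name == "beta":
            if value <= 0:
                raise ValueError("beta must be positive")
            lp += _gamma_logpdf(value, priors.beta_shape, priors.beta_scale)
        elif name == "kappa":
            if abs(value) > KAPPA_BOUND:
                raise ValueError(f"kappa outside [-{KAPPA_BOUND}, {KAPPA_BOUND}]")
        elif name == "alpha_i" and spec.allow_negative_imitation:
            if not -1.0 < value < 1.0:
                raise ValueError("alpha_i must lie in (-1, 1)")
            # symmetric stretch of the Beta prior onto (-1, 1)
            lp += _beta_logpdf((value + 1.0) / 2.0, priors.rate_a, priors.rate_b) - np.log(2.0)
        else:
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
            lp += _beta_logpdf(value, priors.rate_a, priors.rate_b)
    return float(lp)


def _bounds(spec: ModelSpec) -> list[tuple[float, float]]:
    bounds = []
    for name in spec.free_parameters:
        if name == "beta":
            bounds.append((1e-3, BETA_MAX))
        elif name == "kappa":
            bounds.append((-KAPPA_BOUND, KAPPA_BOUND))
        elif name == "alpha_i" and spec.allow_negative_imitation:
            bounds.append((-1.0 + _EPS, 1.0 - _EPS))
        else:
            bounds.append((_EPS, 1.0 - _EPS))
    return bounds


def sample_parameters(spec: ModelSpec, rng, priors: PriorSpec = DEFAULT_PRIORS) -> ParameterSet:
    """Draw one parameter set from the priors (used for simulation cohorts
    and optimiser restarts); kappa ~ Normal(0, kappa_sd) truncated to its
    bound."""
    params = ParameterSet()
    for name, (lo, hi) in zip(spec.free_parameters, _bounds(spec)):
        if name == "beta":
            v = rng.gamma(priors.beta_shape, priors.beta_scale)
        elif name == "kappa":
            v = rng.normal(0.0, priors.kappa_sd)
        elif name == "alpha_i" and spec.allow_negative_imitation:
            v = 2.0 * rng.beta(priors.rate_a, priors.rate_b) - 1.0
        else:
            v = rng.beta(priors.rate_a, priors.rate_b)
        setattr(params, name, float(np.clip(v, lo, hi)))
    return params


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the per-subject optimisation."""

    objective: str = "nll"          # "nll" or "lpp"
    n_restarts: int = 10
    tolerance: float = 1e-6
    seed: int | None = None
    priors: PriorSpec = DEFAULT_PRIORS

    def __post_init__(self) -> None:
        if self.objective not in ("nll", "lpp"):
            raise ValueError("objective must be 'nll' or 'lpp'")
        if self.n_restarts < 1:
            raise ValueError("need at least one restart")


@dataclass
class FitResult:
    """Per-subject, per-model fit summary."""

    model_id: str
    params: ParameterSet
    nll: float
    lpp: float
    aic: float
    p: int
    n_trials_used: int
    converged: bool
    n_restarts: int
    subject_id: str | None = None

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "model": self.model_id,
            "nll": self.nll,
            "lpp": self.lpp,
            "aic": self.aic,
            "n_params": self.p,
            "n_trials": self.n_trials_used,
            "converged": self.converged,
            "n_restarts": self.n_restarts,
        }
        row.update(self.params.to_dict())
        return row


def fit_subject(
    spec: ModelSpec | str,
    dataset: pd.DataFrame | EncodedDataset,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Fit one model to one subject's trials by restarted bounded optimisation.

    Starting points are drawn from the priors (seeded via ``options.seed``);
    the best restart wins (ties broken by first). NLL and LPP are both
    reported at the optimum of the chosen objective; the Akaike score is
    derived from the reported NLL.
    """
    spec = get_model(spec)
    data = dataset if isinstance(dataset, EncodedDataset) else encode_dataset(dataset)
    if data.n_trials == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(options.seed)
    names = spec.free_parameters
    bounds = _bounds(spec)

    def to_params(x: np.ndarray) -> ParameterSet:
        params = ParameterSet()
        for name, v in zip(names, x):
            setattr(params, name, float(v))
        return params

    # direct kernel dispatch: avoids per-call ParameterSet construction
    from ._kernel import _nll_loop
    from .models import PARAM_NAMES

    base = ParameterSet().as_array()
    idx = np.array([PARAM_NAMES.index(n) for n in names])
    static = (
        spec.family_code, spec.variant, spec.symmetric_private, spec.use_kappa,
        spec.match_updates_last_action, spec.alpha_d_fixed, spec.alpha_d_value,
        spec.mb_bias == "blend",
    )
    arrays = (data.ctx, data.is_obs, data.dem, data.cho, data.out,
              data.new_block, data.n_contexts)
    want_lpp = options.objective == "lpp"

    def objective(x: np.ndarray) -> float:
        vec = base.copy()
        vec[idx] = x
        val = _nll_loop(*static, *vec, *arrays)
        if want_lpp:
            val -= log_prior(to_params(x), spec, options.priors)
        return val

    best = None
    n_ok = 0
    failures = []
    for _ in range(options.n_restarts):
        x0 = np.array(
            [getattr(sample_parameters(spec, rng, options.priors), n) for n in names]
        )
        x0 = np.clip(x0, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        try:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": options.tolerance, "maxiter": 500},
            )
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            failures.append(str(exc))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective")
            continue
        n_ok += 1
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {options.n_restarts} restarts failed for {spec.name}: {failures}"
        )
    params = to_params(best.x)
    nll = dataset_nll(spec, params, data)
    lpp = -nll + log_prior(params, spec, options.priors)
    return FitResult(
        model_id=spec.name,
        params=params,
        nll=float(nll),
        lpp=float(lpp),
        aic=aic(nll, len(names)),
        p=len(names),
        n_trials_used=data.n_private,
        converged=bool(best.success) and n_ok > 0,
        n_restarts=options.n_restarts,
    )


def fit_cohort(
    trials: pd.DataFrame,
    models,
    options: FitOptions = FitOptions(),
) -> pd.DataFrame:
    """Fit every model to every subject; one row per subject x model.

    ``trials`` is a multi-subject trial log; each subject gets an
    independent child seed derived from ``options.seed``.
    """
    specs = [get_model(m) for m in models]
    subjects = list(pd.unique(trials["subject_id"]))
    seeds = np.random.SeedSequence(options.seed).spawn(len(subjects))
    rows = []
    for subj, sseq in zip(subjects, seeds):
        data = encode_dataset(trials[trials["subject_id"] == subj])
        subj_seed = int(sseq.generate_state(1)[0] % (2**31))
        for spec in specs:
            res = fit_subject(spec, data, FitOptions(
                objective=options.objective, n_restarts=options.n_restarts,
                tolerance=options.tolerance, seed=subj_seed, priors=options.priors,
            ))
            res.subject_id = subj
            rows.append(res.to_row())
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# model/results objects
# --------------------------------------------------------------------------

class SocialLearningModel:
    """A learner model bound to one subject's trial data.

    Parameters
    ----------
    data : DataFrame
        Chronologically ordered trial log for a single subject (columns per
        :data:`socialrl.task.TRIAL_COLUMNS`).
    model : str or ModelSpec
        Registry identifier, e.g. ``"VS2"``.

    Examples
    --------
    >>> mod = SocialLearningModel(trials, "VS2")          # doctest: +SKIP
    >>> res = mod.fit(seed=0)                             # doctest: +SKIP
    >>> print(res.summary())                              # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, model: str | ModelSpec = "VS2", **flags):
        if data["subject_id"].nunique() > 1:
            raise ValueError(
                "SocialLearningModel holds one subject; use fit_cohort for many"
            )
        self.spec = get_model(model, **flags)
        self.data = data.reset_index(drop=True)
        self._encoded = encode_dataset(self.data)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, model="VS2", **flags):
        return cls(data, model, **flags)

    def nll(self, params: ParameterSet | dict) -> float:
        if not isinstance(params, ParameterSet):
            params = ParameterSet.from_mapping(params)
        return dataset_nll(self.spec, params, self._encoded)

    def loglike(self, params) -> float:
        return -self.nll(params)

    def fit(self, objective: str = "nll", n_restarts: int = 10,
            seed: int | None = None, tolerance: float = 1e-6) -> "SocialLearningResults":
        res = fit_subject(self.spec, self._encoded, FitOptions(
            objective=objective, n_restarts=n_restarts, seed=seed, tolerance=tolerance,
        ))
        res.subject_id = str(self.data["subject_id"].iloc[0])
        return SocialLearningResults(self, res)

    def simulate(self, params: ParameterSet, seed=None) -> pd.DataFrame:
        """Replay this subject's schedule with the model generating choices."""
        from .agents import simulate_agent

        schedule = self.data.copy()
        schedule["choice"] = None
        schedule["outcome"] = None
        return simulate_agent(self.spec, params, schedule, seed)


class SocialLearningResults:
    """Estimates and fit diagnostics for one subject x model."""

    def __init__(self, model: SocialLearningModel, fit: FitResult):
        self.model = model
        self._fit = fit

    @property
    def params(self) -> ParameterSet:
        return self._fit.params

    @property
    def nll(self) -> float:
        return self._fit.nll

    @property
    def lpp(self) -> float:
        return self._fit.lpp

    @property
    def aic(self) -> float:
        return self._fit.aic

    @property
    def converged(self) -> bool:
        return self._fit.converged

    def simulate(self, seed=None) -> pd.DataFrame:
        return self.model.simulate(self.params, seed)

    def summary(self) -> str:
        f = self._fit
        lines = [
            "Social learning model fit",
            "=" * 46,
            f"subject:          {f.subject_id}",
            f"model:            {f.model_id}",
            f"private trials:   {f.n_trials_used}",
            f"free parameters:  {f.p}",
            f"NLL:              {f.nll:.4f}",
            f"LPP:              {f.lpp:.4f}",
            f"AIC (-NLL - p):   {f.aic:.4f}",
            f"converged:        {f.converged} ({f.n_restarts} restarts)",
            "-" * 46,
        ]
        for name in self.model.spec.free_parameters:
            lines.append(f"  {name:<10} {getattr(f.params, name):>10.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<SocialLearningResults {self._fit.model_id} "
                f"NLL={self._fit.nll:.2f} AIC={self._fit.aic:.2f}>")
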