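"""Model space for social reinforcement learning.

Every model shares the same private learning core: a Rescorla-Wagner delta
rule on a two-option value function Q with learning rate ``alpha_p``, and a
softmax policy with inverse temperature ``beta`` and a choice-autocorrelation
(perseveration) weight ``kappa``,

    pi(c) = 1 / (1 + exp(beta * [Q(cbar) - Q(c) - lambda(c) * kappa])),

where lambda(c) is +1 if c was the last performed action and -1 otherwise
(0 when no action has been performed yet).

The families differ only in what a demonstration d does:

* ``RW``   -- nothing; demonstrations are ignored (baseline).
  RW1 updates the chosen option only; RW2 additionally updates the unchosen
  option toward the reflected outcome (symmetric value update).
* ``DB``   -- decision biasing: d transiently biases action selection without
  touching Q. DB1 biases the policy directly (policy update), DB2/DB3 bias a
  disposable copy Q' of Q (value / symmetric value update). DB4-DB6 are the
  same three rules but the bias trace is *not* re-derived from Q on every
  demonstration, so consecutive demonstrations accumulate. All traces are
  discarded after a private choice and at block boundaries.
* ``MB``   -- model-based imitation: d updates a model of the Demonstrator
  (a policy pi_D for MB1-3, values Q_D for MB4-9) with learning rate
  ``alpha_d``; on private trials the model's preferred option biases action
  selection with weight ``alpha_i``. The 3x3 grid crosses the build rule
  (PU / VU / SVU for MB1-3 / MB4-6 / MB7-9) with the bias rule
  (PU / VU / SVU for MB{1,4,7} / MB{2,5,8} / MB{3,6,9}).
* ``VS``   -- value shaping: d is treated as a surrogate reward and directly
  reinforces Q(d) with imitation learning rate ``alpha_i`` (VS1); VS2 also
  pushes Q(dbar) toward -1 (symmetric value update).
* ``metaVS`` -- VS2 with a per-state imitation rate alpha_i(s), initialised
  at 0 and updated toward the agreement signal tau (1 iff the demonstrated
  option currently maximises the learner's Q) with meta learning rate
  ``alpha_m``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "PARAM_NAMES",
    "VARIANT_RANGES",
    "get_model",
    "list_models",
    "FINAL_MODEL_SPACE",
]

PARAM_NAMES = ("alpha_p", "alpha_i", "alpha_d", "alpha_m", "beta", "kappa")

VARIANT_RANGES = {"RW": (1, 2), "DB": (1, 6), "MB": (1, 9), "VS": (1, 2), "metaVS": (1, 1)}

#: the four best-in-family implementations retained for the main comparison
FINAL_MODEL_SPACE = ("RW2", "DB6", "MB9", "VS2")

# integer codes shared with the numba kernel
FAMILY_CODES = {"RW": 0, "DB": 1, "MB": 2, "VS": 3, "metaVS": 4}


@dataclass(frozen=True)
class ModelSpec:
    """Identifies one learner model: a family, a variant, and robustness flags.

    Parameters
    ----------
    family : str
        One of ``RW``, ``DB``, ``MB``, ``VS``, ``metaVS``.
    variant : int
        Implementation index within the family (RW 1-2, DB 1-6, MB 1-9,
        VS 1-2; metaVS has a single implementation).
    use_kappa : bool
        Include the choice-autocorrelation parameter kappa (robustness
        variant removes it).
    symmetric_private : bool
        Use the symmetric private value update (the winning baseline RW2
        convention). RW1 is the asymmetric baseline.
    allow_negative_imitation : bool
        Widen the alpha_i bound to (-1, 1) (robustness variant).
    alpha_d_fixed : bool
        Fix the Demonstrator-model learning rate at ``alpha_d_value``
        instead of fitting it (MB only; fixed is the better-fitting default).
    alpha_d_value : float
        Value used when ``alpha_d_fixed``.
    match_updates_last_action : bool
        On observational trials the learner physically presses the key
        matching the demonstration; when True that matching response counts
        as the "last performed action" for the autocorrelation term.
    mb_bias : str
        ``"argmax"`` (default): the Demonstrator model's preferred option is
        treated as a pseudo-demonstration on each private trial; ``"blend"``:
        the policy is mixed toward the Demonstrator policy with weight
        alpha_i.
    """

    family: str
    variant: int = 1
    use_kappa: bool = True
    symmetric_private: bool = True
    allow_negative_imitation: bool = False
    alpha_d_fixed: bool = True
    alpha_d_value: float = 0.1
    match_updates_last_action: bool = True
    mb_bias: str = "argmax"

    def __post_init__(self) -> None:
        if self.family not in VARIANT_RANGES:
            raise ValueError(f"unknown model family {self.family!r}")
        lo, hi = VARIANT_RANGES[self.family]
        if not lo <= self.variant <= hi:
            raise ValueError(
                f"{self.family} variant must be in [{lo}, {hi}], got {self.variant}"
            )
        if self.mb_bias not in ("argmax", "blend"):
            raise ValueError(f"mb_bias must be 'argmax' or 'blend', got {self.mb_bias!r}")

    @property
    def name(self) -> str:
        if self.family == "metaVS":
            return "metaVS"
        return f"{self.family}{self.variant}"

    @property
    def family_code(self) -> int:
        return FAMILY_CODES[self.family]

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Names of the free parameters of this model, in canonical order."""
        names = ["alpha_p"]
        if self.family in ("DB", "MB", "VS"):
            names.append("alpha_i")
        if self.family == "MB" and not self.alpha_d_fixed:
            names.append("alpha_d")
        if self.family == "metaVS":
            names.append("alpha_m")
        names.append("beta")
        if self.use_kappa:
            names.append("kappa")
        return tuple(names)

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_parameters)

    def replace(self, **changes) -> "ModelSpec":
        return dataclasses.replace(self, **changes)


def get_model(name: str | ModelSpec, **flags) -> ModelSpec:
    """Resolve a registry string like ``"DB6"`` or ``"metaVS"`` to a ModelSpec.

    RW1/RW2 fix ``symmetric_private`` to False/True respectively; every other
    family defaults to the symmetric private update (overridable via flags).
    """
    if isinstance(name, ModelSpec):
        return name.replace(**flags) if flags else name
    name = name.strip()
    if name == "metaVS":
        return ModelSpec(family="metaVS", variant=1, **flags)
    for family in ("RW", "DB", "MB", "VS"):
        if name.startswith(family) and name[len(family):].isdigit():
            variant = int(name[len(family):])
            if family == "RW":
                flags = {"symmetric_private": variant == 2, **flags}
            return ModelSpec(family=family, variant=variant, **flags)
    raise ValueError(f"unknown model identifier {name!r}")


def list_models() -> list[str]:
    """All registry identifiers, RW1 ... metaVS."""
    out = []
    for family, (lo, hi) in VARIANT_RANGES.items():
        if family == "metaVS":
            out.append("metaVS")
        else:
            out.extend(f"{family}{v}" for v in range(lo, hi + 1))
    return out


@dataclass
class ParameterSet:
    """All model parameters; a given ModelSpec uses a subset as free.

    alpha_p : private reward learning rate, in (0, 1)
    alpha_i : imitation learning rate (VS) / decision bias weight (DB, MB),
              in (0, 1), or (-1, 1) when negative imitation is allowed
    alpha_d : Demonstrator-model learning rate (MB), in (0, 1); fixed at 0.1
              by default
    alpha_m : meta learning rate for the per-state imitation rate (metaVS)
    beta    : softmax inverse temperature, in (0, +inf)
    kappa   : choice autocorrelation weight (positive = perseveration)
    """

    alpha_p: float = 0.3
    alpha_i: float = 0.0
    alpha_d: float = 0.1
    alpha_m: float = 0.0
    beta: float = 3.0
    kappa: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha_p, self.alpha_i, self.alpha_d, self.alpha_m, self.beta, self.kappa],
            dtype=np.float64,
        )

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    @classmethod
    def from_mapping(cls, mapping) -> "ParameterSet":
        return cls(**{k: float(v) for k, v in dict(mapping).items() if k in PARAM_NAMES})

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)
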