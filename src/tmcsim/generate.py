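"""Synthetic replication data for manipulation-check experiments.

One replication is a balanced two-group experiment of ``2 * n_per_group``
participants:

* ``x`` — effect-coded condition (+1 experimental, -1 control);
* ``t`` — latent attribute, a two-component normal mixture with group means
  ``±r_tx`` and within-group SD ``sqrt(1 - r_tx**2)`` (unit total variance);
* ``m`` — manipulation check, ``r_tm * t`` plus independent normal noise;
* ``y`` — outcome, ``w1*t + w2*m`` plus independent normal noise, with
  weights from :func:`tmcsim.conditions.solve_outcome_weights`.

All variables have population mean 0 and variance 1 by construction, so
downstream path coefficients are on the standardized scale.  Randomness is
fully reproducible: each replication derives independent child streams for
the latent, check, outcome and bootstrap draws from integer seed material.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .conditions import OutcomeWeights, SimulationCondition, solve_outcome_weights
from .errors import ConfigurationError, DomainError, FeasibilityError

__all__ = [
    "ReplicationData",
    "generate_design",
    "generate_latent",
    "generate_check",
    "generate_outcome",
    "generate_replication",
    "child_rng",
    "replication_frame",
]

# stream purposes hung off one replication's seed material
_PURPOSE = {"latent": 0, "check": 1, "outcome": 2, "bootstrap": 3}


@dataclass(frozen=True)
class ReplicationData:
    """One simulated dataset (x, t, m, y) plus its seed material."""

    x: np.ndarray
    t: np.ndarray
    m: np.ndarray
    y: np.ndarray
    seed_record: tuple[int, ...]

    @property
    def n(self) -> int:
        return self.x.size


def _as_seed_material(seed: int | Sequence[int]) -> tuple[int, ...]:
    if isinstance(seed, (int, np.integer)):
        material = (int(seed),)
    else:
        material = tuple(int(s) for s in seed)
    if len(material) == 0 or any(s < 0 for s in material):
        raise ConfigurationError(
            f"seed material must be non-negative integers, got {seed!r}"
        )
    return material


def child_rng(seed: int | Sequence[int], purpose: str) -> np.random.Generator:
    """Independent generator for one purpose within one replication.

    The stream is keyed by ``(*seed_material, purpose_code)`` through
    :class:`numpy.random.SeedSequence`, so the latent, check, outcome and
    bootstrap streams of a replication never overlap and do not depend on
    execution order.
    """
    material = _as_seed_material(seed)
    try:
        code = _PURPOSE[purpose]
    except KeyError:
        raise ConfigurationError(f"unknown stream purpose {purpose!r}") from None
    return np.random.default_rng(np.random.SeedSequence(material + (code,)))


def generate_design(n_per_group: int) -> np.ndarray:
    """Effect-coded condition vector: a -1 block then a +1 block."""
    if int(n_per_group) != n_per_group or n_per_group < 1:
        raise ConfigurationError(
            f"n_per_group must be a positive integer, got {n_per_group}"
        )
    n = int(n_per_group)
    return np.repeat([-1.0, 1.0], n)


def generate_latent(x: np.ndarray, r_tx: float, rng: np.random.Generator) -> np.ndarray:
    """Latent attribute: normal mixture with group means ±r_tx, unit variance.

    Equivalent form ``t = r_tx * x + sqrt(1 - r_tx**2) * z`` makes the
    population corr(T, X) equal r_tx exactly; at ``r_tx = 1`` the mixture
    degenerates and t coincides with x.
    """
    if not -1.0 <= r_tx <= 1.0:
        raise DomainError(f"r_tx must lie in [-1, 1], got {r_tx}")
    z = rng.standard_normal(x.size)
    return r_tx * x + math.sqrt(1.0 - r_tx * r_tx) * z


def generate_check(t: np.ndarray, r_tm: float, rng: np.random.Generator) -> np.ndarray:
    """Manipulation check: attenuated copy of t with unit total variance."""
    if not -1.0 <= r_tm <= 1.0:
        raise DomainError(f"r_tm must lie in [-1, 1], got {r_tm}")
    z = rng.standard_normal(t.size)
    return r_tm * t + math.sqrt(1.0 - r_tm * r_tm) * z


def generate_outcome(
    t: np.ndarray,
    m: np.ndarray,
    weights: OutcomeWeights,
    rng: np.random.Generator,
) -> np.ndarray:
    """Outcome ``y = w1*t + w2*m + residual_sd * z`` (unit total variance)."""
    if not weights.feasible:
        raise FeasibilityError(
            "outcome weights imply negative residual variance "
            f"(systematic variance {weights.systematic_variance:.4f} > 1)"
        )
    z = rng.standard_normal(t.size)
    return weights.w1 * t + weights.w2 * m + weights.residual_sd * z


def generate_replication(
    c: SimulationCondition, seed: int | Sequence[int]
) -> ReplicationData:
    """Generate one full (x, t, m, y) dataset for a feasible condition.

    ``seed`` is integer seed material, typically
    ``(study_seed, condition_index, replication_index)``; identical material
    reproduces the dataset bit for bit.
    """
    weights = solve_outcome_weights(c)
    if not weights.feasible:
        raise FeasibilityError(
            f"condition {c.params} cannot generate a unit-variance outcome"
        )
    material = _as_seed_material(seed)
    x = generate_design(c.n_per_group)
    t = generate_latent(x, c.r_tx, child_rng(material, "latent"))
    m = generate_check(t, c.r_tm, child_rng(material, "check"))
    y = generate_outcome(t, m, weights, child_rng(material, "outcome"))
    return ReplicationData(x=x, t=t, m=m, y=y, seed_record=material)


def replication_frame(data: ReplicationData) -> pd.DataFrame:
    """One row per participant with columns x, t, m, y (for external checks)."""
    return pd.DataFrame({"x": data.x, "t": data.t, "m": data.m, "y": data.y})
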