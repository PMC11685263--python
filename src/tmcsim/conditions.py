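"""Factorial simulation grid, outcome-construction weights, and feasibility.

A simulated experiment manipulates a latent psychological attribute T through
a two-level condition X (effect coded +/-1) and measures it with a
manipulation check M.  Each cell of the study is described by four population
correlations:

* ``r_tx`` — manipulation intensity, corr(T, X);
* ``r_tm`` — reliability of the manipulation check, corr(T, M);
* ``r_my`` — target correlation between the check and the outcome Y;
* ``r_ty`` — the true effect, corr(T, Y).

The outcome is built as ``Y = w1*T + w2*M + residual_sd*eps`` with weights
chosen so that the population correlations of Y with T and M hit their
targets exactly while Y keeps unit variance.  Not every cell admits such a
construction: when the systematic variance ``w' Sigma w`` exceeds one, the
residual variance would have to be negative and the cell is infeasible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CollinearityError, ConfigurationError, DomainError

__all__ = [
    "SimulationCondition",
    "OutcomeWeights",
    "DEFAULT_LEVELS",
    "PAPER_EXCLUDED",
    "build_grid",
    "solve_outcome_weights",
    "implied_correlation_matrix",
    "is_feasible",
    "grid_table",
]

#: Factor levels of the canonical 4 x 3 x 3 x 2 study grid.
DEFAULT_LEVELS = {
    "r_tx": (0.5, 0.7, 0.95, 1.0),
    "r_tm": (0.5, 0.7, 0.95),
    "r_my": (0.0, 0.3, 0.5),
    "r_ty": (0.3, 0.5),
}

#: The four cells excluded in the original report, for strict replication.
#: Note this list is *not* derivable from the weight construction alone: it
#: keeps two r_tx=0.95 cells that the derived rule admits and admits two
#: lower-intensity cells that the derived rule rejects (see is_feasible).
PAPER_EXCLUDED = (
    (0.95, 0.5, 0.0, 0.5),
    (0.95, 0.7, 0.0, 0.5),
    (0.95, 0.95, 0.0, 0.5),
    (1.0, 0.95, 0.0, 0.5),
)

_EPS = 1e-12  # tolerance on residual variance at exact-zero boundaries


def _check_corr(name: str, value: float) -> float:
    value = float(value)
    if not -1.0 <= value <= 1.0:
        raise DomainError(f"{name} must lie in [-1, 1], got {value}")
    return value


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the factorial grid plus the per-group sample size."""

    r_tx: float
    r_tm: float
    r_my: float
    r_ty: float
    n_per_group: int = 50

    def __post_init__(self) -> None:
        for name in ("r_tx", "r_tm", "r_my", "r_ty"):
            object.__setattr__(self, name, _check_corr(name, getattr(self, name)))
        if int(self.n_per_group) != self.n_per_group or self.n_per_group < 2:
            raise ConfigurationError(
                f"n_per_group must be an integer >= 2, got {self.n_per_group}"
            )
        object.__setattr__(self, "n_per_group", int(self.n_per_group))

    @property
    def params(self) -> tuple[float, float, float, float]:
        """The (r_tx, r_tm, r_my, r_ty) tuple identifying the cell."""
        return (self.r_tx, self.r_tm, self.r_my, self.r_ty)

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_group


@dataclass(frozen=True)
class OutcomeWeights:
    """Loadings of Y on (T, M) and the residual noise scale.

    ``systematic_variance`` is the variance of ``w1*T + w2*M``; the residual
    variance ``1 - systematic_variance`` must be nonnegative for the
    construction to exist.  ``residual_sd`` is clipped at zero so that
    boundary cells (residual variance exactly 0) remain generable.
    """

    w1: float
    w2: float
    systematic_variance: float

    @property
    def residual_variance(self) -> float:
        return 1.0 - self.systematic_variance

    @property
    def residual_sd(self) -> float:
        return math.sqrt(max(0.0, self.residual_variance))

    @property
    def feasible(self) -> bool:
        return self.residual_variance >= -_EPS


def solve_outcome_weights(c: SimulationCondition) -> OutcomeWeights:
    """Solve the 2x2 system fixing corr(T, Y) = r_ty and corr(M, Y) = r_my.

    With standardized T and M and corr(T, M) = r_tm, the loadings satisfy::

        w1 + w2 * r_tm = r_ty
        w1 * r_tm + w2 = r_my

    Raises :class:`CollinearityError` when ``|r_tm| = 1`` (singular system).
    """
    det = 1.0 - c.r_tm**2
    if det == 0.0:
        raise CollinearityError(
            "outcome weights are undefined when |corr(T, M)| = 1"
        )
    w1 = (c.r_ty - c.r_tm * c.r_my) / det
    w2 = (c.r_my - c.r_tm * c.r_ty) / det
    systematic = w1 * w1 + w2 * w2 + 2.0 * w1 * w2 * c.r_tm
    return OutcomeWeights(w1=w1, w2=w2, systematic_variance=systematic)


def implied_correlation_matrix(c: SimulationCondition) -> np.ndarray:
    """Population correlation matrix of (X, T, M, Y) implied by the generator.

    Off-diagonal entries follow from the chained construction:
    corr(X, M) = r_tx * r_tm and corr(X, Y) = r_tx * r_ty.
    """
    # row/col order: X, T, M, Y
    return np.array(
        [
            [1.0, c.r_tx, c.r_tx * c.r_tm, c.r_tx * c.r_ty],
            [c.r_tx, 1.0, c.r_tm, c.r_ty],
            [c.r_tx * c.r_tm, c.r_tm, 1.0, c.r_my],
            [c.r_tx * c.r_ty, c.r_ty, c.r_my, 1.0],
        ]
    )


def is_feasible(c: SimulationCondition, mode: str = "derived") -> bool:
    """Decide whether a grid cell can generate a unit-variance outcome.

    mode="derived"
        True iff the outcome-weight residual variance is >= -1e-12 *and* the
        implied 4x4 correlation matrix of (X, T, M, Y) is positive
        semi-definite.  This rule depends only on (r_tm, r_my, r_ty).
    mode="paper_list"
        True iff the cell is not one of the four tuples in
        :data:`PAPER_EXCLUDED` (strict replication of the original report).
    """
    if mode == "derived":
        if not solve_outcome_weights(c).feasible:
            return False
        eigmin = float(np.linalg.eigvalsh(implied_correlation_matrix(c))[0])
        return eigmin >= -1e-10
    if mode == "paper_list":
        return not any(
            all(math.isclose(a, b, abs_tol=1e-9) for a, b in zip(c.params, row))
            for row in PAPER_EXCLUDED
        )
    raise ConfigurationError(f"unknown feasibility mode {mode!r}")


def build_grid(
    levels_r_tx: Sequence[float] = DEFAULT_LEVELS["r_tx"],
    levels_r_tm: Sequence[float] = DEFAULT_LEVELS["r_tm"],
    levels_r_my: Sequence[float] = DEFAULT_LEVELS["r_my"],
    levels_r_ty: Sequence[float] = DEFAULT_LEVELS["r_ty"],
    n_per_group: int = 50,
) -> list[SimulationCondition]:
    """Cross the four factor lists into an ordered list of conditions.

    The order is the lexicographic cross-product in (r_tx, r_tm, r_my, r_ty),
    which fixes a stable condition index used for seeding.
    """
    for name, levels in (
        ("levels_r_tx", levels_r_tx),
        ("levels_r_tm", levels_r_tm),
        ("levels_r_my", levels_r_my),
        ("levels_r_ty", levels_r_ty),
    ):
        if len(levels) == 0:
            raise ConfigurationError(f"{name} must not be empty")
    return [
        SimulationCondition(rtx, rtm, rmy, rty, n_per_group=n_per_group)
        for rtx, rtm, rmy, rty in itertools.product(
            levels_r_tx, levels_r_tm, levels_r_my, levels_r_ty
        )
    ]


def grid_table(
    conditions: Iterable[SimulationCondition] | None = None,
    mode: str = "derived",
) -> pd.DataFrame:
    """Tabulate a grid with feasibility flags and outcome weights.

    Returns one row per condition with columns
    ``r_tx, r_tm, r_my, r_ty, feasible, w1, w2, residual_sd``; the residual
    SD is NaN for infeasible cells.
    """
    if conditions is None:
        conditions = build_grid()
    rows = []
    for c in conditions:
        w = solve_outcome_weights(c)
        ok = is_feasible(c, mode=mode)
        rows.append(
            {
                "r_tx": c.r_tx,
                "r_tm": c.r_tm,
                "r_my": c.r_my,
                "r_ty": c.r_ty,
                "feasible": ok,
                "w1": w.w1,
                "w2": w.w2,
                "residual_sd": w.residual_sd if w.feasible else math.nan,
            }
        )
    return pd.DataFrame(rows)
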