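"""Closed-form population quantities for the manipulation-check mediation model.

Because every variable is standardized, the population mediation paths are
simple functions of the three observable correlations among (X, M, Y):

    a  = r_xm                      (slope of M on X)
    c  = r_xy                      (total effect of X on Y)
    b  = (r_my - r_xy r_xm) / (1 - r_xm^2)
    c' = (r_xy - r_my r_xm) / (1 - r_xm^2)
    ab = a b,    VIF = 1 / (1 - r_xm^2)

and the observables themselves follow from the latent design:
r_xm = r_tx r_tm, r_xy = r_tx r_ty.  These formulas serve two roles: the
analytic oracle against which the Monte Carlo machinery is validated, and a
design-advisory "what-if" report for researchers deciding whether a
manipulation-check mediation test can be informative for their study before
collecting data.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .conditions import SimulationCondition, is_feasible, solve_outcome_weights
from .errors import CollinearityError, DomainError, FeasibilityError

__all__ = [
    "ObservableCorrelations",
    "PopulationPaths",
    "implied_observables",
    "population_paths",
    "r_to_d",
    "d_to_r",
    "classify_mediation",
    "whatif_report",
]


@dataclass(frozen=True)
class ObservableCorrelations:
    """Population correlations among the three observed variables X, M, Y."""

    r_xm: float
    r_xy: float
    r_my: float

    def __post_init__(self) -> None:
        for name in ("r_xm", "r_xy", "r_my"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [-1, 1], got {v}")
        if float(np.linalg.eigvalsh(self.matrix())[0]) < -1e-10:
            raise DomainError(
                "correlations are jointly impossible (matrix not PSD): "
                f"({self.r_xm}, {self.r_xy}, {self.r_my})"
            )

    def matrix(self) -> np.ndarray:
        """3x3 correlation matrix in (X, M, Y) order."""
        return np.array(
            [
                [1.0, self.r_xm, self.r_xy],
                [self.r_xm, 1.0, self.r_my],
                [self.r_xy, self.r_my, 1.0],
            ]
        )


@dataclass(frozen=True)
class PopulationPaths:
    """Standardized population path coefficients and the population VIF."""

    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    vif: float


def implied_observables(c: SimulationCondition) -> ObservableCorrelations:
    """Observable correlations implied by a (feasible) latent design.

    X relates to M and Y only through T, so the latent correlations
    multiply: r_xm = r_tx * r_tm and r_xy = r_tx * r_ty; r_my is set
    directly by the outcome construction.
    """
    if not is_feasible(c, mode="derived"):
        raise FeasibilityError(
            f"condition {c.params} cannot generate a unit-variance outcome"
        )
    return ObservableCorrelations(
        r_xm=c.r_tx * c.r_tm, r_xy=c.r_tx * c.r_ty, r_my=c.r_my
    )


def population_paths(o: ObservableCorrelations) -> PopulationPaths:
    """Exact population mediation paths from the observable correlations."""
    det = 1.0 - o.r_xm**2
    if det == 0.0:
        raise CollinearityError("population paths undefined when |r_xm| = 1")
    a = o.r_xm
    c = o.r_xy
    b = (o.r_my - o.r_xy * o.r_xm) / det
    c_prime = (o.r_xy - o.r_my * o.r_xm) / det
    return PopulationPaths(a=a, b=b, c=c, c_prime=c_prime, ab=a * b, vif=1.0 / det)


def r_to_d(r: float) -> float:
    """Convert a point-biserial correlation to a standardized mean difference.

    Uses d = 2r / sqrt(1 - r^2), the balanced-groups conversion; e.g. a
    manipulation intensity of r = 0.95 corresponds to d ≈ 6.085.
    """
    if not -1.0 < r < 1.0:
        raise DomainError(f"|r| must be < 1, got {r}")
    return 2.0 * r / math.sqrt(1.0 - r * r)


def d_to_r(d: float) -> float:
    """Inverse conversion: r = d / sqrt(d^2 + 4)."""
    return d / math.sqrt(d * d + 4.0)


def classify_mediation(p: PopulationPaths, tol: float = 1e-10) -> str:
    """Label the population mediation structure.

    * ``"null"`` — no indirect effect (|ab| below tolerance);
    * ``"inconsistent"`` — the indirect effect opposes the total effect
      (suppression: ab and c have opposite signs, or ab*c < 0), so a
      significant ab does not support the intended causal account;
    * ``"consistent"`` — indirect and total effects share their sign.
    """
    if abs(p.ab) < tol:
        return "null"
    if p.ab * p.c < 0.0 or math.copysign(1.0, p.ab) != math.copysign(1.0, p.c):
        return "inconsistent"
    return "consistent"


def whatif_report(c: SimulationCondition) -> dict:
    """Design-advisory summary for one study configuration.

    Reports the observable correlations a researcher would see, the exact
    population paths with their VIF, the manipulation intensity on the d
    scale, and the mediation class — the pre-study check recommended before
    entering a manipulation check as a mediator.
    """
    obs = implied_observables(c)
    paths = population_paths(obs)
    weights = solve_outcome_weights(c)
    d = math.inf if c.r_tx >= 1.0 else r_to_d(c.r_tx)
    return {
        "condition": {
            "r_tx": c.r_tx,
            "r_tm": c.r_tm,
            "r_my": c.r_my,
            "r_ty": c.r_ty,
            "n_per_group": c.n_per_group,
        },
        "implied_observables": asdict(obs),
        "population_paths": asdict(paths),
        "outcome_weights": {
            "w1": weights.w1,
            "w2": weights.w2,
            "residual_sd": weights.residual_sd,
        },
        "manipulation_intensity_d": d,
        "mediation_class": classify_mediation(paths),
    }
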