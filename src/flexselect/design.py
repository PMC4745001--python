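"""Core trial-design types shared across the package.

A two-stage multi-arm trial compares k experimental arms against a shared
control.  At an interim analysis, long-term (primary) responses are available
for ``n1`` patients per arm and short-term responses for ``N1 > n1`` patients
per arm; one experimental arm is selected and continues, together with the
control, until ``n2`` patients per retained arm have primary responses.  The
one-sided hypotheses H_i: theta_i <= 0 (long-term effect vs control) are
tested at familywise level ``alpha``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialDesign",
    "NuisanceParams",
    "EffectVector",
    "SelectionVariant",
    "InvalidDesignError",
    "EstimationError",
    "QuadratureError",
]


class InvalidDesignError(ValueError):
    """Raised when design/nuisance parameters violate a structural constraint."""


class EstimationError(ValueError):
    """Raised when nuisance estimation fails (e.g. degenerate data)."""


class QuadratureError(RuntimeError):
    """Raised when numerical integration fails to reach the requested tolerance."""


class SelectionVariant(str, enum.Enum):
    """Which interim statistic drives treatment selection.

    BREVE
        Primary-endpoint data only (the difference of first-cohort long-term
        means).  Calibrating against this rule gives the classical
        primary-endpoint-only critical value, which does not depend on the
        endpoint correlation.
    HAT
        Primary-endpoint estimate adjusted using short-term data, with the
        short-term treatment effects replaced by their interim estimates.
    TILDE
        The worst-case statistic: the primary-endpoint estimate adjusted with
        externally supplied (assumed known) short-term effects.  Selecting its
        argmax maximises the conditional type I error, so the critical value
        calibrated against it controls the FWER under *any* selection rule.
    """

    BREVE = "breve"
    HAT = "hat"
    TILDE = "tilde"

    @classmethod
    def parse(cls, value: "str | SelectionVariant") -> "SelectionVariant":
        if isinstance(value, cls):
            return value
        aliases = {
            "breve": cls.BREVE,
            "stallard-todd": cls.BREVE,
            "primary-only": cls.BREVE,
            "hat": cls.HAT,
            "stallard": cls.HAT,
            "adjusted": cls.HAT,
            "tilde": cls.TILDE,
            "flexible": cls.TILDE,
            "worst-case": cls.TILDE,
        }
        key = str(value).strip().lower()
        if key not in aliases:
            raise ValueError(f"unknown selection variant {value!r}")
        return aliases[key]


@dataclass(frozen=True)
class TrialDesign:
    """Structural constants of the two-stage selection trial.

    Parameters
    ----------
    k
        Number of experimental arms compared with the shared control.
    n1
        Patients per arm with long-term (primary) data at the interim look.
    N1
        Patients per arm with short-term data at the interim look (N1 > n1).
    n2
        Patients per retained arm (selected + control) at the final analysis.
    alpha
        One-sided familywise error level.
    null_margin
        The margin theta_0 of H_i: theta_i <= theta_0 (default 0).
    """

    k: int
    n1: int
    N1: int
    n2: int
    alpha: float = 0.025
    null_margin: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidDesignError(f"k must be >= 1, got {self.k}")
        if not (2 <= self.n1 < self.N1 <= self.n2):
            raise InvalidDesignError(
                f"need 2 <= n1 < N1 <= n2, got n1={self.n1}, N1={self.N1}, n2={self.n2}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise InvalidDesignError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class NuisanceParams:
    """Endpoint dispersion parameters of the bivariate-normal response model.

    Each patient contributes a pair (Y, W): the long-term (primary) response
    with standard deviation ``sigma`` and the short-term response with
    standard deviation ``sigma0``, correlated within patient with ``rho``.
    Responses from different patients are independent.
    """

    sigma: float
    sigma0: float
    rho: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.sigma0 <= 0:
            raise InvalidDesignError("standard deviations must be positive")
        if not -1.0 < self.rho < 1.0:
            raise InvalidDesignError(f"rho must be in (-1, 1), got {self.rho}")

    @property
    def scale_factor(self) -> float:
        """The regression slope rho * sigma / sigma0 of Y on W."""
        return self.rho * self.sigma / self.sigma0

    def check_compatible(self, design: TrialDesign) -> None:
        """Validate that the conditional variance of S_i given interim data is positive."""
        cv = (design.n2 - design.n1) - self.rho**2 * (design.N1 - design.n1)
        if cv <= 0:
            raise InvalidDesignError(
                "conditional variance of the final statistic given interim data "
                f"is nonpositive: (n2-n1) - rho^2 (N1-n1) = {cv:.6g}"
            )


@dataclass(frozen=True)
class EffectVector:
    """True treatment effects used for calibration scenarios and data generation.

    ``theta_long[i]`` is the long-term effect of arm i+1 vs control,
    ``theta_short[i]`` the short-term effect.  Control means are only needed
    when generating patient-level data.
    """

    theta_long: tuple[float, ...]
    theta_short: tuple[float, ...] = field(default=())
    mu_control_long: float = 0.0
    mu_control_short: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta_long", tuple(float(x) for x in np.atleast_1d(self.theta_long)))
        short = self.theta_short
        if short is None or len(short) == 0:
            short = (0.0,) * len(self.theta_long)
        object.__setattr__(self, "theta_short", tuple(float(x) for x in np.atleast_1d(short)))
        if len(self.theta_short) != len(self.theta_long):
            raise ValueError("theta_short must have the same length as theta_long")

    @property
    def k(self) -> int:
        return len(self.theta_long)

    @classmethod
    def null(cls, k: int) -> "EffectVector":
        return cls(theta_long=(0.0,) * k)
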