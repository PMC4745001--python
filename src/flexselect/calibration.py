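"""Critical-value calibration for the final analysis.

The final-stage hypothesis for the selected arm is rejected when the
standardised statistic S / sqrt(V2) exceeds a critical value c / sqrt(V2)
chosen so that, under the global null theta_1 = ... = theta_k = 0 and
selection by the calibration variant's argmax rule, the rejection
probability equals alpha.  Calibrating against the worst-case (tilde)
statistic yields the flexible design whose critical value is valid for any
selection rule based on the interim data; the hat and breve variants give
the critical values of designs that pre-specify selection by the adjusted
or the primary-endpoint-only estimate respectively.  The breve critical
value does not depend on the endpoint correlation rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .design import InvalidDesignError, NuisanceParams, SelectionVariant, TrialDesign
from .joint_model import JointSelectionModel, selected_stat_cdf, variant_moments

__all__ = [
    "CriticalValueResult",
    "critical_value",
    "error_rate_given_c",
    "CriticalValueTable",
]

#: standardised-scale bracket for the root search
_BRACKET = (1.0, 5.0)
#: tolerance on c / sqrt(V2)
_XTOL = 1e-10


@dataclass(frozen=True)
class CriticalValueResult:
    """A calibrated final-analysis critical value.

    ``c_raw`` is on the scale of the sum statistic S; ``c_standardised`` is
    c / sqrt(V2), the threshold for the usual z statistic.
    """

    c_raw: float
    c_standardised: float
    attained_alpha: float
    variant: SelectionVariant
    quadrature_tol: float = _XTOL

    @property
    def c_2dp(self) -> float:
        """Convenience rounding matching conventional 2-dp reporting."""
        return round(self.c_standardised, 2)


def _null_tail(c_std: float, model: JointSelectionModel, design: TrialDesign) -> float:
    theta0 = np.zeros(design.k)
    return 1.0 - selected_stat_cdf(c_std, model, design, theta0, standardized=True)


def critical_value(
    design: TrialDesign,
    nuisance: NuisanceParams,
    variant: SelectionVariant | str,
) -> CriticalValueResult:
    """Solve P(S_{T*} >= c) = alpha under the global null for the given variant.

    For ``k = 1`` there is no selection and the solution is the one-sided
    normal quantile.  Otherwise the root is bracketed on the standardised
    scale in [1, 5] and found by Brent's method.
    """
    variant = SelectionVariant.parse(variant)
    model = variant_moments(design, nuisance, variant)
    if design.k == 1:
        from scipy.stats import norm

        c_std = float(norm.ppf(1.0 - design.alpha))
        return CriticalValueResult(
            c_raw=c_std * np.sqrt(model.V2),
            c_standardised=c_std,
            attained_alpha=design.alpha,
            variant=variant,
        )

    lo, hi = _BRACKET
    f = lambda c: _null_tail(c, model, design) - design.alpha
    flo, fhi = f(lo), f(hi)
    if flo < 0 or fhi > 0:
        raise InvalidDesignError(
            f"critical value not bracketed in [{lo}, {hi}] "
            f"(tail at ends: {flo + design.alpha:.4g}, {fhi + design.alpha:.4g})"
        )
    c_std = float(brentq(f, lo, hi, xtol=_XTOL))
    attained = _null_tail(c_std, model, design)
    return CriticalValueResult(
        c_raw=c_std * np.sqrt(model.V2),
        c_standardised=c_std,
        attained_alpha=float(attained),
        variant=variant,
    )


def error_rate_given_c(
    design: TrialDesign,
    nuisance: NuisanceParams,
    c_standardised: float,
    actual_selection_variant: SelectionVariant | str,
) -> float:
    """Null rejection rate of threshold ``c_standardised`` under a selection rule.

    Evaluates 1 - P(S_{T*} <= c) at theta = 0 with T* the argmax of the
    ``actual_selection_variant`` statistics.  Using a critical value
    calibrated for breve or hat selection while the data-driven selection
    follows the worst-case (tilde) rule inflates this beyond alpha whenever
    rho > 0.
    """
    model = variant_moments(design, nuisance, actual_selection_variant)
    return _null_tail(float(c_standardised), model, design)


class CriticalValueTable:
    """Standardised critical values precomputed on a rho grid.

    The standardised critical value depends on the nuisance parameters only
    through rho (sigma cancels), so simulation loops that recalibrate per
    replicate from an estimated correlation can interpolate a monotone cubic
    through a grid instead of re-solving.  Values of ``|rho|`` outside the
    admissible range for the design are clipped just inside the boundary.
    """

    def __init__(
        self,
        design: TrialDesign,
        variant: SelectionVariant | str,
        step: float = 0.01,
    ) -> None:
        self.design = design
        self.variant = SelectionVariant.parse(variant)
        # admissible |rho| < 1 and positive conditional variance
        rho_max = 1.0
        n1, N1, n2 = design.n1, design.N1, design.n2
        if N1 > n1:
            rho_max = min(rho_max, np.sqrt((n2 - n1) / (N1 - n1)))
            if self.variant is SelectionVariant.HAT:
                # rho_e < 1 requires n2 (1 - rho^2 (N1-n1)/N1) > n1
                rho_max = min(rho_max, np.sqrt((1.0 - n1 / n2) * N1 / (N1 - n1)))
        self.rho_max = float(min(rho_max, 1.0)) - 1e-6
        grid = np.arange(0.0, self.rho_max + step, step)
        grid = np.clip(grid, 0.0, self.rho_max)
        vals = [
            critical_value(design, NuisanceParams(1.0, 1.0, r), self.variant).c_standardised
            for r in grid
        ]
        self._grid = grid
        self._values = np.asarray(vals)
        self._interp = PchipInterpolator(grid, self._values)

    def __call__(self, rho: float | np.ndarray) -> np.ndarray:
        r = np.clip(np.abs(np.asarray(rho, dtype=float)), 0.0, self.rho_max)
        return self._interp(r)
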