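r"""Interim selection statistics, nuisance estimation and the final test.

The three interim effect estimates for arm i vs control are

* breve: :math:`\breve\theta_i = \sum_{j\le n_1}(y_{ij}-y_{0j})/n_1`
  (primary endpoint data only),
* hat:   :math:`\hat\theta_i = \breve\theta_i - \frac{\rho\sigma}{\sigma_0}
  \bigl(\sum_{j\le n_1}(w_{ij}-w_{0j})/n_1 - \hat\theta_{k+i}\bigr)` with
  :math:`\hat\theta_{k+i} = \sum_{j\le N_1}(w_{ij}-w_{0j})/N_1`
  (short-term effects estimated from all interim data),
* tilde: :math:`\tilde\theta_i = \breve\theta_i + \frac{\rho\sigma}{\sigma_0}
  \sum_{j=n_1+1}^{N_1}(w_{ij}-w_{0j}-\theta_{k+i})/n_1`
  (short-term effects supplied externally; note the divisor n1).

Substituting the estimated short-term effects into the tilde formula
recovers the hat estimate exactly, since
:math:`\sum_{j>n_1}(d_j-\hat\theta_{k+i}) = -\sum_{j\le n_1}(d_j-\hat\theta_{k+i})`
for the within-pair differences :math:`d_j = w_{ij} - w_{0j}`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .design import EstimationError, SelectionVariant

__all__ = [
    "InterimData",
    "FinalData",
    "SelectionEstimates",
    "NuisanceEstimates",
    "FinalTestResult",
    "theta_breve",
    "theta_hat",
    "theta_tilde",
    "estimate_nuisance",
    "select_treatment",
    "final_test",
    "final_test_from_summary",
]


@dataclass(frozen=True)
class InterimData:
    """Patient-level interim data, arm 0 = control.

    ``w`` has shape (k+1, N1): short-term responses for every interim
    patient.  ``y`` has shape (k+1, n1): long-term responses for the first
    cohort (the only ones observed at the interim look).  ``y_late``
    optionally holds the long-term responses of the second cohort
    (shape (k+1, N1-n1)); they are unknown at the interim analysis but are
    used by end-of-trial analyses such as the combination test.
    """

    w: np.ndarray
    y: np.ndarray
    y_late: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "y", y)
        if w.ndim != 2 or y.ndim != 2:
            raise ValueError("w and y must be 2-d arrays (arms x patients)")
        if w.shape[0] != y.shape[0]:
            raise ValueError("w and y must cover the same arms")
        if w.shape[0] < 2:
            raise ValueError("need a control arm and at least one experimental arm")
        if y.shape[1] < 2 or w.shape[1] <= y.shape[1]:
            raise ValueError("require 2 <= n1 < N1")
        if not (np.isfinite(w).all() and np.isfinite(y).all()):
            raise ValueError("interim responses must be finite")
        if self.y_late is not None:
            yl = np.asarray(self.y_late, dtype=float)
            object.__setattr__(self, "y_late", yl)
            if yl.shape != (w.shape[0], w.shape[1] - y.shape[1]):
                raise ValueError("y_late must have shape (k+1, N1-n1)")

    @property
    def k(self) -> int:
        return self.w.shape[0] - 1

    @property
    def n1(self) -> int:
        return self.y.shape[1]

    @property
    def N1(self) -> int:
        return self.w.shape[1]


@dataclass(frozen=True)
class FinalData:
    """Long-term responses for the two retained arms at the final analysis."""

    y_control: np.ndarray
    y_selected: np.ndarray
    selected_arm: int

    def __post_init__(self) -> None:
        yc = np.asarray(self.y_control, dtype=float)
        ys = np.asarray(self.y_selected, dtype=float)
        object.__setattr__(self, "y_control", yc)
        object.__setattr__(self, "y_selected", ys)
        if yc.ndim != 1 or ys.ndim != 1 or yc.size != ys.size or yc.size < 2:
            raise ValueError("retained arms need equal numbers (>= 2) of responses")
        if self.selected_arm < 1:
            raise ValueError("selected_arm is 1-based over experimental arms")

    @property
    def n2(self) -> int:
        return self.y_control.size


@dataclass(frozen=True)
class NuisanceEstimates:
    """Interim estimates of (sigma, sigma0, rho) and the derived scale factor."""

    sigma_hat: float
    sigma0_hat: float
    rho_hat: float
    scale_factor: float


@dataclass(frozen=True)
class SelectionEstimates:
    """All interim selection statistics with full provenance."""

    theta_breve: tuple[float, ...]
    theta_hat: tuple[float, ...]
    theta_short_hat: tuple[float, ...]
    theta_tilde: tuple[float, ...] | None
    variant_used: SelectionVariant
    scale_factor: float
    assumed_theta_short: tuple[float, ...] | None = None
    selected_arm: int = 0

    def to_json(self, **extra) -> str:
        payload = {
            "theta_breve": list(self.theta_breve),
            "theta_hat": list(self.theta_hat),
            "theta_short_hat": list(self.theta_short_hat),
            "theta_tilde": None if self.theta_tilde is None else list(self.theta_tilde),
            "variant_used": self.variant_used.value,
            "scale_factor": self.scale_factor,
            "assumed_theta_short": None
            if self.assumed_theta_short is None
            else list(self.assumed_theta_short),
            "selected_arm": self.selected_arm,
        }
        payload.update(extra)
        return json.dumps(payload, indent=2)


def theta_breve(interim: InterimData) -> np.ndarray:
    """Primary-endpoint-only interim estimates (first-cohort mean differences)."""
    means = interim.y.mean(axis=1)
    return means[1:] - means[0]


def theta_hat(interim: InterimData, scale_factor: float) -> tuple[np.ndarray, np.ndarray]:
    """Adjusted interim estimates using estimated short-term effects.

    Returns ``(theta_hat, theta_short_hat)``.  The adjustment subtracts the
    (scaled) excess of the first-cohort short-term mean difference over the
    all-interim-patients estimate; it has mean zero, so the distribution of
    theta_hat does not depend on the true short-term effects.
    """
    if not np.isfinite(scale_factor):
        raise ValueError("scale_factor must be finite")
    w_first = interim.w[:, : interim.n1].mean(axis=1)
    w_all = interim.w.mean(axis=1)
    dw_first = w_first[1:] - w_first[0]
    th_short = w_all[1:] - w_all[0]
    return theta_breve(interim) - scale_factor * (dw_first - th_short), th_short


def theta_tilde(
    interim: InterimData, scale_factor: float, assumed_theta_short: np.ndarray
) -> np.ndarray:
    """Worst-case selection statistics for externally supplied short-term effects.

    The second-cohort short-term residuals (relative to control and the
    assumed effect) are scaled by rho*sigma/sigma0 and added to the breve
    estimate with divisor n1, matching the conditional mean of the final
    statistic given the interim data.
    """
    assumed = np.asarray(assumed_theta_short, dtype=float)
    if assumed.shape != (interim.k,):
        raise ValueError(
            f"assumed_theta_short must have length k={interim.k}, got shape {assumed.shape}"
        )
    if not np.isfinite(scale_factor):
        raise ValueError("scale_factor must be finite")
    w2 = interim.w[:, interim.n1 :]
    sums = w2.sum(axis=1)
    resid = sums[1:] - sums[0] - (interim.N1 - interim.n1) * assumed
    return theta_breve(interim) + scale_factor * resid / interim.n1


def estimate_nuisance(interim: InterimData, pooling: str = "pooled") -> NuisanceEstimates:
    """Estimate (sigma, sigma0, rho) from the interim data.

    ``pooling="pooled"`` (default) pools within-arm centred sums of squares
    and cross-products across all arms: sigma from the n1-cohort long-term
    responses, sigma0 from all N1 short-term responses, rho from the n1
    complete pairs.  ``pooling="per-arm"`` averages per-arm estimates
    instead.
    """
    n_arms = interim.k + 1
    yc = interim.y - interim.y.mean(axis=1, keepdims=True)
    w_first = interim.w[:, : interim.n1]
    wc_pair = w_first - w_first.mean(axis=1, keepdims=True)
    wc_all = interim.w - interim.w.mean(axis=1, keepdims=True)

    if pooling == "pooled":
        ssy = float((yc**2).sum())
        ssw = float((wc_all**2).sum())
        ssw_pair = float((wc_pair**2).sum())
        sxy = float((yc * wc_pair).sum())
        dof_y = n_arms * (interim.n1 - 1)
        dof_w = n_arms * (interim.N1 - 1)
        if ssy <= 0 or ssw <= 0 or ssw_pair <= 0:
            raise EstimationError("degenerate (zero-variance) interim data")
        sigma_hat = np.sqrt(ssy / dof_y)
        sigma0_hat = np.sqrt(ssw / dof_w)
        rho_hat = sxy / np.sqrt(ssy * ssw_pair)
    elif pooling == "per-arm":
        vy = (yc**2).sum(axis=1) / (interim.n1 - 1)
        vw = (wc_all**2).sum(axis=1) / (interim.N1 - 1)
        ss_pair = (wc_pair**2).sum(axis=1)
        ssy_arm = (yc**2).sum(axis=1)
        if np.any(vy <= 0) or np.any(vw <= 0) or np.any(ss_pair <= 0):
            raise EstimationError("degenerate (zero-variance) interim data")
        sigma_hat = float(np.sqrt(vy.mean()))
        sigma0_hat = float(np.sqrt(vw.mean()))
        rho_hat = float(((yc * wc_pair).sum(axis=1) / np.sqrt(ssy_arm * ss_pair)).mean())
    else:
        raise ValueError(f"unknown pooling scheme {pooling!r}")

    rho_hat = float(np.clip(rho_hat, -1.0, 1.0))
    return NuisanceEstimates(
        sigma_hat=float(sigma_hat),
        sigma0_hat=float(sigma0_hat),
        rho_hat=rho_hat,
        scale_factor=float(rho_hat * sigma_hat / sigma0_hat),
    )


def select_treatment(stats: np.ndarray, rule: SelectionVariant | str | None = None) -> int:
    """1-based index of the arm with the largest selection statistic.

    Ties are broken by the lowest index (a probability-zero event under the
    continuous response model).  ``rule`` is accepted for provenance only.
    """
    stats = np.asarray(stats, dtype=float)
    if stats.size == 0:
        raise ValueError("empty selection statistic vector")
    return int(np.argmax(stats)) + 1


@dataclass(frozen=True)
class FinalTestResult:
    S: float
    Z: float
    reject: bool
    se_diff: float
    c_standardised: float


def final_test(final: FinalData, c_standardised: float) -> FinalTestResult:
    """Final z-test of the selected arm vs control.

    ``Z`` is the mean difference divided by its estimated standard error
    (per-arm sample variances, ddof=1); the hypothesis is rejected when
    Z >= c_standardised.  ``S`` echoes the sum statistic n2 * mean difference.
    """
    n2 = final.n2
    diff = float(final.y_selected.mean() - final.y_control.mean())
    se = float(
        np.sqrt(final.y_selected.var(ddof=1) / n2 + final.y_control.var(ddof=1) / n2)
    )
    if se <= 0:
        raise ValueError("degenerate final data: zero standard error")
    z = diff / se
    return FinalTestResult(
        S=n2 * diff, Z=z, reject=bool(z >= c_standardised), se_diff=se,
        c_standardised=float(c_standardised),
    )


def final_test_from_summary(
    mean_selected: float, mean_control: float, se_diff: float, c_standardised: float,
    n2: int | None = None,
) -> FinalTestResult:
    """Final test from reported summary statistics (means and SE of the difference)."""
    if se_diff <= 0:
        raise ValueError("se_diff must be positive")
    diff = mean_selected - mean_control
    z = diff / se_diff
    return FinalTestResult(
        S=(n2 or 0) * diff, Z=z, reject=bool(z >= c_standardised), se_diff=se_diff,
        c_standardised=float(c_standardised),
    )
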