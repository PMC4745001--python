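r"""Joint normal law of interim selection statistics and final test statistics.

For normally distributed responses, the k interim selection statistics (one
of the variants breve/hat/tilde, see :class:`~flexselect.design.SelectionVariant`)
and the k final-stage statistics

.. math:: S_i = \sum_{j \le n_2} (Y_{ij} - Y_{0j})

are jointly multivariate normal.  Writing :math:`V_1` for the common marginal
variance of the selection statistics, :math:`V_2 = 2 n_2 \sigma^2` for the
variance of each :math:`S_i`, and :math:`\rho_e` for the correlation between a
selection statistic and its own final statistic, the full :math:`2k \times 2k`
covariance has the Kronecker form

.. math::
   \begin{pmatrix} V_1 & \rho_e \sqrt{V_1 V_2}\\
                   \rho_e \sqrt{V_1 V_2} & V_2 \end{pmatrix} \otimes \Sigma,

where :math:`\Sigma` is the equicorrelation matrix with unit diagonal and
off-diagonal 1/2 induced by the shared control arm.  On standardised scales
each statistic decomposes as an arm-specific component plus a common control
component, :math:`Z_i = m_i + (\varepsilon_i + \delta)/\sqrt 2`; the selection
event among arms depends only on the arm components (the control cancels in
pairwise differences), which collapses the distribution function of the
selected final statistic to a single one-dimensional integral per arm:

.. math::
   \Pr(S_{T^*} \le s) = \sum_{i=1}^{k} \int \varphi(t)\,
      \prod_{j \ne i} \Phi\!\bigl(t + \sqrt2 (m_i - m_j)\bigr)\,
      \Phi\!\left(\frac{\sqrt2\,(\tilde s - \nu_i) - \rho_e t}
                       {\sqrt{2 - \rho_e^2}}\right) dt,

with :math:`m_i = \theta_i/\sqrt{V_1}`, :math:`\nu_i = n_2\theta_i/\sqrt{V_2}`
and :math:`\tilde s = s/\sqrt{V_2}` (the inner integral over the control
component is Gaussian and is evaluated in closed form).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate
from scipy.stats import norm

from .design import (
    InvalidDesignError,
    NuisanceParams,
    QuadratureError,
    SelectionVariant,
    TrialDesign,
)

__all__ = [
    "JointSelectionModel",
    "variant_moments",
    "conditional_s_moments",
    "selected_stat_cdf",
    "selection_probabilities",
    "joint_selection_cdf_terms",
]

_SQRT2 = np.sqrt(2.0)
#: absolute tolerance on probabilities returned by the quadrature
QUAD_ATOL = 1e-9
_DEFAULT_NODES = 128


@dataclass(frozen=True)
class JointSelectionModel:
    """Moments of the joint normal law of (selection statistics, S_1..S_k).

    ``cross_corr`` is the between-treatment correlation induced by the shared
    control arm and equals 1/2 exactly for equal per-arm sample sizes.
    """

    V1: float
    V2: float
    rho_e: float
    variant: SelectionVariant
    cross_corr: float = 0.5

    def __post_init__(self) -> None:
        if self.V1 <= 0 or self.V2 <= 0:
            raise InvalidDesignError("V1 and V2 must be positive")
        if not 0.0 < self.rho_e < 1.0:
            raise InvalidDesignError(
                f"rho_e must lie in (0, 1), got {self.rho_e:.6g}"
            )

    def full_covariance(self, k: int) -> np.ndarray:
        """Explicit 2k x 2k covariance matrix (selection stats first)."""
        sigma_block = 0.5 * (np.eye(k) + np.ones((k, k)))
        cross = self.rho_e * np.sqrt(self.V1 * self.V2)
        block = np.array([[self.V1, cross], [cross, self.V2]])
        return np.kron(block, sigma_block)


def variant_moments(
    design: TrialDesign, nuisance: NuisanceParams, variant: SelectionVariant | str
) -> JointSelectionModel:
    """Exact moments of the joint law for the given selection variant.

    All three variants are unbiased for the long-term effects, share
    ``V2 = 2 n2 sigma^2`` and the cross-treatment correlation 1/2; they differ
    in the marginal variance ``V1`` of the selection statistic and its
    correlation ``rho_e`` with the final statistic:

    ======= ============================================= =====================================
    variant V1                                            rho_e
    ======= ============================================= =====================================
    breve   2 sigma^2 / n1                                sqrt(n1 / n2)
    tilde   2 sigma^2 (n1 + rho^2 (N1 - n1)) / n1^2       sqrt((n1 + rho^2 (N1 - n1)) / n2)
    hat     (2 sigma^2 / n1)(1 - rho^2 (N1 - n1) / N1)    sqrt(n1 / (n2 (1 - rho^2 (N1-n1)/N1)))
    ======= ============================================= =====================================

    At ``rho = 0`` all three coincide.
    """
    variant = SelectionVariant.parse(variant)
    nuisance.check_compatible(design)
    n1, N1, n2 = design.n1, design.N1, design.n2
    s2 = nuisance.sigma**2
    r2 = nuisance.rho**2
    V2 = 2.0 * n2 * s2
    if variant is SelectionVariant.BREVE:
        V1 = 2.0 * s2 / n1
        rho_e2 = n1 / n2
    elif variant is SelectionVariant.TILDE:
        a = n1 + r2 * (N1 - n1)
        V1 = 2.0 * s2 * a / n1**2
        rho_e2 = a / n2
    else:  # HAT
        shrink = 1.0 - r2 * (N1 - n1) / N1
        V1 = 2.0 * s2 / n1 * shrink
        rho_e2 = n1 / (n2 * shrink)
    if rho_e2 >= 1.0:
        raise InvalidDesignError(
            f"selection/final correlation rho_e >= 1 (rho_e^2 = {rho_e2:.6g})"
        )
    return JointSelectionModel(V1=V1, V2=V2, rho_e=float(np.sqrt(rho_e2)), variant=variant)


def conditional_s_moments(
    design: TrialDesign,
    nuisance: NuisanceParams,
    theta_i: float,
    theta_tilde_i: float,
) -> tuple[float, float]:
    """Mean and SD of S_i given the interim data (through theta-tilde_i).

    Given the full first-stage data, S_i is normal with mean
    ``(n2 - n1) theta_i + n1 theta_tilde_i`` and variance
    ``2 ((n2 - n1) - (N1 - n1) rho^2) sigma^2``.
    """
    nuisance.check_compatible(design)
    n1, N1, n2 = design.n1, design.N1, design.n2
    var = 2.0 * ((n2 - n1) - (N1 - n1) * nuisance.rho**2) * nuisance.sigma**2
    mean = (n2 - n1) * theta_i + n1 * theta_tilde_i
    return float(mean), float(np.sqrt(var))


@lru_cache(maxsize=8)
def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    # nodes/weights for integral of phi(t) g(t) dt via Gauss-Hermite
    x, w = np.polynomial.hermite.hermgauss(n)
    return _SQRT2 * x, w / np.sqrt(np.pi)


def _terms_gh(
    m: np.ndarray, nu: np.ndarray, rho_e: float, s_std: float | None, n_nodes: int
) -> np.ndarray:
    """Per-arm integrals, Gauss-Hermite with ``n_nodes`` points."""
    k = m.size
    t, w = _gh_nodes(n_nodes)
    out = np.empty(k)
    denom = np.sqrt(2.0 - rho_e**2)
    for i in range(k):
        shifts = _SQRT2 * (m[i] - np.delete(m, i))
        g = norm.cdf(t[:, None] + shifts[None, :]).prod(axis=1) if k > 1 else np.ones_like(t)
        if s_std is not None:
            g = g * norm.cdf((_SQRT2 * (s_std - nu[i]) - rho_e * t) / denom)
        out[i] = float(np.dot(w, g))
    return out


def _terms_quad(
    m: np.ndarray, nu: np.ndarray, rho_e: float, s_std: float | None
) -> np.ndarray:
    """Adaptive-quadrature fallback for the same per-arm integrals."""
    k = m.size
    denom = np.sqrt(2.0 - rho_e**2)
    out = np.empty(k)
    for i in range(k):
        shifts = _SQRT2 * (m[i] - np.delete(m, i))

        def f(t: float, i: int = i, shifts: np.ndarray = shifts) -> float:
            g = norm.pdf(t) * np.prod(norm.cdf(t + shifts))
            if s_std is not None:
                g *= norm.cdf((_SQRT2 * (s_std - nu[i]) - rho_e * t) / denom)
            return g

        val, err = integrate.quad(f, -np.inf, np.inf, epsabs=QUAD_ATOL / 10, limit=200)
        if err > 100 * QUAD_ATOL:
            raise QuadratureError(
                f"adaptive quadrature error estimate {err:.3g} exceeds tolerance"
            )
        out[i] = val
    return out


def joint_selection_cdf_terms(
    model: JointSelectionModel,
    design: TrialDesign,
    theta_long: np.ndarray,
    s_std: float | None,
    n_nodes: int = _DEFAULT_NODES,
) -> np.ndarray:
    """Per-arm probabilities P(arm i selected [, S_i / sqrt(V2) <= s_std]).

    With ``s_std=None`` the final-statistic factor is dropped and the result
    is the vector of selection probabilities.  Gauss-Hermite quadrature is
    refined once; if the refinement disagrees beyond ``QUAD_ATOL`` the
    adaptive fallback is used.
    """
    theta_long = np.asarray(theta_long, dtype=float)
    if theta_long.size != design.k:
        raise ValueError(f"theta_long must have length k={design.k}")
    m = theta_long / np.sqrt(model.V1)
    nu = design.n2 * theta_long / np.sqrt(model.V2)
    coarse = _terms_gh(m, nu, model.rho_e, s_std, n_nodes)
    fine = _terms_gh(m, nu, model.rho_e, s_std, n_nodes + n_nodes // 2)
    if np.max(np.abs(fine - coarse)) > QUAD_ATOL:
        return _terms_quad(m, nu, model.rho_e, s_std)
    return fine


def selected_stat_cdf(
    s: float,
    model: JointSelectionModel,
    design: TrialDesign,
    theta_long: np.ndarray,
    *,
    standardized: bool = False,
    n_nodes: int = _DEFAULT_NODES,
) -> float:
    """CDF of the selected arm's final statistic, P(S_{T*} <= s).

    ``T*`` is the argmax of the model's selection statistics.  ``s`` is on
    the raw scale of S unless ``standardized`` is true, in which case it is
    interpreted as s / sqrt(V2).
    """
    s_std = float(s) if standardized else float(s) / np.sqrt(model.V2)
    terms = joint_selection_cdf_terms(model, design, theta_long, s_std, n_nodes)
    return float(np.clip(terms.sum(), 0.0, 1.0))


def selection_probabilities(
    model: JointSelectionModel,
    design: TrialDesign,
    theta_long: np.ndarray,
    n_nodes: int = _DEFAULT_NODES,
) -> np.ndarray:
    """Probability that each arm is selected (argmax of the selection statistics)."""
    return joint_selection_cdf_terms(model, design, theta_long, None, n_nodes)
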