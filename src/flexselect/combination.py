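"""Inverse-normal combination-test comparator.

The comparator splits the trial into two cohorts defined by recruitment
time: the ``N1`` patients per group recruited before the interim analysis
(whose primary endpoints are analysed once observed, giving the stage-1
p-value) and the ``n2 - N1`` patients per retained group recruited after the
selection (stage-2 p-value).  Because the stage-1 cohort is fixed before any
selection, both p-values satisfy the p-clud condition (stochastically no
smaller than uniform under the null) for any selection rule, and

    z = w1 * Phi^{-1}(1 - p1) + w2 * Phi^{-1}(1 - p2),  w1^2 + w2^2 = 1

rejects when z >= Phi^{-1}(1 - alpha) with strong FWER control.  The stage-1
p-value for the selected arm is adjusted for the selection among k arms by a
one-sided Dunnett-type correction exploiting the shared-control correlation
1/2 (simple Bonferroni is available as a sensitivity option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .design import EffectVector, NuisanceParams, SelectionVariant, TrialDesign
from .estimators import InterimData
from .joint_model import _gh_nodes
from .simulator import OperatingCharacteristics, SimulationConfig

__all__ = [
    "StagePValues",
    "stage_pvalues",
    "inverse_normal_combine",
    "dunnett_adjusted_p",
    "combination_operating_characteristics",
    "compare_designs",
]

_P_CLIP = 1e-15


@dataclass(frozen=True)
class StagePValues:
    """Stagewise p-values and inverse-normal weights (w1^2 + w2^2 = 1)."""

    p1: float
    p2: float
    w1: float
    w2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if abs(self.w1**2 + self.w2**2 - 1.0) > 1e-12:
            raise ValueError("weights must satisfy w1^2 + w2^2 = 1")


def dunnett_adjusted_p(z: np.ndarray | float, k: int, n_nodes: int = 128) -> np.ndarray:
    """One-sided Dunnett-type adjusted p for a statistic among k vs shared control.

    Returns 1 - P(max_i Z_i <= z) under the global null for k equicorrelated
    (corr 1/2) standard normal statistics, evaluated by a single normal
    integral over the shared control component.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if k == 1:
        out = 1.0 - norm.cdf(z)
    else:
        t, wts = _gh_nodes(n_nodes)
        vals = norm.cdf(np.sqrt(2.0) * z[:, None] - t[None, :]) ** k
        out = 1.0 - vals @ wts
    return np.clip(out, 0.0, 1.0)


def stage_pvalues(
    interim: InterimData,
    stage2_selected: np.ndarray,
    stage2_control: np.ndarray,
    selected_arm: int,
    design: TrialDesign,
    sigma: float,
    adjustment: str = "dunnett",
) -> StagePValues:
    """Stagewise p-values from end-of-trial data.

    ``interim`` must carry the second-cohort long-term responses
    (``y_late``), observed by the end of the trial; the stage-1 p-value uses
    the primary endpoint of all N1 first-cohort patients per group and is
    multiplicity-adjusted over the k comparisons.  ``stage2_*`` are the
    primary responses of the n2 - N1 patients per retained group recruited
    after selection.  ``sigma`` is the (known) response SD used in the
    z statistics.  Default weights are sqrt(N1/n2), sqrt((n2-N1)/n2).
    """
    if design.n2 <= design.N1:
        raise ValueError("combination test needs n2 > N1 (a non-empty stage-2 cohort)")
    if interim.y_late is None:
        raise ValueError("stage-1 p-value needs second-cohort primary responses (y_late)")
    stage2_selected = np.asarray(stage2_selected, dtype=float)
    stage2_control = np.asarray(stage2_control, dtype=float)
    n2b = design.n2 - design.N1
    if stage2_selected.size != n2b or stage2_control.size != n2b:
        raise ValueError(f"stage-2 cohorts must each have n2 - N1 = {n2b} responses")

    y_n1 = np.concatenate([interim.y, interim.y_late], axis=1)  # (k+1, N1)
    means = y_n1.mean(axis=1)
    z1 = (means[1:] - means[0]) * np.sqrt(design.N1 / (2.0 * sigma**2))
    z_sel = float(z1[selected_arm - 1])
    if adjustment == "dunnett":
        p1 = float(dunnett_adjusted_p(z_sel, design.k)[0])
    elif adjustment == "bonferroni":
        p1 = float(min(1.0, design.k * (1.0 - norm.cdf(z_sel))))
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")

    z2 = (stage2_selected.mean() - stage2_control.mean()) * np.sqrt(n2b / (2.0 * sigma**2))
    p2 = float(1.0 - norm.cdf(z2))
    w1 = float(np.sqrt(design.N1 / design.n2))
    w2 = float(np.sqrt(n2b / design.n2))
    return StagePValues(p1=p1, p2=p2, w1=w1, w2=w2)


def inverse_normal_combine(p: StagePValues, alpha: float) -> tuple[float, bool]:
    """Inverse-normal combination z and the rejection decision at level alpha."""
    p1, p2 = p.p1, p.p2
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        warnings.warn("degenerate p-value clipped for the inverse-normal transform")
        p1 = float(np.clip(p1, _P_CLIP, 1.0 - _P_CLIP))
        p2 = float(np.clip(p2, _P_CLIP, 1.0 - _P_CLIP))
    z = p.w1 * norm.ppf(1.0 - p1) + p.w2 * norm.ppf(1.0 - p2)
    return float(z), bool(z >= norm.ppf(1.0 - alpha))


# ---------------------------------------------------------------------------
# Cohort-mean simulation engine (known sigma) for head-to-head comparisons
# ---------------------------------------------------------------------------


def _simulate_cohort_means(
    design: TrialDesign,
    nuisance: NuisanceParams,
    effects: EffectVector,
    n_reps: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-arm cohort means (sufficient under known sigma) for n_reps trials.

    Blocks: first cohort (n1, paired w/y means), second cohort (N1 - n1,
    paired w/y means), stage-2 (n2 - N1, y mean) -- mutually independent.
    """
    k, n1, N1, n2 = design.k, design.n1, design.N1, design.n2
    rho, s, s0 = nuisance.rho, nuisance.sigma, nuisance.sigma0
    mu_y = effects.mu_control_long + np.concatenate(([0.0], effects.theta_long))
    mu_w = effects.mu_control_short + np.concatenate(([0.0], effects.theta_short))

    def paired_means(n: int) -> tuple[np.ndarray, np.ndarray]:
        a = rng.standard_normal((n_reps, k + 1))
        b = rho * a + np.sqrt(1 - rho**2) * rng.standard_normal((n_reps, k + 1))
        return (
            mu_w[None, :] + s0 * a / np.sqrt(n),
            mu_y[None, :] + s * b / np.sqrt(n),
        )

    w1, y1 = paired_means(n1)
    w2, y2 = paired_means(N1 - n1)
    y3 = mu_y[None, :] + s * rng.standard_normal((n_reps, k + 1)) / np.sqrt(n2 - N1)
    return {"w1": w1, "y1": y1, "w2": w2, "y2": y2, "y3": y3}


def _select(
    cm: dict[str, np.ndarray],
    design: TrialDesign,
    rule: SelectionVariant,
    scale: float,
    assumed_short: np.ndarray,
) -> np.ndarray:
    n1, N1 = design.n1, design.N1
    d_y1 = cm["y1"][:, 1:] - cm["y1"][:, :1]
    if rule is SelectionVariant.BREVE:
        stats = d_y1
    elif rule is SelectionVariant.HAT:
        d_w1 = cm["w1"][:, 1:] - cm["w1"][:, :1]
        wN = (n1 * cm["w1"] + (N1 - n1) * cm["w2"]) / N1
        th_short = wN[:, 1:] - wN[:, :1]
        stats = d_y1 - scale * (d_w1 - th_short)
    else:
        d_w2 = cm["w2"][:, 1:] - cm["w2"][:, :1]
        stats = d_y1 + scale * (N1 - n1) * (d_w2 - assumed_short[None, :]) / n1
    return np.argmax(stats, axis=1)


def combination_operating_characteristics(
    config: SimulationConfig, adjustment: str = "dunnett"
) -> OperatingCharacteristics:
    """Operating characteristics of the inverse-normal combination test."""
    return compare_designs(config, adjustment=adjustment)["combination"]


def compare_designs(
    config: SimulationConfig,
    adjustment: str = "dunnett",
) -> dict[str, OperatingCharacteristics]:
    """Run the flexible design and the combination test on identical trials.

    Both methods see the same simulated cohort means and the same selection
    decisions, so power differences are head-to-head.  The flexible design
    tests the standardised sum statistic over all n2 patients against
    ``config.c_standardised`` (or the calibrated value); the combination test
    combines the Dunnett-adjusted stage-1 p with the post-selection stage-2 p.
    """
    from .simulator import _assumed_short, _resolve_c

    design, nuisance, effects = config.design, config.nuisance, config.effects
    if design.n2 <= design.N1:
        raise ValueError("comparison requires n2 > N1")
    k, n1, N1, n2 = design.k, design.n1, design.N1, design.n2
    s = nuisance.sigma
    theta = np.asarray(effects.theta_long)
    rng = np.random.default_rng(config.seed)
    cm = _simulate_cohort_means(design, nuisance, effects, config.n_reps, rng)
    sel = _select(cm, design, config.selection_rule, nuisance.scale_factor, _assumed_short(config))
    idx = np.arange(config.n_reps)

    # flexible / group-sequential design: sum statistic over all n2 patients
    c_std = _resolve_c(config)
    y_n2 = (n1 * cm["y1"] + (N1 - n1) * cm["y2"] + (n2 - N1) * cm["y3"]) / n2
    z_all = (y_n2[:, 1:] - y_n2[:, :1]) * np.sqrt(n2 / (2.0 * s**2))
    z_flex = z_all[idx, sel]
    reject_flex = z_flex >= c_std

    # combination test
    y_N1 = (n1 * cm["y1"] + (N1 - n1) * cm["y2"]) / N1
    z1_all = (y_N1[:, 1:] - y_N1[:, :1]) * np.sqrt(N1 / (2.0 * s**2))
    z1_sel = z1_all[idx, sel]
    if adjustment == "dunnett":
        p1 = dunnett_adjusted_p(z1_sel, k)
    else:
        p1 = np.minimum(1.0, k * (1.0 - norm.cdf(z1_sel)))
    z2 = (cm["y3"][:, 1:] - cm["y3"][:, :1])[idx, sel] * np.sqrt((n2 - N1) / (2.0 * s**2))
    p2 = 1.0 - norm.cdf(z2)
    w1 = np.sqrt(N1 / n2)
    w2 = np.sqrt((n2 - N1) / n2)
    p1c = np.clip(p1, _P_CLIP, 1.0 - _P_CLIP)
    p2c = np.clip(p2, _P_CLIP, 1.0 - _P_CLIP)
    z_comb = w1 * norm.ppf(1.0 - p1c) + w2 * norm.ppf(1.0 - p2c)
    reject_comb = z_comb >= norm.ppf(1.0 - design.alpha)

    true_null = theta <= design.null_margin
    n = config.n_reps
    out = {}
    for name, reject in (("flexible", reject_flex), ("combination", reject_comb)):
        fwer = float(np.mean(reject & true_null[sel]))
        p = float(reject.mean())
        out[name] = OperatingCharacteristics(
            reject_any_true_null_rate=fwer,
            reject_rate=p,
            select_and_reject_rate=np.array(
                [np.mean(reject & (sel == i)) for i in range(k)]
            ),
            selection_frequencies=np.bincount(sel, minlength=k) / n,
            mc_se_fwer=OperatingCharacteristics._se(fwer, n),
            mc_se_reject=OperatingCharacteristics._se(p, n),
            n_reps=n,
            seed=config.seed,
            c_standardised=c_std,
        )
    return out
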