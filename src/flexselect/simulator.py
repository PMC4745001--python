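"""Monte-Carlo evaluation of operating characteristics.

Two engines are provided.  The *sufficient* engine draws the selection
statistics and final statistics directly from their joint normal law using
the shared-control decomposition (arm component + common control component,
each pair correlated rho_e); it requires known nuisance parameters and is
exact and fast.  The *individual* engine simulates patient-level bivariate
normal responses, applies the interim estimators (optionally with nuisance
parameters estimated from the simulated interim data and the critical value
re-interpolated from the estimated correlation), and carries the selected
arm through to the final analysis.  Second-cohort long-term responses are
drawn jointly with their short-term responses, so the conditional dependence
of the final statistic on the interim short-term data is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import CriticalValueTable, critical_value
from .design import (
    EffectVector,
    InvalidDesignError,
    NuisanceParams,
    SelectionVariant,
    TrialDesign,
)
from .estimators import (
    FinalData,
    InterimData,
    estimate_nuisance,
    final_test,
    select_treatment,
    theta_breve,
    theta_hat,
    theta_tilde,
)
from .joint_model import variant_moments

__all__ = [
    "SimulationConfig",
    "OperatingCharacteristics",
    "TrialResult",
    "simulate_interim",
    "run_trial",
    "operating_characteristics",
    "fixture_table1",
    "TABLE1_MEANS",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario definition for a batch of simulated trials.

    ``c_standardised`` fixes the critical value directly; alternatively
    ``c_variant`` names the calibration variant and the value is solved (or,
    when ``estimate_nuisance_params`` is set, re-interpolated per replicate
    from the estimated correlation).  ``engine`` is ``"sufficient"`` (joint
    normal draws of the selection and final statistics; known nuisance
    parameters required) or ``"individual"`` (patient-level).
    """

    design: TrialDesign
    nuisance: NuisanceParams
    effects: EffectVector
    selection_rule: SelectionVariant | str = SelectionVariant.TILDE
    assumed_theta_short: tuple[float, ...] | None = None
    c_standardised: float | None = None
    c_variant: SelectionVariant | str | None = None
    estimate_nuisance_params: bool = False
    n_reps: int = 100_000
    seed: int = 0
    engine: str = "sufficient"

    def __post_init__(self) -> None:
        object.__setattr__(self, "selection_rule", SelectionVariant.parse(self.selection_rule))
        if self.c_variant is not None:
            object.__setattr__(self, "c_variant", SelectionVariant.parse(self.c_variant))
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.engine not in ("sufficient", "individual"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.engine == "sufficient" and self.estimate_nuisance_params:
            raise InvalidDesignError(
                "the sufficient-statistic engine requires known nuisance parameters"
            )
        if self.effects.k != self.design.k:
            raise ValueError("effects dimension must match design.k")
        if self.c_standardised is None and self.c_variant is None:
            raise ValueError("provide either c_standardised or c_variant")


@dataclass(frozen=True)
class TrialResult:
    selected_arm: int
    Z: float
    reject: bool


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo rejection/selection rates with binomial standard errors."""

    reject_any_true_null_rate: float
    reject_rate: float
    select_and_reject_rate: np.ndarray
    selection_frequencies: np.ndarray
    mc_se_fwer: float
    mc_se_reject: float
    n_reps: int
    seed: int
    c_standardised: float | None = None

    @staticmethod
    def _se(p: float, n: int) -> float:
        return float(np.sqrt(p * (1.0 - p) / n))


def _resolve_c(config: SimulationConfig) -> float:
    if config.c_standardised is not None:
        return float(config.c_standardised)
    return critical_value(config.design, config.nuisance, config.c_variant).c_standardised


def _assumed_short(config: SimulationConfig) -> np.ndarray:
    """Assumed short-term effects for the tilde rule (default: the truth)."""
    if config.assumed_theta_short is not None:
        a = np.asarray(config.assumed_theta_short, dtype=float)
        if a.shape != (config.design.k,):
            raise ValueError("assumed_theta_short must have length k")
        return a
    return np.asarray(config.effects.theta_short, dtype=float)


def simulate_interim(
    design: TrialDesign,
    nuisance: NuisanceParams,
    effects: EffectVector,
    rng: np.random.Generator,
    with_late_y: bool = False,
) -> InterimData:
    """Draw one interim dataset from the bivariate-normal response model.

    Long-term responses are withheld for patients beyond n1; with
    ``with_late_y`` they are generated (jointly with their short-term
    responses) and stored in ``y_late`` for end-of-trial analyses.
    """
    k, n1, N1 = design.k, design.n1, design.N1
    mu_y = effects.mu_control_long + np.concatenate(([0.0], effects.theta_long))
    mu_w = effects.mu_control_short + np.concatenate(([0.0], effects.theta_short))
    rho, s, s0 = nuisance.rho, nuisance.sigma, nuisance.sigma0
    zw = rng.standard_normal((k + 1, N1))
    zy = rho * zw + np.sqrt(1.0 - rho**2) * rng.standard_normal((k + 1, N1))
    w = mu_w[:, None] + s0 * zw
    y_full = mu_y[:, None] + s * zy
    return InterimData(
        w=w, y=y_full[:, :n1], y_late=y_full[:, n1:] if with_late_y else None
    )


def _selection_stats(
    interim: InterimData,
    rule: SelectionVariant,
    scale_factor: float,
    assumed_short: np.ndarray,
) -> np.ndarray:
    if rule is SelectionVariant.BREVE:
        return theta_breve(interim)
    if rule is SelectionVariant.HAT:
        return theta_hat(interim, scale_factor)[0]
    return theta_tilde(interim, scale_factor, assumed_short)


def run_trial(config: SimulationConfig, rng: np.random.Generator | None = None) -> TrialResult:
    """Simulate a single trial at patient level: interim, selection, final test."""
    rng = rng or np.random.default_rng(config.seed)
    design, nuisance, effects = config.design, config.nuisance, config.effects
    interim = simulate_interim(design, nuisance, effects, rng, with_late_y=True)
    if config.estimate_nuisance_params:
        est = estimate_nuisance(interim)
        scale = est.scale_factor
        if config.c_standardised is not None:
            c_std = float(config.c_standardised)
        else:
            table = CriticalValueTable(design, config.c_variant)
            c_std = float(table(est.rho_hat))
    else:
        scale = nuisance.scale_factor
        c_std = _resolve_c(config)
    stats = _selection_stats(interim, config.selection_rule, scale, _assumed_short(config))
    sel = select_treatment(stats)
    # stage-2 long-term responses for the retained arms
    n_extra = design.n2 - design.N1
    mu_sel = effects.mu_control_long + effects.theta_long[sel - 1]
    y_sel = np.concatenate(
        [
            interim.y[sel],
            interim.y_late[sel],
            mu_sel + nuisance.sigma * rng.standard_normal(n_extra),
        ]
    )
    y_ctrl = np.concatenate(
        [
            interim.y[0],
            interim.y_late[0],
            effects.mu_control_long + nuisance.sigma * rng.standard_normal(n_extra),
        ]
    )
    res = final_test(FinalData(y_control=y_ctrl, y_selected=y_sel, selected_arm=sel), c_std)
    return TrialResult(selected_arm=sel, Z=res.Z, reject=res.reject)


def _oc_sufficient(config: SimulationConfig) -> OperatingCharacteristics:
    design = config.design
    k = design.k
    model = variant_moments(design, config.nuisance, config.selection_rule)
    theta = np.asarray(config.effects.theta_long)
    m = theta / np.sqrt(model.V1)
    nu = design.n2 * theta / np.sqrt(model.V2)
    c_std = _resolve_c(config)
    rho_e = model.rho_e
    rng = np.random.default_rng(config.seed)
    n = config.n_reps
    eps = rng.standard_normal((n, k))
    delta = rng.standard_normal((n, 1))
    e = rho_e * eps + np.sqrt(1.0 - rho_e**2) * rng.standard_normal((n, k))
    d = rho_e * delta + np.sqrt(1.0 - rho_e**2) * rng.standard_normal((n, 1))
    sel_stats = m[None, :] + (eps + delta) / np.sqrt(2.0)
    z_final = nu[None, :] + (e + d) / np.sqrt(2.0)
    sel = np.argmax(sel_stats, axis=1)
    z_sel = z_final[np.arange(n), sel]
    reject = z_sel >= c_std
    true_null = theta <= design.null_margin
    fwer = float(np.mean(reject & true_null[sel]))
    sel_freq = np.bincount(sel, minlength=k) / n
    sr = np.array([np.mean(reject & (sel == i)) for i in range(k)])
    p = float(reject.mean())
    return OperatingCharacteristics(
        reject_any_true_null_rate=fwer,
        reject_rate=p,
        select_and_reject_rate=sr,
        selection_frequencies=sel_freq,
        mc_se_fwer=OperatingCharacteristics._se(fwer, n),
        mc_se_reject=OperatingCharacteristics._se(p, n),
        n_reps=n,
        seed=config.seed,
        c_standardised=c_std,
    )


def _oc_individual(config: SimulationConfig, chunk: int = 2_000) -> OperatingCharacteristics:
    design, nuisance, effects = config.design, config.nuisance, config.effects
    k, n1, N1, n2 = design.k, design.n1, design.N1, design.n2
    theta = np.asarray(effects.theta_long)
    assumed = _assumed_short(config)
    rng = np.random.default_rng(config.seed)
    table = None
    if config.estimate_nuisance_params and config.c_standardised is None:
        table = CriticalValueTable(design, config.c_variant)
    fixed_c = None if table is not None else _resolve_c(config)

    mu_y = effects.mu_control_long + np.concatenate(([0.0], theta))
    mu_w = effects.mu_control_short + np.concatenate(([0.0], np.asarray(effects.theta_short)))
    rho, s, s0 = nuisance.rho, nuisance.sigma, nuisance.sigma0

    n = config.n_reps
    reject_all = np.empty(n, dtype=bool)
    sel_all = np.empty(n, dtype=np.int64)
    done = 0
    while done < n:
        b = min(chunk, n - done)
        zw = rng.standard_normal((b, k + 1, N1))
        zy1 = rho * zw + np.sqrt(1 - rho**2) * rng.standard_normal((b, k + 1, N1))
        w = mu_w[None, :, None] + s0 * zw
        y_interim = mu_y[None, :, None] + s * zy1  # cohorts 1+2, paired with w
        y_stage2 = mu_y[None, :, None] + s * rng.standard_normal((b, k + 1, n2 - N1))

        ybar1 = y_interim[:, :, :n1].mean(axis=2)
        th_breve = ybar1[:, 1:] - ybar1[:, :1]
        wbar1 = w[:, :, :n1].mean(axis=2)
        wbarN = w.mean(axis=2)
        dw1 = wbar1[:, 1:] - wbar1[:, :1]
        th_short_hat = wbarN[:, 1:] - wbarN[:, :1]
        w2sum = w[:, :, n1:].sum(axis=2)

        if config.estimate_nuisance_params:
            yc = y_interim[:, :, :n1] - ybar1[:, :, None]
            wc_all = w - wbarN[:, :, None]
            wc1 = w[:, :, :n1] - wbar1[:, :, None]
            ssy = (yc**2).sum(axis=(1, 2))
            ssw = (wc_all**2).sum(axis=(1, 2))
            ssw1 = (wc1**2).sum(axis=(1, 2))
            sxy = (yc * wc1).sum(axis=(1, 2))
            sigma_hat = np.sqrt(ssy / ((k + 1) * (n1 - 1)))
            sigma0_hat = np.sqrt(ssw / ((k + 1) * (N1 - 1)))
            rho_hat = np.clip(sxy / np.sqrt(ssy * ssw1), -1.0, 1.0)
            scale = rho_hat * sigma_hat / sigma0_hat
        else:
            scale = np.full(b, nuisance.scale_factor)
            rho_hat = None

        if config.selection_rule is SelectionVariant.BREVE:
            stats = th_breve
        elif config.selection_rule is SelectionVariant.HAT:
            stats = th_breve - scale[:, None] * (dw1 - th_short_hat)
        else:
            resid = w2sum[:, 1:] - w2sum[:, :1] - (N1 - n1) * assumed[None, :]
            stats = th_breve + scale[:, None] * resid / n1
        sel = np.argmax(stats, axis=1)

        idx = np.arange(b)
        y_sel_int = y_interim[idx, sel + 1]           # (b, N1)
        y_sel_st2 = y_stage2[idx, sel + 1]            # (b, n2-N1)
        y_ctl_int = y_interim[:, 0]
        y_ctl_st2 = y_stage2[:, 0]
        mean_sel = (y_sel_int.sum(axis=1) + y_sel_st2.sum(axis=1)) / n2
        mean_ctl = (y_ctl_int.sum(axis=1) + y_ctl_st2.sum(axis=1)) / n2
        if config.estimate_nuisance_params:
            var_sel = (
                (y_sel_int**2).sum(axis=1) + (y_sel_st2**2).sum(axis=1) - n2 * mean_sel**2
            ) / (n2 - 1)
            var_ctl = (
                (y_ctl_int**2).sum(axis=1) + (y_ctl_st2**2).sum(axis=1) - n2 * mean_ctl**2
            ) / (n2 - 1)
            se = np.sqrt((var_sel + var_ctl) / n2)
        else:
            se = np.sqrt(2.0 * s**2 / n2)
        z = (mean_sel - mean_ctl) / se
        c_std = fixed_c if table is None else table(rho_hat)
        reject_all[done : done + b] = z >= c_std
        sel_all[done : done + b] = sel
        done += b

    true_null = theta <= design.null_margin
    fwer = float(np.mean(reject_all & true_null[sel_all]))
    sel_freq = np.bincount(sel_all, minlength=k) / n
    sr = np.array([np.mean(reject_all & (sel_all == i)) for i in range(k)])
    p = float(reject_all.mean())
    return OperatingCharacteristics(
        reject_any_true_null_rate=fwer,
        reject_rate=p,
        select_and_reject_rate=sr,
        selection_frequencies=sel_freq,
        mc_se_fwer=OperatingCharacteristics._se(fwer, n),
        mc_se_reject=OperatingCharacteristics._se(p, n),
        n_reps=n,
        seed=config.seed,
        c_standardised=None if table is not None else fixed_c,
    )


def operating_characteristics(config: SimulationConfig) -> OperatingCharacteristics:
    """Estimate FWER / power / selection frequencies for the configured scenario."""
    if config.engine == "sufficient":
        return _oc_sufficient(config)
    return _oc_individual(config)


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------

#: printed interim summary means of the Alzheimer's worked example
#: (rows: control, 16, 24, 32 mg/day galantamine).
TABLE1_MEANS = {
    "y_first": (-1.24, 0.91, 2.64, 3.62),   # long-term mean, first cohort (n1)
    "w_first": (-0.05, 0.56, 2.15, 2.59),   # short-term mean, first cohort (n1)
    "w_second": (0.06, 1.48, 2.43, 0.36),   # short-term mean, second cohort (N1-n1)
}
#: final-analysis summaries: control / selected (24 mg/day) means and SE of
#: the difference on the 6-month ADAS-Cog change scale.
TABLE1_FINAL = {"mean_control": -1.39, "mean_selected": 2.07, "se_diff": 0.525, "selected_arm": 2}


def fixture_table1(
    seed: int = 0, design: TrialDesign | None = None
) -> tuple[InterimData, FinalData]:
    """Synthetic patient-level dataset matching the worked example's summaries.

    Responses are drawn from the bivariate normal model (rho = 0.77, unit
    dispersions) and each arm/cohort block is mean-shifted so the cohort
    means equal the printed summary means exactly; the final-analysis arms
    are additionally rescaled so the estimated SE of the mean difference is
    exactly as reported.  Dispersions of the interim blocks are synthetic
    (the source summaries do not report them).
    """
    design = design or TrialDesign(k=3, n1=40, N1=100, n2=200)
    if design.k != 3:
        raise ValueError("the worked-example fixture is defined for k=3")
    rng = np.random.default_rng(seed)
    n1, N1, n2 = design.n1, design.N1, design.n2
    rho = 0.77
    zw = rng.standard_normal((4, N1))
    zy = rho * zw + np.sqrt(1 - rho**2) * rng.standard_normal((4, N1))
    w = zw.copy()
    y = zy[:, :n1].copy()
    for i in range(4):
        y[i] += TABLE1_MEANS["y_first"][i] - y[i].mean()
        w[i, :n1] += TABLE1_MEANS["w_first"][i] - w[i, :n1].mean()
        w[i, n1:] += TABLE1_MEANS["w_second"][i] - w[i, n1:].mean()
    interim = InterimData(w=w, y=y)

    # final data: exact means and exact pooled SE of the difference
    sd_target = TABLE1_FINAL["se_diff"] * np.sqrt(n2 / 2.0)
    out = []
    for mean in (TABLE1_FINAL["mean_control"], TABLE1_FINAL["mean_selected"]):
        v = rng.standard_normal(n2)
        v = (v - v.mean()) / v.std(ddof=1) * sd_target
        out.append(v + mean)
    final = FinalData(
        y_control=out[0], y_selected=out[1], selected_arm=TABLE1_FINAL["selected_arm"]
    )
    return interim, final
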