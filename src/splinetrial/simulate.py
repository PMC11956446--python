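"""Monte Carlo engine: single sequential trials and operating characteristics.

A scenario fixes the true event rates (treatment, control, discontinuation),
the planned per-arm size, the prior family/informativeness and the rule
family.  Per trial, subject-level Bernoulli outcomes are drawn once for the
full enrolment and the interim counts are the cumulative counts at the
interim size — interim data are a nested subset of the final data, as in a
real sequential trial.  Discontinuation is a binary endpoint observed in the
treatment arm, drawn independently of the primary event process.

Operating characteristics aggregate five indicators over independent
replicates: the proportion declaring a treatment effect (interim or final),
the false discovery rate under null scenarios, true and false interim
futility stops, and true interim efficacy stops.  Truth labelling uses the
scenario's ground truth: the effect is real iff ``pi_T < pi_C`` (lower event
rate under treatment), and a futility stop is "true" iff the effect is not
real or the true discontinuation rate exceeds the acceptability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .design import (DesignConfig, Decision, final_decision_classical,
                     final_decision_hdi, interim_decision_classical,
                     interim_decision_hdi)
from .elicitation import (DEFAULT_LEVELS, BetaPrior, ElicitedQuantiles,
                          SplinePrior, beta_from_summary, discount_prior,
                          fit_spline_prior)
from .inference import (DEFAULT_ARR_DRAWS, DEFAULT_GRID_SIZE, arr_posterior,
                        grid_posterior, hdi, tail_prob)

__all__ = [
    "Scenario",
    "ArmCounts",
    "TrialData",
    "TrialResult",
    "OperatingCharacteristics",
    "uninformative_priors",
    "default_priors",
    "generate_trial_data",
    "run_trial",
    "operating_characteristics",
    "sample_size_search",
    "SampleSizeResult",
]

PriorMap = Mapping[str, BetaPrior | SplinePrior]


@dataclass(frozen=True)
class Scenario:
    """True data-generating state and design choices for a simulation arm."""

    pi_t: float
    pi_c: float
    pi_disc: float
    n_per_arm: int
    rule_family: str = "classical"
    prior_family: str = "parametric"  # "parametric" | "semiparametric"
    informativeness: str = "uninformative"
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("pi_t", "pi_c", "pi_disc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_per_arm < 4:
            raise ValueError("n_per_arm must be at least 4")

    @property
    def effect_real(self) -> bool:
        """Ground truth: the treatment reduces the event rate."""
        return self.pi_t < self.pi_c


@dataclass(frozen=True)
class ArmCounts:
    """Event/discontinuation counts at one look."""

    events_t: int
    events_c: int
    disc_t: int
    n_t: int
    n_c: int


@dataclass(frozen=True)
class TrialData:
    interim: ArmCounts
    final: ArmCounts


@dataclass(frozen=True)
class TrialResult:
    """Decision trace of one simulated trial."""

    interim_decision: Decision
    final_decision: Decision | None
    data: TrialData
    seed: int | None = None

    def __post_init__(self) -> None:
        continued = self.interim_decision.action == "continue"
        if continued != (self.final_decision is not None):
            raise ValueError(
                "final decision must be present exactly when the trial "
                "continues past the interim")

    @property
    def declared_effect(self) -> bool:
        if self.interim_decision.action == "stop_efficacy":
            return True
        return (self.final_decision is not None
                and self.final_decision.action == "declare_efficacy")

    @property
    def stopped_futility(self) -> bool:
        return self.interim_decision.action == "stop_futility"


def uninformative_priors(family: str = "parametric",
                         n_basis: int = 14) -> dict:
    """Flat priors for all three endpoints, in either family."""
    if family == "parametric":
        mk = lambda: BetaPrior(1.0, 1.0, informativeness="uninformative")
    elif family == "semiparametric":
        mk = lambda: SplinePrior.uniform(n_basis=n_basis)
    else:
        raise ValueError(f"unknown prior family {family!r}")
    return {"pi_t": mk(), "pi_c": mk(), "pi_disc": mk()}


#: Stand-in elicited prior centres used when no elicitation data is given:
#: the treatment prior mean sits ABOVE the control one, so null and benefit
#: scenarios exercise prior-data conflict under informative priors.
DEFAULT_PRIOR_MEANS = {"pi_t": 0.4, "pi_c": 0.3, "pi_disc": 0.15}
DEFAULT_PRIOR_ESS = 20.0


def default_priors(family: str = "parametric",
                   informativeness: str = "uninformative",
                   means: Mapping[str, float] | None = None,
                   ess: float = DEFAULT_PRIOR_ESS,
                   n_basis: int = 14) -> dict:
    """Priors for the three endpoints from declared stand-in elicitations.

    Informative priors are centred on ``means`` with the given effective
    sample size: Beta priors directly, spline priors by fitting the exact
    quantiles of the implied Beta at the standard elicitation levels.
    ``discount_prior`` then produces the requested informativeness level.
    """
    if informativeness == "uninformative":
        return uninformative_priors(family, n_basis=n_basis)
    means = dict(DEFAULT_PRIOR_MEANS if means is None else means)
    out = {}
    for endpoint, mean in means.items():
        base = beta_from_summary(mean, ess)
        if family == "semiparametric":
            from scipy.stats import beta as beta_dist
            values = tuple(beta_dist.ppf(DEFAULT_LEVELS, base.alpha,
                                         base.beta))
            prior = fit_spline_prior(
                ElicitedQuantiles(levels=DEFAULT_LEVELS, values=values,
                                  label=endpoint),
                n_basis=n_basis)
        elif family == "parametric":
            prior = base
        else:
            raise ValueError(f"unknown prior family {family!r}")
        out[endpoint] = discount_prior(prior, informativeness)
    return out


def generate_trial_data(sc: Scenario,
                        seed: int | np.random.SeedSequence,
                        interim_fraction: float = 0.5) -> TrialData:
    """Subject-level Bernoulli data for one trial, nested across looks."""
    rng = np.random.default_rng(seed)
    n = sc.n_per_arm
    n_int = int(np.ceil(interim_fraction * n))
    events_t = rng.random(n) < sc.pi_t
    events_c = rng.random(n) < sc.pi_c
    disc_t = rng.random(n) < sc.pi_disc
    interim = ArmCounts(
        events_t=int(events_t[:n_int].sum()),
        events_c=int(events_c[:n_int].sum()),
        disc_t=int(disc_t[:n_int].sum()),
        n_t=n_int, n_c=n_int)
    final = ArmCounts(
        events_t=int(events_t.sum()),
        events_c=int(events_c.sum()),
        disc_t=int(disc_t.sum()),
        n_t=n, n_c=n)
    return TrialData(interim=interim, final=final)


def run_trial(
    sc: Scenario,
    cfg: DesignConfig,
    priors: PriorMap,
    seed: int | np.random.SeedSequence,
    grid_size: int = DEFAULT_GRID_SIZE,
    n_draws: int = DEFAULT_ARR_DRAWS,
) -> TrialResult:
    """Run one sequential trial end-to-end.

    Interim posteriors are computed on the interim counts and the configured
    interim rule is applied; if the trial continues, the final decision uses
    the full counts and the primary endpoint only.  The ARR distribution is
    handled by independent posterior draws from the two arms; the
    discontinuation posterior is one-dimensional, so its tail probability
    and HDI come directly from the grid (no sampling noise).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    ss_data, ss_interim, ss_final = ss.spawn(3)
    data = generate_trial_data(sc, ss_data, cfg.interim_fraction)

    try:
        interim = _look(data.interim, cfg, priors, ss_interim, grid_size,
                        n_draws, stage="interim")
        if interim.action != "continue":
            return TrialResult(interim, None, data)
        final = _look(data.final, cfg, priors, ss_final, grid_size,
                      n_draws, stage="final")
    except Exception as exc:
        raise RuntimeError(
            f"inference failed for scenario {sc.label or sc} "
            f"with counts {data}") from exc
    return TrialResult(interim, final, data)


def _look(counts: ArmCounts, cfg: DesignConfig, priors: PriorMap,
          ss: np.random.SeedSequence, grid_size: int, n_draws: int,
          stage: str) -> Decision:
    post_t = grid_posterior(priors["pi_t"], counts.events_t, counts.n_t,
                            grid_size)
    post_c = grid_posterior(priors["pi_c"], counts.events_c, counts.n_c,
                            grid_size)
    arr = arr_posterior(post_t, post_c, n_draws, ss)
    if stage == "final":
        if cfg.rule_family == "classical":
            return final_decision_classical(tail_prob(arr, 0.0), cfg)
        return final_decision_hdi(hdi(arr, cfg.hdi_final_coverage), cfg)
    post_disc = grid_posterior(priors["pi_disc"], counts.disc_t, counts.n_t,
                               grid_size)
    if cfg.rule_family == "classical":
        p_eff = tail_prob(arr, 0.0)
        p_disc = post_disc.prob_below(cfg.m)
        return interim_decision_classical(p_eff, p_disc, cfg)
    arr_sorted = np.sort(arr)
    return interim_decision_hdi(
        hdi(arr_sorted, cfg.hdi_eff_coverage),
        hdi(post_disc, cfg.hdi_eff_coverage),
        hdi(arr_sorted, cfg.hdi_fut_coverage),
        hdi(post_disc, cfg.hdi_fut_coverage),
        cfg)


def _proportion(flags: Sequence[bool], denom: int) -> tuple[float, float]:
    if denom == 0:
        return float("nan"), float("nan")
    p = sum(flags) / denom
    return p, sqrt(p * (1.0 - p) / denom)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte Carlo summaries of the five design performance indicators."""

    p_declare_effect: float
    fdr: float
    p_true_futility: float
    p_false_futility: float
    p_true_interim_efficacy: float
    n_sims: int
    mc_se: dict = field(default_factory=dict)
    scenario: Scenario | None = None

    def as_row(self) -> dict:
        row = {
            "p_declare_effect": self.p_declare_effect,
            "fdr": self.fdr,
            "p_true_futility": self.p_true_futility,
            "p_false_futility": self.p_false_futility,
            "p_true_interim_efficacy": self.p_true_interim_efficacy,
            "n_sims": self.n_sims,
        }
        for k, v in self.mc_se.items():
            row[f"mc_se_{k}"] = v
        return row


def operating_characteristics(
    sc: Scenario,
    cfg: DesignConfig,
    n_sims: int,
    master_seed: int | np.random.SeedSequence,
    priors: PriorMap | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
    n_draws: int = DEFAULT_ARR_DRAWS,
) -> OperatingCharacteristics:
    """Replicate ``run_trial`` ``n_sims`` times and aggregate the indicators.

    Per-trial seeds are spawned from the master seed (counter-based
    splitting; no global RNG state), so results are exactly reproducible
    for identical (scenario, config, n_sims, master_seed).
    """
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100 for stable summaries")
    if priors is None:
        priors = uninformative_priors(sc.prior_family)
    ss = master_seed if isinstance(master_seed, np.random.SeedSequence) \
        else np.random.SeedSequence(master_seed)
    child_seeds = ss.spawn(n_sims)
    declared, futility, interim_eff = [], [], []
    for child in child_seeds:
        res = run_trial(sc, cfg, priors, child, grid_size, n_draws)
        declared.append(res.declared_effect)
        futility.append(res.stopped_futility)
        interim_eff.append(res.interim_decision.action == "stop_efficacy")

    effect_real = sc.effect_real
    futility_true_state = (not effect_real) or (sc.pi_disc > cfg.m)
    p_declare, se_declare = _proportion(declared, n_sims)
    fdr = p_declare if not effect_real else float("nan")
    p_fut, se_fut = _proportion(futility, n_sims)
    if futility_true_state:
        p_true_fut, se_true_fut = p_fut, se_fut
        p_false_fut, se_false_fut = 0.0, 0.0
    else:
        p_true_fut, se_true_fut = 0.0, 0.0
        p_false_fut, se_false_fut = p_fut, se_fut
    if effect_real:
        p_true_int_eff, se_int_eff = _proportion(interim_eff, n_sims)
    else:
        p_true_int_eff, se_int_eff = 0.0, 0.0
    return OperatingCharacteristics(
        p_declare_effect=p_declare,
        fdr=fdr,
        p_true_futility=p_true_fut,
        p_false_futility=p_false_fut,
        p_true_interim_efficacy=p_true_int_eff,
        n_sims=n_sims,
        mc_se={
            "p_declare_effect": se_declare,
            "fdr": se_declare if not effect_real else float("nan"),
            "p_true_futility": se_true_fut,
            "p_false_futility": se_false_fut,
            "p_true_interim_efficacy": se_int_eff,
        },
        scenario=sc,
    )


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a power-targeted sample size search."""

    n_required: int | None  # None when no size in the grid reaches the target
    target_power: float
    curve: pd.DataFrame  # columns: n, power, mc_se, power_isotonic

    @property
    def achieved(self) -> bool:
        return self.n_required is not None


def sample_size_search(
    sc_template: Scenario,
    cfg_template: DesignConfig,
    target_power: float,
    n_grid: Sequence[int],
    n_sims: int,
    master_seed: int | np.random.SeedSequence,
    priors: PriorMap | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
    n_draws: int = DEFAULT_ARR_DRAWS,
) -> SampleSizeResult:
    """Smallest per-arm size in ``n_grid`` whose power reaches the target.

    The raw Monte Carlo power curve is smoothed by isotonic regression
    (power is nondecreasing in n for a fixed design) before thresholding,
    so a single noisy dip cannot mask an adequate size.
    """
    n_grid = list(n_grid)
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])):
        raise ValueError("n_grid must be strictly increasing")
    ss = master_seed if isinstance(master_seed, np.random.SeedSequence) \
        else np.random.SeedSequence(master_seed)
    rows = []
    for n, child in zip(n_grid, ss.spawn(len(n_grid))):
        sc = replace(sc_template, n_per_arm=n)
        cfg = replace(cfg_template, n_total=n)
        oc = operating_characteristics(sc, cfg, n_sims, child, priors,
                                       grid_size, n_draws)
        rows.append({"n": n, "power": oc.p_declare_effect,
                     "mc_se": oc.mc_se["p_declare_effect"]})
    curve = pd.DataFrame(rows)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    curve["power_isotonic"] = iso.fit_transform(curve["n"], curve["power"])
    qualifying = curve[curve["power_isotonic"] >= target_power]
    n_required = int(qualifying["n"].iloc[0]) if len(qualifying) else None
    return SampleSizeResult(n_required=n_required, target_power=target_power,
                            curve=curve)
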