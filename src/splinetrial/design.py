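"""Decision logic of the two-endpoint sequential design.

The trial takes a single interim look at mid-enrolment and a final look at
full enrolment.  Two rule families implement the same flowchart:

* classical — posterior-probability thresholds transcribed from group
  sequential z-boundaries.  At interim, stop for efficacy iff BOTH
  ``P(pi_T - pi_C < 0) > Φ(c1)`` and ``P(pi_disc < m) > Φ(c1)``; stop for
  futility iff both probabilities fall below 0.5; otherwise continue.  At
  the final look efficacy is declared on the primary endpoint alone when
  ``P(pi_T - pi_C < 0)`` exceeds the final probability threshold.
* hdi — the same decisions phrased through highest-density intervals: an
  interim efficacy stop needs the 0.994-coverage ARR interval entirely
  below 0 and the discontinuation interval entirely below ``m``; an interim
  futility stop needs both 0.5-coverage intervals to straddle their
  thresholds; the final look declares efficacy when the 0.95 ARR interval
  lies below 0.

All boundary comparisons are strict; a posterior probability or interval
bound landing exactly on a threshold resolves to the non-stopping action
(a measure-zero event for continuous posteriors).

The first-look bound ``c1 = 2.74`` is an O'Brien–Fleming-like conservative
z-value, giving ``Φ(c1) ≈ 0.997``.  The final threshold is stored directly
as a probability (default 0.976, the standard two-look O'Brien–Fleming
final bound) rather than as a z-value, so it cannot drift via a rounding
of the z-scale constant.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from math import ceil

import yaml
from scipy.stats import norm

from .inference import HdiInterval

__all__ = [
    "DesignConfig",
    "Decision",
    "phi",
    "hdi_coverage_from_bound",
    "interim_decision_classical",
    "final_decision_classical",
    "interim_decision_hdi",
    "final_decision_hdi",
]

RULE_FAMILIES = ("classical", "hdi")

INTERIM_ACTIONS = ("stop_efficacy", "stop_futility", "continue")
FINAL_ACTIONS = ("declare_efficacy", "no_effect")


def phi(z: float) -> float:
    """Standard normal CDF."""
    return float(norm.cdf(z))


def hdi_coverage_from_bound(c: float) -> float:
    """Two-sided HDI coverage that mimics a one-sided z-boundary.

    ``1 − 2·(1 − Φ(c))``: the central normal mass between −c and c.  At
    c = 2.74 this gives the 0.994 interim coverage of the HDI rules.
    """
    if c <= 0:
        raise ValueError("the boundary must be positive")
    return 1.0 - (1.0 - phi(c)) * 2.0


@dataclass(frozen=True)
class DesignConfig:
    """Structural constants of the sequential design.

    Parameters
    ----------
    n_total
        Planned subjects per arm.
    interim_fraction
        Fraction of enrolment at the single interim look (default 0.5);
        the interim sample size is ``ceil(interim_fraction * n_total)``.
    c1
        First-look boundary on the z-scale (O'Brien–Fleming-like, 2.74).
    final_prob
        Final-look probability threshold Φ(c2) stored directly (0.976).
    m
        Acceptability threshold for the discontinuation rate.
    futility_prob
        Posterior-probability futility threshold at interim (0.5,
        calibrated to stop ~25% of no-effect trials at the interim).
    rule_family
        "classical" or "hdi".
    hdi_eff_coverage, hdi_fut_coverage, hdi_final_coverage
        HDI coverages for interim efficacy (0.994), interim futility (0.5)
        and the final look (0.95).
    """

    n_total: int
    interim_fraction: float = 0.5
    c1: float = 2.74
    final_prob: float = 0.976
    m: float = 0.2
    futility_prob: float = 0.5
    rule_family: str = "classical"
    hdi_eff_coverage: float = 0.994
    hdi_fut_coverage: float = 0.5
    hdi_final_coverage: float = 0.95

    def __post_init__(self) -> None:
        if self.n_total < 4:
            raise ValueError("n_total must be at least 4 per arm")
        if not 0.0 < self.interim_fraction < 1.0:
            raise ValueError("interim_fraction must lie in (0, 1)")
        if not 0.0 < self.m < 1.0:
            raise ValueError("m must lie in (0, 1)")
        if self.rule_family not in RULE_FAMILIES:
            raise ValueError(f"unknown rule family {self.rule_family!r}")
        for name in ("final_prob", "futility_prob", "hdi_eff_coverage",
                     "hdi_fut_coverage", "hdi_final_coverage"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @property
    def efficacy_prob(self) -> float:
        """Interim efficacy threshold Φ(c1)."""
        return phi(self.c1)

    @property
    def n_interim(self) -> int:
        """Subjects per arm at the interim look."""
        return ceil(self.interim_fraction * self.n_total)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DesignConfig":
        return cls(**yaml.safe_load(text))

    def thresholds(self) -> dict:
        """All operative thresholds, for logging/provenance."""
        return {
            "phi_c1": self.efficacy_prob,
            "final_prob": self.final_prob,
            "futility_prob": self.futility_prob,
            "m": self.m,
            "hdi_eff_coverage": self.hdi_eff_coverage,
            "hdi_fut_coverage": self.hdi_fut_coverage,
            "hdi_final_coverage": self.hdi_final_coverage,
        }


@dataclass(frozen=True)
class Decision:
    """Outcome of one look, with the evidence that triggered it."""

    stage: str  # "interim" | "final"
    action: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage == "interim" and self.action not in INTERIM_ACTIONS:
            raise ValueError(f"invalid interim action {self.action!r}")
        if self.stage == "final" and self.action not in FINAL_ACTIONS:
            raise ValueError(f"invalid final action {self.action!r}")
        if self.stage not in ("interim", "final"):
            raise ValueError(f"unknown stage {self.stage!r}")


def interim_decision_classical(p_eff: float, p_disc: float,
                               cfg: DesignConfig) -> Decision:
    """Interim look under posterior-probability thresholds.

    ``p_eff = P(pi_T − pi_C < 0)``, ``p_disc = P(pi_disc < m)``.  Efficacy
    and futility each require BOTH endpoints to agree; any split verdict
    continues the trial.
    """
    evidence = {"p_eff": p_eff, "p_disc": p_disc,
                "phi_c1": cfg.efficacy_prob,
                "futility_prob": cfg.futility_prob}
    thr = cfg.efficacy_prob
    if p_eff > thr and p_disc > thr:
        return Decision("interim", "stop_efficacy", evidence)
    if p_eff < cfg.futility_prob and p_disc < cfg.futility_prob:
        return Decision("interim", "stop_futility", evidence)
    return Decision("interim", "continue", evidence)


def final_decision_classical(p_eff: float, cfg: DesignConfig) -> Decision:
    """Final look: efficacy on the primary endpoint only, strict threshold."""
    evidence = {"p_eff": p_eff, "final_prob": cfg.final_prob}
    if p_eff > cfg.final_prob:
        return Decision("final", "declare_efficacy", evidence)
    return Decision("final", "no_effect", evidence)


def interim_decision_hdi(arr_hdi_eff: HdiInterval, disc_hdi_eff: HdiInterval,
                         arr_hdi_fut: HdiInterval, disc_hdi_fut: HdiInterval,
                         cfg: DesignConfig) -> Decision:
    """Interim look under HDI rules.

    Efficacy: the wide (0.994) ARR interval entirely below 0 AND the wide
    discontinuation interval entirely below ``m``.  Futility: 0 strictly
    inside the narrow (0.5) ARR interval AND ``m`` strictly inside the
    narrow discontinuation interval.
    """
    evidence = {
        "arr_hdi_eff": (arr_hdi_eff.low, arr_hdi_eff.high),
        "disc_hdi_eff": (disc_hdi_eff.low, disc_hdi_eff.high),
        "arr_hdi_fut": (arr_hdi_fut.low, arr_hdi_fut.high),
        "disc_hdi_fut": (disc_hdi_fut.low, disc_hdi_fut.high),
        "m": cfg.m,
    }
    if arr_hdi_eff.high < 0.0 and disc_hdi_eff.high < cfg.m:
        return Decision("interim", "stop_efficacy", evidence)
    if arr_hdi_fut.contains(0.0) and disc_hdi_fut.contains(cfg.m):
        return Decision("interim", "stop_futility", evidence)
    return Decision("interim", "continue", evidence)


def final_decision_hdi(arr_hdi: HdiInterval, cfg: DesignConfig) -> Decision:
    """Final look: declare efficacy iff the ARR interval lies below zero."""
    evidence = {"arr_hdi": (arr_hdi.low, arr_hdi.high)}
    if arr_hdi.high < 0.0:
        return Decision("final", "declare_efficacy", evidence)
    return Decision("final", "no_effect", evidence)
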