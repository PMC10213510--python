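"""Parametric simulated listeners (the synthetic-data generator).

The observer formalises a dynamic-attending account of the task: the
listener entrains to the sentence rhythm and forms a temporal
expectancy for the final-word onset whose precision is a Gaussian SD
``sigma`` expressed as a fraction of the reference gap ``T``.  Rhythm
alteration degrades entrainment (``sigma`` is inflated by a
multiplicative ``rhythm_penalty``), and the attentional pulse is
asymmetric: late onsets are resolved more poorly than early ones by a
multiplicative ``asymmetry`` factor (>1 in the young default profile,
1 in the older default).  Detectability of a gap deviation
``delta = dT/T`` is ``d' = delta / sigma`` and the two-interval
percent correct follows a lapse-mixed Gaussian 2AFC link::

    p(delta) = 0.5 + (0.5 - lapse/2) * erf(d' / 2)

which equals ``(1 - lapse) * Phi(d'/sqrt(2)) + lapse/2`` — chance at
delta = 0, asymptote ``1 - lapse/2``.

Cohorts draw per-subject parameters lognormally around the group
defaults, plus simulated timing/cognition battery covariates (GAP,
S&C, RD, WM): RD is coupled to the observer's early/late asymmetry
while GAP, S&C and WM are coupled to the overall precision, mirroring
the dissociation reported for these measures (RD tracks the late−early
difference score; the others track overall thresholds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf, erfinv

__all__ = [
    "ObserverProfile",
    "BatteryCouplings",
    "CohortSpec",
    "p_correct",
    "threshold_at",
    "sample_cohort",
    "make_responder",
    "P_2DOWN_1UP",
]

#: convergence point of a 2-down/1-up staircase: sqrt(0.5) = 70.7% correct
P_2DOWN_1UP = math.sqrt(0.5)


@dataclass(frozen=True)
class ObserverProfile:
    """One simulated listener.

    sigma_base:
        Expectancy SD as a fraction of T, for unaltered rhythm and
        early onsets (the best cell).
    rhythm_penalty:
        Multiplicative sigma inflation in the altered-rhythm
        conditions (>= 1).
    asymmetry:
        sigma_late / sigma_early (> 0; 1 = symmetric expectancy).
    lapse:
        Probability of a stimulus-independent random response.
    battery_scores:
        Optional simulated covariates {GAP, SC, RD, WM}.
    """

    group: str = "young"
    sigma_base: float = 0.34
    rhythm_penalty: float = 1.22
    asymmetry: float = 1.75
    lapse: float = 0.02
    battery_scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma_base <= 0:
            raise ValueError("sigma_base must be positive")
        if self.rhythm_penalty < 1:
            raise ValueError("rhythm_penalty must be >= 1")
        if self.asymmetry <= 0:
            raise ValueError("asymmetry must be positive")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")

    def sigma(self, rhythm_condition: str, direction: str) -> float:
        """Expectancy SD for one cell of the design."""
        s = self.sigma_base
        if rhythm_condition != "unaltered":
            s *= self.rhythm_penalty
        if direction == "late":
            s *= self.asymmetry
        return s


def p_correct(
    profile: ObserverProfile,
    rhythm_condition: str,
    direction: str,
    delta_frac: float,
) -> float:
    """Probability of a correct two-interval response at gap deviation
    ``delta_frac``; 0.5 at zero deviation, monotone increasing."""
    if delta_frac < 0:
        raise ValueError("delta_frac must be non-negative")
    dprime = delta_frac / profile.sigma(rhythm_condition, direction)
    return 0.5 + (0.5 - profile.lapse / 2.0) * float(erf(dprime / 2.0))


def threshold_at(
    profile: ObserverProfile,
    rhythm_condition: str,
    direction: str,
    p: float = P_2DOWN_1UP,
) -> float:
    """Analytic inverse of :func:`p_correct`: the deviation at which the
    observer scores ``p`` (default the 2-down/1-up convergence point)."""
    top = 1.0 - profile.lapse / 2.0
    if not 0.5 < p < top:
        raise ValueError(f"p must lie in (0.5, {top}) for this observer")
    dprime = 2.0 * float(erfinv((p - 0.5) / (0.5 - profile.lapse / 2.0)))
    return dprime * profile.sigma(rhythm_condition, direction)


def make_responder(profile: ObserverProfile, rhythm_condition: str):
    """Adapt a profile to the ``respond(direction, level, rng)`` callable
    consumed by :func:`rhythmgap.staircase.run_block`."""

    def respond(direction: str, level: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < p_correct(profile, rhythm_condition, direction, level))

    return respond


@dataclass(frozen=True)
class BatteryCouplings:
    """Scales and couplings of the simulated battery covariates.

    Each score is ``mean + sd * (c * z_latent + sqrt(1 - c^2) * eps)``
    with ``eps ~ N(0,1)``; the latent is the standardised log asymmetry
    for RD and the standardised log sigma_base for GAP, S&C and WM.
    Scores are oriented so that larger values accompany higher
    thresholds (for GAP/S&C/WM) or larger late−early differences (RD).
    """

    rd_mean: float = 1.5
    rd_sd: float = 0.6
    rd_asym_coupling: float = 0.8
    gap_mean: float = 75.0
    gap_sd: float = 8.0
    sc_mean: float = 0.04
    sc_sd: float = 0.012
    wm_mean: float = 0.55
    wm_sd: float = 0.1
    sigma_coupling: float = 0.8


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification for a simulated cohort.

    Group medians follow the default young/older profiles; between-
    subject spread is lognormal on sigma_base, rhythm_penalty and
    asymmetry (SDs on the log scale), chosen to produce threshold
    spreads comparable to the observed group SDs (~0.2).
    """

    n_young: int = 11
    n_older: int = 10
    young: ObserverProfile = ObserverProfile(group="young")
    older: ObserverProfile = ObserverProfile(
        group="older", sigma_base=0.47, asymmetry=1.0
    )
    sd_log_sigma: float = 0.35
    sd_log_penalty: float = 0.08
    #: asymmetry spread per group, on the log scale; the older group's
    #: larger spread reflects the reported split of the older listeners
    #: into young-like and symmetric subgroups
    sd_log_asymmetry_young: float = 0.25
    sd_log_asymmetry_older: float = 0.45
    battery: BatteryCouplings = BatteryCouplings()

    def __post_init__(self) -> None:
        if self.n_young < 1 or self.n_older < 1:
            raise ValueError("cohort group sizes must be >= 1")
        for name in ("sd_log_sigma", "sd_log_penalty",
                     "sd_log_asymmetry_young", "sd_log_asymmetry_older"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def sd_log_asymmetry(self, group: str) -> float:
        return self.sd_log_asymmetry_young if group == "young" else self.sd_log_asymmetry_older


def _coupled_score(mean: float, sd: float, coupling: float, z_latent: float,
                   rng: np.random.Generator) -> float:
    z = coupling * z_latent + math.sqrt(max(1.0 - coupling**2, 0.0)) * rng.standard_normal()
    return mean + sd * z


def _lognormal_unit_mean(sd_log: float, z: float) -> float:
    """Multiplicative deviate exp(sd*z - sd^2/2) with expectation one, so
    group-mean parameters stay at their calibrated defaults."""
    return math.exp(sd_log * z - 0.5 * sd_log**2)


def sample_cohort(spec: CohortSpec, rng: np.random.Generator) -> list[ObserverProfile]:
    """Draw a full cohort of observer profiles with battery covariates."""
    cohort: list[ObserverProfile] = []
    bat = spec.battery
    for group, base, n in (("young", spec.young, spec.n_young),
                           ("older", spec.older, spec.n_older)):
        sd_asym = spec.sd_log_asymmetry(group)
        for _ in range(n):
            z_sigma = rng.standard_normal()
            z_asym = rng.standard_normal()
            sigma = base.sigma_base * _lognormal_unit_mean(spec.sd_log_sigma, z_sigma)
            penalty = max(
                base.rhythm_penalty
                * _lognormal_unit_mean(spec.sd_log_penalty, rng.standard_normal()),
                1.0,
            )
            asym = base.asymmetry * _lognormal_unit_mean(sd_asym, z_asym)
            scores = {
                "GAP": _coupled_score(bat.gap_mean, bat.gap_sd, bat.sigma_coupling,
                                      z_sigma, rng),
                "SC": _coupled_score(bat.sc_mean, bat.sc_sd, bat.sigma_coupling,
                                     z_sigma, rng),
                "RD": _coupled_score(bat.rd_mean, bat.rd_sd, bat.rd_asym_coupling,
                                     z_asym, rng),
                "WM": _coupled_score(bat.wm_mean, bat.wm_sd, bat.sigma_coupling,
                                     z_sigma, rng),
            }
            cohort.append(replace(base, group=group, sigma_base=sigma,
                                  rhythm_penalty=penalty, asymmetry=asym,
                                  battery_scores=scores))
    return cohort
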