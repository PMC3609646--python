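"""Genotype-specific hazards constrained to a known average incidence curve.

In a carrier cohort the *average* age-specific incidence is assumed known
from published penetrance estimates. Given per-genotype hazard ratios and a
genotype distribution at age 18 (HWE), the baseline hazard is determined at
every age by requiring that the genotype-frequency-weighted mean hazard
among unaffected survivors equals the average incidence. Because high-risk
genotypes are preferentially removed from the unaffected pool over age
(survivor depletion), the genotype distribution must be updated year by
year; the constraint then holds exactly at every age by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import IncidenceCurve

__all__ = ["PenetranceModel", "InfeasibleHazardError", "constrain_baseline", "constrain_categories"]


class InfeasibleHazardError(ValueError):
    """A per-category yearly hazard reached 1: the yearly grid cannot
    represent the requested hazard ratio at this incidence level."""


def constrain_categories(
    rates: np.ndarray, probs: np.ndarray, hrs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the baseline hazard for arbitrary risk categories.

    Parameters
    ----------
    rates : average yearly hazard lambda-bar(t), length T
    probs : category probabilities at the first age (sum to 1), length C
    hrs : per-category hazard multipliers, length C

    Returns
    -------
    lambda0 : baseline yearly hazard, length T
    pi : category distribution among unaffected survivors, shape (T, C);
         ``pi[t]`` is the distribution *entering* year t, so
         ``sum_c pi[t, c] * lambda0[t] * hrs[c] == rates[t]`` exactly.
    """
    rates = np.asarray(rates, dtype=float)
    probs = np.asarray(probs, dtype=float)
    hrs = np.asarray(hrs, dtype=float)
    if np.any(hrs <= 0):
        raise ValueError("hazard multipliers must be positive")
    T, C = len(rates), len(hrs)
    lam0 = np.zeros(T)
    pi = np.zeros((T, C))
    cur = probs / probs.sum()
    for t in range(T):
        pi[t] = cur
        denom = float(cur @ hrs)
        l0 = rates[t] / denom if denom > 0 else 0.0
        if np.any(l0 * hrs >= 1.0):
            raise InfeasibleHazardError(
                f"yearly hazard >= 1 at grid index {t} (rate {rates[t]:.4f})"
            )
        lam0[t] = l0
        surv = cur * (1.0 - l0 * hrs)
        s = surv.sum()
        if s > 0:
            cur = surv / s
    return lam0, pi


def _hwe_probs(p: float) -> np.ndarray:
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


@dataclass
class PenetranceModel:
    """Constrained genotype-specific penetrance for one disease.

    ``rr`` holds the multipliers (1, e^beta, e^{2 beta}) for the per-allele
    model or (1, e^beta1, e^beta2) for genotype-specific effects.
    """

    disease: str
    ages: np.ndarray
    lambda0: np.ndarray  # baseline yearly hazard per age
    pi: np.ndarray  # (T, 3) genotype distribution among unaffected survivors
    rr: np.ndarray  # genotype hazard multipliers, length 3
    p: float  # allele-2 frequency

    def hazard(self, g: int) -> np.ndarray:
        return self.lambda0 * self.rr[g]

    def average_hazard(self) -> np.ndarray:
        """pi-weighted mean hazard; equals the input curve by construction."""
        return np.einsum("tc,c->t", self.pi, self.rr) * self.lambda0

    def cumulative_risk(self, g: int) -> np.ndarray:
        return 1.0 - np.cumprod(1.0 - self.hazard(g))


def constrain_baseline(
    curve: IncidenceCurve, p: float, beta: float | tuple[float, float]
) -> PenetranceModel:
    """Constrain the baseline so the cohort-average hazard equals ``curve``.

    ``beta`` is the log per-allele hazard ratio, or a pair
    (log HR heterozygote, log HR homozygote) for the 2-parameter model.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("allele frequency must lie in (0, 1)")
    if np.isscalar(beta):
        rr = np.exp(np.array([0.0, beta, 2.0 * beta], dtype=float))
    else:
        b1, b2 = beta
        rr = np.exp(np.array([0.0, b1, b2], dtype=float))
    lam0, pi = constrain_categories(curve.rate, _hwe_probs(p), rr)
    return PenetranceModel(
        disease=curve.disease, ages=curve.ages.copy(), lambda0=lam0, pi=pi, rr=rr, p=p
    )
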