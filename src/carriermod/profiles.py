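"""Combined multilocus risk profiles and absolute-risk curves.

Assuming independent loci with multiplicative per-allele effects, the 3^K
multilocus genotype categories have combined hazard ratio
prod_k hr_k^{g_k} and HWE product probabilities. Combined HRs are reported
relative to the lowest-risk category (so protective alleles anchor at their
homozygous-carrier state) and percentiles are taken on the probability-
weighted discrete distribution.

Absolute risks generalise the constrained-baseline construction to the
enumerated categories: the baseline is solved at every age so that the
category-averaged hazard among unaffected survivors equals the published
average incidence curve, and the per-category cumulative risk follows. The
survivor-depletion update of the category distribution is exactly what
makes the probability-weighted mean of the category risks reproduce the
population risk at every age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EffectTable, IncidenceCurve
from .penetrance import constrain_categories

__all__ = ["RiskProfile", "AbsoluteRiskCurve", "enumerate_profiles", "absolute_risk_curves"]

MAX_LOCI = 20


@dataclass
class RiskProfile:
    """Enumerated multilocus genotype categories, sorted by combined HR."""

    snp_ids: list[str]
    genotypes: np.ndarray  # (C, K) allele-2 counts per category
    combined_hr: np.ndarray  # relative to the minimum-HR category (min = 1)
    prob: np.ndarray  # HWE product probabilities, sum to 1

    def percentile(self, q: float) -> float:
        """Smallest category HR h with cumulative probability >= q
        (lower-step convention), on the weighted discrete distribution."""
        if not 0.0 <= q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        cum = np.cumsum(self.prob)
        idx = int(np.searchsorted(cum, q, side="left"))
        return float(self.combined_hr[min(idx, len(self.combined_hr) - 1)])

    def percentile_category(self, q: float) -> int:
        cum = np.cumsum(self.prob)
        return int(min(np.searchsorted(cum, q, side="left"), len(self.prob) - 1))


@dataclass
class AbsoluteRiskCurve:
    label: str
    ages: np.ndarray
    cumulative_risk: np.ndarray  # F(t) at the end of each year


def _hwe(g: int, p: float) -> float:
    return ((1 - p) ** 2, 2 * p * (1 - p), p * p)[g]


def enumerate_profiles(effects: EffectTable) -> RiskProfile:
    """Enumerate all 3^K multilocus genotypes with combined HRs and HWE
    probabilities; HRs renormalised so the lowest-risk category equals 1."""
    K = len(effects)
    if K > MAX_LOCI:
        raise ValueError(
            f"{K} loci would enumerate 3^{K} categories; reduce the table "
            "or use a sampling approach"
        )
    log_hr = np.log(effects.hr)
    grids = np.indices((3,) * K).reshape(K, -1).T  # (3^K, K)
    combined = np.exp(grids @ log_hr)
    prob = np.ones(len(grids))
    for k in range(K):
        p = effects.freq2[k]
        probs_k = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
        prob *= probs_k[grids[:, k]]
    order = np.argsort(combined, kind="stable")
    combined = combined[order]
    prob = prob[order]
    grids = grids[order]
    combined = combined / combined[0]
    return RiskProfile(
        snp_ids=list(effects.snp_ids),
        genotypes=grids,
        combined_hr=combined,
        prob=prob / prob.sum(),
    )


def absolute_risk_curves(
    profile: RiskProfile,
    curve: IncidenceCurve,
    percentiles: tuple = (5, 10, 50, 90, 95),
    deplete: bool = True,
) -> dict[str, AbsoluteRiskCurve]:
    """Per-percentile (and population-average) cumulative risk curves under
    the category-constrained baseline.

    ``deplete=False`` holds the category distribution fixed at its age-18
    values, for comparison; only the depleting version conserves the
    population risk exactly.
    """
    hrs = profile.combined_hr
    probs = profile.prob
    if deplete:
        lam0, pi = constrain_categories(curve.rate, probs, hrs)
    else:
        T = len(curve.rate)
        denom = float(probs @ hrs)
        lam0 = curve.rate / denom
        if np.any(np.outer(lam0, hrs) >= 1.0):
            from .penetrance import InfeasibleHazardError

            raise InfeasibleHazardError("yearly category hazard >= 1")
        pi = np.tile(probs, (T, 1))

    # F_c(t) = 1 - prod_{u<=t} (1 - lam0(u) hr_c)
    haz = np.outer(lam0, hrs)  # (T, C)
    surv = np.cumprod(1.0 - haz, axis=0)
    F = 1.0 - surv

    out: dict[str, AbsoluteRiskCurve] = {}
    for q in percentiles:
        c = profile.percentile_category(q / 100.0)
        out[f"p{q}"] = AbsoluteRiskCurve(
            label=f"{q}th percentile", ages=curve.ages.copy(), cumulative_risk=F[:, c]
        )
    # probability-weighted average over categories (population risk)
    out["average"] = AbsoluteRiskCurve(
        label="population average",
        ages=curve.ages.copy(),
        cumulative_risk=F @ probs,
    )
    out["minimum"] = AbsoluteRiskCurve("lowest-risk category", curve.ages.copy(), F[:, 0])
    out["maximum"] = AbsoluteRiskCurve("highest-risk category", curve.ages.copy(), F[:, -1])
    return out
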