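"""Bundled reference inputs: modifier-locus effect tables and default
average incidence curves.

The ovarian effect table transcribes the published per-allele hazard-ratio
and unaffected-carrier allele-2 frequency estimates for the seven
ovarian-cancer risk-modifying regions known for BRCA1 mutation carriers
(one top SNP per region). The incidence curves are synthetic
penetrance-consistent defaults: piecewise-constant yearly hazards chosen to
give cumulative risks in line with published BRCA1 penetrance (roughly 65%
breast and 40% ovarian cancer by age 80); they stand in for the external
cohort-specific rates that users can supply as CSV files.
"""

from __future__ import annotations

import numpy as np

from .data import EffectTable, IncidenceCurve

__all__ = [
    "ovarian_effects_table",
    "default_breast_incidence",
    "default_ovarian_incidence",
]

# (snp_id, per-allele HR, allele-2 frequency in unaffected carriers)
_OVARIAN_TOP_SNPS = [
    ("rs3814113", 0.77, 0.34),  # 9p22
    ("rs9918771", 0.86, 0.17),  # 8q24
    ("rs7651446", 1.46, 0.043),  # 3q25
    ("rs11651753", 1.14, 0.43),  # 17q21
    ("c19_pos17158477", 0.64, 0.038),  # 19p13
    ("rs17631303", 1.27, 0.19),  # 17q21.31
    ("rs4691139", 1.20, 0.48),  # 4q32.3
]


def ovarian_effects_table() -> EffectTable:
    """Per-allele HRs and allele frequencies for the seven ovarian-risk
    modifier loci in BRCA1 carriers (top SNP per region)."""
    return EffectTable(
        snp_ids=[s for s, _, _ in _OVARIAN_TOP_SNPS],
        hr=np.array([h for _, h, _ in _OVARIAN_TOP_SNPS]),
        freq2=np.array([f for _, _, f in _OVARIAN_TOP_SNPS]),
    )


def _piecewise(disease: str, pieces: list[tuple[int, int, float]]) -> IncidenceCurve:
    ages = np.arange(18, 81)
    rate = np.zeros_like(ages, dtype=float)
    for lo, hi, r in pieces:
        rate[(ages >= lo) & (ages <= hi)] = r
    return IncidenceCurve(disease=disease, ages=ages, rate=rate)


def default_breast_incidence() -> IncidenceCurve:
    """Synthetic average breast-cancer incidence for BRCA1 carriers
    (~64% cumulative risk by age 80)."""
    return _piecewise(
        "breast",
        [(18, 29, 0.002), (30, 39, 0.02), (40, 49, 0.035), (50, 80, 0.015)],
    )


def default_ovarian_incidence() -> IncidenceCurve:
    """Synthetic average ovarian-cancer incidence for BRCA1 carriers
    (~42% cumulative risk by age 80)."""
    return _piecewise(
        "ovarian",
        [(18, 34, 0.0005), (35, 44, 0.008), (45, 54, 0.018), (55, 80, 0.012)],
    )
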