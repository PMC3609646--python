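"""Multi-stage design: ranked SNP selection across analyses, and
stage-stratified combined testing.

A fixed genotyping budget is split across eight ranked candidate analyses
in nominal proportions (61.5%, 20%, 2.5%, 2.5%, 2.5%, 0.5%, 0.5%, 10%).
Quotas are filled in rank (ascending P) order; a SNP already selected by an
earlier-filled analysis is skipped; a SNP in strong LD (r^2 >= 0.90) with a
higher-ranking selected SNP is admitted only if its P-value passes the
analysis-appropriate gate (1e-4 for the two main analyses, 1e-5 otherwise)
and at most two such correlated admissions exist for that LD group. Quota
unused after the first pass is spilled back proportionally in a second pass.

Combining stages is plain stratification: the stage label is crossed with
the country (or super-stratum) label, and scores/information add across the
resulting strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import CarrierRecord, GenotypeMatrix, IncidenceCurve
from .retrospective import RetrospectiveHazardsModel

__all__ = ["AnalysisRanking", "SelectionConfig", "SelectedSNP", "select_snps", "combine_stages"]

DEFAULT_PROPORTIONS = (0.615, 0.20, 0.025, 0.025, 0.025, 0.005, 0.005, 0.10)


@dataclass
class AnalysisRanking:
    """P-value ranked candidates from one of the component analyses."""

    analysis_id: int
    snp_ids: list[str]
    p_values: list[float]

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(self.p_values):
            raise ValueError("snp_ids and p_values must have equal length")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"analysis {self.analysis_id}: duplicate snp ids")
        order = sorted(
            range(len(self.snp_ids)), key=lambda i: (self.p_values[i], self.snp_ids[i])
        )
        self.snp_ids = [self.snp_ids[i] for i in order]
        self.p_values = [self.p_values[i] for i in order]


@dataclass
class SelectionConfig:
    budget: int = 100
    proportions: tuple = DEFAULT_PROPORTIONS
    r2_cap: float = 0.90
    max_correlated: int = 2
    p_gate_main: float = 1e-4
    p_gate_other: float = 1e-5

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("allocation proportions must sum to 1")


@dataclass
class SelectedSNP:
    snp_id: str
    analysis_id: int
    rank: int
    p_value: float
    rule: str  # 'quota' or 'correlated_admission' or 'spill'


def _quotas(budget: int, proportions: Sequence[float]) -> list[int]:
    """Floor allocation, remainders to the largest fractional parts."""
    raw = [budget * p for p in proportions]
    base = [int(np.floor(x)) for x in raw]
    rem = budget - sum(base)
    fracs = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in fracs[:rem]:
        base[i] += 1
    return base


def select_snps(
    rankings: list[AnalysisRanking],
    ld: dict[frozenset, float],
    config: SelectionConfig,
) -> list[SelectedSNP]:
    """Fill per-analysis quotas in rank order under the dedup and LD rules.

    ``ld`` maps frozenset({snp_a, snp_b}) -> r^2; absent pairs are treated
    as uncorrelated. Returns the ordered selections with provenance.
    """
    rankings = sorted(rankings, key=lambda r: r.analysis_id)
    for r in rankings:
        if not 1 <= r.analysis_id <= len(config.proportions):
            raise ValueError(f"analysis_id {r.analysis_id} out of range")

    def r2(a: str, b: str) -> float:
        v = ld.get(frozenset((a, b)), 0.0)
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"inconsistent r^2 for pair ({a}, {b}): {v}")
        return v

    selected: list[SelectedSNP] = []
    chosen: set[str] = set()
    group_counts: dict[str, int] = {}  # anchor snp -> correlated admissions
    cursors = {r.analysis_id: 0 for r in rankings}
    quotas = dict(zip([r.analysis_id for r in rankings], _quotas(config.budget, config.proportions)))

    def gate(analysis_id: int) -> float:
        return config.p_gate_main if analysis_id in (1, 2) else config.p_gate_other

    def try_fill(r: AnalysisRanking, quota: int, rule: str) -> int:
        taken = 0
        i = cursors[r.analysis_id]
        while taken < quota and i < len(r.snp_ids):
            snp, p = r.snp_ids[i], r.p_values[i]
            i += 1
            if snp in chosen:
                continue  # duplications not allowed
            anchor = None
            for s in chosen:
                if r2(snp, s) >= config.r2_cap:
                    anchor = s
                    break
            applied = rule
            if anchor is not None:
                if p >= gate(r.analysis_id):
                    continue
                if group_counts.get(anchor, 0) >= config.max_correlated:
                    continue
                group_counts[anchor] = group_counts.get(anchor, 0) + 1
                applied = "correlated_admission"
            chosen.add(snp)
            selected.append(
                SelectedSNP(
                    snp_id=snp,
                    analysis_id=r.analysis_id,
                    rank=i,
                    p_value=p,
                    rule=applied,
                )
            )
            taken += 1
        cursors[r.analysis_id] = i
        return taken

    # first pass: nominal quotas in analysis order
    unused = 0
    for r in rankings:
        q = quotas.get(r.analysis_id, 0)
        got = try_fill(r, q, "quota")
        unused += q - got

    # second pass: spill unused budget back proportionally over analyses
    # that still have candidates
    while unused > 0:
        open_rs = [r for r in rankings if cursors[r.analysis_id] < len(r.snp_ids)]
        if not open_rs:
            break
        weights = [config.proportions[r.analysis_id - 1] for r in open_rs]
        share = _quotas(unused, [w / sum(weights) for w in weights])
        progressed = 0
        for r, q in zip(open_rs, share):
            progressed += try_fill(r, q, "spill")
        if progressed == 0:
            break
        unused -= progressed
    return selected


def combine_stages(
    stages: dict[str, tuple[list[CarrierRecord], GenotypeMatrix]],
    snp_id: str,
    disease: str,
    incidence: IncidenceCurve | dict,
    **kwargs,
) -> RetrospectiveHazardsModel:
    """Pool several experiment stages into one stage x stratum analysis.

    Stages must be disjoint in samples. Returns the pooled model; its
    score test and fit() sum scores and information across all strata, so
    a single stage reproduces the plain stratified analysis bit for bit.
    """
    seen: dict[str, str] = {}
    overlap = []
    for stage, (records, _) in stages.items():
        for r in records:
            if r.sample_id in seen:
                overlap.append(r.sample_id)
            seen[r.sample_id] = stage
    if overlap:
        raise ValueError(f"samples present in more than one stage: {sorted(set(overlap))}")

    all_records: list[CarrierRecord] = []
    cols = []
    one_stage = len(stages) == 1
    for stage, (records, geno) in stages.items():
        sub = geno.subset_samples([r.sample_id for r in records])
        col = sub.column(snp_id)
        for r, g in zip(records, col):
            r2 = CarrierRecord(**{f: getattr(r, f) for f in r.__dataclass_fields__})
            if not one_stage:
                r2.stratum = f"{stage}:{r.stratum}"
            all_records.append(r2)
            cols.append(g)

    from .data import endpoint_view

    views = [endpoint_view(r, disease) for r in all_records]
    if isinstance(incidence, dict) and not one_stage:
        incidence = {
            f"{stage}:{s}": c
            for stage in stages
            for s, c in incidence.items()
        }
    return RetrospectiveHazardsModel(
        times=np.array([v.time for v in views]),
        events=np.array([v.affected for v in views]),
        genotypes=np.array(cols, dtype=float),
        strata=[r.stratum for r in all_records],
        incidence=incidence,
        families=[r.family_id for r in all_records],
        disease=disease,
        **kwargs,
    )
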