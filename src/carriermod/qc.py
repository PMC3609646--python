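"""Stepwise sample and SNP quality control, including the country-stratified
Hardy-Weinberg test.

The HWE statistic avoids the Wahlund effect (spurious heterozygote deficits
when strata with different allele frequencies are pooled): the within-stratum
disequilibrium coefficient f = 1 - observed het / expected het is combined
across strata by inverse-variance weighting (null variance 1/n per stratum)
into a single 1-df chi-square. With one stratum this reduces exactly to the
classic Pearson HWE chi-square (n * f^2).

``run_qc`` applies the filters in a fixed, documented order:

1. sample call rate
2. sample heterozygosity outliers (mean +/- band * SD)
3. declared-duplicate resolution (keep the higher-call-rate member)
4. SNP call rate
5. monomorphic SNPs
6. stratified HWE
7. SNPs discordant among declared duplicates

Step order matters (e.g. removing low-call-rate SNPs changes heterozygosity
statistics only if done first); the canonical order above is part of the
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import CarrierRecord, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "MonomorphicInAllStrataError",
    "QCEmptyError",
    "hwe_stratified_test",
    "run_qc",
]

REASONS = (
    "callrate_sample",
    "heterozygosity",
    "duplicate_sample",
    "callrate_snp",
    "monomorphic",
    "hwe",
    "duplicate_discordance",
)


class MonomorphicInAllStrataError(ValueError):
    """HWE is undefined: the SNP is monomorphic in every stratum."""


class QCEmptyError(RuntimeError):
    """All samples or all SNPs were removed by quality control."""


@dataclass
class QCThresholds:
    sample_callrate_min: float = 0.95
    snp_callrate_min: float = 0.95
    hwe_p_min: float = 1e-7
    het_sd_band: float = 4.0
    duplicate_concordance_min: float = 0.98
    iplex_sample_fail_fraction: float = 0.20


@dataclass
class QCReport:
    removed_samples: list = field(default_factory=list)  # (sample_id, reason)
    removed_snps: list = field(default_factory=list)  # (snp_id, reason)
    step_counts: dict = field(default_factory=dict)

    def n_removed(self) -> tuple[int, int]:
        return len(self.removed_samples), len(self.removed_snps)


def hwe_exact_counts(calls: np.ndarray) -> tuple[int, int, int]:
    c = calls[~np.isnan(calls)].astype(int)
    return int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum())


def hwe_stratified_test(calls: np.ndarray, strata) -> float:
    """Country-stratified 1-df HWE test; returns the upper-tail P-value.

    Within each stratum with >= 2 genotyped samples and both alleles
    present, the disequilibrium coefficient f = 1 - h_obs / h_exp is
    computed; strata are combined by inverse-variance weights (null
    variance 1/n), giving chi2 = (sum n_s f_s)^2 / sum n_s.
    """
    calls = np.asarray(calls, dtype=float)
    strata = np.asarray(strata, dtype=object)
    num = 0.0
    den = 0.0
    informative = 0
    for s in np.unique(strata):
        c = calls[strata == s]
        c = c[~np.isnan(c)]
        n = len(c)
        if n < 2:
            continue
        p = c.mean() / 2.0
        if p <= 0.0 or p >= 1.0:
            continue
        h_obs = float(np.mean(c == 1))
        h_exp = 2.0 * p * (1.0 - p)
        f = 1.0 - h_obs / h_exp
        num += n * f
        den += n
        informative += 1
    if informative == 0:
        raise MonomorphicInAllStrataError("SNP monomorphic (or unobserved) in all strata")
    chi2 = num**2 / den
    return float(stats.chi2.sf(chi2, df=1))


def _heterozygosity(values: np.ndarray) -> np.ndarray:
    obs = ~np.isnan(values)
    het = np.where(obs, values == 1.0, 0.0).sum(axis=1)
    n = obs.sum(axis=1)
    return np.divide(het, n, out=np.full(len(values), np.nan), where=n > 0)


def run_qc(
    phenotypes: list[CarrierRecord],
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    duplicates: list[tuple[str, str]] | None = None,
    exclusion_list: list[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the stepwise sample and SNP filters; returns the filtered
    matrix and a per-step report.

    ``duplicates`` are declared duplicate pairs (intended or cryptic, as
    identified upstream). ``exclusion_list`` stands in for filters that
    need data outside this model (e.g. inferred-gender errors).
    """
    th = thresholds or QCThresholds()
    duplicates = duplicates or []
    report = QCReport()
    strata_by_id = {r.sample_id: r.stratum for r in phenotypes}

    work = genotypes
    original = genotypes  # duplicate concordance uses pre-resolution calls

    def drop_samples(ids: list[str], reason: str) -> None:
        nonlocal work
        for s in ids:
            report.removed_samples.append((s, reason))
        keep = [s for s in work.samples if s not in set(ids)]
        work = work.subset_samples(keep)

    def drop_snps(ids: list[str], reason: str) -> None:
        nonlocal work
        for s in ids:
            report.removed_snps.append((s, reason))
        keep = [s for s in work.snp_ids if s not in set(ids)]
        work = work.subset_snps(keep)

    # step 0 (optional): user-supplied exclusions
    if exclusion_list:
        present = [s for s in exclusion_list if s in work.samples]
        drop_samples(present, "excluded_by_list")
        report.step_counts["exclusion_list"] = len(present)

    # step 1: sample call rate
    cr = work.sample_call_rate()
    bad = [s for s, c in zip(work.samples, cr) if c < th.sample_callrate_min]
    drop_samples(bad, "callrate_sample")
    report.step_counts["callrate_sample"] = len(bad)

    # step 2: heterozygosity outliers
    het = _heterozygosity(work.values)
    mu, sd = float(np.mean(het)), float(np.std(het))
    if sd > 0:
        lo, hi = mu - th.het_sd_band * sd, mu + th.het_sd_band * sd
        bad = [s for s, h in zip(work.samples, het) if h < lo or h > hi]
    else:
        bad = []
    drop_samples(bad, "heterozygosity")
    report.step_counts["heterozygosity"] = len(bad)

    # step 3: duplicate resolution, keep the higher-call-rate member
    bad = []
    for a, b in duplicates:
        if a in work.samples and b in work.samples:
            cra = work.sample_call_rate()[work.samples.index(a)]
            crb = work.sample_call_rate()[work.samples.index(b)]
            bad.append(b if cra >= crb else a)
    drop_samples(bad, "duplicate_sample")
    report.step_counts["duplicate_sample"] = len(bad)

    # step 4: SNP call rate
    scr = work.snp_call_rate()
    bad_snps = [s for s, c in zip(work.snp_ids, scr) if c < th.snp_callrate_min]
    drop_snps(bad_snps, "callrate_snp")
    report.step_counts["callrate_snp"] = len(bad_snps)

    # step 5: monomorphic SNPs
    freqs = work.allele2_freq()
    bad_snps = [s for s, p in zip(work.snp_ids, freqs) if not (0.0 < p < 1.0)]
    drop_snps(bad_snps, "monomorphic")
    report.step_counts["monomorphic"] = len(bad_snps)

    # step 6: stratified HWE
    strata = np.array([strata_by_id.get(s, "UNKNOWN") for s in work.samples], dtype=object)
    bad_snps = []
    for j, snp_id in enumerate(work.snp_ids):
        try:
            p = hwe_stratified_test(work.values[:, j], strata)
        except MonomorphicInAllStrataError:
            continue  # handled by step 5; unreachable for polymorphic SNPs
        if p < th.hwe_p_min:
            bad_snps.append(snp_id)
    drop_snps(bad_snps, "hwe")
    report.step_counts["hwe"] = len(bad_snps)

    # step 7: SNPs discordant among declared duplicates (pre-resolution calls)
    bad_snps = []
    for snp_id in work.snp_ids:
        col = original.column(snp_id)
        n_comp = 0
        n_conc = 0
        for a, b in duplicates:
            if a in original.samples and b in original.samples:
                va = col[original.samples.index(a)]
                vb = col[original.samples.index(b)]
                if not (np.isnan(va) or np.isnan(vb)):
                    n_comp += 1
                    n_conc += int(va == vb)
        if n_comp > 0 and n_conc / n_comp < th.duplicate_concordance_min:
            bad_snps.append(snp_id)
    drop_snps(bad_snps, "duplicate_discordance")
    report.step_counts["duplicate_discordance"] = len(bad_snps)

    if len(work.samples) == 0 or len(work.snps) == 0:
        raise QCEmptyError("quality control removed all samples or all SNPs")
    return work, report
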