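"""Synthetic clinic-ascertained carrier-family cohorts with known modifier
effects.

The generator emulates the sampling of high-risk mutation carriers through
cancer-genetics clinics: families (parents plus a sibship of carriers) are
recruited only when a designated proband is affected, which oversamples
affected women exactly as in real carrier cohorts. Founder genotypes are
drawn under HWE at the configured minor-allele frequencies; sibship
genotypes follow Mendelian transmission (so sibling allele sharing matches
the kinship expectation phi = 0.25). Onset ages for breast and ovarian
cancer are drawn from genotype-specific discrete yearly hazards whose
baseline is constrained so the cohort-average incidence equals the input
curves; the two diseases are independent competing processes given
genotype. Prophylactic surgery uptake, administrative censoring,
missingness, duplicate samples and allele-frequency-shifted ancestry
outliers are planted as configured and recorded in a truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import CarrierRecord, GenotypeMatrix, IncidenceCurve, SNPRecord
from .datasets import default_breast_incidence, default_ovarian_incidence
from .penetrance import constrain_categories

__all__ = ["SimConfig", "simulate_cohort"]

GRID_AGE0 = 18


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``sibship_size_distribution[k]`` is the probability of a sibship of
    size k+1. ``strata`` maps country labels to sampling weights. Surgery
    uptake is a constant per-year probability from the given start age;
    the default rates are modest clinic-typical uptakes (no published
    uptake model exists, so they are free parameters).
    """

    n_families: int = 500
    sibship_size_distribution: tuple = (0.5, 0.3, 0.2)
    maf: tuple = (0.25,)
    true_log_hr_bc: tuple = (0.0,)
    true_log_hr_oc: tuple = (0.0,)
    incidence_bc: IncidenceCurve | None = None
    incidence_oc: IncidenceCurve | None = None
    ascertainment: str = "proband_affected"
    mastectomy_rate: float = 0.005
    mastectomy_start_age: int = 30
    rrso_rate: float = 0.01
    rrso_start_age: int = 35
    missing_rate: float = 0.02
    n_duplicates: int = 0
    n_ancestry_outliers: int = 0
    outlier_freq_shift: float = 0.2
    strata: dict = field(default_factory=lambda: {"POP": 1.0})
    censor_age_range: tuple = (25.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.sibship_size_distribution) - 1.0) > 1e-9:
            raise ValueError("sibship size distribution must sum to 1")
        if self.ascertainment not in ("proband_affected", "random"):
            raise ValueError("ascertainment must be 'proband_affected' or 'random'")
        K = len(self.maf)
        if len(self.true_log_hr_bc) != K or len(self.true_log_hr_oc) != K:
            raise ValueError("per-SNP effect vectors must match the MAF vector length")
        for r in (self.mastectomy_rate, self.rrso_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        w = sum(self.strata.values())
        if w <= 0:
            raise ValueError("stratum weights must be positive")


def _population_baseline(curve: IncidenceCurve, maf: np.ndarray, beta: np.ndarray):
    """Baseline hazard such that the HWE-average incidence equals the curve.

    Only loci with a non-zero effect widen the joint hazard-ratio
    distribution, so the enumeration runs over those alone.
    """
    active = np.nonzero(beta != 0.0)[0]
    if len(active) == 0:
        lam0, _ = constrain_categories(curve.rate, np.ones(1), np.ones(1))
        return lam0
    if len(active) > 15:
        raise ValueError("more than 15 loci with non-zero effects is unsupported")
    K = len(active)
    grids = np.indices((3,) * K).reshape(K, -1).T
    probs = np.ones(len(grids))
    for k, snp in enumerate(active):
        p = maf[snp]
        pk = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
        probs *= pk[grids[:, k]]
    hrs = np.exp(grids @ beta[active])
    lam0, _ = constrain_categories(curve.rate, probs, hrs)
    return lam0


def _sample_onsets(lam0: np.ndarray, rr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling of onset ages on the yearly grid; inf = no event
    by the end of the grid."""
    T = len(lam0)
    # per-individual yearly log-survival; rr is (N,)
    haz = np.outer(rr, lam0)  # (N, T)
    np.clip(haz, 0.0, 1.0 - 1e-12, out=haz)
    F = 1.0 - np.cumprod(1.0 - haz, axis=1)
    u = rng.random(len(rr))
    idx = (F < u[:, None]).sum(axis=1)  # first year with F >= u
    onset = np.where(idx < T, GRID_AGE0 + idx, np.inf).astype(float)
    return onset


def _surgery_age(rate: float, start_age: int, n: int, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0.0:
        return np.full(n, np.inf)
    return start_age + rng.geometric(rate, size=n) - 1.0


def simulate_cohort(config: SimConfig):
    """Generate one synthetic cohort.

    Returns ``(records, genotypes, truth)`` where ``truth`` holds every
    latent parameter and planted defect: true effects, founder MAFs, raw
    onset/surgery ages, proband ids, duplicate pairs, outlier ids, and the
    complete (pre-missingness) genotype matrix.
    """
    rng = np.random.default_rng(config.seed)
    curve_b = config.incidence_bc or default_breast_incidence()
    curve_o = config.incidence_oc or default_ovarian_incidence()
    maf = np.asarray(config.maf, dtype=float)
    beta_b = np.asarray(config.true_log_hr_bc, dtype=float)
    beta_o = np.asarray(config.true_log_hr_oc, dtype=float)
    K = len(maf)

    lam0_b = _population_baseline(curve_b, maf, beta_b)
    lam0_o = _population_baseline(curve_o, maf, beta_o)

    nf = config.n_families
    sizes = rng.choice(
        np.arange(1, len(config.sibship_size_distribution) + 1),
        size=nf,
        p=np.asarray(config.sibship_size_distribution, dtype=float),
    )
    N = int(sizes.sum())
    fam_of = np.repeat(np.arange(nf), sizes)

    # founder (parental) alleles and Mendelian transmission to the sibship
    mother = rng.random((nf, K, 2)) < maf[None, :, None]
    father = rng.random((nf, K, 2)) < maf[None, :, None]
    pick_m = rng.integers(0, 2, size=(N, K))
    pick_f = rng.integers(0, 2, size=(N, K))
    gm = np.take_along_axis(mother[fam_of], pick_m[:, :, None], axis=2)[:, :, 0]
    gf = np.take_along_axis(father[fam_of], pick_f[:, :, None], axis=2)[:, :, 0]
    G = (gm.astype(int) + gf.astype(int)).astype(float)  # (N, K)

    labels = list(config.strata)
    weights = np.array([config.strata[s] for s in labels], dtype=float)
    fam_stratum = rng.choice(labels, size=nf, p=weights / weights.sum())

    rr_b = np.exp(G @ beta_b)
    rr_o = np.exp(G @ beta_o)
    onset_b = _sample_onsets(lam0_b, rr_b, rng)
    onset_o = _sample_onsets(lam0_o, rr_o, rng)
    mast = _surgery_age(config.mastectomy_rate, config.mastectomy_start_age, N, rng)
    rrso = _surgery_age(config.rrso_rate, config.rrso_start_age, N, rng)
    lo, hi = config.censor_age_range
    censor = rng.uniform(lo, hi, size=N)

    def observed(onset, surgery, censor):
        """Event observed iff before surgery and before censoring (event
        priority on ties); surgery observed iff before onset and censoring."""
        ev = (onset <= censor) & (onset <= surgery)
        sg = (~ev) & (surgery <= censor)
        return ev, sg

    ev_b, sg_m = observed(onset_b, mast, censor)
    ev_o, sg_r = observed(onset_o, rrso, censor)

    records: list[CarrierRecord] = []
    for i in range(N):
        f = fam_of[i]
        records.append(
            CarrierRecord(
                sample_id=f"S{i:06d}",
                family_id=f"F{f:05d}",
                stratum=str(fam_stratum[f]),
                birth_year=int(1990 - np.floor(censor[i])),
                age_last_followup=float(censor[i]),
                age_bc=float(onset_b[i]) if ev_b[i] else None,
                age_oc=float(onset_o[i]) if ev_o[i] else None,
                age_mastectomy=float(mast[i]) if sg_m[i] else None,
                age_rrso=float(rrso[i]) if sg_r[i] else None,
            )
        )

    affected = ev_b | ev_o

    # ascertainment: retain a family only if a designated proband (the
    # eldest affected member) exists
    keep = np.ones(N, dtype=bool)
    probands: list[str] = []
    if config.ascertainment == "proband_affected":
        keep[:] = False
        for f in range(nf):
            m = (fam_of == f) & affected
            if m.any():
                idx = np.nonzero(m)[0]
                eldest = idx[np.argmax(censor[idx])]
                probands.append(records[eldest].sample_id)
                keep[fam_of == f] = True

    kept_idx = np.nonzero(keep)[0]
    records = [records[i] for i in kept_idx]
    G = G[kept_idx]

    # planted duplicates (genotype-identical before missingness)
    dup_pairs: list[tuple[str, str]] = []
    if config.n_duplicates > 0 and len(records) > 0:
        chosen = rng.choice(len(records), size=min(config.n_duplicates, len(records)), replace=False)
        for c in chosen:
            src = records[c]
            dup = CarrierRecord(**{f: getattr(src, f) for f in src.__dataclass_fields__})
            dup.sample_id = src.sample_id + "_dup"
            records.append(dup)
            G = np.vstack([G, G[c][None, :]])
            dup_pairs.append((src.sample_id, dup.sample_id))

    # planted ancestry outliers: singletons from an allele-frequency-shifted
    # population, phenotypes under the same constrained hazards
    outlier_ids: list[str] = []
    if config.n_ancestry_outliers > 0:
        no = config.n_ancestry_outliers
        maf_out = np.clip(maf + config.outlier_freq_shift, 0.01, 0.99)
        Gout = (
            (rng.random((no, K)) < maf_out).astype(int)
            + (rng.random((no, K)) < maf_out).astype(int)
        ).astype(float)
        rr_bo = np.exp(Gout @ beta_b)
        rr_oo = np.exp(Gout @ beta_o)
        ob = _sample_onsets(lam0_b, rr_bo, rng)
        oo = _sample_onsets(lam0_o, rr_oo, rng)
        co = rng.uniform(lo, hi, size=no)
        for j in range(no):
            sid = f"OUT{j:04d}"
            outlier_ids.append(sid)
            records.append(
                CarrierRecord(
                    sample_id=sid,
                    family_id=f"FOUT{j:04d}",
                    stratum=str(labels[0]),
                    birth_year=int(1990 - np.floor(co[j])),
                    age_last_followup=float(co[j]),
                    age_bc=float(ob[j]) if ob[j] <= co[j] else None,
                    age_oc=float(oo[j]) if oo[j] <= co[j] else None,
                )
            )
        G = np.vstack([G, Gout])

    G_complete = G.copy()
    if config.missing_rate > 0:
        mask = rng.random(G.shape) < config.missing_rate
        G = G.copy()
        G[mask] = np.nan

    snps = [
        SNPRecord(snp_id=f"snp{k + 1}", chrom="1", pos=1000 * (k + 1), allele1="A", allele2="B")
        for k in range(K)
    ]
    matrix = GenotypeMatrix(
        samples=[r.sample_id for r in records], snps=snps, values=G
    )

    truth = {
        "seed": config.seed,
        "maf": maf.tolist(),
        "true_log_hr_bc": beta_b.tolist(),
        "true_log_hr_oc": beta_o.tolist(),
        "ascertainment": config.ascertainment,
        "probands": probands,
        "duplicate_pairs": dup_pairs,
        "outlier_ids": outlier_ids,
        "n_families_retained": int(len(set(r.family_id for r in records))),
        "onset_bc": onset_b[kept_idx],
        "onset_oc": onset_o[kept_idx],
        "censor": censor[kept_idx],
        "genotypes_complete": G_complete,
        "baseline_bc": lam0_b,
        "baseline_oc": lam0_o,
    }
    return records, matrix, truth
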