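"""Retrospective-likelihood association testing and HR estimation.

Carrier cohorts are typically sampled through clinics, which oversamples
affected women; prospective (Cox-type) likelihoods are then biased. The
remedy is to model the probability of the observed *genotypes conditional
on the phenotypes*:

    L_i = P(d_i, t_i | g_i) P(g_i) / sum_g' P(d_i, t_i | g') P(g')

where P(g) is HWE at the stratum allele frequency and P(d, t | g) is the
discrete-time survival likelihood under the genotype-specific hazard
lambda0(t) * rr_g, with the baseline lambda0 constrained at every age so the
cohort-average hazard equals the published incidence curve.

The 1-df score test is the derivative of this log-likelihood at beta = 0.
Because the null phenotype likelihood does not depend on genotype, the score
reduces to

    U = sum_i w_i (g_i - 2 p_hat),   w_i = delta_i - sum_{u in risk years}
                                            lambda(u) / (1 - lambda(u)),

a discrete-time martingale residual weight. Plugging the per-stratum sample
allele frequency makes U the exact derivative of the plug-in log-likelihood
and centres the score within stratum, which keeps the null distribution
calibrated under affected-biased sampling. The variance is adjusted for
relatedness with genomic kinship (cov(g_i, g_j) = 2 phi_ij Var(g)) and,
separately, with a family-cluster sandwich.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data import CarrierRecord, GenotypeMatrix, IncidenceCurve, endpoint_view
from .penetrance import constrain_baseline

logger = logging.getLogger(__name__)

__all__ = [
    "MonomorphicSNPError",
    "ScoreTestResult",
    "RetrospectiveHazardsModel",
    "RetrospectiveResults",
]


class MonomorphicSNPError(ValueError):
    """The tested SNP has no variation among the analysis samples."""


@dataclass
class ScoreTestResult:
    """1-df score test with kinship-adjusted and robust variances."""

    U: float
    V_kin: float
    V_rob: float
    chi2: float
    p_value: float
    n_used: int
    chi2_rob: float = np.nan
    p_value_rob: float = np.nan


def _dosage_weights(g: np.ndarray) -> np.ndarray:
    """Nearest genotype-probability decomposition of a dosage column.

    Returns (n, 3) soft counts q with mean allele count equal to the dosage;
    hard calls map to indicator rows.
    """
    q = np.zeros((len(g), 3))
    lo = g <= 1.0
    q[lo, 0] = 1.0 - g[lo]
    q[lo, 1] = g[lo]
    q[~lo, 1] = 2.0 - g[~lo]
    q[~lo, 2] = g[~lo] - 1.0
    return q


class RetrospectiveHazardsModel:
    """Single-disease retrospective-likelihood model for one SNP.

    Parameters
    ----------
    times, events : follow-up age and affection status per carrier, under
        the disease-specific censoring convention (see ``endpoint_view``).
    genotypes : allele-2 counts (0/1/2) or dosages in [0, 2]; NaN = missing.
        Missing genotypes contribute nothing to the likelihood or score.
    strata : country / super-stratum label per carrier.
    incidence : one average incidence curve, or a mapping stratum -> curve.
    kinship : optional (n, n) kinship coefficient matrix aligned with the
        input order (phi; 0.5 on the diagonal for non-inbred samples).
    families : optional family labels for the robust cluster variance.
    freq_mode : 'sample' (default) plugs the per-stratum analysis-sample
        allele frequency; 'unaffected' uses unaffected carriers only
        (falling back to all samples in strata with no unaffected carriers).
    """

    def __init__(
        self,
        times: np.ndarray,
        events: np.ndarray,
        genotypes: np.ndarray,
        strata: Sequence[str] | None = None,
        incidence: IncidenceCurve | dict | None = None,
        kinship: np.ndarray | None = None,
        families: Sequence[str] | None = None,
        freq_mode: str = "sample",
        disease: str = "breast",
    ) -> None:
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=bool)
        genotypes = np.asarray(genotypes, dtype=float)
        n = len(times)
        if not (len(events) == len(genotypes) == n):
            raise ValueError("times, events and genotypes must have equal length")
        if strata is None:
            strata = ["ALL"] * n
        if incidence is None:
            raise ValueError("an incidence curve is required")
        if freq_mode not in ("sample", "unaffected"):
            raise ValueError("freq_mode must be 'sample' or 'unaffected'")
        self.disease = disease
        self.freq_mode = freq_mode
        self.n_total = n

        used = ~np.isnan(genotypes)
        if kinship is not None:
            kinship = np.asarray(kinship, dtype=float)
            if kinship.shape != (n, n):
                raise ValueError("kinship matrix must be square over all input samples")
            kinship = kinship[np.ix_(used.nonzero()[0], used.nonzero()[0])]
        self.kinship = kinship
        self.times = times[used]
        self.events = events[used]
        self.g = genotypes[used]
        self.strata = np.asarray(strata, dtype=object)[used]
        self.families = (
            np.asarray(families, dtype=object)[used]
            if families is not None
            else np.array([f"__s{i}" for i in range(used.sum())], dtype=object)
        )
        self.n_used = int(used.sum())
        if self.n_used == 0:
            raise ValueError("no samples with observed genotypes")

        self._curves: dict[str, IncidenceCurve] = {}
        labels = sorted(set(self.strata.tolist()), key=str)
        for s in labels:
            curve = incidence[s] if isinstance(incidence, dict) else incidence
            self._curves[s] = curve
        self.stratum_labels = labels

        # yearly grid index per individual (floored ages, clipped to grid)
        self._tidx = {}
        self._freq = {}
        for s in labels:
            m = self.strata == s
            curve = self._curves[s]
            a0 = int(curve.ages[0])
            ti = np.clip(np.floor(self.times[m]).astype(int) - a0, 0, len(curve.ages) - 1)
            self._tidx[s] = ti
            gs = self.g[m]
            if freq_mode == "unaffected":
                unaff = ~self.events[m]
                pool = gs[unaff] if unaff.any() else gs
                if not unaff.any():
                    logger.warning(
                        "stratum %s has no unaffected carriers; allele frequency "
                        "estimated from all samples",
                        s,
                    )
            else:
                pool = gs
            self._freq[s] = float(np.mean(pool) / 2.0)
        if all(f <= 0.0 or f >= 1.0 for f in self._freq.values()) or np.all(
            self.g == self.g[0]
        ):
            raise MonomorphicSNPError("SNP is monomorphic among the analysis samples")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_cohort(
        cls,
        records: Sequence[CarrierRecord],
        genotypes: GenotypeMatrix,
        snp_id: str,
        disease: str,
        incidence: IncidenceCurve | dict,
        kinship: np.ndarray | None = None,
        **kwargs,
    ) -> "RetrospectiveHazardsModel":
        """Build the model from carrier records and a genotype matrix.

        Samples are intersected by id (mismatches are logged, not fatal).
        """
        geno_ids = set(genotypes.samples)
        kept = [r for r in records if r.sample_id in geno_ids]
        if len(kept) < len(records):
            logger.info(
                "%d phenotype records without genotypes dropped", len(records) - len(kept)
            )
        sub = genotypes.subset_samples([r.sample_id for r in kept])
        views = [endpoint_view(r, disease) for r in kept]
        if kinship is not None and kinship.shape[0] != len(kept):
            raise ValueError("kinship matrix does not cover the analysis samples")
        return cls(
            times=np.array([v.time for v in views]),
            events=np.array([v.affected for v in views]),
            genotypes=sub.column(snp_id),
            strata=[r.stratum for r in kept],
            incidence=incidence,
            kinship=kinship,
            families=[r.family_id for r in kept],
            disease=disease,
            **kwargs,
        )

    # -- likelihood --------------------------------------------------------

    def _per_genotype_logf(self, s: str, beta) -> np.ndarray:
        return self._per_genotype_logf_at(s, beta, self._freq[s])

    def _per_genotype_logf_at(self, s: str, beta, p: float) -> np.ndarray:
        """log P(d, t | g) for every individual in stratum s, shape (n_s, 3)."""
        curve = self._curves[s]
        pm = constrain_baseline(curve, p, beta)
        with np.errstate(divide="ignore"):
            log1m = np.log1p(-np.outer(pm.rr, pm.lambda0))  # (3, T)
            logh = np.log(np.outer(pm.rr, pm.lambda0))
        cum = np.cumsum(log1m, axis=1)  # inclusive of year t
        ti = self._tidx[s]
        ev = self.events[self.strata == s]
        out = np.empty((len(ti), 3))
        # censored at year t: survived years a0..t
        out[~ev] = cum[:, ti[~ev]].T
        # event in year t: survived a0..t-1, event hazard at t
        te = ti[ev]
        prev = np.where(te > 0, cum[:, np.maximum(te - 1, 0)], 0.0)
        prev[:, te == 0] = 0.0
        out[ev] = (prev + logh[:, te]).T
        return out

    def loglik(self, beta, freqs: dict | None = None) -> float:
        """Retrospective log-likelihood at ``beta`` (scalar per-allele, or
        (log hr het, log hr hom)), with the baseline re-constrained.

        ``freqs`` optionally overrides the per-stratum allele frequencies
        (used when profiling them out of the likelihood).
        """
        freqs = freqs if freqs is not None else self._freq
        total = 0.0
        for s in self.stratum_labels:
            m = self.strata == s
            p = freqs[s]
            logf = self._per_genotype_logf_at(s, beta, p)
            logpi = np.log(np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p]))
            a = logf + logpi  # (n_s, 3)
            amax = a.max(axis=1, keepdims=True)
            logden = amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))
            q = _dosage_weights(self.g[m])
            lognum = (q * a).sum(axis=1)
            contrib = lognum - logden
            if not np.all(np.isfinite(contrib)):
                bad = np.nonzero(~np.isfinite(contrib))[0][0]
                raise ValueError(
                    f"non-finite likelihood contribution in stratum {s}, "
                    f"local record {bad} (event at a zero-hazard age?)"
                )
            total += float(contrib.sum())
        return total

    # -- score test --------------------------------------------------------

    def _null_weights(self) -> np.ndarray:
        """Martingale-residual score weights at beta = 0, per individual."""
        w = np.empty(self.n_used)
        for s in self.stratum_labels:
            m = self.strata == s
            lam = self._curves[s].rate
            r = lam / (1.0 - lam)
            K = np.cumsum(r)
            ti = self._tidx[s]
            ev = self.events[m]
            ws = np.where(
                ev,
                1.0 - np.where(ti > 0, K[np.maximum(ti - 1, 0)], 0.0),
                -K[ti],
            )
            w[m] = ws
        return w

    def score_test(self) -> ScoreTestResult:
        """Kinship-adjusted 1-df score test at the null of no association.

        Accepts hard calls and dosages identically (the score is linear in
        the expected allele count).
        """
        w = self._null_weights()
        wt = np.empty_like(w)
        c = np.empty_like(w)
        sig = np.empty_like(w)
        U = 0.0
        V_diag = 0.0
        for s in self.stratum_labels:
            m = self.strata == s
            ws = w[m] - w[m].mean()
            cs = self.g[m] - 2.0 * self._freq[s]
            wt[m] = ws
            c[m] = cs
            sw2 = float(np.sum(ws**2))
            var_g = float(np.sum(ws**2 * cs**2) / sw2) if sw2 > 0 else 0.0
            sig[m] = np.sqrt(var_g)
            U += float(np.sum(ws * cs))
            V_diag += float(np.sum(ws**2)) * var_g
        if np.allclose(c, 0.0):
            raise MonomorphicSNPError("SNP is monomorphic among the analysis samples")

        if self.kinship is None:
            V_kin = V_diag
        else:
            z = wt * sig
            V_kin = float(z @ (2.0 * self.kinship) @ z)

        u_i = wt * c
        V_rob = 0.0
        for f in np.unique(self.families):
            V_rob += float(u_i[self.families == f].sum() ** 2)

        chi2 = U**2 / V_kin if V_kin > 0 else np.nan
        chi2_rob = U**2 / V_rob if V_rob > 0 else np.nan
        return ScoreTestResult(
            U=U,
            V_kin=V_kin,
            V_rob=V_rob,
            chi2=chi2,
            p_value=float(stats.chi2.sf(chi2, df=1)) if np.isfinite(chi2) else np.nan,
            n_used=self.n_used,
            chi2_rob=chi2_rob,
            p_value_rob=float(stats.chi2.sf(chi2_rob, df=1))
            if np.isfinite(chi2_rob)
            else np.nan,
        )

    # -- maximum likelihood ------------------------------------------------

    def fit(
        self,
        model: str = "per_allele",
        maxiter: int = 50,
        tol: float = 1e-8,
        profile_freq: bool = False,
    ):
        """Maximise the retrospective likelihood by Newton-Raphson.

        The baseline constraint is re-solved at every candidate beta;
        derivatives are central finite differences; steps are halved when
        the log-likelihood decreases.

        ``profile_freq=True`` estimates the per-stratum allele frequencies
        jointly with beta (on the logit scale) instead of plugging the
        sample frequencies in. Under strong affected-biased sampling the
        plug-in frequency is itself distorted by the ascertainment, which
        the joint maximum corrects.
        """
        if model == "per_allele":
            k_beta = 1
            unpack = lambda th: float(th[0])
        elif model == "genotype_specific":
            k_beta = 2
            unpack = lambda th: (float(th[0]), float(th[1]))
        else:
            raise ValueError("model must be 'per_allele' or 'genotype_specific'")

        if not profile_freq:
            f = lambda th: self.loglik(unpack(th))
            theta0 = np.zeros(k_beta)
        else:
            labels = self.stratum_labels

            def f(th):
                freqs = {
                    s: 1.0 / (1.0 + np.exp(-th[k_beta + i])) for i, s in enumerate(labels)
                }
                return self.loglik(unpack(th), freqs=freqs)

            p0 = np.array([self._freq[s] for s in labels])
            p0 = np.clip(p0, 1e-4, 1 - 1e-4)
            theta0 = np.concatenate([np.zeros(k_beta), np.log(p0 / (1 - p0))])

        theta, ll, converged, hess = _newton_maximize(f, theta0, maxiter=maxiter, tol=tol)
        th0 = theta.copy()
        th0[:k_beta] = 0.0
        ll0 = f(th0)
        return RetrospectiveResults(
            model_obj=self,
            model_kind=model,
            params=theta[:k_beta],
            loglik=ll,
            loglik_null=ll0,
            converged=converged,
            hessian=hess,
            n_beta=k_beta,
        )


def _numeric_grad(f, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(theta)
    for k in range(len(theta)):
        e = np.zeros_like(theta)
        e[k] = h
        g[k] = (f(theta + e) - f(theta - e)) / (2 * h)
    return g


def _numeric_hess(f, theta: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(theta)
    H = np.zeros((k, k))
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros_like(theta)
        ei[i] = h
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros_like(theta)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h**2)
    return H


def _newton_maximize(f, theta0: np.ndarray, maxiter: int = 50, tol: float = 1e-8):
    theta = theta0.astype(float).copy()
    ll = f(theta)
    converged = False
    H = None
    for _ in range(maxiter):
        g = _numeric_grad(f, theta)
        H = _numeric_hess(f, theta)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            break
        # step halving on likelihood decrease
        lam = 1.0
        for _ in range(30):
            cand = theta + lam * step
            llc = f(cand)
            if llc >= ll - 1e-12:
                break
            lam *= 0.5
        else:
            break
        moved = float(np.max(np.abs(lam * step)))
        theta, ll = cand, llc
        if moved < tol:
            converged = True
            break
    if H is None:
        H = _numeric_hess(f, theta)
    else:
        H = _numeric_hess(f, theta)
    return theta, ll, converged, H


@dataclass
class RetrospectiveResults:
    """MLE results: log-HRs, observed-information CIs, and diagnostics."""

    model_obj: RetrospectiveHazardsModel
    model_kind: str
    params: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    hessian: np.ndarray
    n_beta: int = 1

    def __post_init__(self) -> None:
        info = -self.hessian
        try:
            cov = np.linalg.inv(info)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))[: self.n_beta]
        except np.linalg.LinAlgError:
            bse = np.full(self.n_beta, np.nan)
        self.bse = bse

    # exp-scale accessors -------------------------------------------------

    @property
    def hr_per_allele(self) -> float:
        return float(np.exp(self.params[0])) if self.model_kind == "per_allele" else np.nan

    @property
    def ci95(self) -> tuple[float, float]:
        lo = self.params - 1.959963984540054 * self.bse
        hi = self.params + 1.959963984540054 * self.bse
        return (float(np.exp(lo[0])), float(np.exp(hi[0])))

    @property
    def hr_het(self) -> float:
        if self.model_kind == "genotype_specific":
            return float(np.exp(self.params[0]))
        return float(np.exp(self.params[0]))

    @property
    def hr_hom(self) -> float:
        if self.model_kind == "genotype_specific":
            return float(np.exp(self.params[1]))
        return float(np.exp(2 * self.params[0]))

    def lr_test(self) -> tuple[float, float]:
        """Likelihood-ratio chi-square against beta = 0 (df = #params)."""
        lr = 2.0 * (self.loglik - self.loglik_null)
        df = len(self.params)
        return lr, float(stats.chi2.sf(max(lr, 0.0), df=df))

    def summary(self) -> str:
        lines = [
            "Retrospective hazards model ({})".format(self.model_kind),
            f"  disease: {self.model_obj.disease}   n used: {self.model_obj.n_used}",
            f"  log-likelihood: {self.loglik:.4f}  (null {self.loglik_null:.4f})",
            f"  converged: {self.converged}",
        ]
        if self.model_kind == "per_allele":
            lo, hi = self.ci95
            lines.append(
                f"  per-allele HR: {self.hr_per_allele:.4f}  95% CI ({lo:.4f}, {hi:.4f})"
            )
        else:
            lines.append(f"  heterozygote HR: {self.hr_het:.4f}")
            lines.append(f"  homozygote  HR: {self.hr_hom:.4f}")
            lr, p = self.lr_test()
            lines.append(f"  2-df LRT chi2 = {lr:.3f}, P = {p:.3g}")
        return "\n".join(lines)
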