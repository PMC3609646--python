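"""Genomic kinship estimation, multidimensional scaling and ancestry exclusion.

Pairwise kinship is estimated from a panel of weakly correlated SNPs with
the allele-frequency-standardised estimator

    phi_ij = mean_k (g_ik - 2 p_k)(g_jk - 2 p_k) / (4 p_k (1 - p_k)),

which gives ~0.5 for duplicates, ~0.25 for parent-offspring pairs and ~0
for unrelated pairs. Kinship is converted to a distance (0.5 - phi, floored
at zero so duplicates sit at distance 0) and subjected to classical metric
scaling together with labelled reference panels. The proportion of European
ancestry of each sample is its projection onto the segment joining the
European reference centroid and the nearest non-European centroid in the
first two components; samples with more than a threshold fraction (default
22%) of non-European ancestry are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "KinshipMatrix",
    "AncestryResult",
    "prune_by_r2",
    "genomic_kinship",
    "mds_ancestry",
]


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    phi: np.ndarray  # symmetric (n, n) kinship coefficients

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.sample_ids)
        if self.phi.shape != (n, n):
            raise ValueError("kinship matrix shape mismatch")

    def align(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids])
        return self.phi[np.ix_(idx, idx)]


@dataclass
class AncestryResult:
    sample_id: str
    coordinates: tuple[float, float]
    euro_fraction: float
    excluded: bool


def prune_by_r2(matrix: GenotypeMatrix, r2_max: float = 0.10) -> list[str]:
    """Greedy LD pruning: keep a SNP iff its r-squared with every previously
    kept SNP is below ``r2_max`` (input order).

    Correlations are computed on mean-imputed, standardised columns (missing
    cells contribute nothing), which is the usual approximation for pruning.
    """
    vals = matrix.values
    n, m = vals.shape
    mu = np.nanmean(vals, axis=0)
    z = np.where(np.isnan(vals), 0.0, vals - mu)
    norms = np.sqrt((z**2).sum(axis=0))
    kept: list[int] = []
    Z = np.empty((n, 0))
    for j in range(m):
        if norms[j] == 0:
            continue
        zj = z[:, j] / norms[j]
        if Z.shape[1]:
            r = zj @ Z
            if np.any(r * r >= r2_max):
                continue
        kept.append(j)
        Z = np.column_stack([Z, zj])
    ids = matrix.snp_ids
    return [ids[j] for j in kept]


def genomic_kinship(
    matrix: GenotypeMatrix, prune_r2: float | None = 0.10, min_snps: int = 100
) -> KinshipMatrix:
    """Allele-frequency-standardised kinship from LD-pruned autosomal SNPs.

    Missing cells are pairwise-deleted; monomorphic SNPs are skipped (count
    logged). The diagonal uses the same standardised form, ~0.5 for
    non-inbred samples. ``prune_r2=None`` skips pruning (for panels already
    pruned upstream; note that greedy pruning on *sample* correlations in
    small cohorts preferentially discards SNPs with chance correlations and
    deflates kinship estimates).
    """
    keep = matrix.snp_ids if prune_r2 is None else prune_by_r2(matrix, prune_r2)
    sub = matrix.subset_snps(keep)
    vals = sub.values
    p = sub.allele2_freq()
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("skipping %d monomorphic SNPs in kinship estimation", n_mono)
    vals = vals[:, poly]
    p = p[poly]
    if vals.shape[1] < min_snps:
        raise ValueError(
            f"only {vals.shape[1]} SNPs remain after pruning; >= {min_snps} required"
        )
    z = (vals - 2 * p) / (2.0 * np.sqrt(p * (1 - p)))
    obs = ~np.isnan(z)
    z0 = np.where(obs, z, 0.0)
    num = z0 @ z0.T
    cnt = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = num / cnt
    phi[cnt == 0] = 0.0
    return KinshipMatrix(sample_ids=list(matrix.samples), phi=phi)


def _classical_mds(D: np.ndarray, k: int = 2) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(lam)


def mds_ancestry(
    kinship: KinshipMatrix,
    reference_labels: dict[str, str],
    threshold: float = 0.22,
    european_panel: str = "CEU",
) -> list[AncestryResult]:
    """Classical scaling of kinship distances and per-sample European fraction.

    ``reference_labels`` maps reference sample ids to panel names; exactly
    one panel must be the designated European panel and at least one other
    panel must be present. Study samples are all ids without a label.
    """
    panels = set(reference_labels.values())
    if european_panel not in panels:
        raise ValueError(f"no samples labelled with the European panel {european_panel!r}")
    if panels == {european_panel}:
        raise ValueError("at least one non-European reference panel is required")

    D = np.clip(0.5 - kinship.phi, 0.0, None)
    np.fill_diagonal(D, 0.0)
    X = _classical_mds(D, k=2)

    ids = kinship.sample_ids
    centroids: dict[str, np.ndarray] = {}
    for panel in panels:
        idx = [i for i, s in enumerate(ids) if reference_labels.get(s) == panel]
        centroids[panel] = X[idx].mean(axis=0)

    # orientation convention: European centroid non-negative on each axis
    for d in range(2):
        if centroids[european_panel][d] < 0:
            X[:, d] *= -1.0
            for panel in centroids:
                centroids[panel] = centroids[panel].copy()
                centroids[panel][d] *= -1.0

    E = centroids[european_panel]
    others = {p: c for p, c in centroids.items() if p != european_panel}
    results = []
    for i, s in enumerate(ids):
        x = X[i]
        nearest = min(others.values(), key=lambda c: float(np.sum((x - c) ** 2)))
        seg = E - nearest
        denom = float(seg @ seg)
        t = float((x - nearest) @ seg) / denom if denom > 0 else 1.0
        ef = float(np.clip(t, 0.0, 1.0))
        results.append(
            AncestryResult(
                sample_id=s,
                coordinates=(float(x[0]), float(x[1])),
                euro_fraction=ef,
                excluded=(1.0 - ef) > threshold,
            )
        )
    return results
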