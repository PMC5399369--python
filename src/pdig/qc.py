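"""Genotype quality control and population-structure assessment.

Implements the standard candidate-SNP QC battery: minor-allele frequency,
the exact conditional Hardy-Weinberg test, per-SNP/per-subject missingness,
and identity-by-state (IBS) distances with classical multidimensional
scaling for detecting population stratification.

Default thresholds follow common imaging-genetics practice: SNPs with
MAF < 1%, exact HWE p < 1e-6, or missing rate > 5% are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pdig.genotypes import GenotypeMatrix

__all__ = [
    "compute_maf",
    "compute_missing_rates",
    "hwe_exact_pvalue",
    "apply_snp_qc",
    "ibs_distance",
    "classical_mds",
    "QcReport",
    "MdsEmbedding",
]


def compute_maf(g: GenotypeMatrix) -> pd.Series:
    """Per-SNP minor-allele frequency, folded to [0, 0.5].

    MAF = (count of coded-allele copies) / (2 x non-missing subjects), then
    folded to min(f, 1-f): the minor allele is determined empirically from
    post-missingness counts, with ties at 0.5 keeping the declared coding.
    SNPs whose calls are all missing get NaN.
    """
    calls = g.calls.to_numpy()
    n_obs = (~np.isnan(calls)).sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nansum(calls, axis=0) / (2.0 * n_obs)
    maf = np.minimum(freq, 1.0 - freq)
    maf[n_obs == 0] = np.nan
    return pd.Series(maf, index=g.snp_ids, name="maf")


def compute_missing_rates(g: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """(per-SNP, per-subject) missing-call proportions."""
    isna = g.calls.isna()
    snp_rates = isna.mean(axis=0).rename("missing_rate")
    subject_rates = isna.mean(axis=1).rename("call_missing_rate")
    return snp_rates, subject_rates


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (with the parity the allele counts force) whose
    conditional probability does not exceed that of the observed table.
    This is the exact test of Wigginton, Cutler & Abecasis (2005), the
    standard replacement for the chi-square approximation at low MAF.

    Parameters are genotype counts: homozygous major, heterozygous,
    homozygous minor.  Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped subject")
    # rare-allele copy count; symmetric in which homozygote is 'minor'
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # support: heterozygote counts share the parity of n_rare
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = list(range(het_min, het_max + 1, 2))

    # unnormalized probabilities via the standard recurrence:
    # P(h+2)/P(h) = [ (r-h)/2 * (n - (r+h)/2) * 4 ] / [ (h+2)(h+1) ]
    # computed from the mode outward for numerical stability.
    probs = {h: 0.0 for h in hets}
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mid % 2 != het_min:
        mid += 1 if mid < het_max else -1
    mid = min(max(mid, het_min), het_max)
    probs[mid] = 1.0
    for h in range(mid, het_max, 2):  # ascend
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    for h in range(mid, het_min, -2):  # descend
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))

    total = math.fsum(probs.values())
    p_obs = probs[n_Aa] / total
    tail = math.fsum(p / total for p in probs.values() if p / total <= p_obs * (1 + 1e-12))
    return min(1.0, tail)


@dataclass
class QcReport:
    """Outcome of SNP-level QC.

    Per-criterion failure lists are non-exclusive: a SNP violating two
    filters appears under both, but is removed from the matrix once.
    """

    maf_min: float
    hwe_min_p: float
    miss_max: float
    failed_maf: list[str] = field(default_factory=list)
    failed_hwe: list[str] = field(default_factory=list)
    failed_missing: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    subject_missing_rates: pd.Series | None = None
    convention: str = (
        "per-criterion counts are marginal (non-exclusive); "
        "the union of failing SNPs is removed once"
    )

    @property
    def removed(self) -> list[str]:
        seen: dict[str, None] = {}
        for snp in self.failed_maf + self.failed_hwe + self.failed_missing:
            seen.setdefault(snp)
        return list(seen)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "maf": len(self.failed_maf),
            "hwe": len(self.failed_hwe),
            "missing": len(self.failed_missing),
            "removed": len(self.removed),
            "retained": len(self.retained),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for snp in self.removed:
            rows.append(
                {
                    "snp_id": snp,
                    "failed_maf": snp in set(self.failed_maf),
                    "failed_hwe": snp in set(self.failed_hwe),
                    "failed_missing": snp in set(self.failed_missing),
                }
            )
        return pd.DataFrame(rows, columns=["snp_id", "failed_maf", "failed_hwe", "failed_missing"])


def apply_snp_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_min_p: float = 1e-6,
    miss_max: float = 0.05,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs failing MAF, exact-HWE, or missingness filters.

    A SNP is removed iff MAF < ``maf_min`` OR exact HWE p < ``hwe_min_p``
    OR missing rate > ``miss_max``.  All-missing SNPs fail missingness (and
    have undefined MAF).  Subject-level call rates are reported but no
    subject is dropped here.
    """
    for name, val in (("maf_min", maf_min), ("hwe_min_p", hwe_min_p), ("miss_max", miss_max)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    if g.n_snps == 0:
        raise ValueError("genotype matrix has no SNPs")

    maf = compute_maf(g)
    snp_miss, subject_miss = compute_missing_rates(g)

    report = QcReport(maf_min=maf_min, hwe_min_p=hwe_min_p, miss_max=miss_max,
                      subject_missing_rates=subject_miss)
    for snp in g.snp_ids:
        m = maf[snp]
        if not np.isnan(m) and m < maf_min:
            report.failed_maf.append(snp)
        n_AA, n_Aa, n_aa, _ = g.genotype_counts(snp)
        if n_AA + n_Aa + n_aa > 0 and hwe_exact_pvalue(n_AA, n_Aa, n_aa) < hwe_min_p:
            report.failed_hwe.append(snp)
        if snp_miss[snp] > miss_max:
            report.failed_missing.append(snp)

    removed = set(report.removed)
    report.retained = [s for s in g.snp_ids if s not in removed]
    return g.subset_snps(report.retained), report


def ibs_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state distance between subjects.

    distance(i, j) = 1 - mean over jointly non-missing SNPs of the shared
    allele fraction, where per SNP the shared fraction is
    1 - |call_i - call_j| / 2.  Symmetric with zero diagonal, in [0, 1].
    A pair with no jointly observed SNP gets NaN (reported via warning).
    """
    if g.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    calls = g.calls.to_numpy()
    n = calls.shape[0]
    obs = ~np.isnan(calls)
    filled = np.where(obs, calls, 0.0)

    dist = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs[i + 1 :]
        diff = np.abs(filled[i] - filled[i + 1 :]) * both
        counts = both.sum(axis=1).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = diff.sum(axis=1) / (2.0 * counts)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    if np.isnan(dist).any():
        warnings.warn("some subject pairs share no jointly observed SNP; distance NaN")
    return pd.DataFrame(dist, index=g.subjects, columns=g.subjects)


@dataclass
class MdsEmbedding:
    """Classical-MDS coordinates and the Gram-matrix eigenvalues."""

    coordinates: pd.DataFrame  # subjects x k
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    n_positive: int


def classical_mds(distances: pd.DataFrame, k: int = 2) -> MdsEmbedding:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix into a Gram matrix, takes
    the top-k eigenpairs, and scales eigenvectors by sqrt(eigenvalue).
    Negative eigenvalues (non-Euclidean input) are dropped from the
    coordinates with a warning; k is truncated to the positive-eigenvalue
    count if needed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")

    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(1e-12, 1e-9 * max(abs(evals[0]), 1.0))
    n_pos = int((evals > tol).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating"
        )
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    index = distances.index if isinstance(distances, pd.DataFrame) else pd.RangeIndex(n)
    frame = pd.DataFrame(
        coords, index=index, columns=[f"mds_{i + 1}" for i in range(k_eff)]
    )
    return MdsEmbedding(coordinates=frame, eigenvalues=evals, n_positive=n_pos)
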