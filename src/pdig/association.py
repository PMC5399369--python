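"""Per-SNP quantitative-trait association with permutation empirical p.

Each candidate SNP is tested against one intermediate phenotype (a node
degree centrality or the MDS-UPDRS) by ordinary least squares under the
additive genetic model: the phenotype is regressed on the minor-allele
count with age and sex as covariates, and the SNP coefficient's |t| is
compared against its permutation null obtained by shuffling the phenotype
across subjects (covariates and genotypes fixed, model refit each time).

The empirical p uses the add-one rule p = (1 + #{|t*| >= |t|}) / (1 + N),
so it lies in [1/(N+1), 1] and can never be zero.  Missing genotype calls
are handled per SNP by complete-case analysis.  Sex is coded F = 0, M = 1.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pdig.genotypes import GenotypeMatrix

__all__ = ["SnpFit", "fit_snp_model", "permutation_empirical_p", "scan"]

SEX_CODING = {"F": 0.0, "M": 1.0}


@dataclass
class SnpFit:
    beta: float
    se: float
    t: float
    p: float
    n: int
    testable: bool = True


def _design(y, snp_calls, covariates) -> tuple[np.ndarray, np.ndarray]:
    """Complete-case response and [1, snp, covariates...] design."""
    y = np.asarray(y, dtype=float)
    snp = np.asarray(snp_calls, dtype=float)
    cov = np.column_stack([np.asarray(c, dtype=float) for c in covariates]) \
        if len(covariates) else np.empty((y.size, 0))
    keep = ~(np.isnan(y) | np.isnan(snp) | np.isnan(cov).any(axis=1))
    y, snp, cov = y[keep], snp[keep], cov[keep]
    X = np.column_stack([np.ones_like(y), snp, cov])
    return y, X


def _ols_snp_stats(y: np.ndarray, X: np.ndarray) -> SnpFit:
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = float(beta[1] / se) if se > 0 else np.nan
    p = float(2.0 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else np.nan
    return SnpFit(beta=float(beta[1]), se=se, t=t, p=p, n=n)


def fit_snp_model(y, snp_calls, age, sex) -> SnpFit:
    """OLS of a phenotype on [1, minor-allele count, age, sex].

    Returns the SNP coefficient's estimate, standard error, t and
    two-sided nominal p.  A SNP constant after complete-case filtering is
    flagged untestable (NaN statistics) rather than raising.
    """
    yv, X = _design(y, snp_calls, [age, sex])
    if yv.size < 5:
        raise ValueError(f"need >= 5 complete cases, got {yv.size}")
    if np.ptp(X[:, 1]) == 0.0:
        return SnpFit(beta=np.nan, se=np.nan, t=np.nan, p=np.nan,
                      n=yv.size, testable=False)
    return _ols_snp_stats(yv, X)


def _perm_abs_t(y: np.ndarray, X: np.ndarray, n_perm: int,
                rng: np.random.Generator) -> tuple[float, np.ndarray]:
    """Observed |t| and the permutation |t| sample, fully vectorized.

    Each permutation refits the whole model (covariates included) on the
    shuffled phenotype; with X fixed this reduces to matrix products.
    """
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = xtx_inv @ X.T  # k x n
    dof = n - k

    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Y = np.column_stack([y] + [y[idx] for idx in perm_idx])  # n x (n_perm+1)
    B = proj @ Y
    sse = (Y**2).sum(axis=0) - np.einsum("kj,kj->j", B, X.T @ Y)
    sse = np.maximum(sse, 0.0)
    se = np.sqrt(sse / dof * xtx_inv[1, 1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_all = np.abs(B[1] / se)
    return float(t_all[0]), t_all[1:]


def permutation_empirical_p(
    y,
    snp_calls,
    covariates,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Permutation empirical p for the SNP coefficient.

    ``covariates`` is a sequence of subject-aligned arrays (typically age
    and sex).  Deterministic given ``seed``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse empirical-p grid")
    yv, X = _design(y, snp_calls, list(covariates))
    if yv.size < 5:
        raise ValueError(f"need >= 5 complete cases, got {yv.size}")
    if np.ptp(X[:, 1]) == 0.0:
        raise ValueError("SNP is constant after complete-case filtering")
    rng = np.random.default_rng(seed)
    t_obs, t_perm = _perm_abs_t(yv, X, n_perm, rng)
    exceed = int((t_perm >= t_obs).sum())
    return (1 + exceed) / (1 + n_perm)


def _substream_seed(master_seed: int, phenotype: str, snp_id: str) -> int:
    """Deterministic per-(phenotype, SNP) sub-seed from the master seed."""
    label = f"{phenotype}\x1f{snp_id}".encode()
    return int(np.random.SeedSequence([master_seed, zlib.crc32(label)])
               .generate_state(1)[0] % (2**31))


def scan(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    candidate_snps: list[str],
    covariates: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Association scan over candidate SNPs and intermediate phenotypes.

    ``phenotypes`` has one column per phenotype (subjects in the index);
    ``covariates`` must contain ``age`` and ``sex`` (0/1 or F/M).  Each
    (phenotype, SNP) cell gets its own permutation stream derived from the
    master seed; subjects are sorted by id internally, making results
    invariant to input row order.  Rows are sorted by phenotype then
    empirical p.
    """
    cands = list(dict.fromkeys(candidate_snps))
    if not cands:
        raise ValueError("candidate SNP list is empty")
    if len(cands) < len(candidate_snps):
        warnings.warn("duplicate candidate SNP ids removed")
    unknown = [s for s in cands if s not in genotypes.calls.columns]
    if unknown:
        raise ValueError(f"candidate SNPs not in panel: {unknown}")

    order = sorted(phenotypes.index)
    phen = phenotypes.loc[order]
    cov = covariates.loc[order].copy()
    if cov["sex"].dtype == object:
        cov["sex"] = cov["sex"].map(SEX_CODING)
    calls = genotypes.calls.loc[order]
    cov_arrays = [cov["age"].to_numpy(float), cov["sex"].to_numpy(float)]

    rows = []
    for phenotype in phen.columns:
        yfull = phen[phenotype].to_numpy(float)
        for snp_id in cands:
            meta = genotypes.snps.loc[snp_id]
            sub_seed = _substream_seed(seed, str(phenotype), snp_id)
            fit = fit_snp_model(yfull, calls[snp_id], cov_arrays[0], cov_arrays[1])
            if fit.testable:
                p_emp = permutation_empirical_p(
                    yfull, calls[snp_id], cov_arrays, n_perm=n_perm, seed=sub_seed
                )
            else:
                p_emp = np.nan
            rows.append(
                {
                    "phenotype": phenotype,
                    "gene_label": meta["gene_label"],
                    "snp_id": snp_id,
                    "bp": meta["base_pair_position"],
                    "minor_allele": meta["minor_allele"],
                    "beta": fit.beta,
                    "se": fit.se,
                    "t": fit.t,
                    "p_nominal": fit.p,
                    "p_empirical": p_emp,
                    "n": fit.n,
                    "n_perm": n_perm,
                    "seed": sub_seed,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["phenotype", "p_empirical"], kind="stable").reset_index(drop=True)
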