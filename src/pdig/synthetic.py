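"""Synthetic cohort generator with known ground truth.

Emulates a matched imaging-genetics cohort of 40 healthy controls and 40
Parkinson's disease patients: demographics and clinical covariates,
additive-coded genotypes for a candidate SNP panel (with optional planted
QC violations), per-subject streamline tables whose fiber-density degree
centralities hit configurable per-group node targets, and an MDS-UPDRS
score generated from a declared linear model with SNPxSNP and imagingxSNP
interactions plus Gaussian noise.

Every generator is a pure function of (config, seed).  Default node DC
targets encode the published group contrast pattern on the CBGT circuit:
associative cortex, motor cortex and thalamus higher in patients, pallidum
lower; the four remaining nodes are group-equal.  The generative direction
runs backward from the target DC distribution (node targets -> symmetric
edge matrix -> fiber records), because raw tractography is out of scope
and only the DC distribution matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pdig.atlas import RoiAtlas, DEFAULT_ATLAS, CBGT_REGIONS
from pdig.genotypes import GenotypeMatrix

__all__ = [
    "SnpSpec",
    "TrueModelSpec",
    "CohortBundle",
    "DEFAULT_PANEL",
    "DEFAULT_DC_TARGETS",
    "DEFAULT_TRUE_MODEL",
    "generate_subjects",
    "generate_genotypes",
    "sample_dc",
    "generate_streamlines",
    "generate_phenotype",
    "simulate_cohort",
    "feature_frame",
    "panel_with_planted_violations",
]


# --------------------------------------------------------------------------
# panel specification

@dataclass(frozen=True)
class SnpSpec:
    """One SNP in the candidate panel.

    ``hwe_violation_f`` is an inbreeding-style distortion of genotype
    frequencies (0 = Hardy-Weinberg proportions; near 1 = strong
    heterozygote deficit), the single knob that moves the exact-test p.
    """

    snp_id: str
    gene_label: str
    base_pair_position: int
    minor_allele: str
    target_maf: float
    hwe_violation_f: float = 0.0
    missing_rate: float = 0.0
    causal_roles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_maf <= 0.5:
            raise ValueError(
                f"{self.snp_id}: target_maf must be in [0, 0.5], got {self.target_maf}"
            )
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{self.snp_id}: missing_rate must be in [0, 1]")


# Candidate panel: the seven PD-linked variants of the study's association
# table (genes, rsIDs, positions, minor alleles), plus background variants.
_CANDIDATE_SNPS = [
    SnpSpec("rs6901583", "PARK2", 162543210, "C", 0.30,
            causal_roles=frozenset({"interaction partner"})),
    SnpSpec("rs225103", "PARK7", 8042301, "T", 0.35),
    SnpSpec("rs1473533", "SNCA", 90735702, "T", 0.30),
    SnpSpec("rs9346876", "PARK2", 162032871, "C", 0.30,
            causal_roles=frozenset({"UPDRS effect", "interaction partner"})),
    SnpSpec("rs9364608", "PARK2", 162034799, "G", 0.25),
    SnpSpec("rs363611", "HtrA2", 74759708, "T", 0.30,
            causal_roles=frozenset({"UPDRS effect", "interaction partner"})),
    SnpSpec("rs7421653", "GIGYF2", 233711471, "G", 0.25),
]
_BACKGROUND_SNPS = [
    SnpSpec(f"rs_bg_{i + 1}", "background", 10_000_000 + 50_000 * i, "A", maf)
    for i, maf in enumerate((0.10, 0.20, 0.30, 0.40, 0.15))
]
DEFAULT_PANEL: tuple[SnpSpec, ...] = tuple(_CANDIDATE_SNPS + _BACKGROUND_SNPS)


def panel_with_planted_violations(
    n_low_maf: int = 3,
    n_hwe: int = 2,
    n_missing: int = 4,
    base_panel: tuple[SnpSpec, ...] = DEFAULT_PANEL,
) -> tuple[SnpSpec, ...]:
    """Append disjoint QC-violating SNPs to a clean panel.

    Planted violations: near-monomorphic target MAF (0.001), strong
    heterozygote-deficit distortion (F = 0.9) at common MAF, and a 15%
    missing-call rate, each on its own SNPs.
    """
    extra: list[SnpSpec] = []
    pos = 900_000_000
    for i in range(n_low_maf):
        extra.append(SnpSpec(f"rs_lowmaf_{i + 1}", "planted", pos, "T", 0.001))
        pos += 1000
    for i in range(n_hwe):
        extra.append(
            SnpSpec(f"rs_hwe_{i + 1}", "planted", pos, "T", 0.30, hwe_violation_f=0.9)
        )
        pos += 1000
    for i in range(n_missing):
        extra.append(
            SnpSpec(f"rs_miss_{i + 1}", "planted", pos, "T", 0.30, missing_rate=0.15)
        )
        pos += 1000
    return tuple(base_panel) + tuple(extra)


# --------------------------------------------------------------------------
# degree-centrality targets (per node, per group: mean, sd)

DEFAULT_DC_TARGETS: dict[str, dict[str, tuple[float, float]]] = {
    # published contrast pattern
    "associative_cortex": {"HC": (0.017, 0.004), "PD": (0.019, 0.004)},
    "motor_cortex": {"HC": (0.012, 0.003), "PD": (0.015, 0.003)},
    "thalamus": {"HC": (0.007, 0.002), "PD": (0.008, 0.002)},
    "pallidum": {"HC": (0.006, 0.001), "PD": (0.005, 0.001)},
    # unreported nodes: group-equal at plausible magnitudes
    "caudate": {"HC": (0.009, 0.002), "PD": (0.009, 0.002)},
    "putamen": {"HC": (0.011, 0.003), "PD": (0.011, 0.003)},
    "limbic_cortex": {"HC": (0.014, 0.003), "PD": (0.014, 0.003)},
    "substantia_nigra": {"HC": (0.004, 0.001), "PD": (0.004, 0.001)},
}


# --------------------------------------------------------------------------
# true clinical-score model

@dataclass(frozen=True)
class TrueModelSpec:
    """Ground-truth linear model for the MDS-UPDRS score.

    Coefficient keys name generated columns: region names for DC values,
    rsIDs for additive SNP codes, covariate names, or two-way products
    written ``"a x b"``.
    """

    intercept: float
    coefficients: dict[str, float]
    noise_sd: float

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def term_keys(self) -> list[str]:
        return list(self.coefficients)


# Default truth mirrors the published combined model's structure: three DC
# nodes, two SNP main effects, two interactions, clinical covariates.  Raw
# coefficients are scaled so each term contributes roughly 1.5-3.5 score
# points of sd given the default generator distributions, with noise_sd
# chosen so the realized R^2 sits near 0.7.
DEFAULT_TRUE_MODEL = TrueModelSpec(
    intercept=5.0,
    coefficients={
        "motor_cortex": 1100.0,
        "thalamus": 1700.0,
        "pallidum": -3400.0,
        "rs9346876": 5.0,
        "rs363611": 4.5,
        "rs9346876 x rs363611": 4.0,
        "pallidum x rs6901583": -900.0,
        "GDS": 1.2,
        "sex": 3.0,
        "age": 0.15,
    },
    noise_sd=6.0,
)


# --------------------------------------------------------------------------
# generators

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_subjects(
    n_hc: int,
    n_pd: int,
    seed: int,
    age_mean: float = 62.0,
    age_sd: float = 9.0,
) -> pd.DataFrame:
    """Demographics and clinical covariates for a matched cohort.

    Age is Normal(62, 9) years in both groups and sex is exactly balanced
    within each group, so groups are matched by construction.  GDS (0-15)
    and MoCA (20-30) are integer draws over plausible instrument ranges,
    identical between groups.  MDS_UPDRS is left missing until phenotype
    generation.
    """
    if n_hc < 2 or n_pd < 2:
        raise ValueError(f"need at least 2 subjects per group, got {n_hc}/{n_pd}")
    rng = _rng(seed, 0)
    n = n_hc + n_pd
    ids = [f"S{i + 1:04d}" for i in range(n)]
    group = ["HC"] * n_hc + ["PD"] * n_pd

    def balanced_sex(count: int) -> np.ndarray:
        sexes = np.array(["M"] * (count // 2) + ["F"] * (count - count // 2))
        return rng.permutation(sexes)

    df = pd.DataFrame(
        {
            "subject_id": ids,
            "group": group,
            "age": np.round(rng.normal(age_mean, age_sd, n), 1),
            "sex": np.concatenate([balanced_sex(n_hc), balanced_sex(n_pd)]),
            "handedness": rng.choice(["R", "L"], size=n, p=[0.9, 0.1]),
            "family_history": np.concatenate(
                [rng.binomial(1, 0.10, n_hc), rng.binomial(1, 0.30, n_pd)]
            ),
            "GDS": rng.binomial(15, 0.15, n),
            "MoCA": 20 + rng.binomial(10, 0.7, n),
            "site": rng.integers(1, 10, n),
            "MDS_UPDRS": np.nan,
        }
    ).set_index("subject_id")
    return df


def generate_genotypes(
    subjects: pd.DataFrame,
    panel: tuple[SnpSpec, ...] = DEFAULT_PANEL,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw additive-coded genotypes for each panel SNP.

    Genotypes follow Hardy-Weinberg proportions at the target MAF p unless
    the SNP carries an inbreeding-style distortion F, in which case
    P(het) = 2p(1-p)(1-F) with the deficit moved to the homozygotes.
    Missing calls are injected independently at the SNP's missing rate.
    """
    if not panel:
        raise ValueError("SNP panel is empty")
    rng = _rng(seed, 1)
    n = len(subjects)
    calls = {}
    meta_rows = []
    for spec in panel:
        p = spec.target_maf
        f = spec.hwe_violation_f
        p_hom_major = (1 - p) ** 2 + f * p * (1 - p)
        p_het = 2 * p * (1 - p) * (1 - f)
        p_hom_minor = p**2 + f * p * (1 - p)
        probs = np.clip([p_hom_major, p_het, p_hom_minor], 0.0, 1.0)
        probs = probs / probs.sum()
        g = rng.choice([0.0, 1.0, 2.0], size=n, p=probs)
        if spec.missing_rate > 0:
            g[rng.random(n) < spec.missing_rate] = np.nan
        calls[spec.snp_id] = g
        meta_rows.append(
            {
                "snp_id": spec.snp_id,
                "gene_label": spec.gene_label,
                "base_pair_position": spec.base_pair_position,
                "minor_allele": spec.minor_allele,
            }
        )
    return GenotypeMatrix(
        calls=pd.DataFrame(calls, index=subjects.index),
        snps=pd.DataFrame(meta_rows).set_index("snp_id"),
    )


def _check_dc_targets(dc_targets: dict) -> None:
    missing = [r for r in CBGT_REGIONS if r not in dc_targets]
    if missing:
        raise ValueError(f"dc_targets must cover all 8 nodes; missing {missing}")
    for region, groups in dc_targets.items():
        for grp in ("HC", "PD"):
            if grp not in groups:
                raise ValueError(f"dc_targets[{region!r}] lacks group {grp!r}")
            mean, sd = groups[grp]
            if mean < 0:
                raise ValueError(f"negative target mean for {region!r}/{grp}")
            if sd < 0:
                raise ValueError(f"negative target sd for {region!r}/{grp}")


def sample_dc(
    subjects: pd.DataFrame,
    dc_targets: dict = DEFAULT_DC_TARGETS,
    seed: int = 0,
    genotypes: GenotypeMatrix | None = None,
    snp_dc_effects: list[tuple[str, str, float]] | None = None,
) -> pd.DataFrame:
    """Per-subject node degree-centrality values drawn from group targets.

    Each node's DC is Normal(mean_g, sd_g) for the subject's group,
    truncated below at 5% of the group mean (DC is non-negative).
    Optional ``snp_dc_effects`` entries (snp_id, node, beta_per_allele)
    shift a node's DC by beta times the subject's minor-allele count,
    planting a genotype -> imaging-phenotype association.
    """
    _check_dc_targets(dc_targets)
    rng = _rng(seed, 2)
    n = len(subjects)
    out = {}
    for region in CBGT_REGIONS:
        means = np.array([dc_targets[region][g][0] for g in subjects["group"]])
        sds = np.array([dc_targets[region][g][1] for g in subjects["group"]])
        vals = rng.normal(means, sds)
        out[region] = np.maximum(vals, 0.05 * means)
    dc = pd.DataFrame(out, index=subjects.index)
    if snp_dc_effects:
        if genotypes is None:
            raise ValueError("snp_dc_effects requires genotypes")
        for snp_id, node, beta in snp_dc_effects:
            g = genotypes.calls[snp_id].fillna(genotypes.calls[snp_id].mean())
            dc[node] = np.maximum(dc[node] + beta * g.to_numpy(), 0.0)
    return dc


def _edge_matrix_for_row_sums(t: np.ndarray, tol: float = 1e-12, max_iter: int = 2000) -> np.ndarray:
    """Symmetric non-negative matrix with zero diagonal and row sums t.

    Sinkhorn-style symmetric scaling starting from the rank-one outer
    product; converges for strictly positive feasible targets.
    """
    k = t.size
    W = np.outer(t, t)
    np.fill_diagonal(W, 0.0)
    for _ in range(max_iter):
        r = W.sum(axis=1)
        scale = np.sqrt(t / r)
        W = W * np.outer(scale, scale)
        np.fill_diagonal(W, 0.0)
        if np.max(np.abs(W.sum(axis=1) - t) / t) < tol:
            break
    return W


def generate_streamlines(
    subjects: pd.DataFrame,
    dc_targets: dict = DEFAULT_DC_TARGETS,
    seed: int = 0,
    atlas: RoiAtlas = DEFAULT_ATLAS,
    dc: pd.DataFrame | None = None,
    fibers_per_pair: tuple[int, int] = (5, 12),
) -> pd.DataFrame:
    """Per-subject fiber records realizing the target DC distribution.

    For each subject, node DC targets are drawn (see :func:`sample_dc`),
    a symmetric edge-weight matrix matching those row sums is constructed,
    and each region pair's fibers (count, lognormal lengths, FA in (0,1))
    are scaled in length so the pair's fiber-density weight equals the
    matrix entry exactly.  Rebuilding connectivity from the returned table
    therefore reproduces the drawn DC values to numerical precision.
    """
    if dc is None:
        dc = sample_dc(subjects, dc_targets, seed)
    rng = _rng(seed, 3)
    regions = atlas.regions
    records: list[tuple] = []
    lo, hi = fibers_per_pair
    for sid in subjects.index:
        t = dc.loc[sid, list(regions)].to_numpy(float)
        W = _edge_matrix_for_row_sums(t)
        fiber_counter = 0
        for a in range(8):
            for b in range(a + 1, 8):
                w = W[a, b]
                if w <= 0:
                    continue
                n_f = int(rng.integers(lo, hi + 1))
                lengths = rng.lognormal(np.log(60.0), 0.3, n_f)
                fa = rng.uniform(0.3, 0.7, n_f)
                s_sum = atlas.area(regions[a]) + atlas.area(regions[b])
                w_raw = fa.mean() * (2.0 / s_sum) * np.sum(1.0 / lengths)
                lengths = lengths * (w_raw / w)
                for l_mm, fa_v in zip(lengths, fa):
                    records.append(
                        (sid, regions[a], regions[b], f"f{fiber_counter:05d}",
                         float(l_mm), float(fa_v))
                    )
                    fiber_counter += 1
    return pd.DataFrame(
        records,
        columns=["subject_id", "region_i", "region_j", "fiber_id", "length_mm", "mean_fa"],
    )


# --------------------------------------------------------------------------
# phenotype generation

@dataclass
class CohortBundle:
    """All generated components of one synthetic cohort, subject-aligned."""

    subjects: pd.DataFrame
    genotypes: GenotypeMatrix
    dc: pd.DataFrame
    streamlines: pd.DataFrame | None = None
    truth: TrueModelSpec | None = None
    design: pd.DataFrame | None = None
    n_clipped: int = 0

    def __post_init__(self) -> None:
        idx = list(self.subjects.index)
        if list(self.genotypes.calls.index) != idx or list(self.dc.index) != idx:
            raise ValueError("bundle components must share the subject index")


def _resolve_column(key: str, columns: pd.DataFrame) -> np.ndarray:
    if key in columns.columns:
        col = columns[key].to_numpy(float)
    else:
        raise KeyError(
            f"true-model term {key!r} does not resolve to a generated column"
        )
    if np.isnan(col).any():
        raise ValueError(f"column {key!r} has missing values; cannot generate scores")
    return col


def generate_phenotype(
    bundle: CohortBundle,
    truth: TrueModelSpec = DEFAULT_TRUE_MODEL,
    seed: int = 0,
) -> CohortBundle:
    """Fill MDS_UPDRS from the declared true model plus Gaussian noise.

    Scores are clipped at 0 (the instrument is non-negative) and the
    number of clipped subjects is recorded on the bundle; the realized
    design matrix is stored for parameter-recovery tests.
    """
    rng = _rng(seed, 4)
    columns = feature_frame(bundle)
    design = {}
    y = np.full(len(bundle.subjects), truth.intercept, dtype=float)
    for key, coef in truth.coefficients.items():
        if " x " in key:
            a, b = key.split(" x ")
            col = _resolve_column(a, columns) * _resolve_column(b, columns)
        else:
            col = _resolve_column(key, columns)
        design[key] = col
        y = y + coef * col
    y = y + rng.normal(0.0, truth.noise_sd, y.size)
    n_clipped = int((y < 0).sum())
    y = np.maximum(y, 0.0)

    subjects = bundle.subjects.copy()
    subjects["MDS_UPDRS"] = y
    return replace(
        bundle,
        subjects=subjects,
        truth=truth,
        design=pd.DataFrame(design, index=bundle.subjects.index),
        n_clipped=n_clipped,
    )


def feature_frame(bundle: CohortBundle) -> pd.DataFrame:
    """Numeric analysis frame: DC nodes, SNP codes, covariates, group.

    Sex is coded F = 0 / M = 1; group HC = 0 / PD = 1.
    """
    covs = bundle.subjects.copy()
    covs["sex"] = covs["sex"].map({"F": 0.0, "M": 1.0})
    covs["group"] = covs["group"].map({"HC": 0.0, "PD": 1.0})
    keep = ["group", "age", "sex", "family_history", "GDS", "MoCA", "site"]
    if "MDS_UPDRS" in covs.columns:
        keep.append("MDS_UPDRS")
    frame = pd.concat([bundle.dc, bundle.genotypes.calls, covs[keep]], axis=1)
    return frame


def simulate_cohort(
    n_hc: int = 40,
    n_pd: int = 40,
    seed: int = 0,
    panel: tuple[SnpSpec, ...] = DEFAULT_PANEL,
    dc_targets: dict = DEFAULT_DC_TARGETS,
    truth: TrueModelSpec | None = DEFAULT_TRUE_MODEL,
    snp_dc_effects: list[tuple[str, str, float]] | None = None,
    with_streamlines: bool = True,
) -> CohortBundle:
    """Generate a complete cohort: subjects, genotypes, DC, streamlines, score.

    ``with_streamlines=False`` skips fiber-record synthesis (the DC table
    is drawn identically either way), for simulation studies that only
    need the downstream features.
    """
    subjects = generate_subjects(n_hc, n_pd, seed)
    genotypes = generate_genotypes(subjects, panel, seed)
    dc = sample_dc(subjects, dc_targets, seed, genotypes=genotypes,
                   snp_dc_effects=snp_dc_effects)
    streamlines = (
        generate_streamlines(subjects, dc_targets, seed, dc=dc)
        if with_streamlines
        else None
    )
    bundle = CohortBundle(
        subjects=subjects, genotypes=genotypes, dc=dc, streamlines=streamlines
    )
    if truth is not None:
        bundle = generate_phenotype(bundle, truth, seed)
    return bundle
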