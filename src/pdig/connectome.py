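"""Structural connectivity on the 8-node CBGT network.

Edges are fiber-density weights derived from streamline summaries: for a
region pair (i, j) with fibers f of length l(f) (mm) and pair-mean
fractional anisotropy meanFA(i, j),

    w(i, j) = meanFA(i, j) * [2 / (S_i + S_j)] * sum_f 1 / l(f)

i.e. the number of fibers normalized by length and by the surface areas
S_i, S_j of the connected regions, modulated by white-matter integrity
(FA).  Degree centrality (DC) of a node is the sum of its incident edge
weights; DC per node is the imaging intermediate phenotype compared
between groups with Welch t-tests under Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pdig.atlas import RoiAtlas, DEFAULT_ATLAS

FIBER_DENSITY_VARIANT = "meanFA*2/(S_i+S_j)*sum(1/l)"

STREAMLINE_COLUMNS = ("subject_id", "region_i", "region_j", "fiber_id", "length_mm", "mean_fa")


def fiber_density_edge(
    lengths_mm: np.ndarray | list[float],
    fa_values: np.ndarray | list[float],
    area_i: float,
    area_j: float,
) -> float:
    """Fiber-density weight for one region pair.

    ``lengths_mm`` and ``fa_values`` are per-fiber; the pair FA enters as
    the mean over fiber-level values.  An empty fiber list gives weight 0.
    """
    if not (area_i > 0 and area_j > 0):
        raise ValueError("surface areas must be positive")
    lengths = np.asarray(lengths_mm, dtype=float)
    fa = np.asarray(fa_values, dtype=float)
    if lengths.size == 0:
        return 0.0
    if lengths.size != fa.size:
        raise ValueError("lengths and FA values must align per fiber")
    if not (lengths > 0).all():
        raise ValueError("fiber lengths must be strictly positive")
    if not ((fa > 0) & (fa < 1)).all():
        raise ValueError("FA values must lie in (0, 1)")
    mean_fa = float(fa.mean())
    return mean_fa * (2.0 / (area_i + area_j)) * float(np.sum(1.0 / lengths))


def build_connectivity(
    streamlines: pd.DataFrame,
    atlas: RoiAtlas = DEFAULT_ATLAS,
    subject_id: str | None = None,
) -> pd.DataFrame:
    """8x8 fiber-density connectivity matrix for one subject.

    ``streamlines`` holds one row per fiber with columns ``region_i``,
    ``region_j``, ``length_mm``, ``mean_fa`` (a ``subject_id`` column, if
    present, must be constant or ``subject_id`` must select one subject).
    Symmetric with zero diagonal by construction.
    """
    df = streamlines
    if "subject_id" in df.columns:
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
        elif df["subject_id"].nunique() > 1:
            raise ValueError("streamline table holds multiple subjects; pass subject_id")
    regions = atlas.regions
    unknown = (set(df["region_i"]) | set(df["region_j"])) - set(regions)
    if unknown:
        raise ValueError(f"unknown region label(s) {sorted(unknown)}")

    mat = np.zeros((8, 8))
    if len(df):
        for (ri, rj), grp in df.groupby(["region_i", "region_j"], sort=False):
            if ri == rj:
                raise ValueError(f"self-loop streamlines at region {ri!r}")
            w = fiber_density_edge(
                grp["length_mm"].to_numpy(),
                grp["mean_fa"].to_numpy(),
                atlas.area(ri),
                atlas.area(rj),
            )
            a, b = atlas.index(ri), atlas.index(rj)
            mat[a, b] += w
            mat[b, a] += w
    return pd.DataFrame(mat, index=regions, columns=regions)


def _check_connectivity(c: pd.DataFrame) -> np.ndarray:
    m = np.asarray(c, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("connectivity matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-12):
        raise ValueError("connectivity matrix must have zero diagonal")
    if not np.isfinite(m).all() or (m < 0).any():
        raise ValueError("edge weights must be finite and non-negative")
    return m


def degree_centrality(c: pd.DataFrame) -> pd.Series:
    """Node degree centrality: the row sums of the connectivity matrix."""
    m = _check_connectivity(c)
    return pd.Series(m.sum(axis=1), index=c.index, name="dc")


def dc_table(
    connectivity_by_subject: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Stack per-subject DC vectors into a subjects x regions table."""
    rows = {sid: degree_centrality(c) for sid, c in connectivity_by_subject.items()}
    return pd.DataFrame(rows).T.rename_axis("subject_id")


@dataclass
class GroupDcTestResult:
    """Per-node Welch t-test of DC between groups, Bonferroni-corrected."""

    table: pd.DataFrame  # per node: means, sds, t, p, p_corrected, significant
    alpha: float
    n_tests: int

    @property
    def significant_nodes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def group_dc_tests(
    dc_hc: pd.DataFrame,
    dc_pd: pd.DataFrame,
    alpha: float = 0.05,
) -> GroupDcTestResult:
    """Compare node DC between healthy-control and patient groups.

    Two-sample Welch t-tests per node with Bonferroni correction over the
    tested nodes; the significant node set feeds the association stage as
    intermediate phenotypes.  A node with zero variance in both groups is
    reported with p = 1 and a warning.
    """
    if list(dc_hc.columns) != list(dc_pd.columns):
        raise ValueError("group DC tables must share node columns")
    if len(dc_hc) < 2 or len(dc_pd) < 2:
        raise ValueError("need at least 2 subjects per group")
    nodes = list(dc_hc.columns)
    m = len(nodes)
    rows = []
    for node in nodes:
        a = dc_hc[node].to_numpy(dtype=float)
        b = dc_pd[node].to_numpy(dtype=float)
        if a.std() == 0.0 and b.std() == 0.0:
            warnings.warn(f"node {node!r} has zero variance in both groups; p set to 1")
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        p_corr = min(1.0, float(p) * m)
        rows.append(
            {
                "node": node,
                "mean_hc": a.mean(),
                "sd_hc": a.std(ddof=1),
                "mean_pd": b.mean(),
                "sd_pd": b.std(ddof=1),
                "t": float(t),
                "p_raw": float(p),
                "p_corrected": p_corr,
                "significant": p_corr < alpha,
            }
        )
    table = pd.DataFrame(rows).set_index("node")
    return GroupDcTestResult(table=table, alpha=alpha, n_tests=m)
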