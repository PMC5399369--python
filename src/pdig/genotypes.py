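"""Genotype container: subjects x SNPs additive-coded calls with metadata.

Calls count copies of the declared minor allele (0/1/2); missing calls are
NaN.  SNP metadata (rsID, gene label, base-pair position, minor allele) ride
alongside in a DataFrame indexed by snp_id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SNP_META_COLUMNS = ("gene_label", "base_pair_position", "minor_allele")


@dataclass
class GenotypeMatrix:
    """Additive-coded genotype calls.

    Attributes
    ----------
    calls
        DataFrame of shape (n_subjects, n_snps); values in {0, 1, 2, NaN}
        counting minor alleles, index = subject_id, columns = snp_id.
    snps
        Per-SNP metadata DataFrame indexed by snp_id with columns
        ``gene_label``, ``base_pair_position``, ``minor_allele``.
    """

    calls: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(float)
        if list(self.calls.columns) != list(self.snps.index):
            raise ValueError("calls columns and SNP metadata index must match in order")
        if self.calls.index.duplicated().any():
            raise ValueError("duplicate subject ids")
        if self.snps.index.duplicated().any():
            raise ValueError("duplicate SNP ids")
        vals = self.calls.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"calls must be in {{0, 1, 2, NaN}}; found {bad}")
        missing_meta = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing_meta:
            raise ValueError(f"SNP metadata missing columns {missing_meta}")

    @property
    def subjects(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_subjects(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int, int]:
        """(n_AA, n_Aa, n_aa, n_missing) for one SNP.

        AA = zero minor alleles, Aa = one, aa = two.
        """
        col = self.calls[snp_id].to_numpy()
        n_missing = int(np.isnan(col).sum())
        n_aa2 = int(np.nansum(col == 2.0))
        n_het = int(np.nansum(col == 1.0))
        n_hom_major = col.size - n_missing - n_het - n_aa2
        return n_hom_major, n_het, n_aa2, n_missing

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            calls=self.calls[snp_ids].copy(), snps=self.snps.loc[snp_ids].copy()
        )

    def subset_subjects(self, subject_ids: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            calls=self.calls.loc[subject_ids].copy(), snps=self.snps.copy()
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        same_calls = self.calls.shape == other.calls.shape and bool(
            ((self.calls == other.calls) | (self.calls.isna() & other.calls.isna()))
            .all()
            .all()
        ) and list(self.calls.index) == list(other.calls.index) and list(
            self.calls.columns
        ) == list(other.calls.columns)
        return same_calls and self.snps.equals(other.snps)
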