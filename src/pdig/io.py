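"""Readers and writers for the pipeline's text formats.

Genotypes travel as PLINK-style text (.ped/.map, whitespace separated,
missing call "0 0"), with a sidecar ``<prefix>.snpinfo.tsv`` carrying gene
labels and allele letters so that read(write(g)) reproduces the in-memory
object exactly.  Phenotype/covariate tables and streamline tables are TSV;
connectivity matrices are CSV with region names as header row and column;
configs are YAML.  All readers report malformed content with file and line
context.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pdig.genotypes import GenotypeMatrix

__all__ = [
    "write_plink",
    "read_plink",
    "write_tsv",
    "read_tsv",
    "write_connectivity_csv",
    "read_connectivity_csv",
    "write_yaml",
    "read_yaml",
    "write_json",
    "read_json",
]

_SEX_TO_PED = {"M": "1", "F": "2"}


def _major_allele(minor: str) -> str:
    for base in "ACGT":
        if base != minor:
            return base
    return "A"


def write_plink(g: GenotypeMatrix, prefix: str | Path,
                sex: pd.Series | None = None) -> tuple[Path, Path, Path]:
    """Write .ped/.map (+ .snpinfo.tsv sidecar) for a genotype matrix.

    The .ped carries the standard 6 leading columns (family, individual,
    paternal, maternal, sex with 1=M/2=F/0=unknown, phenotype -9) then two
    allele letters per SNP; a missing call is "0 0".
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    info_path = prefix.with_suffix(".snpinfo.tsv")

    minors = g.snps["minor_allele"].tolist()
    majors = [_major_allele(m) for m in minors]

    with map_path.open("w") as fh:
        for snp_id, row in g.snps.iterrows():
            fh.write(f"1\t{snp_id}\t0\t{int(row['base_pair_position'])}\n")

    info = g.snps.copy()
    info["major_allele"] = majors
    info.to_csv(info_path, sep="\t")

    calls = g.calls.to_numpy()
    with ped_path.open("w") as fh:
        for i, sid in enumerate(g.subjects):
            sex_code = _SEX_TO_PED.get(sex.get(sid), "0") if sex is not None else "0"
            fields = [sid, sid, "0", "0", sex_code, "-9"]
            for j in range(g.n_snps):
                c = calls[i, j]
                if np.isnan(c):
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [majors[j], majors[j]]
                elif c == 1:
                    fields += [majors[j], minors[j]]
                else:
                    fields += [minors[j], minors[j]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path, info_path


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read .ped/.map text genotypes into a GenotypeMatrix.

    If the ``.snpinfo.tsv`` sidecar exists, gene labels and the declared
    minor allele come from it; otherwise the minor allele is the rarer
    allele letter in the data and the gene label is "NA".
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    info_path = prefix.with_suffix(".snpinfo.tsv")

    snp_ids: list[str] = []
    positions: list[int] = []
    with map_path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            snp_ids.append(parts[1])
            positions.append(int(parts[3]))

    rows: list[list[str]] = []
    subjects: list[str] = []
    n_expected = 6 + 2 * len(snp_ids)
    with ped_path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != n_expected:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {n_expected} fields, got {len(parts)}"
                )
            subjects.append(parts[1])
            rows.append(parts[6:])

    if info_path.exists():
        info = pd.read_csv(info_path, sep="\t", index_col=0)
        if list(info.index) != snp_ids:
            raise ValueError(f"{info_path}: SNP ids disagree with {map_path}")
        minors = info["minor_allele"].tolist()
        genes = info["gene_label"].tolist()
    else:
        minors = [None] * len(snp_ids)
        genes = ["NA"] * len(snp_ids)

    n_subj = len(subjects)
    calls = np.full((n_subj, len(snp_ids)), np.nan)
    for j in range(len(snp_ids)):
        a1 = [rows[i][2 * j] for i in range(n_subj)]
        a2 = [rows[i][2 * j + 1] for i in range(n_subj)]
        alleles = [a for a in a1 + a2 if a != "0"]
        if minors[j] is None:
            uniq = sorted(set(alleles))
            if len(uniq) > 2:
                raise ValueError(f"{ped_path}: SNP {snp_ids[j]} has >2 alleles {uniq}")
            counts = {u: alleles.count(u) for u in uniq}
            minors[j] = min(counts, key=lambda u: (counts[u], u)) if uniq else "A"
        minor = minors[j]
        for i in range(n_subj):
            if a1[i] == "0" or a2[i] == "0":
                continue
            calls[i, j] = (a1[i] == minor) + (a2[i] == minor)

    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "gene_label": genes,
            "base_pair_position": positions,
            "minor_allele": minors,
        }
    ).set_index("snp_id")
    return GenotypeMatrix(
        calls=pd.DataFrame(calls, index=subjects, columns=snp_ids), snps=snps
    )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_connectivity_csv(c: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    c.to_csv(path)
    return path


def read_connectivity_csv(path: str | Path) -> pd.DataFrame:
    c = pd.read_csv(path, index_col=0)
    m = c.to_numpy(float)
    if m.shape[0] != m.shape[1] or list(c.index) != list(c.columns):
        raise ValueError(f"{path}: connectivity matrix must be square with matching labels")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{path}: connectivity matrix is not symmetric")
    return c


def write_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def read_yaml(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def read_json(path: str | Path):
    with Path(path).open() as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
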