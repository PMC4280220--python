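"""Genotype, pedigree and dyad I/O.

Reads and writes PLINK-style PED/MAP text files, delimited sample tables,
and reduces genotyped mother-child pairs to per-variant count tables over
the seven Mendelian-compatible (mother, child) dosage cells.

Dosages are stored as a float matrix of minor-allele counts with ``nan``
marking a missing genotype.  The minor allele is the less frequent allele
among controls (ties broken lexicographically) so that reported control
minor-allele frequencies never exceed 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DYAD_CELLS",
    "Variant",
    "GenotypeDataset",
    "PedigreeRecord",
    "DyadDataset",
    "DyadExclusionReport",
    "PedParseError",
    "read_ped_map",
    "write_ped_map",
    "read_sample_table",
    "read_dyad_counts",
    "extract_dyads",
]

#: The seven (mother dosage, child dosage) pairs compatible with Mendelian
#: transmission of a biallelic variant; (0,2) and (2,0) are impossible.
DYAD_CELLS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 0), (1, 1), (1, 2), (2, 1), (2, 2),
)

_VALID_ALLELES = frozenset("ACGT12")
_MISSING_ALLELE = "0"


class PedParseError(ValueError):
    """Raised on a malformed PED/MAP record; message names the line."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with its minor/major allele orientation."""

    id: str
    chromosome: str
    position_bp: int
    allele_minor: str
    allele_major: str
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"{self.id}: position_bp must be >= 1")
        if self.allele_minor == self.allele_major:
            raise ValueError(f"{self.id}: minor and major allele identical")


@dataclass
class GenotypeDataset:
    """Samples x variants minor-allele dosage matrix with phenotypes.

    ``dosage[i, j]`` is the number of minor alleles carried by sample ``i``
    at variant ``j`` (0, 1, 2, or ``nan`` if missing).  ``phenotype`` is 1
    for cases and 0 for controls.  ``covariates`` holds per-sample numeric
    columns (infant sex, principal-component scores, ...).
    """

    variants: list[Variant]
    samples: list[str]
    dosage: np.ndarray
    phenotype: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=int)
        n, m = self.dosage.shape if self.dosage.ndim == 2 else (0, 0)
        if self.dosage.ndim != 2 or n != len(self.samples) or m != len(self.variants):
            raise ValueError("dosage shape does not match samples x variants")
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype must be defined for every sample")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == variant_id:
                return j
        raise KeyError(variant_id)

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        variant_mask: np.ndarray | None = None,
    ) -> "GenotypeDataset":
        """Return a copy restricted to the masked samples/variants."""
        smask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        vmask = np.ones(self.n_variants, bool) if variant_mask is None else np.asarray(variant_mask, bool)
        cov = self.covariates.loc[smask].reset_index(drop=True) if len(self.covariates) else self.covariates
        return GenotypeDataset(
            variants=[v for v, k in zip(self.variants, vmask) if k],
            samples=[s for s, k in zip(self.samples, smask) if k],
            dosage=self.dosage[np.ix_(smask, vmask)].copy(),
            phenotype=self.phenotype[smask].copy(),
            covariates=cov,
        )


@dataclass(frozen=True)
class PedigreeRecord:
    family_id: str
    individual_id: str
    mother_id: str | None
    sex: str  # {male, female, unknown}
    role: str  # {mother, child}


@dataclass
class DyadDataset:
    """Per-variant mother-child dosage-pair counts split by dyad status.

    Count matrices have one row per variant and one column per cell of
    :data:`DYAD_CELLS`.
    """

    variants: list[Variant]
    case_counts: np.ndarray
    control_counts: np.ndarray
    n_case_dyads: int
    n_control_dyads: int

    def __post_init__(self) -> None:
        self.case_counts = np.asarray(self.case_counts, dtype=int)
        self.control_counts = np.asarray(self.control_counts, dtype=int)
        shape = (len(self.variants), len(DYAD_CELLS))
        if self.case_counts.shape != shape or self.control_counts.shape != shape:
            raise ValueError(f"count matrices must have shape {shape}")
        if (self.case_counts < 0).any() or (self.control_counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.case_counts.sum(axis=1) > self.n_case_dyads).any():
            raise ValueError("case counts exceed the number of case dyads")
        if (self.control_counts.sum(axis=1) > self.n_control_dyads).any():
            raise ValueError("control counts exceed the number of control dyads")

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for k, (m, c) in enumerate(DYAD_CELLS):
            cols[f"case_m{m}c{c}"] = self.case_counts[:, k]
        for k, (m, c) in enumerate(DYAD_CELLS):
            cols[f"control_m{m}c{c}"] = self.control_counts[:, k]
        return pd.DataFrame({
            "variant": [v.id for v in self.variants],
            "chromosome": [v.chromosome for v in self.variants],
            "position": [v.position_bp for v in self.variants],
            "gene": [v.gene for v in self.variants],
            **cols,
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class DyadExclusionReport:
    """Accounting of pairs dropped during dyad extraction."""

    n_mendelian_excluded: int = 0
    n_missing_skipped: int = 0
    per_variant_excluded: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PED/MAP


def _read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    out = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise PedParseError(f"{map_path}:{lineno}: expected 4 MAP columns")
            chrom, vid, _cm, pos = parts[:4]
            out.append((chrom, vid, int(pos)))
    return out


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read whitespace-separated PED/MAP files into a dosage dataset.

    Alleles are oriented so dosage counts the allele that is rarer among
    controls (PED phenotype 1); "0 0" allele pairs become missing.  PED
    phenotype 2 maps to case, 1 to control.
    """
    sites = _read_map(map_path)
    m = len(sites)
    samples: list[str] = []
    phenotype: list[int] = []
    sexes: list[float] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise PedParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns, got {len(parts)}"
                )
            _fid, iid, _pat, _mat, sex, pheno = parts[:6]
            for a in parts[6:]:
                if a != _MISSING_ALLELE and a not in _VALID_ALLELES:
                    raise PedParseError(f"{ped_path}:{lineno}: invalid allele symbol {a!r}")
            samples.append(iid)
            phenotype.append(1 if pheno == "2" else 0)
            sexes.append(float(sex))
            allele_rows.append(parts[6:])

    n = len(samples)
    pheno_arr = np.array(phenotype, int)
    alleles = np.array(allele_rows, dtype="U1").reshape(n, m, 2) if n else np.empty((0, m, 2), "U1")
    dosage = np.full((n, m), np.nan)
    variants: list[Variant] = []
    controls = pheno_arr == 0 if (pheno_arr == 0).any() else np.ones(n, bool)
    for j, (chrom, vid, pos) in enumerate(sites):
        col = alleles[:, j, :]
        present = col != _MISSING_ALLELE
        observed = sorted(set(col[present]))
        if len(observed) > 2:
            raise PedParseError(f"{map_path}: variant {vid} has >2 alleles")
        # minor = less frequent allele among controls; ties lexicographic
        ctrl_col = col[controls]
        counts = {a: int((ctrl_col == a).sum()) for a in observed}
        if len(observed) == 2:
            a, b = observed  # lexicographic order
            minor, major = (a, b) if counts.get(a, 0) <= counts.get(b, 0) else (b, a)
        elif len(observed) == 1:
            major = observed[0]
            minor = next(x for x in "ACGT12" if x != major)
        else:  # fully missing variant
            major, minor = "A", "C"
        variants.append(Variant(vid, chrom, pos, minor, major))
        complete = present.all(axis=1)
        dosage[complete, j] = (col[complete] == minor).sum(axis=1)

    cov = pd.DataFrame({"sex": sexes})
    return GenotypeDataset(variants, samples, dosage, pheno_arr, cov)


def write_ped_map(
    dataset: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a dataset as PED/MAP re-readable by :func:`read_ped_map`."""
    with open(map_path, "w") as fh:
        for v in dataset.variants:
            fh.write(f"{v.chromosome}\t{v.id}\t0\t{v.position_bp}\n")
    sex = dataset.covariates["sex"] if "sex" in dataset.covariates else None
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(dataset.samples):
            sx = int(sex.iloc[i]) if sex is not None else 0
            row = [sid, sid, "0", "0", str(sx), str(1 + int(dataset.phenotype[i]))]
            for j, v in enumerate(dataset.variants):
                d = dataset.dosage[i, j]
                if np.isnan(d):
                    row += [_MISSING_ALLELE, _MISSING_ALLELE]
                else:
                    k = int(d)
                    row += [v.allele_minor] * k + [v.allele_major] * (2 - k)
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# Sample table

_STATUS_MAP = {
    "case": 1, "control": 0, "1": 1, "0": 0, "2": 1,
    "affected": 1, "unaffected": 0,
}


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited sample table with a header.

    Requires a sample-id column (first column, or one named ``sample``/
    ``id``/``iid``) and a ``status`` column with values mappable to
    case/control.  Returns a DataFrame with a numeric ``phenotype`` column
    (1 = case); other columns are preserved, numeric where parseable.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols_lower = {c.lower(): c for c in df.columns}
    id_col = next((cols_lower[k] for k in ("sample", "sample_id", "id", "iid") if k in cols_lower), df.columns[0])
    if "status" not in cols_lower:
        raise ValueError(f"{path}: no 'status' column")
    status_col = cols_lower["status"]
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    status = df[status_col].astype(str).str.strip().str.lower()
    bad = ~status.isin(_STATUS_MAP)
    if bad.any():
        raise ValueError(f"{path}: unrecognized status value {status[bad].iloc[0]!r}")
    out = df.copy()
    out[id_col] = ids
    out["phenotype"] = status.map(_STATUS_MAP).astype(int)
    return out


def read_dyad_counts(path: str | Path) -> DyadDataset:
    """Read a dyad-count TSV written by :meth:`DyadDataset.write_tsv`."""
    df = pd.read_csv(path, sep="\t")
    variants = []
    for _, row in df.iterrows():
        gene = row.get("gene")
        variants.append(Variant(
            id=str(row["variant"]), chromosome=str(row["chromosome"]),
            position_bp=int(row["position"]), allele_minor="A", allele_major="G",
            gene=None if pd.isna(gene) else str(gene),
        ))
    case = df[[f"case_m{m}c{c}" for m, c in DYAD_CELLS]].to_numpy(int)
    control = df[[f"control_m{m}c{c}" for m, c in DYAD_CELLS]].to_numpy(int)
    return DyadDataset(variants, case, control,
                       int(case.sum(axis=1).max(initial=0)),
                       int(control.sum(axis=1).max(initial=0)))


# ---------------------------------------------------------------------------
# Dyad extraction


def extract_dyads(
    genotypes: GenotypeDataset,
    pedigree: Sequence[PedigreeRecord],
    dyad_status: Mapping[str, bool],
) -> tuple[DyadDataset, DyadExclusionReport]:
    """Tally mother-child dosage pairs into the 7-cell count vectors.

    ``dyad_status`` maps family id to True for case (affected pregnancy)
    dyads.  Pairs with a missing genotype at a variant are skipped for
    that variant; Mendelian-incompatible pairs ((0,2) or (2,0)) are
    excluded there and counted in the returned exclusion report.
    """
    by_family: dict[str, dict[str, list[PedigreeRecord]]] = {}
    for rec in pedigree:
        by_family.setdefault(rec.family_id, {}).setdefault(rec.role, []).append(rec)

    sample_index = {s: i for i, s in enumerate(genotypes.samples)}
    pairs: list[tuple[str, int, int]] = []  # family, mother row, child row
    for fam, roles in by_family.items():
        mothers = roles.get("mother", [])
        if len(mothers) > 1:
            raise ValueError(f"family {fam}: more than one mother record")
        children = roles.get("child", [])
        if not mothers or not children:
            continue
        mother = mothers[0]
        child = children[0]
        if child.mother_id is not None and child.mother_id != mother.individual_id:
            raise ValueError(f"family {fam}: child's mother_id does not resolve")
        if mother.individual_id in sample_index and child.individual_id in sample_index:
            pairs.append((fam, sample_index[mother.individual_id], sample_index[child.individual_id]))

    cell_index = {cell: k for k, cell in enumerate(DYAD_CELLS)}
    n_var = genotypes.n_variants
    case_counts = np.zeros((n_var, 7), int)
    control_counts = np.zeros((n_var, 7), int)
    report = DyadExclusionReport()
    n_case = n_control = 0
    for fam, mi, ci in pairs:
        is_case = bool(dyad_status.get(fam, False))
        if is_case:
            n_case += 1
        else:
            n_control += 1
        target = case_counts if is_case else control_counts
        md = genotypes.dosage[mi]
        cd = genotypes.dosage[ci]
        for j in range(n_var):
            if np.isnan(md[j]) or np.isnan(cd[j]):
                report.n_missing_skipped += 1
                continue
            cell = (int(md[j]), int(cd[j]))
            if cell in cell_index:
                target[j, cell_index[cell]] += 1
            else:  # (0,2) or (2,0): Mendelian-incompatible
                report.n_mendelian_excluded += 1
                vid = genotypes.variants[j].id
                report.per_variant_excluded[vid] = report.per_variant_excluded.get(vid, 0) + 1

    dyads = DyadDataset(
        variants=list(genotypes.variants),
        case_counts=case_counts,
        control_counts=control_counts,
        n_case_dyads=n_case,
        n_control_dyads=n_control,
    )
    return dyads, report
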