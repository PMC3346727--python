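"""Genotype, annotation and pathway file handling.

Readers for the PLINK ``--recodeA`` additive-dosage text dialect, PLINK
``.map`` SNP annotations, gene-interval tables (TSV or BED), and GMT gene
sets; plus SNP-to-pathway mapping through a kilobase window around gene
bodies and deterministic per-SNP mode imputation of missing genotypes.

Coordinates are 1-based inclusive throughout (PLINK convention); BED input
is converted from 0-based half-open on read.  Distances are strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SnpAnnotation",
    "GeneAnnotation",
    "PathwayDefinition",
    "GenotypeMatrix",
    "PathwaySnpSet",
    "read_additive_genotypes",
    "write_additive_genotypes",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_map",
    "read_gene_table",
    "read_bed_genes",
    "read_gmt",
    "write_gmt",
    "impute_missing",
    "map_snps_to_pathway",
]

#: Sentinel dosage for a missing genotype before imputation.
MISSING = np.int8(-9)

_LEAD_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


@dataclass(frozen=True)
class SnpAnnotation:
    """A SNP's identity and genomic location (1-based)."""

    snp_id: str
    chromosome: str
    position: int
    counted_allele: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval, 1-based inclusive on both ends."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class PathwayDefinition:
    """A named gene set (GMT semantics)."""

    pathway_id: str
    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"pathway {self.pathway_id}: empty gene set")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"pathway {self.pathway_id}: duplicate gene ids")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive minor-allele counts with binary phenotype.

    ``dosages`` is int8 with values in {0, 1, 2} (or :data:`MISSING` before
    imputation); ``phenotype`` is int8 with 1 = case, 0 = control.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    phenotype: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.ascontiguousarray(self.dosages, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.snp_ids) != p:
            raise ValueError("snp_ids length does not match dosage columns")
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match dosage rows")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be coded 0/1 after loading")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_missing(self) -> int:
        return 0 if self.missing_mask is None else int(self.missing_mask.sum())

    def has_both_classes(self) -> bool:
        return bool((self.phenotype == 1).any() and (self.phenotype == 0).any())


@dataclass(frozen=True)
class PathwaySnpSet:
    """Column indices of a GenotypeMatrix mapped to one pathway."""

    pathway_id: str
    snp_indices: tuple[int, ...]
    n_genes_matched: int

    def __post_init__(self) -> None:
        if len(set(self.snp_indices)) != len(self.snp_indices):
            raise ValueError("snp_indices contains duplicates")

    def __len__(self) -> int:
        return len(self.snp_indices)


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def _detect_phenotype_coding(values: Sequence[str]) -> str:
    uniq = set(values)
    if uniq <= {"1", "2"}:
        return "1/2"
    if uniq <= {"0", "1"}:
        return "0/1"
    raise ParseError(
        f"ambiguous or invalid phenotype values {sorted(uniq)}; "
        "pass phenotype_coding explicitly"
    )


def _map_phenotype(values: Sequence[str], coding: str, path: str) -> np.ndarray:
    if coding == "auto":
        coding = _detect_phenotype_coding(values)
    case, control = ("2", "1") if coding == "1/2" else ("1", "0")
    out = np.empty(len(values), dtype=np.int8)
    for i, v in enumerate(values):
        if v == case:
            out[i] = 1
        elif v == control:
            out[i] = 0
        else:
            raise ParseError(
                f"{path}: phenotype value {v!r} outside {coding} coding "
                f"(sample row {i + 1})"
            )
    return out


def read_additive_genotypes(
    path: str | Path, phenotype_coding: str = "auto"
) -> GenotypeMatrix:
    """Read a PLINK ``--recodeA`` additive-dosage text file.

    Layout: whitespace-separated; header row ``FID IID PAT MAT SEX PHENOTYPE``
    followed by one column per SNP (PLINK appends the counted allele as an
    ``_A`` style suffix, which is split off into the SNP id); then one row per
    sample with dosages in {0, 1, 2, NA}.

    Parameters
    ----------
    phenotype_coding:
        ``"1/2"`` (PLINK: 2 = case, 1 = control), ``"0/1"`` (1 = case) or
        ``"auto"`` to detect.  Files whose phenotype column mixes the two
        codings are rejected.

    Missing dosages are flagged in ``missing_mask``; run
    :func:`impute_missing` before any test.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split()
    if len(header) < 6 or tuple(h.upper() for h in header[:6]) != _LEAD_COLS:
        raise ParseError(
            f"{path}: header must start with the 6 sample columns "
            f"{' '.join(_LEAD_COLS)}"
        )
    raw_snp_cols = header[6:]
    snp_ids: list[str] = []
    counted: list[str | None] = []
    for col in raw_snp_cols:
        if "_" in col:
            sid, allele = col.rsplit("_", 1)
            snp_ids.append(sid)
            counted.append(allele)
        else:
            snp_ids.append(col)
            counted.append(None)
    p = len(snp_ids)
    n = len(lines) - 1
    dosages = np.zeros((n, p), dtype=np.int8)
    missing = np.zeros((n, p), dtype=bool)
    sample_ids: list[str] = []
    pheno_raw: list[str] = []
    for r, line in enumerate(lines[1:], start=2):
        fields = line.split()
        if len(fields) != 6 + p:
            raise ParseError(
                f"{path}: line {r} has {len(fields)} fields, expected {6 + p}"
            )
        sample_ids.append(fields[1])
        pheno_raw.append(fields[5])
        for j, tok in enumerate(fields[6:]):
            if tok in ("NA", "na", "-9"):
                dosages[r - 2, j] = MISSING
                missing[r - 2, j] = True
            elif tok in ("0", "1", "2"):
                dosages[r - 2, j] = int(tok)
            else:
                raise ParseError(
                    f"{path}: line {r}: invalid dosage {tok!r} for SNP {snp_ids[j]}"
                )
    phenotype = _map_phenotype(pheno_raw, phenotype_coding, str(path))
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        dosages=dosages,
        phenotype=phenotype,
        missing_mask=missing if missing.any() else None,
    )


def write_additive_genotypes(
    matrix: GenotypeMatrix, path: str | Path, phenotype_coding: str = "1/2"
) -> None:
    """Write a GenotypeMatrix in the PLINK ``--recodeA`` text dialect."""
    path = Path(path)
    case, control = ("2", "1") if phenotype_coding == "1/2" else ("1", "0")
    with open(path, "w") as fh:
        fh.write(" ".join(_LEAD_COLS) + " " + " ".join(matrix.snp_ids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            ph = case if matrix.phenotype[i] == 1 else control
            row = matrix.dosages[i]
            toks = [
                "NA" if (matrix.missing_mask is not None and matrix.missing_mask[i, j])
                else str(int(row[j]))
                for j in range(matrix.n_snps)
            ]
            fh.write(f"{sid} {sid} 0 0 0 {ph} " + " ".join(toks) + "\n")


def read_matrix_tsv(path: str | Path, phenotype_coding: str = "auto") -> GenotypeMatrix:
    """Read a plain TSV sample-by-SNP matrix.

    First column = sample id, second = phenotype, remaining columns = SNP
    dosages (header row carries SNP ids).
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "sample" or header[1] != "phenotype":
        raise ParseError(f"{path}: header must be sample<TAB>phenotype<TAB>snp...")
    snp_ids = header[2:]
    sample_ids, pheno_raw, rows, miss_rows = [], [], [], []
    for r, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(f"{path}: line {r} has {len(fields)} fields")
        sample_ids.append(fields[0])
        pheno_raw.append(fields[1])
        row = np.empty(len(snp_ids), dtype=np.int8)
        mrow = np.zeros(len(snp_ids), dtype=bool)
        for j, tok in enumerate(fields[2:]):
            if tok in ("NA", ""):
                row[j], mrow[j] = MISSING, True
            else:
                row[j] = int(tok)
        rows.append(row)
        miss_rows.append(mrow)
    missing = np.array(miss_rows)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        dosages=np.array(rows),
        phenotype=_map_phenotype(pheno_raw, phenotype_coding, str(path)),
        missing_mask=missing if missing.any() else None,
    )


def write_matrix_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tphenotype\t" + "\t".join(matrix.snp_ids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            toks = [
                "NA" if (matrix.missing_mask is not None and matrix.missing_mask[i, j])
                else str(int(matrix.dosages[i, j]))
                for j in range(matrix.n_snps)
            ]
            fh.write(f"{sid}\t{int(matrix.phenotype[i])}\t" + "\t".join(toks) + "\n")


def read_map(path: str | Path) -> list[SnpAnnotation]:
    """Read a PLINK ``.map`` file: chrom, snp id, genetic distance, position."""
    out: list[SnpAnnotation] = []
    with open(path) as fh:
        for r, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}: line {r}: expected 4 columns")
            out.append(
                SnpAnnotation(
                    snp_id=fields[1], chromosome=fields[0], position=int(fields[3])
                )
            )
    return out


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a 4-column TSV of gene intervals: id, chrom, start, end (1-based)."""
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for r, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}: line {r}: expected 4 columns")
            out.append(
                GeneAnnotation(
                    gene_id=fields[0],
                    chromosome=fields[1],
                    start=int(fields[2]),
                    end=int(fields[3]),
                )
            )
    return out


def read_bed_genes(path: str | Path) -> list[GeneAnnotation]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for r, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}: line {r}: BED needs chrom,start,end,name")
            out.append(
                GeneAnnotation(
                    gene_id=fields[3],
                    chromosome=fields[0],
                    start=int(fields[1]) + 1,
                    end=int(fields[2]),
                )
            )
    return out


def read_gmt(path: str | Path) -> list[PathwayDefinition]:
    """Read GMT gene sets: name, description, then tab-separated gene ids.

    Duplicate genes within a line are dropped (first occurrence kept).
    """
    out: list[PathwayDefinition] = []
    with open(path) as fh:
        for r, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {r}: GMT needs >= 3 tab-separated fields")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            out.append(
                PathwayDefinition(pathway_id=fields[0], name=fields[1], gene_ids=genes)
            )
    return out


def write_gmt(pathways: Iterable[PathwayDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join((pw.pathway_id, pw.name, *pw.gene_ids)) + "\n")


def impute_missing(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the SNP's most frequent observed dosage.

    Ties break toward the smaller dosage value.  Idempotent; a SNP with all
    values missing is an error.
    """
    if matrix.missing_mask is None or not matrix.missing_mask.any():
        return replace(matrix, missing_mask=None)
    dosages = matrix.dosages.copy()
    mask = matrix.missing_mask
    for j in np.nonzero(mask.any(axis=0))[0]:
        observed = dosages[~mask[:, j], j]
        if observed.size == 0:
            raise ValueError(
                f"SNP {matrix.snp_ids[j]}: all genotypes missing, cannot impute"
            )
        counts = np.bincount(observed, minlength=3)
        mode = int(np.argmax(counts))  # argmax takes the first (smallest) on ties
        dosages[mask[:, j], j] = mode
    return GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        snp_ids=list(matrix.snp_ids),
        dosages=dosages,
        phenotype=matrix.phenotype.copy(),
        missing_mask=None,
    )


def map_snps_to_pathway(
    pathway: PathwayDefinition,
    genes: Sequence[GeneAnnotation],
    snps: Sequence[SnpAnnotation],
    window_kb: float = 20.0,
) -> PathwaySnpSet:
    """Map SNPs to a pathway through a window around its genes' bodies.

    A SNP belongs to the pathway iff it lies on the same chromosome as some
    pathway gene and its position falls in ``[start - w, end + w]`` with
    ``w = round(window_kb * 1000)`` bp, boundaries inclusive.  Each SNP is
    included once however many genes it hits; pathway genes absent from the
    annotation are skipped and reflected in ``n_genes_matched``.
    """
    if window_kb < 0:
        raise ValueError("window_kb must be >= 0")
    window = round(window_kb * 1000)
    by_id = {g.gene_id: g for g in genes}
    matched = [by_id[g] for g in pathway.gene_ids if g in by_id]
    indices: list[int] = []
    for j, snp in enumerate(snps):
        for gene in matched:
            if snp.chromosome == gene.chromosome and (
                gene.start - window <= snp.position <= gene.end + window
            ):
                indices.append(j)
                break
    return PathwaySnpSet(
        pathway_id=pathway.pathway_id,
        snp_indices=tuple(indices),
        n_genes_matched=len(matched),
    )
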