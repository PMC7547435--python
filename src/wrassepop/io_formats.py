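"""Readers, writers and in-memory containers for the pipeline's formats.

Three kinds of input circulate through the pipeline:

* multi-sample VCFs of biallelic SNPs (read via :mod:`cyvcf2`),
* plain-text genotype matrices (individuals x loci, diploid dosage codes),
* two-column k-mer frequency histograms (multiplicity, count).

Genotypes are always coded as the number of ALT (or minor) allele copies —
0, 1 or 2 — with ``-1`` as the missing sentinel.  Missing data is never
imputed at I/O time.  Positions are 1-based, as in VCF.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("wrassepop")

MISSING = -1


class FormatError(ValueError):
    """Raised when an input file violates its expected layout."""


@dataclass
class Locus:
    """A biallelic SNP locus: contig, 1-based position and an identifier."""

    contig: str
    pos: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")
        if not self.id:
            self.id = f"{self.contig}:{self.pos}"


@dataclass
class SiteRecord:
    """One biallelic VCF site with its quality annotations and genotypes.

    ``genotypes`` hold ALT-allele dosages per sample (0/1/2, -1 missing).
    ``sample_depths`` carries per-sample FORMAT/DP when the VCF provides it;
    otherwise it is None and ``depth`` (site INFO/DP) stands for every sample.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float
    depth: float
    mapq: float
    genotypes: np.ndarray
    sample_depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.qual < 0 or self.depth < 0:
            raise ValueError("qual and depth must be non-negative")


@dataclass
class GenotypeMatrix:
    """Diploid dosage codes for individuals x loci with population labels.

    ``codes`` is an (n_individuals, n_loci) int8/int16 array in {0, 1, 2, -1}.
    Loci are kept sorted by (contig, pos) and must be unique by coordinate.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[Locus]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        n_ind, n_loc = self.codes.shape
        if len(self.individuals) != n_ind:
            raise ValueError("individuals/codes dimension mismatch")
        if len(self.populations) != n_ind:
            raise ValueError("every individual needs a population label")
        if len(self.loci) != n_loc:
            raise ValueError("loci/codes dimension mismatch")
        coords = [(l.contig, l.pos) for l in self.loci]
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate (contig, pos) among loci")
        if coords != sorted(coords):
            idx = np.lexsort((
                [l.pos for l in self.loci], [l.contig for l in self.loci]
            ))
            self.loci = [self.loci[i] for i in idx]
            self.codes = self.codes[:, idx]
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def pop_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self) -> dict[str, np.ndarray]:
        pops = np.asarray(self.populations)
        return {p: np.flatnonzero(pops == p) for p in self.pop_names}

    def subset_loci(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            populations=list(self.populations),
            loci=[self.loci[i] for i in keep],
            codes=self.codes[:, keep],
        )

    def subset_individuals(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in keep],
            populations=[self.populations[i] for i in keep],
            loci=list(self.loci),
            codes=self.codes[keep, :],
        )


@dataclass
class KmerHistogram:
    """Histogram of k-mer multiplicities: multiplicity (>=1) -> distinct count."""

    k: int
    entries: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[int, int] = {}
        for m in sorted(self.entries):
            c = self.entries[m]
            if m < 1:
                raise ValueError("multiplicities must be >= 1")
            if c < 0:
                raise ValueError("counts must be >= 0")
            cleaned[int(m)] = int(c)
        self.entries = cleaned

    @property
    def multiplicities(self) -> np.ndarray:
        return np.fromiter(self.entries.keys(), dtype=np.int64)

    @property
    def counts(self) -> np.ndarray:
        return np.fromiter(self.entries.values(), dtype=np.int64)

    @property
    def total_distinct(self) -> int:
        return int(self.counts.sum())

    @property
    def total_observations(self) -> int:
        return int((self.multiplicities * self.counts).sum())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    population_map: Mapping[str, str] | None = None,
) -> Iterator[SiteRecord]:
    """Stream biallelic SNP records from a VCF.

    Multi-allelic and non-SNP records are skipped with a logged warning.
    If ``population_map`` is given, every VCF sample must appear in it.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if population_map is not None:
        absent = [s for s in samples if s not in population_map]
        if absent:
            raise FormatError(
                f"individuals absent from population map: {absent}"
            )
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            logger.warning(
                "skipping non-biallelic-SNP record %s:%s", var.CHROM, var.POS
            )
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        depths = None
        try:
            d = var.format("DP")
            if d is not None:
                depths = np.asarray(d, dtype=float).reshape(-1)
        except KeyError:
            pass
        mq = var.INFO.get("MQ")
        yield SiteRecord(
            contig=var.CHROM,
            pos=var.POS,
            ref_allele=var.REF,
            alt_allele=var.ALT[0],
            qual=float(var.QUAL) if var.QUAL is not None else 0.0,
            depth=float(var.INFO.get("DP", 0.0)),
            mapq=float(mq) if mq is not None else 0.0,
            genotypes=gt,
            sample_depths=depths,
        )


def vcf_samples(path: str | Path) -> list[str]:
    from cyvcf2 import VCF

    return list(VCF(str(path)).samples)


def records_to_matrix(
    records: Sequence[SiteRecord],
    individuals: Sequence[str],
    population_map: Mapping[str, str],
) -> GenotypeMatrix:
    """Assemble SiteRecords into a GenotypeMatrix (columns sorted by coordinate)."""
    loci = [Locus(r.contig, r.pos) for r in records]
    codes = (
        np.stack([r.genotypes for r in records], axis=1)
        if records
        else np.zeros((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        individuals=list(individuals),
        populations=[population_map[s] for s in individuals],
        loci=loci,
        codes=codes,
    )


def write_vcf(path: str | Path, g: GenotypeMatrix,
              qual: float = 900.0, dp: int = 100, mq: float = 60.0) -> None:
    """Write a minimal VCF 4.2 for a GenotypeMatrix (synthetic-data plumbing)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="MapQ">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        contigs = {l.contig for l in g.loci}
        for c in sorted(contigs):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individuals) + "\n"
        )
        for j, loc in enumerate(g.loci):
            cells = "\t".join(
                f"{gt_str[int(c)]}:{dp}" for c in g.codes[:, j]
            )
            fh.write(
                f"{loc.contig}\t{loc.pos}\t{loc.id}\tA\tG\t{qual:g}\t.\t"
                f"DP={dp};MQ={mq:g}\tGT:DP\t{cells}\n"
            )


# ---------------------------------------------------------------------------
# Genotype tables
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read a tab-separated genotype matrix.

    The canonical orientation is individuals as rows with columns
    ``individual``, ``population``, then one column per locus id
    (``contig:pos``).  A transposed table (loci as rows, header starting
    with ``locus``) is auto-detected and flipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty genotype table")
    first = df.columns[0].lower()
    if first in ("locus", "locus_id", "snp", "marker"):
        # loci-as-rows orientation: columns are locus, contig?, pos?, individuals
        df = df.set_index(df.columns[0])
        meta_cols = [c for c in df.columns if c.lower() in ("contig", "pos")]
        meta = df[meta_cols]
        body = df.drop(columns=meta_cols).T
        body.index.name = "individual"
        body = body.reset_index()
        body.insert(1, "population", "pop1")
        return _frame_to_matrix(body, loci_meta=meta)
    if first not in ("individual", "id", "sample"):
        raise FormatError(
            f"{path}: cannot detect orientation from header column '{df.columns[0]}'"
        )
    return _frame_to_matrix(df)


def _frame_to_matrix(df: pd.DataFrame, loci_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    cols = list(df.columns)
    if len(cols) < 3 or cols[1].lower() not in ("population", "pop"):
        raise FormatError("expected columns: individual, population, <loci...>")
    individuals = df.iloc[:, 0].astype(str).tolist()
    populations = df.iloc[:, 1].astype(str).tolist()
    locus_ids = cols[2:]
    raw = df.iloc[:, 2:].to_numpy(dtype=object)
    codes = np.empty(raw.shape, dtype=np.int8)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            s = "NA" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if s in ("NA", "", "."):
                codes[i, j] = MISSING
            elif s in ("0", "1", "2"):
                codes[i, j] = int(s)
            else:
                raise FormatError(
                    f"invalid genotype {s!r} at row {i + 2}, column {locus_ids[j]!r}"
                )
    loci = []
    for lid in locus_ids:
        if loci_meta is not None and lid in loci_meta.index and "contig" in [c.lower() for c in loci_meta.columns]:
            row = loci_meta.loc[lid]
            contig = str(row[[c for c in loci_meta.columns if c.lower() == "contig"][0]])
            pos = int(row[[c for c in loci_meta.columns if c.lower() == "pos"][0]])
            loci.append(Locus(contig, pos, str(lid)))
        elif ":" in str(lid):
            contig, pos = str(lid).rsplit(":", 1)
            # ids may carry a non-numeric suffix after the position
            digits = re.match(r"(\d+)", pos)
            if digits is None:
                raise FormatError(f"cannot parse position from locus id {lid!r}")
            loci.append(Locus(contig, int(digits.group(1)), str(lid)))
        else:
            loci.append(Locus(str(lid), 1, str(lid)))
    return GenotypeMatrix(individuals, populations, loci, codes)


def write_genotype_table(path: str | Path, g: GenotypeMatrix) -> None:
    """Write a GenotypeMatrix as the canonical individuals-as-rows TSV."""
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\t" + "\t".join(l.id for l in g.loci) + "\n")
        for i, ind in enumerate(g.individuals):
            row = "\t".join(
                "NA" if c == MISSING else str(int(c)) for c in g.codes[i]
            )
            fh.write(f"{ind}\t{g.populations[i]}\t{row}\n")


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (individual, population) whitespace/tab mapping."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected two columns")
            mapping[parts[0]] = parts[1]
    return mapping


# ---------------------------------------------------------------------------
# K-mer histograms
# ---------------------------------------------------------------------------

def read_kmer_histogram(path: str | Path, k: int = 32) -> KmerHistogram:
    """Read a two-column (multiplicity, count) histogram text file."""
    entries: dict[int, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected two columns")
            try:
                m, c = int(parts[0]), int(parts[1])
            except ValueError as err:
                raise FormatError(f"{path}:{ln}: non-integer field") from err
            entries[m] = c
    if not entries:
        raise FormatError(f"{path}: empty histogram")
    return KmerHistogram(k=k, entries=entries)


def write_kmer_histogram(path: str | Path, hist: KmerHistogram) -> None:
    with open(path, "w") as fh:
        for m in sorted(hist.entries):
            fh.write(f"{m} {hist.entries[m]}\n")
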