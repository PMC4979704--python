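"""Genotype table I/O: a simple TSV dialect, VCF, batch merging, dosage coding.

Genotypes are unphased unordered pairs of allele symbols (A/C/G/T) at
biallelic SNP loci. Missingness is preserved at this layer and never imputed;
each downstream analysis declares its own missing-data policy.

TSV dialect: header ``sample_id  habitat  batch  <locus_1> <locus_2> ...``,
one row per sample, cells two-letter genotype strings ("AC", alphabetical)
or "NA". A companion locus file maps ``locus_id -> linkage_group``.

VCF: v4.2 biallelic SNP records with GT; sample habitat/batch travel in a
sidecar metadata TSV (columns sample_id, habitat, batch), not in VCF headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MISSING",
    "HABITATS",
    "GenotypeTable",
    "DosageMatrix",
    "GenotypeError",
    "MalformedHeaderError",
    "TriallelicLocusError",
    "UnknownHabitatError",
    "DuplicateIdError",
    "MultiallelicRecordError",
    "MissingMetadataError",
    "EmptyLocusIntersectionError",
    "OverlappingSamplesError",
    "AllMissingLocusError",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_vcf",
    "write_vcf",
    "merge_batches",
    "to_dosage",
]

#: Sentinel for a missing genotype call.
MISSING = ""

#: Valid habitat labels (sampling zones of the lake).
HABITATS = ("littoral", "benthic", "pelagic")

_ALLELES = set("ACGT")


class GenotypeError(ValueError):
    """Base class for genotype-data validation errors."""


class MalformedHeaderError(GenotypeError):
    """TSV header does not start with sample_id/habitat/batch."""


class TriallelicLocusError(GenotypeError):
    """More than two distinct allele symbols observed at one locus."""


class UnknownHabitatError(GenotypeError):
    """Habitat label outside {littoral, benthic, pelagic}."""


class DuplicateIdError(GenotypeError):
    """Duplicate sample or locus identifier."""


class MultiallelicRecordError(GenotypeError):
    """VCF record with more than one ALT allele."""


class MissingMetadataError(GenotypeError):
    """VCF sample without a sidecar metadata row."""


class EmptyLocusIntersectionError(GenotypeError):
    """Batch merge with no loci in common."""


class OverlappingSamplesError(GenotypeError):
    """Batch merge with shared sample ids."""


class AllMissingLocusError(GenotypeError):
    """Locus with no non-missing calls cannot be dosage-coded."""


def _norm_call(call: str) -> str:
    """Canonicalize an unphased genotype string (alphabetical allele order)."""
    if call == MISSING:
        return MISSING
    return "".join(sorted(call))


@dataclass
class GenotypeTable:
    """Samples x loci unphased genotype calls with sample/locus metadata.

    ``calls[i, j]`` is a two-character string of allele symbols (alphabetical,
    e.g. "AC") or :data:`MISSING`.
    """

    sample_ids: list[str]
    habitat: list[str]
    batch: list[int]
    locus_ids: list[str]
    linkage_group: list[int]
    calls: np.ndarray  # (n_samples, n_loci) dtype=object

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIdError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise DuplicateIdError("duplicate locus ids")
        for h in self.habitat:
            if h not in HABITATS:
                raise UnknownHabitatError(f"unknown habitat label {h!r}")
        if self.calls.shape != (self.n_samples, self.n_loci):
            raise GenotypeError(
                f"calls shape {self.calls.shape} != "
                f"({self.n_samples}, {self.n_loci})"
            )
        for j, locus in enumerate(self.locus_ids):
            alleles = self.locus_alleles(j)
            if len(alleles) > 2:
                raise TriallelicLocusError(
                    f"locus {locus} carries alleles {sorted(alleles)}"
                )
            if not alleles <= _ALLELES:
                raise GenotypeError(
                    f"locus {locus}: allele outside ACGT: {sorted(alleles)}"
                )

    def locus_alleles(self, j: int) -> set[str]:
        """Distinct allele symbols observed at locus column ``j``."""
        alleles: set[str] = set()
        for call in self.calls[:, j]:
            if call != MISSING:
                alleles.update(call)
        return alleles

    def subset_loci(self, locus_ids: list[str]) -> "GenotypeTable":
        idx = [self.locus_ids.index(l) for l in locus_ids]
        return GenotypeTable(
            sample_ids=list(self.sample_ids),
            habitat=list(self.habitat),
            batch=list(self.batch),
            locus_ids=list(locus_ids),
            linkage_group=[self.linkage_group[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )


@dataclass
class DosageMatrix:
    """Minor-allele dosage coding (0/1/2, -1 for missing) of a genotype table.

    The minor allele at each locus is the less frequent one over all
    non-missing calls; at an exact 0.50/0.50 tie the alphabetically later
    symbol is taken as minor (deterministic; estimators are invariant to the
    choice). A locus monomorphic in the sample has minor_allele "" and all
    dosages 0.
    """

    values: np.ndarray  # (n_samples, n_loci) int8, -1 = missing
    minor_allele: list[str]
    major_allele: list[str]
    sample_ids: list[str]
    habitat: list[str]
    batch: list[int]
    locus_ids: list[str]
    linkage_group: list[int]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def minor_freq(self) -> np.ndarray:
        """Per-locus minor-allele frequency over non-missing calls."""
        ok = self.values >= 0
        n = ok.sum(axis=0)
        tot = np.where(ok, self.values, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def subset(self, samples=None, loci=None) -> "DosageMatrix":
        """Row/column subset by integer index arrays (None = keep all)."""
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        li = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return DosageMatrix(
            values=self.values[np.ix_(si, li)].copy(),
            minor_allele=[self.minor_allele[i] for i in li],
            major_allele=[self.major_allele[i] for i in li],
            sample_ids=[self.sample_ids[i] for i in si],
            habitat=[self.habitat[i] for i in si],
            batch=[self.batch[i] for i in si],
            locus_ids=[self.locus_ids[i] for i in li],
            linkage_group=[self.linkage_group[i] for i in li],
        )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_genotype_tsv(path, locus_path=None) -> GenotypeTable:
    """Read the genotype TSV dialect (optionally with its companion locus file).

    Parameters
    ----------
    path
        Genotype TSV: header ``sample_id habitat batch <locus...>``.
    locus_path
        Optional TSV mapping ``locus_id -> linkage_group``; loci absent from
        the file (or if the file is omitted) get linkage group 0.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise MalformedHeaderError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if header[:3] != ["sample_id", "habitat", "batch"]:
        raise MalformedHeaderError(
            f"{path}: header must start with sample_id/habitat/batch, "
            f"got {header[:3]}"
        )
    locus_ids = header[3:]
    lg_map: dict[str, int] = {}
    if locus_path is not None:
        for line in Path(locus_path).read_text().splitlines():
            if not line.strip() or line.startswith("locus_id"):
                continue
            lid, lg = line.split("\t")[:2]
            lg_map[lid] = int(lg)

    sample_ids, habitat, batch, rows = [], [], [], []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 3 + len(locus_ids):
            raise GenotypeError(
                f"{path}: row for {fields[0]!r} has {len(fields)} fields, "
                f"expected {3 + len(locus_ids)}"
            )
        sample_ids.append(fields[0])
        habitat.append(fields[1])
        batch.append(int(fields[2]))
        row = []
        for cell in fields[3:]:
            if cell in ("NA", "", "."):
                row.append(MISSING)
            else:
                if len(cell) != 2 or not set(cell) <= _ALLELES:
                    raise GenotypeError(f"{path}: bad genotype cell {cell!r}")
                row.append(_norm_call(cell))
        rows.append(row)

    calls = np.empty((len(sample_ids), len(locus_ids)), dtype=object)
    for i, row in enumerate(rows):
        calls[i, :] = row
    return GenotypeTable(
        sample_ids=sample_ids,
        habitat=habitat,
        batch=batch,
        locus_ids=locus_ids,
        linkage_group=[lg_map.get(l, 0) for l in locus_ids],
        calls=calls,
    )


def write_genotype_tsv(table: GenotypeTable, path, locus_path=None) -> None:
    """Write a genotype table (and optional companion locus file) as TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", "habitat", "batch"] + table.locus_ids))
        fh.write("\n")
        for i, sid in enumerate(table.sample_ids):
            cells = [
                c if c != MISSING else "NA" for c in table.calls[i, :]
            ]
            fh.write(
                "\t".join([sid, table.habitat[i], str(table.batch[i])] + cells)
            )
            fh.write("\n")
    if locus_path is not None:
        with open(locus_path, "w") as fh:
            fh.write("locus_id\tlinkage_group\n")
            for lid, lg in zip(table.locus_ids, table.linkage_group):
                fh.write(f"{lid}\t{lg}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(table: GenotypeTable, path) -> None:
    """Write a minimal VCF 4.2 with synthetic coordinates.

    Linkage group is used as the contig name ("LG<k>"), the locus index + 1
    as the position, and the locus id as the record ID. REF is the
    alphabetically first observed allele (placeholder "A" for a locus with no
    observed calls); unordered genotypes are emitted unphased.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for lg in sorted({f"LG{g}" for g in table.linkage_group}):
        lines.append(f"##contig=<ID={lg}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.sample_ids)
    )
    for j, lid in enumerate(table.locus_ids):
        alleles = sorted(table.locus_alleles(j))
        if not alleles:
            alleles = ["A"]
        ref = alleles[0]
        alt = alleles[1] if len(alleles) > 1 else "."
        gts = []
        for call in table.calls[:, j]:
            if call == MISSING:
                gts.append("./.")
            else:
                a, b = sorted(0 if c == ref else 1 for c in call)
                gts.append(f"{a}/{b}")
        lines.append(
            "\t".join(
                [f"LG{table.linkage_group[j]}", str(j + 1), lid, ref, alt,
                 ".", "PASS", ".", "GT"] + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_sample_metadata(path) -> dict[str, tuple[str, int]]:
    """Read the sidecar sample metadata TSV (sample_id, habitat, batch)."""
    meta: dict[str, tuple[str, int]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("sample_id"):
            continue
        sid, hab, b = line.split("\t")[:3]
        meta[sid] = (hab, int(b))
    return meta


def read_vcf(path, metadata_path) -> GenotypeTable:
    """Read biallelic SNP records with GT fields from a VCF.

    "./." genotypes become :data:`MISSING`. Habitat/batch come from the
    sidecar metadata TSV; a VCF sample absent from it raises
    :class:`MissingMetadataError`. A record with more than one ALT allele
    raises :class:`MultiallelicRecordError`.
    """
    from cyvcf2 import VCF

    meta = read_sample_metadata(metadata_path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    for sid in sample_ids:
        if sid not in meta:
            raise MissingMetadataError(f"no metadata row for sample {sid!r}")

    locus_ids, linkage_group, columns = [], [], []
    for var in vcf:
        if var.ALT and len(var.ALT) > 1:
            raise MultiallelicRecordError(
                f"record {var.ID or var.POS} has ALT alleles {var.ALT}"
            )
        alleles = [var.REF] + list(var.ALT)
        locus_ids.append(var.ID if var.ID not in (None, ".") else
                         f"{var.CHROM}_{var.POS}")
        chrom = var.CHROM
        linkage_group.append(
            int(chrom[2:]) if chrom.startswith("LG") and chrom[2:].isdigit()
            else 0
        )
        col = []
        for a, b, *_ in var.genotypes:
            if a < 0 or b < 0:
                col.append(MISSING)
            else:
                col.append(_norm_call(alleles[a] + alleles[b]))
        columns.append(col)
    vcf.close()

    calls = np.empty((len(sample_ids), len(locus_ids)), dtype=object)
    for j, col in enumerate(columns):
        calls[:, j] = col
    return GenotypeTable(
        sample_ids=sample_ids,
        habitat=[meta[s][0] for s in sample_ids],
        batch=[meta[s][1] for s in sample_ids],
        locus_ids=locus_ids,
        linkage_group=linkage_group,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Merging and dosage coding
# ---------------------------------------------------------------------------

def merge_batches(t1: GenotypeTable, t2: GenotypeTable) -> GenotypeTable:
    """Union of samples restricted to the loci shared by both batches.

    Locus order follows ``t1``. Sample ids must be disjoint; an empty locus
    intersection is an error.
    """
    overlap = set(t1.sample_ids) & set(t2.sample_ids)
    if overlap:
        raise OverlappingSamplesError(f"shared sample ids: {sorted(overlap)}")
    common = [l for l in t1.locus_ids if l in set(t2.locus_ids)]
    if not common:
        raise EmptyLocusIntersectionError("no loci shared between batches")
    a = t1.subset_loci(common)
    b = t2.subset_loci(common)
    return GenotypeTable(
        sample_ids=a.sample_ids + b.sample_ids,
        habitat=a.habitat + b.habitat,
        batch=a.batch + b.batch,
        locus_ids=common,
        linkage_group=a.linkage_group,
        calls=np.vstack([a.calls, b.calls]),
    )


def to_dosage(table: GenotypeTable) -> DosageMatrix:
    """Code genotypes as minor-allele dosages (0/1/2; -1 missing).

    Major/minor assignment is by frequency over all non-missing calls at the
    locus; an exact tie makes the alphabetically later symbol minor. Raises
    :class:`AllMissingLocusError` for a locus with no calls at all.
    """
    n, L = table.calls.shape
    values = np.full((n, L), -1, dtype=np.int8)
    minor, major = [], []
    for j, lid in enumerate(table.locus_ids):
        counts: dict[str, int] = {}
        for call in table.calls[:, j]:
            if call != MISSING:
                for c in call:
                    counts[c] = counts.get(c, 0) + 1
        if not counts:
            raise AllMissingLocusError(f"locus {lid}: all calls missing")
        if len(counts) == 1:
            maj = next(iter(counts))
            mnr = ""
        else:
            (a1, c1), (a2, c2) = sorted(counts.items())
            if c1 == c2:
                maj, mnr = a1, a2  # tie: alphabetically later symbol is minor
            elif c1 > c2:
                maj, mnr = a1, a2
            else:
                maj, mnr = a2, a1
        major.append(maj)
        minor.append(mnr)
        for i in range(n):
            call = table.calls[i, j]
            if call != MISSING:
                values[i, j] = sum(1 for c in call if c == mnr)
    return DosageMatrix(
        values=values,
        minor_allele=minor,
        major_allele=major,
        sample_ids=list(table.sample_ids),
        habitat=list(table.habitat),
        batch=list(table.batch),
        locus_ids=list(table.locus_ids),
        linkage_group=list(table.linkage_group),
    )
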